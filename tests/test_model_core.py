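"""Model data structures, I/O round trips, media and edit primitives."""

import pytest

from ringfba.fba_engine import fba
from ringfba.model_core import (
    BiomassComponent,
    MediumSpec,
    ModelError,
    SBMLParseError,
    add_biomass_component,
    add_intercompartment_exchange,
    apply_medium,
    base_name,
    load_reaction_table,
    load_sbml,
    parse_equation,
    remove_biomass_component,
    sbml_string,
    validate_model,
    write_sbml,
    yes_medium,
)
from ringfba.synthetic_models import random_growth_model


# -- equation / table parsing -----------------------------------------------

@pytest.mark.parametrize(
    "eq, expected, reversible",
    [
        ("1 A[c] + 2 B[c] -> 1 C[c]", {"A[c]": -1, "B[c]": -2, "C[c]": 1}, False),
        ("glc[e] <=> ", {"glc[e]": -1}, True),
        ("A[c] + B[c] <=> C[m]", {"A[c]": -1, "B[c]": -1, "C[m]": 1}, True),
        ("0.5 A[c] -> ", {"A[c]": -0.5}, False),
    ],
)
def test_equation_parsing_sign_convention(eq, expected, reversible):
    stoich, rev = parse_equation(eq)
    assert stoich == expected
    assert rev is reversible


@pytest.mark.parametrize("bad", ["A[c] B[c]", "A -> B", "-> "])
def test_unparseable_equations_rejected(bad):
    with pytest.raises(ModelError):
        parse_equation(bad)


def test_reaction_table_load(tmp_path):
    table = tmp_path / "model.tsv"
    table.write_text(
        "id\tequation\tlower_bound\tupper_bound\tgenes\tkind\n"
        "EX_a\ta[e] <=> \t-5\t1000\t\texchange\n"
        "T_a\ta[e] -> a[c]\t\t\tg1\ttransport\n"
        "CONV\t1 a[c] -> 2 b[c]\t\t\tg2,g3\tmetabolic\n"
        "BM\tb[c] -> \t\t\t\tbiomass\n"
    )
    model = load_reaction_table(table)
    assert model.reactions["CONV"].stoichiometry == {"a[c]": -1.0, "b[c]": 2.0}
    assert model.reactions["CONV"].genes == frozenset({"g2", "g3"})
    assert model.reactions["EX_a"].lower_bound == -5
    assert model.reactions["T_a"].lower_bound == 0.0  # irreversible arrow
    assert fba(model).growth == pytest.approx(10.0)  # 5 uptake * 2


def test_reaction_table_duplicate_id_rejected(tmp_path):
    table = tmp_path / "dup.tsv"
    table.write_text(
        "id\tequation\tlower_bound\tupper_bound\tgenes\tkind\n"
        "R1\ta[e] <=> \t\t\t\texchange\n"
        "R1\ta[e] -> \t\t\t\texchange\n"
    )
    with pytest.raises(ModelError, match="duplicate"):
        load_reaction_table(table)


# -- invariants -------------------------------------------------------------

def test_undeclared_metabolite_rejected(core_model):
    broken = core_model.copy()
    broken.reactions["GLY"].stoichiometry["ghost[c]"] = 1.0
    with pytest.raises(ModelError, match="ghost"):
        broken.check()


def test_two_biomass_reactions_rejected(core_model):
    broken = core_model.copy()
    broken.reactions["LDH"].kind = "biomass"
    with pytest.raises(ModelError, match="biomass"):
        broken.check()


# -- SBML round trips -------------------------------------------------------

def test_sbml_round_trip_identity(core_model, tmp_path):
    path = tmp_path / "core.xml"
    write_sbml(core_model, path)
    back = load_sbml(path)
    assert core_model.structurally_equal(back)


def test_sbml_round_trip_preserves_ring_edit_and_annotations(core_model, tmp_path):
    edited, rid = add_intercompartment_exchange(core_model, "accoa", "m", "c")
    edited.excluded_reactions.add("LDH")
    edited.deletion_overrides["GLY"] = frozenset({"GLY", "PDC"})
    edited.balance_exempt.add("hemeX")
    path = tmp_path / "edited.xml"
    write_sbml(edited, path)
    back = load_sbml(path)
    assert edited.structurally_equal(back)
    assert back.reactions[rid].provenance == "RING-added"
    assert "hemeX" in back.balance_exempt
    # second pass is byte-stable
    assert sbml_string(back) == sbml_string(edited)


def test_foreign_level2_sbml_with_gene_notes(tmp_path):
    text = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="toy">
  <listOfCompartments><compartment id="c"/><compartment id="e"/></listOfCompartments>
  <listOfSpecies>
   <species id="A_e" compartment="e"/>
   <species id="A_c" compartment="c"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="EX_A" reversible="true">
    <listOfReactants><speciesReference species="A_e"/></listOfReactants>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML"><ci>FLUX_VALUE</ci></math>
     <listOfParameters>
      <parameter id="LOWER_BOUND" value="-10"/>
      <parameter id="UPPER_BOUND" value="1000"/>
      <parameter id="FLUX_VALUE" value="0"/>
     </listOfParameters>
    </kineticLaw>
   </reaction>
   <reaction id="T_A" reversible="false">
    <notes><body xmlns="http://www.w3.org/1999/xhtml">
      <p>GENE_ASSOCIATION: (gA and gB) or gC</p>
    </body></notes>
    <listOfReactants><speciesReference species="A_e"/></listOfReactants>
    <listOfProducts><speciesReference species="A_c"/></listOfProducts>
   </reaction>
   <reaction id="biomass" reversible="false">
    <listOfReactants><speciesReference species="A_c"/></listOfReactants>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""
    path = tmp_path / "legacy.xml"
    path.write_text(text)
    with pytest.warns(UserWarning, match="flattened"):
        model = load_sbml(path)
    assert model.reactions["T_A"].genes == frozenset({"gA", "gB", "gC"})
    assert model.reactions["EX_A"].lower_bound == -10
    assert model.objective_id == "biomass"
    assert fba(model).growth == pytest.approx(10.0)


def test_malformed_sbml_raises_parse_error(tmp_path):
    path = tmp_path / "broken.xml"
    path.write_text("<sbml><model><unclosed></model></sbml>")
    with pytest.raises(SBMLParseError):
        load_sbml(path)


# -- validation -------------------------------------------------------------

def test_clean_model_validates_empty(core_model):
    assert validate_model(core_model) == []


def test_planted_carbon_imbalance_found(core_model):
    broken = core_model.copy()
    # glc (C6) -> 3 pyr (3x C3 = C9): carbon imbalance of +3
    broken.reactions["GLY"].stoichiometry["pyr[c]"] = 3.0
    findings = validate_model(broken)
    assert [f.kind for f in findings] == ["element_imbalance"]
    assert findings[0].members == ("GLY",)

    # independent per-reaction element-count oracle
    def carbon_balance(rxn, model):
        total = 0.0
        for met, coef in rxn.stoichiometry.items():
            formula = model.metabolites[met].formula
            total += coef * float(formula[1:] or 1)
        return total

    assert carbon_balance(broken.reactions["GLY"], broken) == pytest.approx(3.0)
    assert carbon_balance(core_model.reactions["GLY"], core_model) == pytest.approx(0.0)


def test_balance_exempt_metabolite_never_flagged(core_model):
    from ringfba.model_core import Metabolite

    model = core_model.copy()
    model.metabolites["h2o[c]"] = Metabolite("h2o[c]", "water", "c", "H2O")
    # produce water without balancing it anywhere
    model.reactions["GLY"].stoichiometry["h2o[c]"] = 1.0
    assert validate_model(model) == []


# -- media ------------------------------------------------------------------

def test_yes_medium_sets_glucose_uptake(core_model):
    medium = yes_medium(core_model)
    applied = apply_medium(core_model, medium)
    assert applied.reactions["EX_glc"].lower_bound == pytest.approx(-4.19)
    assert fba(applied).growth == pytest.approx(4.19)


def test_empty_medium_closes_all_uptakes(core_model):
    applied = apply_medium(core_model, MediumSpec("empty", {}))
    assert all(r.lower_bound == 0.0 for r in applied.exchanges())
    assert fba(applied).growth == pytest.approx(0.0)


def test_medium_with_unknown_exchange_rejected(core_model):
    medium = MediumSpec("bad", {"EX_unobtainium": (-1, 1)})
    with pytest.raises(ModelError, match="EX_unobtainium"):
        apply_medium(core_model, medium)


# -- biomass component edits ------------------------------------------------

def test_negligible_biomass_component_barely_perturbs_growth(core_model):
    mu0 = fba(core_model).growth
    edited = add_biomass_component(core_model, BiomassComponent("lac[c]"))
    mu1 = fba(edited).growth
    assert abs(mu1 - mu0) / mu0 < 1e-3


def test_unproducible_biomass_component_kills_growth(core_model):
    # cit[m] only cycles inside the TCA loop; a net drain cannot be supplied
    edited = add_biomass_component(core_model, BiomassComponent("cit[m]"))
    assert fba(edited).growth == pytest.approx(0.0)


def test_biomass_component_add_then_remove_is_identity(core_model):
    edited = add_biomass_component(core_model, BiomassComponent("lac[c]", 0.01))
    restored = remove_biomass_component(edited, "lac[c]")
    assert restored.structurally_equal(core_model)
    with pytest.raises(ModelError, match="already"):
        add_biomass_component(edited, BiomassComponent("lac[c]"))


# -- intercompartment exchange ----------------------------------------------

def test_exchange_addition_unlocks_cross_compartment_supply(core_model):
    from ringfba.knockout_sim import delete_reactions

    model = core_model.copy()
    model.biomass.stoichiometry.pop("accoa[m]")
    model.biomass.stoichiometry["accoa[c]"] = -1.0
    model.metabolites["accoa[c]"] = type(model.metabolites["accoa[m]"])(
        "accoa[c]", "accoa", "c", "C2"
    )
    from ringfba.model_core import Reaction

    model.reactions["ACS"] = Reaction(
        "ACS", {"pyr[c]": -1.0, "accoa[c]": 1.0, "co2[c]": 1.0},
        lower_bound=0.0, upper_bound=1000.0, genes=frozenset({"g_acs"}),
    )
    assert delete_reactions(model, ["ACS"]).predicted == "lethal"
    linked, _ = add_intercompartment_exchange(model, "accoa", "m", "c")
    assert delete_reactions(linked, ["ACS"]).predicted == "viable"


def test_exchange_addition_on_connected_model_is_neutral(core_model):
    mu0 = fba(core_model).growth
    linked, _ = add_intercompartment_exchange(core_model, "co2", "m", "c")
    assert fba(linked).growth == pytest.approx(mu0)


def test_exchange_addition_same_compartment_rejected(core_model):
    with pytest.raises(ModelError):
        add_intercompartment_exchange(core_model, "pyr", "c", "c")


def test_exchange_addition_is_pure_relaxation(rng):
    """Adding a transport never decreases the optimum (random models)."""
    for _ in range(25):
        model = random_growth_model(rng)
        mu0 = fba(model).growth
        mets = sorted({base_name(m) for m in model.metabolites if m.endswith("[c]")})
        pick = mets[int(rng.integers(0, len(mets)))]
        linked, _ = add_intercompartment_exchange(model, pick, "c", "m")
        assert fba(linked).growth >= mu0 - 1e-9


def test_edits_leave_input_model_unchanged(core_model):
    snapshot = core_model.canonical_json()
    add_biomass_component(core_model, BiomassComponent("lac[c]"))
    add_intercompartment_exchange(core_model, "pyr", "c", "m")
    apply_medium(core_model, MediumSpec("empty", {}))
    assert core_model.canonical_json() == snapshot
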