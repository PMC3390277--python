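"""Discrepancy categorization, reconciliation actions, and the guarded loop."""

import pytest

from ringfba.fba_engine import fba
from ringfba.model_core import Metabolite, Reaction
from ringfba.phenotype_eval import PhenotypeRecord
from ringfba.ring_engine import (
    Discrepancy,
    ReconciliationAction,
    RingConfig,
    apply_action,
    categorize_discrepancies,
    evaluate_model,
    propose_actions,
    replay_actions,
    ring_iterate,
)
from ringfba.synthetic_models import (
    DefectSpec,
    make_core_model,
    make_phenotype_library,
    plant_defects,
)

CATEGORY_OF = {
    "compartment_duplicate": "FP1_compartment_duplicate",
    "orphan": "FP2_orphan",
    "dead_end": "FP3_dead_end",
    "multi_reaction_gene": "FP4_multi_reaction_gene",
    "multi_gene_reaction": "FN1_multi_gene_reaction",
    "missing_transporter": "FN2_sole_precursor_source",
}


def planted(kind):
    model, truth = plant_defects(make_core_model(), [DefectSpec(kind)])
    records = make_phenotype_library(model, truth)
    return model, truth, records


# -- categorization ---------------------------------------------------------

@pytest.mark.parametrize("kind", sorted(CATEGORY_OF))
def test_each_planted_defect_gets_its_category(kind):
    model, truth, records = planted(kind)
    _, labels = evaluate_model(model, records)
    discrepancies = categorize_discrepancies(model, labels, records)
    by_target = {d.target: d for d in discrepancies}
    for entry in truth:
        for rid in entry["members"]:
            assert by_target[rid].category == CATEGORY_OF[kind], rid
            assert by_target[rid].confusion_label == entry["expected_label"]


def test_every_false_prediction_is_categorized_once(defected):
    model, _, records = defected
    _, labels = evaluate_model(model, records)
    discrepancies = categorize_discrepancies(model, labels, records)
    false_targets = set(labels[labels["label"].isin(["FP", "FN"])]["target"])
    assert {d.target for d in discrepancies} == false_targets
    assert len(discrepancies) == len(false_targets)


def test_zero_flux_false_positive_flagged_unresolved(core_model):
    # an FP on a flux-free branch with no structural diagnosis: PDC carries
    # no flux at the optimum and has a single gene with a single reaction
    records_list = make_phenotype_library(core_model, [])
    records = [
        PhenotypeRecord(r.gene, "lethal" if r.gene == "g_pdc" else r.observed)
        for r in records_list
    ]
    _, labels = evaluate_model(core_model, records)
    disc = {d.target: d for d in categorize_discrepancies(core_model, labels, records)}
    assert disc["PDC"].category == "FP_unresolved_zero_flux"
    assert "flux" in disc["PDC"].reason


def test_unresolved_category_requires_reason():
    with pytest.raises(ValueError, match="reason"):
        Discrepancy("r", ("g",), "FP", "FP_unresolved")
    with pytest.raises(ValueError, match="inconsistent"):
        Discrepancy("r", ("g",), "FN", "FP2_orphan")


# -- actions ----------------------------------------------------------------

def test_dead_end_proposals_prefer_linking_then_augmentation():
    model, truth, records = planted("dead_end")
    _, labels = evaluate_model(model, records)
    disc = [d for d in categorize_discrepancies(model, labels, records)
            if d.category == "FP3_dead_end"][0]
    actions = propose_actions(disc, model)
    # terminal has no cross-compartment consumer, so only augmentation remains
    assert [a.kind for a in actions] == ["biomass_augmentation"]
    assert actions[0].payload["metabolite"] == truth[0]["terminal"]


def test_gap_fill_link_proposed_when_cross_compartment_consumer_exists():
    model, truth, records = planted("dead_end")
    terminal = truth[0]["terminal"]  # heme1[c]
    # give the base metabolite a consumer in the mitochondria
    model.metabolites["heme1[m]"] = Metabolite("heme1[m]", "heme1", "m", "C3")
    model.reactions["HEMESINK"] = Reaction(
        "HEMESINK", {"heme1[m]": -1.0, "co2[m]": 3.0},
        lower_bound=0.0, upper_bound=1000.0, genes=frozenset({"g_sink"}),
    )
    records = make_phenotype_library(model, truth)
    _, labels = evaluate_model(model, records)
    disc = [d for d in categorize_discrepancies(model, labels, records)
            if d.category == "FP3_dead_end"][0]
    kinds = [a.kind for a in propose_actions(disc, model)]
    assert kinds == ["gap_fill_link", "biomass_augmentation"]


def test_unresolved_discrepancies_propose_nothing(core_model):
    disc = Discrepancy("PDC", ("g_pdc",), "FP", "FP_unresolved_zero_flux",
                       reason="no flux")
    assert propose_actions(disc, core_model) == []


def test_apply_action_is_pure_and_revert_is_identity(core_model):
    snapshot = core_model.canonical_json()
    action = ReconciliationAction(
        "simultaneous_deletion_set", {"reactions": ["GLY", "PDC"]}, "test"
    )
    edited = apply_action(core_model, action)
    assert core_model.canonical_json() == snapshot  # input untouched
    assert edited.deletion_overrides["GLY"] == frozenset({"GLY", "PDC"})
    # reverting = discarding the edited copy
    assert core_model.canonical_json() == snapshot


def test_exclusion_masks_analysis_but_keeps_stoichiometry(core_model):
    action = ReconciliationAction(
        "exclude_from_analysis", {"reactions": ["LDH"]}, "test"
    )
    edited = apply_action(core_model, action)
    assert "LDH" in edited.excluded_reactions
    assert edited.reactions["LDH"].stoichiometry == core_model.reactions["LDH"].stoichiometry
    assert fba(edited).growth == pytest.approx(fba(core_model).growth)


def test_intercompartment_action_never_decreases_growth(core_model):
    action = ReconciliationAction(
        "add_intercompartment_exchange",
        {"base": "pyr", "comp_a": "c", "comp_b": "m"}, "test",
    )
    assert fba(apply_action(core_model, action)).growth >= fba(core_model).growth - 1e-9


def test_invalid_action_payload_leaves_model_untouched(core_model):
    snapshot = core_model.canonical_json()
    from ringfba.model_core import ModelError

    with pytest.raises(ModelError):
        apply_action(core_model, ReconciliationAction(
            "simultaneous_deletion_set", {"reactions": ["GHOST"]}, "test"
        ))
    assert core_model.canonical_json() == snapshot


# -- the loop ---------------------------------------------------------------

@pytest.mark.parametrize("kind", sorted(CATEGORY_OF))
def test_each_defect_class_is_resolved_in_isolation(kind):
    model, truth, records = planted(kind)
    final, report = ring_iterate(model, records)
    _, labels = evaluate_model(final, records)
    by = dict(zip(labels["target"], labels["label"]))
    for entry in truth:
        for rid in entry["members"]:
            assert by[rid] in ("TP", "TN", "excluded"), (kind, rid, by[rid])
    assert not report.unresolved
    assert report.final_summary.FP == report.final_summary.FN == 0


def test_consistent_model_accepts_no_actions(core_model):
    records = make_phenotype_library(core_model, [])
    final, report = ring_iterate(core_model, records)
    assert report.accepted_actions == []
    assert len(report.iterations) == 1
    assert final.structurally_equal(core_model)
    assert report.initial_summary.overall_accuracy == 1.0


def test_accuracy_guard_rejects_action_that_breaks_other_predictions(core_model):
    """A transporter that fixes one false negative but flips three observed-
    lethal mitochondrial reactions to viable must be rejected."""
    model = core_model.copy()
    model.metabolites["accoa[c]"] = Metabolite("accoa[c]", "accoa", "c", "C2")
    model.reactions["ACS"] = Reaction(
        "ACS", {"pyr[c]": -1.0, "accoa[c]": 1.0, "co2[c]": 1.0},
        lower_bound=0.0, upper_bound=1000.0, genes=frozenset({"g_acs"}),
    )
    # biomass needs acetyl-CoA in BOTH compartments
    model.biomass.stoichiometry["accoa[c]"] = -1.0
    records = make_phenotype_library(model, [])
    # in vivo, the ACS gene is viable -> its essential prediction is an FN
    records = [PhenotypeRecord(r.gene, "viable") if r.gene == "g_acs" else r
               for r in records]
    summary0, labels0 = evaluate_model(model, records)
    assert dict(zip(labels0["target"], labels0["label"]))["ACS"] == "FN"

    final, report = ring_iterate(model, records)
    rejected_kinds = [a.kind for it in report.iterations for a in it.rejected]
    assert "add_intercompartment_exchange" in rejected_kinds
    assert "T_accoa_m_c" not in final.reactions
    assert [d.target for d in report.unresolved] == ["ACS"]
    # the guard held: accuracy never dropped
    trace = report.accuracy_trace()
    assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))


def test_full_reconciliation_of_all_planted_defects(defected):
    model, truth, records = defected
    final, report = ring_iterate(model, records)
    assert report.final_summary.FP == 0 and report.final_summary.FN == 0
    assert report.final_summary.overall_accuracy == pytest.approx(1.0)
    trace = report.accuracy_trace()
    assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))
    # category totals + true predictions account for every compared target
    it = report.iterations[0]
    compared0 = report.initial_summary.total
    assert sum(it.category_counts.values()) + report.initial_summary.TP \
        + report.initial_summary.TN == compared0


def test_ring_is_idempotent(defected):
    model, _, records = defected
    final, _ = ring_iterate(model, records)
    again, report2 = ring_iterate(final, records)
    assert report2.accepted_actions == []
    assert again.structurally_equal(final)


def test_replaying_the_action_log_reproduces_the_final_model(defected):
    model, _, records = defected
    final, report = ring_iterate(model, records)
    replayed = replay_actions(model, report.accepted_actions)
    assert replayed.canonical_json() == final.canonical_json()


def test_action_log_round_trips_through_yaml(defected):
    from ringfba.ring_engine import actions_from_yaml

    model, _, records = defected
    final, report = ring_iterate(model, records)
    actions = actions_from_yaml(report.actions_yaml())
    assert replay_actions(model, actions).canonical_json() == final.canonical_json()


def test_non_growing_model_rejected_before_loop(core_model):
    model = core_model.copy()
    model.reactions["EX_glc"].lower_bound = 0.0
    with pytest.raises(ValueError, match="does not grow"):
        ring_iterate(model, [PhenotypeRecord("g_gly", "lethal")])


def test_empty_library_rejected(core_model):
    with pytest.raises(ValueError, match="empty"):
        ring_iterate(core_model, [])


def test_max_iterations_caps_the_loop(defected):
    model, _, records = defected
    _, report = ring_iterate(model, records, RingConfig(max_iterations=1))
    assert len(report.iterations) == 1
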