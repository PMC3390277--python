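# Methods

## Model and simulation framework

`ringfba` works on compartmentalized stoichiometric models under the
standard flux-balance assumptions: at pseudo-steady state every internal
metabolite is balanced, `S v = 0`, with each flux bounded by
`v_min <= v <= v_max` (mmol/gDCW/h) and a linear objective `Z = c v`,
normally the flux of the biomass pseudo-reaction (its value is the specific
growth rate in 1/h). The LP is solved with scipy's HiGHS backend. Results
are required to be backend-invariant: optimal solutions must satisfy
`||S v||_inf <= 1e-6` with bounds respected to `1e-9`, which the test suite
asserts directly.

Exchange reactions carry exactly one metabolite with coefficient −1, so
positive flux is secretion and uptake limits are negative lower bounds
(a glucose uptake of 4.19 mmol/gDCW/h is the lower bound −4.19). Gene
associations are flat gene sets: boolean gene–protein–reaction structure in
input files is flattened (with a warning) because simulations here operate
at the reaction level, and uncertain boolean GPRs would add structure the
deletion protocol does not use.

## Knockouts and essentiality

A deletion clamps the bounds of every targeted reaction to zero and
re-maximizes growth. A knockout is *lethal* when the mutant/wild-type growth
ratio falls strictly below the viability threshold (default 0.10); a ratio
of exactly 10% counts as viable — the published wording covers "less than"
and "greater than" but not equality, so the strict inequality is this
package's committed convention. Infeasible mutant LPs are mapped to zero
growth, and growth below 1e−9 is treated as numerically zero.

Gene-level deletion (`gene_knockout`) removes, by default, *every* reaction
whose gene set contains the gene, including duplicate compartmental
instances; a conservative `exact` mode (only reactions associated with that
single gene) exists for sensitivity analysis.

"Carries no flux in the wild type" is ambiguous under degenerate optima, so
`zero_flux_set` uses flux variability analysis: a reaction is flux-free only
if its FVA minimum and maximum are both zero while holding the objective at
100% of its optimum. This is stricter than inspecting one LP solution and is
invariant to the solver's choice among alternate optima.

Product yields (`max_product_yield`) maximize product secretion at a finite
substrate uptake and report mol product per mol substrate actually taken
up. No growth is demanded by default (yields are then pure stoichiometric
capabilities); a growth-coupled mode constrains biomass to a fraction of its
optimum, since published yield tables rarely state which setting was used.

## Comparison with an in vivo phenotype library

The in vivo side is a per-gene table (gene → viable/lethal) emulating a
single-gene knockout mutant library. The comparison unit is the scanned
*target* (one row per non-exchange reaction, or per gene in gene-level
scans) carrying its gene set. A prediction is counted false when it
disagrees with the observed phenotype of **any** associated gene that has a
record: predicted viable with a lethal gene is a false positive (FP),
predicted lethal with a viable gene a false negative (FN). This is the only
reading under which a reaction with mixed viable/lethal genes can appear —
as published knockout studies report — among the false predictions of
either sign. Targets whose genes all lack records go to an `uncompared`
bucket; reconciliation can move targets to an `excluded` bucket; neither is
silently dropped.

Derived rates follow the standard definitions — overall accuracy
(TP+TN)/total, negative prediction rate TN/(TN+FN), positive prediction
rate TP/(TP+FP), sensitivity TP/(TP+FN), specificity TN/(TN+FP), false
viable rate FP/(FP+FN) — reported as percentages to one decimal, rounded
half away from zero, with raw fractions retained. Zero-denominator rates
are reported as not-available, never as zero.

## Network diagnostics

Defined graph-theoretically over producer/consumer sets (reversible
reactions count on both sides; exchanges count as consumers/producers by
default; balance-exempt species never tie a reaction in):

* **Compartment duplicates** — metabolic reactions with identical
  compartment-stripped stoichiometry in different compartments. Bounds and
  genes are ignored; identical stoichiometry within one compartment is
  parallel isozymy, not duplication.
* **Orphan reactions** — disconnected on both sides: some substrate has no
  other producer *and* some product no other consumer. Such reactions can
  never carry steady-state flux (tRNA-charging reactions whose tRNA species
  occur nowhere else are the canonical case).
* **Dead-end chains** — upstream-connected linear pathways whose terminal
  metabolite has no consumer; the terminal is reported as the candidate for
  biomass augmentation. Fully disconnected stubs are classified as orphans,
  not dead ends. The orphan/dead-end boundary is not formalized in the
  literature this emulates; these definitions are the package's committed,
  configurable interpretation.
* **Gene/reaction multiplicity** — genes with ≥2 reactions, and reactions
  with ≥2 genes tagged `mixed`/`all_viable`/`all_lethal`/`unknown` from the
  library.

## The reconciliation loop

Every false prediction receives exactly one diagnosis, assigned in a fixed
staged order (FP: duplicate → orphan → dead end → multi-reaction gene →
unresolved zero-flux / mixed-genes; FN: multi-gene reaction → sole
precursor source → unresolved). Diagnoses map to typed, reversible actions:

| diagnosis | action |
|---|---|
| FP, compartment duplicate | simulate all instances deleted together (deletion override) |
| FP, orphan | exclude from the comparison, keep in the model |
| FP, dead end | link the terminal cross-compartment if a consumer exists there, else add the terminal to biomass at a negligible coefficient |
| FP, multi-reaction gene | simulate all of the gene's reactions deleted together |
| FN, multi-gene reaction | exclude from the comparison; noted for future research |
| FN, sole precursor source | add a reversible intercompartment transport from a compartment holding an alternative producer |

Deletion overrides and exclusions are analysis annotations carried on the
model (and serialized with it); they never alter stoichiometry. Structural
additions (transports, biomass components) are tagged `RING-added`.

Acceptance is per action, not per batch: each action is applied tentatively,
the whole scan/comparison recomputed, and the action kept only if it
resolves its target and overall accuracy does not decrease (`>=`, allowing
accuracy-neutral structural fixes). Otherwise the model reverts. Gap-fill
candidates come only from cross-compartment counterparts already in the
model, never from an external reaction database. Iterations repeat until an
iteration accepts nothing (default cap 10). Processing order is
deterministic (staged order, ties by sorted id), the accepted-action log is
a replayable YAML patch, and replaying it on the initial model reproduces
the final model byte-exactly (canonical JSON serialization).

The negligible biomass coefficient defaults to 1e−6 mmol/gDCW — no
published value exists; the default is chosen so that coupling a pathway to
growth perturbs the wild-type growth rate by far less than 0.1%, which the
suite asserts.

## Media

`yes_medium` builds the rich YES medium for a model: glucose uptake capped
at the measured 4.19 mmol/gDCW/h; the five supplements (adenine, histidine,
leucine, uracil, lysine), an editable yeast-extract nutrient list (20 amino
acids, nucleobases, vitamins) and minerals including iron left
unconstrained at ±1000. Yeast extract is not fully enumerable; the shipped
list (`data/yes_medium.yaml`) is a documented approximation and exchanges
absent from a given model are skipped. Exchanges not named by a medium
default to uptake closed, secretion open.

## Synthetic models

The generator is first-class, tested code, and its defaults are the study
conditions for every end-to-end check. The core model is a deliberately
small (18 reactions, ≤40 by design so exhaustive LP checks stay trivial)
two-compartment caricature of sugar catabolism with carbon-only
pseudo-formulas: glucose uptake/transport, lumped glycolysis
(glc → 2 pyr), fermentation (pyr → acald → ethanol; pyr → lactate), and a
lumped mitochondrial oxidation cycle (pyr → acetyl-CoA + CO2;
acetyl-CoA + oaa → cit → oaa + 2 CO2). Biomass consumes cytosolic pyruvate
and mitochondrial acetyl-CoA. Closed forms follow from carbon balance:
2 ethanol, 2 lactate, or 6 CO2 per glucose. Redox/energy cofactors are
omitted on purpose; consequently the generator does not emulate
cofactor-coupled essentiality, ATP maintenance, or genome-scale topology
statistics, and passing tests say nothing about those aspects of real
reconstructions.

`plant_defects` inserts one instance of each discrepancy class with ground
truth recorded: a nucleus-localized duplicate of glycolysis (same gene, no
connecting transports), tRNA-charging-style orphans, a two-step
heme-like dead-end chain, a gene with two alternative routes to a biomass
component, an auxiliary viable gene added to an essential transporter, and
the acetyl-CoA scenario — biomass demanding cytosolic acetyl-CoA whose
sole producer's gene is viable in vivo, with the alternative producer in
the mitochondria and the transporter missing. The planted variant re-points
the biomass acetyl-CoA demand to the cytosol so that the reversible
transport added during reconciliation relieves exactly the planted defect
and nothing else. The matching library gives every non-defect gene the
phenotype the defected model predicts (true by construction) and every
defect gene the phenotype that falsifies the pre-reconciliation prediction;
this assignment is the harness's contract, not a claim about real
libraries.

## Numerical choices and degenerate inputs

Feasibility tolerance 1e−6 (steady-state residual), bound tolerance 1e−9,
growth zero below 1e−9; FVA minima/maxima are re-ordered if the solver
returns them within tolerance of each other. Vertex enumeration
(`enumerate_optimum`) fixes every subset of fluxes to bounds, solves the
free part, and keeps unique in-bounds solutions; it is exponential (3^n)
and capped at 8 reactions — it exists purely as an independent oracle.
Non-growing wild types are rejected before any knockout work (the
viability threshold is undefined); empty media on import-dependent models
give zero growth, not errors.

## Known limitations

* The staged order of the reconciliation loop is one committed
  interpretation; published applications of this style of procedure do not
  state which discrepancy classes were handled in which iteration.
* Gene-level observed phenotypes are taken at face value; genes essential
  for non-metabolic reasons will remain unresolved false positives, which
  is the intended behavior (they flag missing knowledge, not model edits).
* Reported problem sizes: the acceptance script uses 200 random small
  systems for the LP/enumeration comparison and 30 random growth models
  (~200 deletions) for the scan/brute-force comparison — sizes at which the
  exhaustive oracles are exact and instantaneous.
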