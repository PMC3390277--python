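# ringfba

Constraint-based knockout-phenotype prediction and iterative in silico /
in vivo reconciliation for compartmentalized genome-scale metabolic models.

Genome-scale metabolic reconstructions are validated by simulating every
single-gene knockout and comparing the predicted growth phenotypes with an
experimental mutant library. Disagreements are not noise: each false
prediction points at a concrete defect in the network — a duplicated
reaction in the wrong compartment, an orphan or dead-end pathway, a gene
spread over several reactions, a missing intercompartment transporter.
`ringfba` implements that whole workflow for curators of compartmentalized
models: flux balance analysis and flux variability, deletion scans,
confusion-matrix evaluation against a phenotype library, topological
diagnostics, and RING — a guarded, iterative reconciliation loop that
proposes typed model edits and keeps only those that do not hurt overall
accuracy.

## The model

Fluxes `v` (mmol/gDCW/h) satisfy steady-state mass balance and bounds,

    S v = 0,      v_min <= v <= v_max,

and FBA maximizes an objective `Z = c v`, normally the biomass flux (the
growth rate, 1/h). A knockout clamps the targeted reaction fluxes to zero;
it is called **lethal** when the mutant grows at less than 10% of the wild
type. Against a library of observed phenotypes each prediction becomes
TP/TN/FP/FN, with overall accuracy (TP+TN)/total, sensitivity TP/(TP+FN),
specificity TN/(TN+FP), and the positive/negative prediction rates
TP/(TP+FP), TN/(TN+FN).

The RING loop then diagnoses every FP/FN in a staged order (compartment
duplicates → orphans → dead ends → multi-reaction genes for FPs;
multi-gene reactions → sole precursor sources for FNs), proposes reversible
actions (simultaneous deletion sets, analysis exclusions, gap-fill links,
negligible-coefficient biomass augmentation, added intercompartment
transports), applies each tentatively, re-scans everything, and accepts it
only if its target is resolved and overall accuracy does not decrease.
Accepted actions form a replayable patch log.

## Worked example

Generate a synthetic compartmentalized model with one planted defect of
every class plus its matching phenotype library, then reconcile:

    $ ringfba synth --defects all --seed 7 --out fixture
    $ ringfba reconcile fixture/model.sbml.xml \
          --library fixture/phenotypes.tsv --out ringout
    initial accuracy: 60.0% (12/20)
    iteration 1: accepted 6, rejected 0, accuracy 100.0% (18/18)
      + simultaneous_deletion_set [GLY_n1:FP1_compartment_duplicate] {'reactions': ['GLY', 'GLY_n1']}
      + exclude_from_analysis [ORPH1:FP2_orphan] {'reactions': ['ORPH1']}
      + biomass_augmentation [DE1a:FP3_dead_end] {'metabolite': 'heme1[c]', 'coefficient': None}
      + simultaneous_deletion_set [MRG1a:FP4_multi_reaction_gene] {'reactions': ['MRG1a', 'MRG1b']}
      + exclude_from_analysis [GLCt:FN1_multi_gene_reaction] {'reactions': ['GLCt']}
      + add_intercompartment_exchange [ACS1:FN2_sole_precursor_source] {'base': 'accoa', 'comp_a': 'm', 'comp_b': 'c'}
    iteration 2: accepted 0, rejected 0, accuracy 100.0% (18/18)

Reading: the planted model starts at 60% accuracy (12 of 20 compared
reaction targets predicted correctly). One iteration resolves all eight
false predictions — the nucleus-localized glycolysis duplicate and the
two-route gene are re-simulated as simultaneous deletions, the orphan and
the multi-gene transporter are masked out of the comparison (but kept in
the network), the heme-like dead end is coupled to biomass, and a
mitochondria→cytosol acetyl-CoA transport fixes the sole-producer false
negative. The second iteration accepts nothing, so the loop stops at 100%
accuracy on the 18 still-compared targets. `ringout/` holds the JSON
report, the replayable `actions.yaml`, and the reconciled SBML.

Other subcommands: `fba`, `fva`, `yields`, `knockout`, `scan`, `evaluate`
(including a counts-only mode for published confusion tables), `validate`.

    $ ringfba yields fixture/model.sbml.xml --product EX_etoh --substrate EX_glc
    EX_etoh	EX_glc	2

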