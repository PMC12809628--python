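# Methods

## The model

One regression model is fitted over all targets at once. Each curated
datapoint — a standardized molecule (keyed by InChIKey) measured against
one transporter — becomes a row whose features are the concatenation of a
ligand block and a protein block, and whose response is pIC50 =
−log10(IC50[M]). The protein block encodes the residues the target
presents at a fixed list of aligned binding-site positions; each residue
contributes its first three Sandberg Z-scales (Z1 lipophilicity, Z2
steric, Z3 electronic), yielding features named `pos{N}_Z{k}` with `N` the
residue number in the SGLT2 reference structure (PDB 7VSI). No
ligand×protein cross terms are used; the tree ensembles are expected to
learn any interactions themselves.

Assumptions worth stating explicitly:

* a pocket is adequately summarized by its variable aligned positions —
  positions identical across all targets carry no signal for a regression
  and are pruned at matrix assembly;
* activity differences between targets are attributable to binding-site
  residue differences; two targets with identical pockets but discordant
  activities for shared compounds are irreconcilable under this model and
  are flagged (one member, by default the data-poorer one, is dropped);
* pooled IC50/EC50 values measured in different assays are comparable
  after conversion to pIC50 and SEM-gated averaging.

## Curation rules

Records must have non-missing type/relation/units, type IC50 or EC50,
relation `=`, and units convertible to nM (nM/µM/mM/M/pM). Duplicates are
merged in two passes: identical (molecule, target, document) rows are one
source and collapse to their mean value; identical (molecule, target,
value) rows across documents are one measurement cited repeatedly and
collapse to the first. SMILES are standardized (cleanup, parent fragment,
charge neutralization, stereo removal, canonical tautomer) and converted
to InChIKeys; structural filters drop permanently charged or
isotope-labeled molecules, MolWt outside [150, 800], more than five
aromatic rings, and peptide-backbone matches without a sugar
substructure. Aggregation keeps a molecule–target pair with fewer than
five measurements only if the standard error of the mean (sample sd,
n−1 denominator; defined as 0 for singletons) is ≤ 0.3 pIC50 units;
pairs with five or more measurements are always averaged. The SEM
convention for singletons is ours; keeping single measurements is the only
behavior consistent with the data volumes this kind of extract has.

## Modeling choices

* Split: target-stratified 70/30, per-target rounding to the nearest
  integer, singleton targets assigned to training so every pocket encoding
  is seen during fitting.
* Algorithms: random forest (default: 300 trees, `max_features=0.3`),
  XGBoost (400 rounds, depth 6, η=0.1), RBF-SVR (C=10, ε=0.1) with
  location-scale standardization fitted inside the pipeline on training
  rows only, and mean/median dummy baselines. Grids for optional
  grid search are conventional small grids and fully overridable; the
  fixed defaults are used wherever runs must be comparable (ablation).
* Q² is the mean of the ten fold R² values from shuffled K-fold CV on the
  training rows, with per-fold predictions retained so the statistic can
  be recomputed independently. CV folds are random over rows by default; a
  grouped-by-InChIKey mode exists because a molecule measured against
  several targets otherwise straddles folds (a mild leakage of ligand
  identity). Both modes are exposed rather than silently choosing one.
* Determinism: every stochastic step (splitting, model seeds, CV
  shuffling) takes an explicit seed; re-running a configuration reproduces
  artifacts byte for byte.

## Residue-importance analysis

Method 1 ranks all features by the forest's mean decrease in impurity,
ascending, so the most important of n features has rank n; mean, median,
and sd of ranks are reported over several re-seeded fits (ties broken by
feature name for determinism). Impurity importance cannot reveal whether
another feature could substitute for the credited one, so method 2
retrains the model — fixed hyperparameters, fixed split, fixed seed — with
each position's three Z-scales removed, and with each position alone added
back to the ligand block, plus all-positions / no-positions / chosen-subset
baselines. Positions whose columns were constant (pruned) reproduce the
reference metrics under removal by construction. A value-shuffling
permutation importance (no retraining) is included as a cheap third
opinion, not as a replacement for retraining.

The strong-outlier census retrains the model under several seeds on one
split and counts, per test datapoint, the runs where |pIC50_exp −
pIC50_pred| > 2. Selectivity is evaluated on molecules measured against at
least two targets and confined entirely to the test set, via `pIC_diff =
(Δexp − Δpred)`, which is antisymmetric under swapping the target pair.
Point-mutant prediction encodes an arbitrarily mutated pocket and reuses
the fitted model; a mutation at a position outside the model's columns
cannot change the prediction, and the report flags this.

## The synthetic data generator

The generator emulates the structure of a public bioactivity extract for a
transporter panel, with known ground truth:

* **Chemistry.** Twelve drug-like core templates (aryl C-/O-glycosides,
  diaryl pyrazoles, anilides, sulfonanilides, and similar) decorated at
  two sites with halogen/alkyl/hydroxy/alkoxy/CF3 substituents form
  congeneric series; substituent pairs are enumerated so each series
  contains positional-isomer pairs. Molecule potency is Free-Wilson-like:
  a per-scaffold base level (Normal(6.0, 0.6) pIC50) plus additive
  per-substituent contributions (sd 0.35) and a small site-specific
  adjustment (sd 0.1), so the ligand part is learnable from structure. A
  designated fraction of molecules (default 4 %) whose positional isomer
  is present receives an activity cliff of −3 pIC50 units.
* **Targets.** Eight synthetic pockets reuse the real sixteen-position
  SLC5 alignment. Two positions are *causal*: 286 (V/L, effect 1.0 pIC50
  per unit Z-distance; ΔZ(V,L) ≈ 2.16) and 460 (S/T, effect 0.5;
  ΔZ(S,T) ≈ 3.01). The fourteen remaining positions vary only between two
  *lineages* — a phylogeny-like block structure — and are deliberately
  orthogonal to both causal positions, so they identify a target's lineage
  but carry no activity information. This is what makes importance
  recovery falsifiable: any method crediting a lineage position is wrong,
  and removing a causal position genuinely destroys information instead of
  being substitutable.
* **Offsets.** A target's potency offset is the sum over causal positions
  of effect × Euclidean distance in (Z1, Z2, Z3) between its residue and
  the reference (first) target's residue — a monotone link to exactly the
  features the model sees.
* **Dirt.** Records are emitted in nM (10 % in µM), 20 % typed EC50;
  a censored fraction (default 5 %) gets relation ">" or missing units; a
  duplicated fraction (default 10 %) is re-emitted 1–3 times, half in the
  same document with the same value and half in a second document (with a
  small value perturbation, sd 0.05, when measurement noise is on, so the
  SEM rule has real work). Measurement noise is Normal(0, 0.3) pIC50.
  Default scale: 25 scaffolds × 30 members ≈ 750 molecules, each assayed
  against 1–3 targets with mildly imbalanced target weights, giving about
  1450 unique pairs (~1400 after curation).

What the generator does **not** emulate: real SAR (substituent effects are
random, not pharmacophoric), assay heterogeneity beyond unit/type
variation, correlated noise within documents, stereochemistry, tautomer
ambiguity in the inputs, and pocket geometries (residue identity is all
there is). Passing tests therefore demonstrate that the pipeline's
machinery recovers planted structure under realistic data volumes and
dirt — not that any particular biological conclusion about real SLC5
transporters is reproduced.

## Numerical conventions and degenerate inputs

pIC50 conversion is −log10(value[nM]/1e9) and rejects non-positive
values. Correlation pruning of physico-chemical descriptors (automatic
mode, |Pearson| > 0.7) keeps the first member of each correlated pair in
name-sorted order; NaN-producing descriptors are dropped. Constant feature
columns are pruned everywhere (a single-molecule block is legitimately
empty; a single-target matrix warns that the protein block is
uninformative). Per-target R² is reported as NaN for targets with fewer
than two test rows or a constant response, while the ±1/±0.5 fractions are
always reported. Mutations must name the wild-type residue and fail loudly
on mismatch, guarding against numbering mistakes between UniProt,
alignment, and structure numbering.

## Problem sizes used in the shipped analyses

The test suite runs the full study at the default generator scale
(~1400 curated datapoints) with five seeds for the importance analyses and
three for the outlier census; unit tests use an 8-scaffold × 10-member
miniature of the same design. These sizes were chosen as the smallest at
which the planted effects are comfortably above estimation noise.

## Known limitations

* The 49-descriptor physico-chemical selection shipped as a default is a
  constructed stand-in covering the usual property families, not a
  published reference list; users with a preferred list should supply it.
* Impurity-based importance inherits the known biases of tree ensembles
  (preference for high-cardinality/continuous features); the ablation
  method is the authoritative one where they disagree.
* The identical-pocket conflict rule compares aggregated pIC50s with a
  configurable tolerance (default 0.5); it cannot distinguish assay
  artifacts from genuine allosteric differences a pocket encoding misses.
* Selectivity evaluation requires molecules wholly confined to the test
  set; small datasets may yield none (the summary is then empty and
  flagged).
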