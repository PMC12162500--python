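# Methods

## The model

`kddc` treats disease-state classification from immune repertoires as a
bag-of-k-mers problem. A repertoire — the multiset of CDR3 amino-acid
sequences observed in the cells of one sample (optionally restricted to one
cell subset) — is represented by the counts of every length-k amino-acid
string ("concatemer") it contains. The feature space is enumerated
exhaustively over the 20 standard amino acids, lexicographically within
each k block, blocks in ascending k: 400 columns for k = 2, 8 000 for
k = 3, 160 000 for k = 4, 168 400 for the combined k ∈ {2, 3, 4} dataset.
Zero-filling is semantic, not a storage mandate: counts are held sparse
(CSR) with a dense-on-demand view.

Windows are overlapping with step 1. A window containing a character
outside the alphabet (X, \*, gaps) is skipped rather than the record
dropped, so non-standard residues cost at most a few windows and the
feature space stays exactly 20^k; a strict mode drops such records at load
time instead.

The aggregation unit is the (sample, cell-subset) repertoire: infection
state is a property of the sample, not of a single cell, and per-sample
rows give the classifier one observation per label. One record per cell is
counted (no clonotype collapsing) because repeated occurrences of a clone
are themselves signal; `dedupe_clonotypes` (CLI `--dedupe-clonotypes`)
offers the per-clonotype alternative and `--row-unit cell` the per-cell
sensitivity analysis. Counts are raw occurrences; `--normalize` switches to
per-row relative frequencies.

## Feature screening and reduction

Two stages, both fitted on training rows only (see below):

- **zero screen** — drop features whose fraction of zero rows is ≥ the
  threshold (default 0.95, strict inequality for keeping). Rationale: a
  k-mer absent from nearly all repertoires cannot support a stable
  between-group contrast, and at k = 4 most of the 160 000 features are in
  this regime.
- **one-way ANOVA** — per feature, F = MS_between / MS_within across the
  state groups with (g − 1, n − g) degrees of freedom (computed by
  `scipy.stats.f_oneway`, verified in the tests against a hand-written
  sums-of-squares oracle to 1e-9); keep p < α (default 0.05, the
  conventional level, no multiple-testing adjustment by default;
  Benjamini–Hochberg by flag). Features with undefined or non-finite F
  (zero variance) are degenerate and dropped.

With exact integer counts near zero the F-test is conservative: on the
generator's own null data the selected fraction at α = 0.05 sits near
0.04 rather than 0.05. On label-independent data with non-degenerate counts
(e.g. Poisson with mean ≥ 5) the selection is calibrated to α within
binomial error, which is what the test suite checks.

## Train/test protocol and leakage

The split is stratified 4:1 (`train_fraction=0.8`). Screening + ANOVA live
inside the sklearn `Pipeline` as a transformer, so grid-search
cross-validation re-estimates them per fold and the test partition never
influences which features exist. This matters: an included experiment runs
the alternative ordering — selection on the full dataset, then the split —
on label-permuted data and measures held-out macro AUC ≈ 0.87 versus
≈ 0.5 for the default ordering. The alternative remains available as
`selection_mode="pre-split"` (CLI `--paper-order`) strictly for
comparability with analyses that report that ordering.

Scaling (variance-only, sparse-safe, also inside the pipeline) is applied
for every family so distance- and margin-based classifiers are not
dominated by high-count k-mers; it is inert for the tree families.

## Classifier families and grids

Seven families: logistic regression, RBF-kernel SVM, multi-layer
perceptron (one hidden layer of 64), k-nearest neighbours, decision tree,
random forest (200 trees), XGBoost (100 trees, hist). The default grids
are deliberately small — one axis per family (e.g. C ∈ {0.1, 1, 10},
max_depth ∈ {None, 10}) — so the full 7 datasets × 7 families sweep runs at
desk scale; they are overridable per run (`grid_overrides` in the YAML
config). Grid search uses stratified K-fold CV (default 5 folds, reduced
with a warning when the rarest class cannot fill them) scored by macro
AUC, and refits the winner on the whole training partition.

Scores for ROC/AUC are predicted probabilities where the family provides
them; the SVM uses its one-vs-rest decision values (rank-equivalent, hence
valid ROC scores), softmax-mapped only for presentation. Macro AUC is the
unweighted mean of the one-vs-rest per-class AUCs, so the small severe
class counts as much as the large healthy one. The ordinal structure
H < M < S is deliberately ignored (nominal treatment).

## Permutation significance

The reported p-value is a label-permutation test of the held-out macro
AUC: each of the n_perm permutations shuffles the labels of the full
dataset and re-runs everything — stratified split, in-pipeline selection,
fitting, scoring — and p = (1 + #{perm ≥ obs}) / (1 + n_perm), which is
exact-valid and never zero. The achievable floor is 1/(1 + n_perm); with
the quick mode's n_perm = 19 the floor (0.05) is not below α = 0.05, so
quick runs cannot certify significance — use n_perm ≥ 39 (floor 0.025)
when the gate matters. Under the null the p-value is uniform on its grid
(checked by a KS test in the suite). Default n_perm = 99 per (dataset,
family) in pipeline runs; 999 gives the conventional three-decimal
resolution when runtime allows.

The best-model table mirrors the usual report shape (dataset, model, macro
AUC, p-value, per-class H/M/S): per dataset, the highest macro AUC among
families with p < α wins, ties breaking toward the simpler family in the
fixed order LR < SVM < MLP < KNN < DC < RF < XGB; datasets with no
significant family report their best AUC flagged not-significant.

## Shared-motif intersection

For each pair of cell subsets, the top-N (default 50) most important
k-mers of each subset's best model are intersected, importances taken from
tree impurity importances or linear coefficient magnitudes, with the
in-pipeline ANOVA F statistic as the fallback for families exposing
neither (KNN, MLP). Shared k-mers are ordered by summed rank. This asks
whether the same short CDR3 motifs discriminate state in different cell
subsets — structural similarity of the responding receptors.

## Synthetic benchmark

The generator emulates exactly the structure the pipeline claims to
detect: class-conditional usage of short motifs on a neutral background.

- Each cell's CDR3 draws its length from a configurable distribution
  (default uniform on 8–20 residues, the typical CDR3 range) and its
  letters i.i.d. from a background composition (default uniform).
- For a cell of a motif-carrying class, one motif of that class is chosen
  uniformly and, with that motif's insertion probability, written over a
  uniformly placed window. Overwriting, not inserting, keeps length
  distributions identical across classes, so any signal is purely
  compositional — length is never a confound (a KS test across classes
  confirms this in the suite).
- Defaults are the benchmark study conditions: 3 classes × 30 samples ×
  200 cells, three 3-mer motifs per non-healthy class at insertion
  probability 0.9 (class 1: DLW, FDL, YDY; class 2: RGG, GGF, EQY). With
  one motif chosen per cell, each motif lands in roughly 30 % of its
  class's cells — a strong but not degenerate signal.
- `truth_recovery_check` scores the fraction of planted motifs among the
  top-N features by F statistic.

What the generator does **not** model: V(D)J recombination statistics,
germline-encoded flanks (real CDR3s start near C and end near F/W),
clonal expansion (cells are i.i.d., real repertoires are not),
somatic hypermutation, per-sample depth variation, and batch effects.
Passing tests therefore demonstrate that the machinery is correct and the
protocol leak-free under compositional class signal — not that comparable
AUCs will be reached on any particular real cohort, where signal strength,
clonal correlation and confounding are unknowns.

## Numerical and operational choices

- All randomness flows from one user seed through `derive_seed` (CRC-based
  sub-seeds < 2^31, one per named stage), so identical config + seed
  reproduces every output file byte-for-byte; for the same reason
  per-stage timings go to the log, not to output files.
- Degenerate selections (no feature passes) fall back to the single
  smallest-p feature so downstream fits stay well-defined.
- AUC ties among score pairs follow the standard trapezoidal (half-credit)
  convention via scikit-learn; table ties break toward simpler families as
  above.
- Empty CDR3s are dropped and counted at load; duplicate (barcode, chain)
  rows keep the first entry with a logged count; duplicate barcodes in the
  metadata are an error, since the join could silently fabricate cells.
- The default test-suite problem sizes (e.g. 20 samples × 50 cells for the
  leakage sentinel, 10 seeds at full benchmark scale for signal recovery)
  were chosen so the whole suite runs in a few minutes on one core while
  leaving the statistical assertions comfortably powered.
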