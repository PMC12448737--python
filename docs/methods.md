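# Methods

This note documents the models, estimators and numerical choices behind
`attbiomarker`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite does not itself compute.

## Problem setting

Given one or more case/control expression studies (log2-scale
genes × samples tables with binary sample labels), the package selects a
compact, minimally redundant gene subset that discriminates the classes,
quantifies that subset's discriminative value with a convolutional
classifier, and intersects it with conventional differential-expression
calls. The motivating application is transcriptomic biomarker discovery
for preeclampsia from multi-study microarray compendia, but nothing in
the code is specific to that disease.

## Stage 1 — per-gene statistics and the common matrix

**Welch t stand-in.** Per-gene statistics are computed with the Welch
unequal-variance two-sample t test (Satterthwaite degrees of freedom,
two-sided p). Moderated (empirical-Bayes) tests such as limma's shrink
gene variances toward a pooled prior and have better small-sample power;
they are deliberately *not* reimplemented. Users who have moderated-t
output can ingest it verbatim (`read_gene_stats`) and reproduce their
tool's filters exactly; the Welch stand-in exists so the pipeline is
runnable from an expression matrix alone. Degenerate genes (zero variance
in both classes) get p = 1 when the class means agree and a flagged p = 0
when they do not.

**Prefilter and intersection.** The permissive per-study filter
p < 0.25 (strict) is a recall-oriented prefilter, not a significance
claim: it exists to keep weakly associated genes available to the
multivariate rounds. It is applied per study and the surviving gene sets
are intersected; the concatenated cross-study matrix S applies no batch
correction (a warning is logged). This mirrors the workflow being
reproduced; on synthetic nulls the triple intersection is far harsher
than on real moderated-t output, because uniform null p-values survive
three independent 0.25 filters with probability ≈ 0.016.

**DEG filter.** Differential expression uses p < 0.05 and |log2FC| > 1,
both strict. The p-value column is used as supplied; whether it is
FDR-adjusted is the caller's decision.

## Stage 2 — Fisher-score ranking

Each gene is scored by the ratio of between-class to within-class
variation,

    f(i) = Σ_x q_x (μ_i^x − μ_i)² / Σ_x q_x (σ_i^x)² ,

with q_x the class size and σ population (divide-by-n) standard
deviations. Population rather than sample variances keep the per-gene
score consistent with the unnormalized scatter-matrix form
f(S′) = tr(M_b)/tr(M_w), which the package also exposes
(`fisher_trace_criterion`); the within-class scatter is the standard
Σ_x Σ_{j∈x} (z_j − μ̄_x)(z_j − μ̄_x)ᵀ. A gene with zero within-class
variance but separated classes receives a +∞ sentinel and sorts above
all finite scores; ties break by ascending original index.

**Knee detection.** Subset sizing from the sorted score curve is
automated by the max-distance-to-chord rule: min–max normalize both
axes, draw the chord between the endpoints, and return the interior
index with the greatest perpendicular distance (Kneedle-style). A flat
or linear curve has no knee; the function warns and keeps all genes.
Because published workflows often pick sizes by eye, explicit size
grids override the automatic knee everywhere.

**Pooled vs per-study scoring.** Fisher scores are computed on the
pooled multi-study matrix by default; `generate_multistudy`'s shared
gene universe makes a per-study scoring + combination scheme easy to
build from the same primitives if wanted.

## Stage 3 — mRMR refinement

Greedy minimum-redundancy maximum-relevance with the difference
objective (MID): step s selects argmax_f [I(f, label) −
(1/|Φ_s|) Σ_{g∈Φ_s} I(f, g)], step 1 being pure relevance (redundancy
of an empty set is 0). The quotient form (MIQ) is intentionally not
offered. Mutual information is the plug-in estimator in nats on
discretized data. Discretization is per-gene equal-frequency binning
with B = 5 bins by default — the classic choice for mRMR on continuous
expression; duplicated quantile edges collapse (realized bin counts are
recorded) and constant genes collapse to one bin with a flag. The label
enters as an already-discrete 2-state variable. MI terms are summed in
sorted order so that I(a,b) = I(b,a) holds bitwise, not just to
round-off. Ties break by ascending
gene index, making runs reproducible; redundancy sums are accumulated
incrementally so ranking r genes from p candidates costs O(p·r) MI
evaluations.

The estimator (B, equal-frequency) is a declared default, not an
inference from the reproduced workflow, which is silent on how I(·,·)
was estimated; B is a config knob.

## The attention CNN

A sample's p expression values form a length-p, single-channel sequence.
The baseline wiring is

    conv1d(1→32, k=3, same, ReLU) → conv1d(32→64, k=3, same, ReLU)
    → GAP → dense(64→p) + softmax  (per-position attention α)
    → h′ = α ⊙ h  (position-wise reweighting of the conv-2 map)
    → flatten(p·64) → dense(128, ReLU) → dropout(0.5) → dense(1, sigmoid).

Two choices deserve comment:

- **Attention as reweighting, not summation.** The attention context
  vector c = Σ_i α_i h_i is recoverable exactly by summing the
  reweighted map over positions (`context_reweight` + sum, tested
  against a loop oracle), but the map is kept position-resolved before
  flattening. This is the only wiring whose trainable-parameter count
  reproduces the published figure (8 263 593 at p = 1000, decomposed
  128 + 6208 + 65 000 + 8 192 128 + 129): a summed 64-d context cannot
  feed an 8.19 M-parameter dense layer.
- **Single vs double attention.** The prose architecture has one
  attention block (after conv-2) and its parameter count confirms that;
  the ablation study, however, names first and second attention layers.
  The package therefore treats the single-attention network as the
  baseline and defines a two-attention *parent* spec (a symmetric
  GAP→dense(p)→softmax→reweight block after conv-1, + f1·p + p
  parameters) solely as the reference for the WFAL / WSAL / RBAL
  ablations. RFCL removes the 128-unit dense layer
  (flatten → dropout → output). A "plain CNN" comparator removes
  attention and feeds the pooled 64-vector directly into the dense
  layer.

**Implementation.** No deep-learning framework is used: the forward
pass, hand-derived backpropagation (including the softmax-attention
path, where the reweighted map's gradient flows both directly and
through the attention weights via GAP) and Adam are implemented on
numpy arrays, with convolutions as im2col matrix products. Correctness
is established by finite-difference gradient checks in the test suite
and by the exact agreement of spec-arithmetic and instantiated
parameter counts for every variant.

**Training protocol.** Adam (lr 1e-3), binary cross-entropy, batch 16,
at most 50 epochs, early stopping on validation loss with patience 5
and best-weights restoration. Inference disables dropout. All
randomness (Glorot initialization, shuffling, dropout masks) derives
from one seed. The determinism contract is fixed-seed / same-backend /
single-threaded; bit-reproducibility across BLAS builds is not
promised. A grid-search helper covers learning rate {1e-3, 1e-4},
dropout {0.3, 0.5} and filter pairs {(32,64), (16,32)}, but the
pipeline does not grid-search by default — at these budgets it would
dominate runtime without changing the workflow's structure.

## Evaluation

Stratified 80/20 holdout (per-class test counts round half to even),
stratified 5-fold CV on the training portion, and metrics AUC / ACC /
F1 / PRE / REC per fold and on the held-out test set. The report
carries both CV aggregates and test metrics; headline numbers are the
held-out test metrics. Thresholded metrics predict positive at
probability ≥ 0.5 (the case class is positive); AUC is the Mann-Whitney
statistic with ties counted ½.

**DeLong test.** Correlated AUCs on the same samples are compared with
the structural-components (midrank) estimator: z = ΔAUC/√var(Δ) with a
two-sided normal p and no small-sample correction. Identical score
vectors short-circuit to z = 0, p = 1; a zero variance estimate with a
nonzero ΔAUC raises rather than fabricating a p-value. The test suite
checks type-I calibration against a simulated null and cross-checks a
small case against a stratified bootstrap of the AUC difference.

**Comparators.** SVM and gradient-boosting baselines are thin adapters
around scikit-learn estimators evaluated on identical splits (this
environment ships neither XGBoost nor LightGBM, so sklearn's gradient
boosting stands in for the boosting family); the plain CNN comparator
is the spec transformation described above. These are harness, never
reimplementations.

## Synthetic data

The generator emits the regime the workflow targets: n_studies = 3
studies of 2·n_per_class samples (default 25 per class, matching the
36–60-sample studies of the motivating compendium), n_genes = 2000
log-scale values, Gaussian within-class noise (sd 1.0), per-study
per-gene baseline offsets (sd 0.3 — a modest uncorrected batch effect;
no published value exists, so this is a one-time judgment call),
n_informative = 50 planted genes with a +δ·sd case shift (δ = 1.5), and
10 redundant blocks of 5 genes sharing one latent informative signal at
pairwise correlation ρ = 0.95 (block member = √ρ·latent + √(1−ρ)·noise,
so members correlate at ρ and carry the full class shift). Study draws
come from `seed XOR (study_index + 1)`; gene identities come from the
master seed so studies share them. The +1 keeps study 0's stream
distinct from the master stream.

What a green test does *not* establish: the generator has no
heavy-tailed intensities, no probe effects, no missing values, no
count noise, and its batch structure is mean-shift only — so passing
recovery tests demonstrates the algorithms work under their stated
assumptions, not that they are robust to real microarray artifacts.

## Pipeline

One stratified split fixed at pipeline start is reused by every round,
so candidate subsets are compared on identical samples. The winner of
each round is the subset with the highest held-out test accuracy (ties:
higher AUC, then smaller size — accuracy is the metric published
model-selection tables bold). Stage seeds derive from the master seed
plus a CRC-32 of the stage name, so stages re-run independently.
Requested subset sizes are clamped to the available gene count (a size
grid of [p] therefore reduces the pipeline to evaluating the unselected
matrix). Round nesting (round-2 genes ⊆ round-1 genes ⊆ filtered common
genes) is asserted on every run.

## Known limitations

- Multi-class labels are supported by the Fisher formulas but untested
  beyond binary; the classifier head is strictly binary.
- The numpy network is CPU-only and unoptimized beyond BLAS matmuls;
  large input lengths (p ≳ 5000) train slowly.
- No probe-to-symbol mapping, normalization, or GEO access: inputs are
  assumed preprocessed, and gene matching is exact string equality.
- The DeLong normal approximation is unreliable below ~20 samples per
  class; no continuity correction is applied.
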