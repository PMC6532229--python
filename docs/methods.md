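# Methods

This note documents the statistical models behind each pipeline stage, the
design of the synthetic-data generator, the numerical conventions, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

Single-cell expression is held on the log2(TPM/10 + 1) scale (the loader can
apply this transform to raw TPM); bulk expression is TPM. Gene identifiers
are plain symbols, upper-cased on load, duplicates dropped with a warning
(first occurrence wins); no alias resolution is attempted. Bulk samples
missing survival time or event status are dropped with a logged count.
Ligand→receptor pairs are directed: (A, B) and (B, A) are distinct.

## Cell typing

Cells are clustered on the top 5% of genes by variance of log expression
(the `hvg_fraction` flag; variance of log values was chosen over raw-scale
CV because the data model is log-scale — this can diverge from dispersion
fits that model a mean-variance trend). The HVG submatrix is z-scored per
gene (so no single gene dominates the metric), embedded by PCA (20
components), and partitioned by k-means; `k="auto"` selects k ∈ [2, 20] by
silhouette score.

The malignancy call uses patient composition: glioma malignant cells carry
patient-private expression programs (CNV-driven in real data), so malignant
clusters are nearly pure in one patient while healthy cells co-cluster
across patients. A cluster is called neoplastic when its purity (largest
patient fraction) is ≥ `purity_min`; the threshold is inclusive (purity
exactly at the cut counts as neoplastic). The default `purity_min = 0.9` is
a deliberately strict reading of "one cluster per patient"; the cluster
report also carries the composition entropy (purity = 1 ⇔ entropy = 0).

Validation compares a positive marker (EGFR in real data) and a negative
immune marker (PTPRC) between neoplastic and healthy cells with a two-sided
rank-sum test — chosen over a t-test because zero-inflated expression is far
from normal. A marker is flagged inconsistent when its p ≥ 0.05 or its mean
difference points the wrong way. Healthy clusters are annotated with the
cell type whose marker-set mean score is maximal; exact ties resolve
alphabetically with a warning, and a cluster scoring zero on every set is
left `unassigned`.

## TAM subtypes, polarization, stemness

The macrophage/microglia split runs PCA on the 237-gene subtype signature
restricted to TAM cells and partitions the first two components by 2-means
(seeded, deterministic); a plane rather than a single-axis sign split
because the separation need not align with PC1. Groups are then *named* by
which half of the 66-gene macrophage/microglia marker panel scores higher on
average; swapping the two marker sub-lists therefore swaps the labels
exactly. If the two groups are not distinguishable (silhouette < 0.05, or
all cells identical), the split falls back to per-cell marker-score
comparison with a warning.

M1/M2 polarization scores are marker-set means on the log scale (the
linear-vs-log choice is a convention; log matches the data model), and the
cohort-level association between them is a Spearman correlation. Genes
missing from a marker list are dropped, never imputed; the shipped synthetic
lists carry no typos by construction, and all marker lists are
user-replaceable.

CSC calling scores tumor cells as the mean log expression of the 90-gene
stemness panel and flags cells at or above the (1 − quantile) empirical
quantile (default top 25%; "high stemness" is not quantified in the
literature this emulates, so the quantile is exposed as a flag). Ties at the
threshold are flagged, so an all-equal cohort is all-CSC with a warning.

## Hurdle differential expression

Per gene, between two disjoint cell groups:

* discrete part: binomial likelihood-ratio of detection (value > 0) on
  group membership vs intercept-only — the closed form of logistic
  regression with one binary covariate; χ²(1).
* continuous part: normal likelihood-ratio on log values of detected cells,
  group vs intercept-only, statistic n·log(RSS₀/RSS₁); χ²(1). If either
  group has fewer than two detected cells the part contributes statistic 0
  with p = 1.

The combined statistic is the sum. Its reference distribution is χ²(2) in
the generic case, with adaptive degrees of freedom at structural
degeneracies: saturated detection (all or none detected in both groups)
removes the discrete df, and an unavailable or zero-variance continuous part
removes the continuous df, so the combined p reduces exactly to the
remaining part's χ²(1) p. The log fold-change is the difference of overall
group means of log2 expression (zeros included), so detection-driven changes
carry a sign; detected-only means are reported alongside.

No covariates are modeled — in particular no cellular-detection-rate term —
a deliberate simplification relative to full hurdle-model implementations.
Under the generator's zero-inflated NB null (100 cells per group) the
combined test is slightly liberal (empirical type-I error ≈ 0.05–0.06 at
α = 0.05, measured by the benchmark suite), the expected cost of χ²
asymptotics at these group sizes. Multiple testing uses Benjamini–Hochberg
step-up; screens filter on adjusted p < 0.05 by default (`use_adjusted`
exposes the raw-p alternative) and on the fold-change sign.

## Crosstalk screens

Spearman ρ is Pearson correlation of mid-ranks; two-sided p-values use the
t approximation with n − 2 df for n > 8 and exact enumeration over all n!
rank permutations for n ≤ 8 (counting |ρ| ≥ |ρ_obs| − 10⁻¹²). Constant
vectors are rejected rather than given ρ = 0.

The autocrine screen is two-stage: stage 1 keeps ligand-receptor rows whose
two genes are both in the up-in-tumor DE table; stage 2 keeps pairs with
bulk co-expression ρ > 0.4 (strict inequality) and p < 0.05. Both flags are
recorded per pair, so the output is monotone in both thresholds. Self-pairs
(ligand = receptor) are excluded with a warning. The directional screen
keeps rows whose ligand is up in the sender vs its reference and whose
receptor is up in the receiver vs its reference, both at BH-adjusted
p < 0.05; the CSC→macrophage screen uses (CSC, differentiated tumor,
macrophage, microglia) and the reverse direction swaps the roles.

Pathway over-representation is the one-sided hypergeometric upper tail with
BH correction across pathways; the universe defaults to all genes in the
expression matrix and query genes outside it are dropped with a warning.

## Survival screening

Kaplan–Meier estimation and the log-rank test are delegated to lifelines
(and are checked in the test suite against hand-computed product-limit and
O−E oracles). The median-split screen puts samples strictly above a gene's
expression median in the "high" group (ties to "low"), computes the
log-rank χ²(1), and reports which group has worse survival from the sign of
the high group's observed-minus-expected event count. Constant genes are
skipped with a warning. Following the per-gene reporting convention of the
analyses this emulates, the screen's `significant` flag uses unadjusted
p < 0.05; BH-adjusted screening is available via the `bh_adjust` utility.

## Prognostic model

The binary outcome is death observed at or before a horizon, defaulting to
the cohort's median follow-up time; samples censored before the horizon are
uninformative and excluded with a logged count. This label construction is
the package's own (exposed as `--horizon`), and is the largest
reproducibility gap relative to published precision/recall figures, which
never state their label rule.

The classifier is gradient-boosted trees (XGBoost): depth 3, 200 rounds,
learning rate 0.1, 0.8 row and column subsampling, and a class-balancing
`scale_pos_weight` computed from the training labels so the fixed 0.5
probability cut is meaningful under imbalanced outcomes. Early stopping on a
10% validation fold is available (`early_stopping=True`) but off by
default: at cohort sizes of a few hundred samples the extra fold both
shrinks the training set and adds fold-sampling variance, which measurably
destabilized held-out recall. Features enter as log2(TPM + 1).

Training uses a stratified 75/25 split (the 3:1 rule; stratification
stabilizes small-test-set metrics). Reported precision/recall are
positive-class (high-risk) metrics at the 0.5 cut. Feature importance is
XGBoost's default importance ranking, zero for features never used in a
split; note that duplicated or highly correlated features share credit.
External validation predicts risk groups on an independent cohort and tests
their separation by log-rank; random-gene baselines retrain the identical
procedure on uniformly drawn gene panels of the same size.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale, with known truth — not glioma biology.

**Single-cell cohort.** Counts are negative-binomial with gene-level
dispersion (size log-normal around 10, σ = 0.3) around a log-mean built
from: a base abundance per gene ~ N(2.5, 0.5) on the natural-log count
scale (a deliberately tight "expressed genes" band: with a wide band,
low-abundance sampling noise dominates the log-scale variance ranking and
the HVG statistic stops reflecting biology); patient-private malignant
programs (a disjoint random 2% of genes per patient shifted by
`program_effect`, default 3.0 — block shifts standing in for CNV-scale
differences, larger than any single-marker effect); three shared healthy
programs (myeloid, oligodendrocyte, neuron); and marker-set shifts of
`marker_effect` (default 2.0) — EGFR-analogue in malignant cells,
PTPRC-analogue in myeloid cells, per-type healthy markers (the macrophage
and microglia marker sets both fire in all myeloid cells: residential
annotation treats them as one myeloid type), the stemness panel in a
`csc_fraction` of tumor cells, and independent per-cell M1/M2 activation
levels in macrophages. The macrophage/microglia signature contrast is set
to `marker_effect`/4 so that — as in the real data — the two subtypes
co-cluster as one myeloid group globally and separate only under targeted
signature PCA. Default cell fractions give each of the 13 programs ≈ 7% of
cells, so no program monopolizes the top-5% HVG slots. Dropout is Bernoulli
with probability decaying in the latent mean (rate·e^(−μ/10)): lowly
expressed transcripts fail capture, highly expressed ones rarely do. Counts
are then scaled to TPM per cell and logged.

**Bulk cohort.** Gene TPM is log-normal; each planted (ligand, receptor,
ρ) pair is drawn from a bivariate Gaussian copula with Pearson parameter
r = 2·sin(πρ/6) — the exact Gaussian-copula↔Spearman correspondence — so
the empirical Spearman correlation targets ρ (each gene may appear in at
most one planted pair). Survival times are exponential with log hazard
linear in the standardized latent expression of designated hazard genes
(baseline mean survival 1000 days). Censoring marks each subject
independently with probability `censoring_rate` and draws the censored
observation time uniformly below the latent death time — chosen because it
hits the configured rate exactly, including the all-censored boundary.

**LR table.** Planted pairs plus uniformly drawn decoy pairs over genes not
involved in any planted pair; truth flags are returned separately.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: CNV structure (patient programs are disjoint
gene blocks, not chromosomal segments), doublets, batch and patient-level
technical effects, gene-length bias in TPM, mean-variance trends beyond the
NB family, correlated marker programs, non-proportional hazards, and
covariate-driven censoring. Results on real cohorts additionally depend on
the marker lists and the LR database supplied.

## Benchmark problem sizes

The benchmark suite (`gliotalk.benchmarks`, reported by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`) uses:
10,000 null genes at 100 cells/group for hurdle calibration; 20 replicates
of 10 planted pairs (ρ = 0.6) + 500 decoys at 300 bulk samples for
crosstalk recovery; one 10-patient × 100-cell cohort for malignancy, TAM
and CSC recovery; five 200-gene null cohorts and 20 planted-gene replicates
at 500 samples for the survival screen; and five 600-sample cohorts with
six hazard genes (coefficient 1.5) for the prognostic model, with 50
random-gene baselines and 20 external-validation replicates. Quantities
with non-trivial sampling noise (survival null rate, precision/recall) are
reported as means over the replicate cohorts; all thresholds apply to those
means.

## Limitations

The purity threshold for the malignancy call, the CSC quantile, the DE
thresholds of the screens, and the outcome horizon are conventions exposed
as flags, not estimated quantities. The hurdle test omits the
detection-rate covariate and will not numerically match full hurdle-model
packages. k-means clustering assumes roughly isotropic clusters in the PCA
embedding; silhouette-based auto-k can under-segment when cluster sizes are
very unequal. Published headline counts from the real cohorts (autocrine
pair counts, survival-gene counts, precision/recall on TCGA/CGGA) are not
reproducible without those datasets and are out of scope here; the
benchmarks establish the property-level analogues on synthetic data.
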