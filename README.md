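# gliotalk

Ligand-receptor crosstalk analysis of the glioma tumor microenvironment,
from single-cell and bulk expression data to a prognostic classifier.

Gliomas are infiltrated by non-malignant cells — mostly macrophages and
microglia — and tumor cells communicate with them (and with themselves)
through secreted ligands binding cell-surface receptors. `gliotalk`
implements the full analysis chain that turns a single-cell expression
matrix, a bulk survival cohort, and a ligand→receptor pair table into a
ranked set of candidate cell-to-cell interactions and a survival model:

1. **Cell typing** — cluster cells on the top-5% highly variable genes;
   call a cluster *neoplastic* when it is dominated by a single patient
   (malignant expression programs are patient-private, healthy programs are
   shared), validate with an EGFR-like positive and PTPRC-like negative
   marker, and annotate healthy clusters by marker-set scoring.
2. **TAM subtypes and stem-like cells** — separate macrophages from
   microglia by PCA on a 237-gene signature followed by 2-means, score
   M1/M2 polarization, and flag cancer stem-like cells (CSCs) as the tumor
   cells in the top quantile of a 90-gene stemness score.
3. **Differential expression** — a two-part (hurdle) test per gene:
   a binomial likelihood-ratio on detection plus a normal likelihood-ratio
   on detected log values, combined as a chi-square sum, with
   Benjamini–Hochberg FDR control.
4. **Crosstalk screens** — *autocrine*: ligand and receptor both
   up-regulated in tumor cells, then validated by bulk co-expression
   (Spearman ρ > 0.4, p < 0.05); *directional*: ligand up in the sender
   population, receptor up in the receiver population (CSC → macrophage and
   macrophage → CSC), both at adjusted p < 0.05. Pathway over-representation
   of the surviving genes uses the hypergeometric tail.
5. **Survival screening** — Kaplan–Meier curves and log-rank tests after
   splitting the bulk cohort at each crosstalk gene's median expression.
6. **Prognosis** — an XGBoost classifier over the crosstalk-gene panel
   predicting death by a follow-up horizon, trained on a stratified 3:1
   split, scored by positive-class precision/recall, validated on an
   external cohort by log-rank separation of predicted risk groups, and
   benchmarked against random-gene models.

A bundled synthetic-data generator (`gliotalk.synthetic`) emulates all of
the required inputs with known ground truth — patient-private malignant
programs, shared healthy programs, a planted stemness gradient, planted
co-expressed ligand-receptor pairs with a target Spearman ρ (via the exact
Gaussian-copula mapping r = 2·sin(πρ/6)), and exponential survival times
linked to designated hazard genes — so every stage is testable end to end.

## Worked example

The whole pipeline runs on a synthetic cohort with one command
(`gliotalk demo --seed 1`) or from Python:

```python
from gliotalk import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(seed=1, out_dir="demo"))
```

With seed 1 this prints (to `demo/summary.json`):

```json
{
  "n_cells": 800,
  "n_clusters": 12,
  "n_neoplastic_clusters": 10,
  "marker_validation_consistent": true,
  "n_macrophages": 31,
  "n_microglia": 30,
  "m1_m2_spearman_rho": 0.0577,
  "m1_m2_spearman_p": 0.758,
  "n_csc": 160,
  "n_autocrine_stage1": 20,
  "n_autocrine_pairs": 4,
  "n_csc_to_macrophage_pairs": 4,
  "n_macrophage_to_csc_pairs": 5,
  "n_survival_screened": 18,
  "n_survival_significant": 6,
  "test_precision": 0.765,
  "test_recall": 0.765,
  "test_logrank_p": 8.66e-13
}
```

Reading it: the 800 cells resolve into 12 clusters of which 10 are
patient-private (one per patient — the neoplastic clusters), and the
malignancy call is confirmed by the marker validation. The myeloid cells
split into 31 macrophages and 30 microglia, whose M1/M2 scores are
uncorrelated (ρ = 0.06, p = 0.76 — mixed polarization states, not a
dichotomy). Of 212 ligand-receptor pairs, 20 have both genes up-regulated
in tumor cells and 4 survive the bulk co-expression filter — exactly the 4
autocrine pairs the generator planted. The directional screens recover the
planted CSC→macrophage and macrophage→CSC pairs, 6 of the 18 crosstalk
genes are survival-associated at the median split, and the classifier
trained on the crosstalk panel reaches precision = recall = 0.765 on the
held-out quarter, splitting it into risk groups with log-rank p ≈ 9·10⁻¹³.

Every stage is also exposed as a CLI subcommand over files
(`gliotalk simulate | celltype | tam | de | autocrine | crosstalk |
survive | prognosis | run`); see `gliotalk <cmd> --help`.

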