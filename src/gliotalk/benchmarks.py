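"""End-to-end benchmark measurements of the pipeline on synthetic cohorts.

Each function simulates data under the study conditions the package is
designed for, runs the relevant pipeline stages from scratch, and measures a
calibration or recovery quantity: hurdle-test type-I error, planted
ligand-receptor recovery, malignancy-call accuracy, TAM-subtype and CSC
recovery, survival-screen calibration and power, and prognostic-model
performance against random-gene baselines. The test suite asserts on these
quantities and ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cell_typing import call_neoplastic, cluster_cells, select_hvg, validate_malignancy
from .crosstalk import autocrine_screen
from .diffexpr import de_screen, hurdle_test_genes
from .pipeline import default_demo_sim
from .prognosis import (
    baseline_percentile,
    external_validate,
    make_outcome_labels,
    random_gene_baseline,
    train_model,
)
from .survival import median_split_screen
from .synthetic import SimConfig, simulate_bulk_cohort, simulate_lr_table, simulate_sc_cohort
from .tam_stem import call_csc, split_tam


def hurdle_type1_error(seed: int, n_genes: int = 10000, cells_per_group: int = 100,
                       alpha: float = 0.05) -> dict:
    """Empirical type-I error of the hurdle test under the zero-inflated NB null."""
    sim = SimConfig(
        n_patients=2, cells_per_patient=cells_per_group, n_genes=n_genes,
        marker_effect=0.0, program_effect=0.0, healthy_fraction={},
        csc_fraction=0.0, seed=seed,
    )
    matrix, truth, _ = simulate_sc_cohort(sim)
    group_a = truth.index[truth["patient"] == "patient_00"]
    group_b = truth.index[truth["patient"] == "patient_01"]
    res = hurdle_test_genes(matrix, group_a, group_b)
    return {"type1_error": float((res["combined_p"] < alpha).mean()), "n": n_genes}


def crosstalk_recovery(seed: int, n_replicates: int = 20, n_planted: int = 10,
                       n_decoys: int = 500, n_bulk: int = 300) -> dict:
    """Planted autocrine-pair recovery through the full two-stage screen.

    Each replicate simulates a single-cell cohort (for the DE stage) and a
    bulk cohort with the planted pairs at Spearman rho = 0.6, both sides of
    every planted pair drawn from the tumor-elevated stemness block, plus
    decoy pairs; recall and the decoy pass rate are averaged over replicates.
    """
    recalls, decoy_rates = [], []
    for rep in range(n_replicates):
        base = SimConfig(n_patients=10, cells_per_patient=50, n_genes=1500,
                         n_bulk_samples=n_bulk, seed=seed + 1000 * rep)
        from .synthetic import build_gene_layout

        layout = build_gene_layout(base, np.random.default_rng(base.seed))
        stem = layout.catalog["stemness_90"]
        pairs = [(stem[2 * i], stem[2 * i + 1], 0.6) for i in range(n_planted)]
        sim = dataclasses.replace(base, planted_pairs=pairs)
        matrix, truth, _ = simulate_sc_cohort(sim)
        bulk, _ = simulate_bulk_cohort(sim, genes=matrix.genes)
        lr, lr_truth = simulate_lr_table(sim, n_decoys=n_decoys, genes=matrix.genes)
        tumor = truth.index[truth["true_type"] == "neoplastic"]
        healthy = truth.index[truth["true_type"] != "neoplastic"]
        lr_genes = pd.Index(lr.pairs.to_numpy().ravel()).unique()
        de_up = de_screen(matrix, tumor, healthy, genes=lr_genes,
                          direction="up_in_a", alpha=0.05, use_adjusted=True)
        result = autocrine_screen(de_up, lr, bulk, rho_min=0.4, alpha=0.05)
        key = result.set_index(["ligand", "receptor"])["pass_overall"]
        planted_keys = [(l, r) for l, r, _ in pairs]
        decoy_keys = list(
            lr_truth.loc[~lr_truth["planted"], ["ligand", "receptor"]]
            .itertuples(index=False, name=None)
        )
        recalls.append(float(key.reindex(planted_keys).fillna(False).mean()))
        decoy_rates.append(float(key.reindex(decoy_keys).fillna(False).mean()))
    return {
        "recall": float(np.mean(recalls)),
        "decoy_pass_rate": float(np.mean(decoy_rates)),
        "n": n_replicates,
    }


def malignancy_benchmark(seed: int) -> dict:
    """Cluster-level neoplastic/healthy call accuracy plus marker validation."""
    sim = SimConfig(seed=seed)  # 10 patients x 100 cells, marker_effect 2
    matrix, truth, catalog = simulate_sc_cohort(sim)
    labels = cluster_cells(matrix, select_hvg(matrix, 0.05), k=13, seed=seed)
    report = call_neoplastic(labels, matrix.cell_meta["patient"], purity_min=0.9)
    tumor_frac = pd.crosstab(labels, truth["true_type"] == "neoplastic")
    cluster_truth = (tumor_frac[True] / tumor_frac.sum(axis=1)) > 0.5
    accuracy = float(
        (report.table["neoplastic"] == cluster_truth.loc[report.table.index]).mean()
    )
    validation = validate_malignancy(matrix, labels, report)
    return {
        "cluster_accuracy": accuracy,
        "egfr_p": float(validation.loc["EGFR", "p_value"]),
        "consistent": bool(~validation["inconsistent"].any()),
        "n": matrix.n_cells,
    }


def tam_csc_benchmark(seed: int) -> dict:
    """Macrophage/microglia subtype accuracy and CSC flag/truth Jaccard."""
    sim = SimConfig(seed=seed)
    matrix, truth, catalog = simulate_sc_cohort(sim)
    tam_cells = truth.index[truth["true_type"].isin(["macrophage", "microglia"])]
    report = split_tam(matrix, tam_cells, catalog["tam_signature_237"],
                       catalog["mac_markers"], catalog["mic_markers"], seed=seed)
    tam_acc = float((report.cells["subtype"] == truth.loc[tam_cells, "true_type"]).mean())
    tumor = truth.index[truth["true_type"] == "neoplastic"]
    csc = call_csc(matrix, tumor, catalog["stemness_90"], quantile=sim.csc_fraction)
    called = set(csc.cells.index[csc.cells["is_csc"]])
    planted = set(truth.index[truth["is_csc"]])
    jaccard = float(len(called & planted) / len(called | planted))
    return {"tam_accuracy": tam_acc, "csc_jaccard": jaccard, "n": int(len(tam_cells))}


def survival_benchmark(seed: int, n_null_genes: int = 200, n_replicates: int = 20,
                       n_samples: int = 500) -> dict:
    """Median-split screen: null significance rate and planted-gene power.

    The null rate is the mean over five replicate cohorts of the significant
    fraction among ``n_null_genes`` survival-independent genes (one 200-gene
    draw has ~0.016 binomial noise, so replicates measure the same rate with
    usable precision).
    """
    null_rates = []
    for rep in range(5):
        sim = SimConfig(n_genes=900, n_bulk_samples=n_samples, seed=seed + 7 * rep)
        cohort, _ = simulate_bulk_cohort(sim)
        null_screen = median_split_screen(cohort, list(cohort.genes[:n_null_genes]))
        null_rates.append(float(null_screen["significant"].mean()))
    null_rate = float(np.mean(null_rates))
    hits = 0
    for rep in range(n_replicates):
        sim_r = SimConfig(n_genes=900, n_bulk_samples=n_samples, seed=seed + 100 + rep,
                          hazard_genes=[("G00700", 1.0)])
        cohort_r, _ = simulate_bulk_cohort(sim_r)
        row = median_split_screen(cohort_r, ["G00700"]).iloc[0]
        hits += bool(row["significant"] and row["direction"] == "high_worse")
    return {
        "null_significant_rate": null_rate,
        "planted_detection_rate": hits / n_replicates,
        "n": n_samples,
    }


def prognosis_benchmark(seed: int, n_samples: int = 600, n_replicates: int = 5,
                        n_baselines: int = 50, n_external: int = 20) -> dict:
    """Prognostic-model precision/recall, baseline percentile, transportability.

    Precision and recall are means over independent cohort replicates; the
    baseline comparison and external validation use the first replicate's
    model.
    """
    base = default_demo_sim(seed)
    features = sorted({g for p in base.planted_pairs for g in p[:2]})
    hazard = [(g, 1.5) for g in features[:6]]
    precs, recs = [], []
    first_model = first_bulk = first_labels = first_sim = None
    for rep in range(n_replicates):
        sim = dataclasses.replace(base, n_bulk_samples=n_samples,
                                  hazard_genes=hazard, seed=seed + 10 * rep)
        bulk, _ = simulate_bulk_cohort(sim)
        labels, _ = make_outcome_labels(bulk.clinical)
        model, report = train_model(bulk, features, labels, seed=seed + rep)
        precs.append(report.precision)
        recs.append(report.recall)
        if rep == 0:
            first_model, first_bulk, first_labels, first_sim = model, bulk, labels, sim
    baseline = random_gene_baseline(first_bulk, len(features), n_baselines,
                                    first_labels, seed=seed + 5000)
    pct_prec = baseline_percentile(baseline, precs[0], "precision")
    pct_rec = baseline_percentile(baseline, recs[0], "recall")
    sig = 0
    for rep in range(n_external):
        fresh, _ = simulate_bulk_cohort(
            dataclasses.replace(first_sim, seed=seed + 20000 + rep)
        )
        sig += external_validate(first_model, fresh).logrank_p < 0.05
    return {
        "precision": float(np.mean(precs)),
        "recall": float(np.mean(recs)),
        "baseline_percentile_precision": float(pct_prec),
        "baseline_percentile_recall": float(pct_rec),
        "external_logrank_significant_fraction": sig / n_external,
        "n": n_samples,
    }


def structural_echoes(seed: int) -> dict:
    """Printed-parameter checks: HVG count, 3:1 split sizes, LR pair count."""
    from .cell_typing import HVGSelector
    from .data_model import LRTable

    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(rng.random((1000, 20)),
                         index=[f"G{i:04d}" for i in range(1000)])
    hvg_count = len(HVGSelector(0.05).fit(frame).selected_)

    sim = default_demo_sim(seed)
    bulk, _ = simulate_bulk_cohort(dataclasses.replace(sim, n_bulk_samples=150))
    features = sorted({g for p in sim.planted_pairs for g in p[:2]})
    labels, _ = make_outcome_labels(bulk.clinical)
    labels = labels.iloc[:100]
    _, report = train_model(bulk, features, labels, split_ratio=0.75, seed=seed)
    test_n = int(report.n)

    rng2 = np.random.default_rng(seed + 1)
    genes = [f"LG{i:05d}" for i in range(400)]
    pairs = set()
    while len(pairs) < 2419:
        i, j = rng2.integers(0, 400, 2)
        if i != j:
            pairs.add((genes[i], genes[j]))
    lr = LRTable(pd.DataFrame(sorted(pairs), columns=["ligand", "receptor"]))
    return {
        "hvg_count_at_5pct_of_1000": hvg_count,
        "test_fraction_of_100": test_n,
        "lr_pair_count": len(lr),
        "n": 2419,
    }
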