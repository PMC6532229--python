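"""End-to-end orchestration: simulate -> cell typing -> TAM/CSC -> DE ->
autocrine -> directional crosstalk -> survival screen -> prognosis.

A :class:`PipelineConfig` carries every stage threshold and a single global
seed, which fans out to per-stage seeds by fixed offsets so stage-level
stochasticity is isolated. ``run_pipeline`` writes per-stage TSV outputs, a
manifest (parameters, seeds, input hashes, package version) and a summary
(pair counts per screen, significant survival genes, model metrics); the
summary is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cell_typing import annotate_healthy, call_neoplastic, cluster_cells, select_hvg, validate_malignancy
from .crosstalk import autocrine_screen, directional_screen
from .data_model import BulkCohort, GeneSetCatalog, LRTable, SingleCellMatrix, write_expression, write_gene_sets, write_lr_table
from .diffexpr import de_screen
from .prognosis import external_validate, make_outcome_labels, rank_importance, train_model
from .survival import median_split_screen
from .synthetic import SimConfig, simulate_bulk_cohort, simulate_lr_table, simulate_sc_cohort
from .tam_stem import call_csc, polarization, split_tam

logger = logging.getLogger("gliotalk")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Thresholds and seeds for a full run (defaults follow the study)."""

    hvg_fraction: float = 0.05
    purity_min: float = 0.9
    csc_quantile: float = 0.25
    alpha: float = 0.05
    rho_min: float = 0.4
    split_ratio: float = 0.75
    k: int | str = "auto"
    horizon: float | None = None
    seed: int = 0
    out_dir: str = "gliotalk_out"
    sim: SimConfig | None = None
    n_decoys: int = 200
    n_planted_pairs: int = 8

    def validate(self) -> None:
        checks = [
            ("hvg_fraction", self.hvg_fraction, 0.0, 1.0),
            ("purity_min", self.purity_min, 0.0, 1.0),
            ("csc_quantile", self.csc_quantile, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
            ("rho_min", self.rho_min, -1.0, 1.0),
            ("split_ratio", self.split_ratio, 0.0, 1.0),
        ]
        for name, value, lo, hi in checks:
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


def default_demo_sim(seed: int, n_genes: int = 1500, cells_per_patient: int = 80,
                     n_bulk_samples: int = 400) -> SimConfig:
    """Demo simulation: planted LR pairs aligned with every screen.

    Autocrine pairs take both genes from the stemness block (up-regulated in
    tumor cells); CSC -> macrophage pairs take ligands from the stemness
    block and receptors from the macrophage marker panel; the reverse
    direction swaps the roles. Hazard coefficients sit on crosstalk genes so
    the survival screen and the prognostic model see planted signal, with
    co-expression planted at Spearman rho = 0.6 throughout.
    """
    import dataclasses

    from .synthetic import build_gene_layout

    base = SimConfig(
        n_patients=10,
        cells_per_patient=cells_per_patient,
        n_genes=n_genes,
        n_bulk_samples=n_bulk_samples,
        seed=seed,
    )
    layout = build_gene_layout(base, np.random.default_rng(seed))
    stem = layout.catalog["stemness_90"]
    mac = layout.mac_markers
    planted = (
        [(stem[i], stem[4 + i], 0.6) for i in range(4)]          # autocrine
        + [(stem[8 + i], mac[i], 0.6) for i in range(4)]          # csc -> mac
        + [(mac[4 + i], stem[12 + i], 0.6) for i in range(4)]     # mac -> csc
    )
    hazard = [(g, 1.0) for g in stem[8:12]] + [(g, 1.0) for g in mac[:2]]
    return dataclasses.replace(base, planted_pairs=planted, hazard_genes=hazard)


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    matrix: SingleCellMatrix | None = None,
    bulk: BulkCohort | None = None,
    lr: LRTable | None = None,
    catalog: GeneSetCatalog | None = None,
) -> dict:
    """Run every stage; returns the summary dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    stage = "simulate"
    try:
        if matrix is None or bulk is None or lr is None or catalog is None:
            sim = config.sim or default_demo_sim(config.seed)
            matrix, truth, catalog = simulate_sc_cohort(sim)
            bulk, gene_truth = simulate_bulk_cohort(sim, genes=matrix.genes)
            lr, lr_truth = simulate_lr_table(sim, n_decoys=config.n_decoys, genes=matrix.genes)
            truth.to_csv(out / "truth_cells.tsv", sep="\t")
            gene_truth.to_csv(out / "truth_genes.tsv", sep="\t")
            lr_truth.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
            write_expression(matrix, out / "sc_matrix.tsv", out / "sc_meta.tsv")
            write_expression(bulk, out / "bulk_matrix.tsv", out / "bulk_clinical.tsv")
            write_lr_table(lr, out / "lr_table.tsv")
            write_gene_sets(catalog, out / "gene_sets.gmt")
        summary["n_cells"] = matrix.n_cells
        summary["n_bulk_samples"] = len(bulk.samples)
        summary["n_lr_pairs"] = len(lr)

        stage = "celltype"
        hvg = select_hvg(matrix, config.hvg_fraction)
        labels = cluster_cells(matrix, hvg, k=config.k, seed=config.seed + 10)
        report = call_neoplastic(labels, matrix.cell_meta["patient"], config.purity_min)
        validation = validate_malignancy(matrix, labels, report)
        types = annotate_healthy(matrix, labels, report, catalog)
        matrix.cell_meta["cluster"] = labels
        matrix.cell_meta["cell_type"] = types
        report.table.to_csv(out / "cluster_report.tsv", sep="\t")
        validation.to_csv(out / "marker_validation.tsv", sep="\t")
        types.to_frame().to_csv(out / "cell_types.tsv", sep="\t")
        summary["n_clusters"] = len(report.table)
        summary["n_neoplastic_clusters"] = len(report.neoplastic_clusters())
        summary["marker_validation_consistent"] = bool(~validation["inconsistent"].any())

        stage = "tam"
        tam_cells = types.index[types.isin(["macrophage", "microglia"])]
        tumor_cells = types.index[types == "neoplastic"]
        tam = split_tam(matrix, tam_cells, catalog["tam_signature_237"],
                        catalog["mac_markers"] if "mac_markers" in catalog else catalog["mac_micro_markers_66"][:33],
                        catalog["mic_markers"] if "mic_markers" in catalog else catalog["mac_micro_markers_66"][33:],
                        seed=config.seed + 20)
        macs = tam.cells.index[tam.cells["subtype"] == "macrophage"]
        micro = tam.cells.index[tam.cells["subtype"] == "microglia"]
        _, rho_pol, p_pol = polarization(matrix, macs, catalog["m1_markers"], catalog["m2_markers"])
        csc = call_csc(matrix, tumor_cells, catalog["stemness_90"], config.csc_quantile)
        matrix.cell_meta["is_csc"] = csc.cells["is_csc"].reindex(matrix.cells, fill_value=False)
        tam.cells.to_csv(out / "tam_report.tsv", sep="\t")
        csc.cells.to_csv(out / "csc_report.tsv", sep="\t")
        summary["n_macrophages"] = int(len(macs))
        summary["n_microglia"] = int(len(micro))
        summary["m1_m2_spearman_rho"] = float(rho_pol)
        summary["m1_m2_spearman_p"] = float(p_pol)
        summary["n_csc"] = int(csc.cells["is_csc"].sum())

        stage = "de"
        healthy_cells = types.index[~types.isin(["neoplastic"])]
        lr_genes = pd.Index(lr.pairs["ligand"]).union(lr.pairs["receptor"])
        de_up = de_screen(matrix, tumor_cells, healthy_cells, genes=lr_genes,
                          direction="up_in_a", alpha=config.alpha, use_adjusted=True)
        de_up.to_csv(out / "de_up_in_tumor.tsv", sep="\t")
        summary["n_de_up_lr_genes"] = int(len(de_up))

        stage = "autocrine"
        auto = autocrine_screen(de_up, lr, bulk, rho_min=config.rho_min, alpha=config.alpha)
        auto.to_csv(out / "autocrine.tsv", sep="\t", index=False)
        summary["n_autocrine_stage1"] = int(auto["pass_de"].sum())
        summary["n_autocrine_pairs"] = int(auto["pass_overall"].sum())

        stage = "crosstalk"
        diff_tumor = tumor_cells.difference(csc.cells.index[csc.cells["is_csc"]])
        csc_cells = csc.cells.index[csc.cells["is_csc"]]
        c2m = directional_screen(matrix, csc_cells, diff_tumor, macs, micro, lr,
                                 alpha=config.alpha, direction_label="csc_to_macrophage")
        m2c = directional_screen(matrix, macs, micro, csc_cells, diff_tumor, lr,
                                 alpha=config.alpha, direction_label="macrophage_to_csc")
        pd.concat([c2m, m2c]).to_csv(out / "crosstalk.tsv", sep="\t", index=False)
        summary["n_csc_to_macrophage_pairs"] = int(len(c2m))
        summary["n_macrophage_to_csc_pairs"] = int(len(m2c))

        stage = "survive"
        talk_genes = pd.Index(pd.concat([c2m, m2c])[["ligand", "receptor"]].to_numpy().ravel()).unique()
        if len(talk_genes) == 0:
            talk_genes = lr_genes
        screen = median_split_screen(bulk, talk_genes)
        screen.to_csv(out / "survival_screen.tsv", sep="\t", index=False)
        summary["n_survival_screened"] = int(len(screen))
        summary["n_survival_significant"] = int(screen["significant"].sum())

        stage = "prognosis"
        labels_y, horizon = make_outcome_labels(bulk.clinical, config.horizon)
        features = list(talk_genes)
        model, eval_report = train_model(bulk, features, labels_y,
                                         split_ratio=config.split_ratio,
                                         seed=config.seed + 30)
        importance = rank_importance(model, top_k=10)
        importance.to_csv(out / "importance.tsv", sep="\t", index=False)
        eval_report.risk_groups.to_frame().to_csv(out / "risk_groups.tsv", sep="\t")
        summary["horizon_days"] = float(horizon)
        summary["test_precision"] = float(eval_report.precision)
        summary["test_recall"] = float(eval_report.recall)
        summary["test_logrank_p"] = float(eval_report.logrank_p)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "sim"},
        "sim": asdict(config.sim) if config.sim else "demo-default",
        "inputs": {
            "sc_matrix": _hash_frame(matrix.values),
            "bulk_matrix": _hash_frame(bulk.values),
            "lr_table": _hash_frame(lr.pairs),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", summary)
    return summary
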