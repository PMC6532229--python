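"""Synthetic single-cell and bulk glioma cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not glioma biology itself:

* **Single-cell cohort** — each patient contributes a block of cells. Malignant
  cells carry a patient-private expression program (a mean shift on a disjoint
  random 2% of genes), so that clustering recovers one cluster per patient;
  healthy cells carry programs shared across patients (one myeloid program for
  macrophages+microglia, one each for oligodendrocytes and neurons by default,
  reproducing the 10-private + 3-shared cluster layout of the real data).
  Marker genes follow the configured effect size: an EGFR-like gene is up in
  malignant cells, a PTPRC-like gene in myeloid cells, per-type healthy
  markers in their home type, the 66 macrophage/microglia markers split
  between the two TAM subtypes, the 237-gene TAM signature split likewise,
  M1/M2 markers driven by independent per-cell activation levels, and the
  90-gene stemness set elevated in a configured fraction of tumor cells.
  Counts are negative-binomial with log-normal gene dispersion, thinned by
  Bernoulli dropout, scaled to TPM per cell and logged as log2(TPM/10 + 1).

* **Bulk cohort** — log-normal TPM per gene; each planted (ligand, receptor,
  rho) pair is drawn from a bivariate Gaussian copula with Pearson parameter
  r = 2 sin(pi * rho / 6), the exact Gaussian-copula <-> Spearman mapping, so
  the empirical Spearman correlation targets rho. Survival times follow an
  exponential proportional-hazards model whose log hazard is linear in the
  standardized expression of designated hazard genes; censoring is applied at
  a configured rate.

* **LR table** — the planted pairs plus random decoy pairs drawn from genes
  not involved in any planted pair; ground-truth flags are returned
  separately.

All outputs are deterministic functions of the :class:`SimConfig` seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import BulkCohort, GeneSetCatalog, LRTable, SingleCellMatrix

HEALTHY_TYPES = ("macrophage", "microglia", "oligodendrocyte", "neuron", "endothelial")


class ConfigError(ValueError):
    """SimConfig violates one of its invariants."""


def _default_healthy_fraction() -> dict[str, float]:
    # ~80% tumor, 20% healthy; endothelial off by default so the healthy cells
    # form three shared programs (myeloid, oligodendrocyte, neuron). Each
    # shared program covers about the same cell fraction as one patient's
    # tumor cells (~7%), so no single program dominates the variance ranking.
    return {
        "macrophage": 0.034,
        "microglia": 0.034,
        "oligodendrocyte": 0.068,
        "neuron": 0.068,
        "endothelial": 0.0,
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic glioma study.

    Defaults mirror the real study's shape at desk scale: 10 patients,
    a ~500-sample bulk cohort, 60/40 tumor/healthy mix, a 20% stem-like
    fraction of tumor cells, and moderate dropout.
    """

    n_patients: int = 10
    cells_per_patient: int = 100
    healthy_fraction: dict[str, float] = field(default_factory=_default_healthy_fraction)
    n_genes: int = 2000
    marker_effect: float = 2.0       # log-scale shift of marker genes in their home type
    program_effect: float = 3.0      # log-scale shift of private/shared program genes
    dropout_rate: float = 0.3
    csc_fraction: float = 0.2
    # program_effect default exceeds marker_effect: patient-private malignant
    # programs emulate CNV-scale block shifts, which dwarf single-marker effects
    n_bulk_samples: int = 512
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    hazard_genes: list[tuple[str, float]] = field(default_factory=list)
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in [
            ("dropout_rate", self.dropout_rate),
            ("csc_fraction", self.csc_fraction),
            ("censoring_rate", self.censoring_rate),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {frac}")
        if any(f < 0 for f in self.healthy_fraction.values()):
            raise ConfigError("healthy fractions must be non-negative")
        if sum(self.healthy_fraction.values()) > 1.0 + 1e-9:
            raise ConfigError("healthy fractions must sum to <= 1")
        if any(t not in HEALTHY_TYPES for t in self.healthy_fraction):
            raise ConfigError(f"healthy types must be among {HEALTHY_TYPES}")
        for lig, rec, rho in self.planted_pairs:
            if not -1.0 < rho < 1.0:
                raise ConfigError(f"target Spearman rho for ({lig}, {rec}) must be in (-1, 1)")
        if self.n_patients < 1 or self.cells_per_patient < 1 or self.n_genes < 1:
            raise ConfigError("n_patients, cells_per_patient and n_genes must be positive")


# ---------------------------------------------------------------------------
# gene universe layout
# ---------------------------------------------------------------------------

_N_HEALTHY_MARKERS = 12   # per healthy cell type
_N_MAC_MICRO = 66         # split 33/33
_N_SIGNATURE = 237        # includes the 66, split between the two TAM subtypes
_N_POLAR = 8              # per M1/M2 set
_N_STEMNESS = 90


@dataclass
class GeneLayout:
    """Index allocation of marker sets, programs and free genes."""

    symbols: pd.Index
    catalog: GeneSetCatalog
    egfr: str
    ptprc: str
    mac_markers: list[str]
    mic_markers: list[str]
    sig_mac: list[str]
    sig_mic: list[str]
    program_genes: dict[str, np.ndarray]  # program name -> gene indices
    free: np.ndarray                       # indices untouched by markers/programs


def build_gene_layout(config: SimConfig, rng: np.random.Generator) -> GeneLayout:
    """Allocate gene indices to marker sets and expression programs."""
    n = config.n_genes
    n_marker = 2 + 5 * _N_HEALTHY_MARKERS + _N_MAC_MICRO + (_N_SIGNATURE - _N_MAC_MICRO) + 2 * _N_POLAR + _N_STEMNESS
    n_program_sets = config.n_patients + 3  # private programs + myeloid/oligo/neuron
    program_size = max(4, int(round(0.02 * n)))
    if n < n_marker + n_program_sets * program_size + 50:
        raise ConfigError(
            f"n_genes={n} too small for marker sets plus {n_program_sets} programs "
            f"of {program_size} genes"
        )
    symbols = np.array([f"G{i:05d}" for i in range(n)], dtype=object)
    symbols[0], symbols[1] = "EGFR", "PTPRC"

    cursor = 2

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = symbols[cursor:cursor + k].tolist()
        cursor += k
        return out

    healthy_sets = {t: take(_N_HEALTHY_MARKERS) for t in HEALTHY_TYPES}
    mac_markers = take(_N_MAC_MICRO // 2)
    mic_markers = take(_N_MAC_MICRO // 2)
    extra = _N_SIGNATURE - _N_MAC_MICRO
    sig_mac_extra = take(extra // 2)
    sig_mic_extra = take(extra - extra // 2)
    m1 = take(_N_POLAR)
    m2 = take(_N_POLAR)
    stemness = take(_N_STEMNESS)

    sig_mac = mac_markers + sig_mac_extra
    sig_mic = mic_markers + sig_mic_extra

    # programs: disjoint random subsets of the remaining genes
    pool = rng.permutation(np.arange(cursor, n))
    programs: dict[str, np.ndarray] = {}
    offset = 0
    for p in range(config.n_patients):
        programs[f"private:{p}"] = pool[offset:offset + program_size]
        offset += program_size
    for prog in ("myeloid", "oligodendrocyte", "neuron"):
        programs[prog] = pool[offset:offset + program_size]
        offset += program_size
    free = np.sort(pool[offset:])

    catalog = GeneSetCatalog(
        {
            **{f"healthy_markers:{t}": g for t, g in healthy_sets.items()},
            "tam_signature_237": sig_mac + sig_mic,
            "mac_micro_markers_66": mac_markers + mic_markers,
            "mac_markers": mac_markers,
            "mic_markers": mic_markers,
            "m1_markers": m1,
            "m2_markers": m2,
            "stemness_90": stemness,
        }
    )
    return GeneLayout(
        symbols=pd.Index(symbols),
        catalog=catalog,
        egfr="EGFR",
        ptprc="PTPRC",
        mac_markers=mac_markers,
        mic_markers=mic_markers,
        sig_mac=sig_mac,
        sig_mic=sig_mic,
        program_genes=programs,
        free=free,
    )


# ---------------------------------------------------------------------------
# single-cell cohort
# ---------------------------------------------------------------------------


def simulate_sc_cohort(config: SimConfig) -> tuple[SingleCellMatrix, pd.DataFrame, GeneSetCatalog]:
    """Simulate a single-cell glioma cohort with known per-cell truth.

    Returns ``(matrix, truth, catalog)`` where ``truth`` is indexed by cell id
    with columns ``patient``, ``true_type`` (neoplastic / healthy type) and
    ``is_csc``, and ``catalog`` holds the marker sets wired into the data.
    """
    rng = np.random.default_rng(config.seed)
    layout = build_gene_layout(config, rng)
    n_genes = config.n_genes

    sym_to_idx = {s: i for i, s in enumerate(layout.symbols)}

    def idx(genes: list[str]) -> np.ndarray:
        return np.array([sym_to_idx[g] for g in genes], dtype=int)

    # per-cell type assignment
    cells, patients, types, is_csc = [], [], [], []
    for p in range(config.n_patients):
        n_cells = config.cells_per_patient
        counts = {t: int(round(f * n_cells)) for t, f in config.healthy_fraction.items()}
        n_healthy = sum(counts.values())
        n_tumor = n_cells - n_healthy
        n_csc = int(round(config.csc_fraction * n_tumor))
        cell_types = (
            ["neoplastic"] * n_tumor
            + [t for t, c in counts.items() for _ in range(c)]
        )
        csc_flags = [True] * n_csc + [False] * (n_tumor - n_csc) + [False] * n_healthy
        for j, (t, flag) in enumerate(zip(cell_types, csc_flags)):
            cells.append(f"P{p:02d}_C{j:03d}")
            patients.append(f"patient_{p:02d}")
            types.append(t)
            is_csc.append(flag)
    n_cells_total = len(cells)
    truth = pd.DataFrame(
        {"patient": patients, "true_type": types, "is_csc": is_csc},
        index=pd.Index(cells, name="cell"),
    )

    # log-scale mean matrix: base + type/program/marker shifts
    # base abundance of expressed genes: a fairly tight log-normal band, as in
    # an expression matrix already filtered to detected genes; a wide band
    # would let low-abundance sampling noise dominate the variance ranking
    base = rng.normal(2.5, 0.5, size=n_genes)
    log_mu = np.tile(base[:, None], (1, n_cells_total))

    type_arr = np.array(types)
    patient_codes = np.array([int(p.split("_")[1]) for p in patients])
    is_tumor = type_arr == "neoplastic"
    is_myeloid = np.isin(type_arr, ["macrophage", "microglia"])
    eff = config.marker_effect

    def bump(gene_list: list[str], cell_mask: np.ndarray, amount: float) -> None:
        if amount != 0.0 and cell_mask.any() and gene_list:
            log_mu[np.ix_(idx(gene_list), np.where(cell_mask)[0])] += amount

    # patient-private malignant programs and shared healthy programs
    for p in range(config.n_patients):
        mask = is_tumor & (patient_codes == p)
        g = layout.program_genes[f"private:{p}"]
        if mask.any():
            log_mu[np.ix_(g, np.where(mask)[0])] += config.program_effect
    for prog, mask in (
        ("myeloid", is_myeloid),
        ("oligodendrocyte", type_arr == "oligodendrocyte"),
        ("neuron", type_arr == "neuron"),
    ):
        g = layout.program_genes[prog]
        if mask.any():
            log_mu[np.ix_(g, np.where(mask)[0])] += config.program_effect

    # validation markers
    bump([layout.egfr], is_tumor, eff)
    bump([layout.ptprc], is_myeloid, eff)
    # healthy cell-type markers in their home type; macrophage and microglia
    # marker sets both fire in all myeloid cells (the residential annotation
    # treats them as one myeloid type; the subtype contrast lives in the
    # 66-marker / 237-gene signature instead)
    for t, genes in layout.catalog.healthy_markers().items():
        mask = is_myeloid if t in ("macrophage", "microglia") else type_arr == t
        bump(genes, mask, eff)
    # TAM signature + 66 markers split between subtypes, at a quarter of the
    # marker effect: the macrophage/microglia contrast is a sub-cluster
    # distinction, resolved by targeted signature PCA but not by global
    # clustering (the two subtypes co-cluster as one myeloid group)
    bump(layout.sig_mac, type_arr == "macrophage", eff / 4.0)
    bump(layout.sig_mic, type_arr == "microglia", eff / 4.0)
    # independent per-macrophage M1/M2 activation levels
    mac_cols = np.where(type_arr == "macrophage")[0]
    if mac_cols.size and eff != 0.0:
        a1 = rng.uniform(0.0, eff, size=mac_cols.size)
        a2 = rng.uniform(0.0, eff, size=mac_cols.size)
        log_mu[np.ix_(idx(layout.catalog["m1_markers"]), mac_cols)] += a1[None, :]
        log_mu[np.ix_(idx(layout.catalog["m2_markers"]), mac_cols)] += a2[None, :]
    # stemness program in CSC-flagged tumor cells
    bump(layout.catalog["stemness_90"], truth["is_csc"].to_numpy(), eff)

    # negative-binomial counts with log-normal gene dispersion, then dropout
    size = np.exp(rng.normal(np.log(10.0), 0.3, size=n_genes))[:, None]
    mu = np.exp(log_mu)
    p_nb = size / (size + mu)
    counts = rng.negative_binomial(size, p_nb).astype(float)
    if config.dropout_rate > 0:
        # dropout decays with the latent mean: lowly expressed transcripts are
        # the ones that fail capture, highly expressed ones rarely do
        p_drop = config.dropout_rate * np.exp(-mu / 10.0)
        keep = rng.random(counts.shape) >= p_drop
        counts *= keep

    # TPM per cell, then log2(TPM/10 + 1)
    totals = counts.sum(axis=0)
    totals[totals == 0] = 1.0
    tpm = counts / totals[None, :] * 1e6
    values = pd.DataFrame(np.log2(tpm / 10.0 + 1.0), index=layout.symbols, columns=truth.index)

    meta = truth[["patient"]].copy()
    matrix = SingleCellMatrix(values, meta)
    return matrix, truth, layout.catalog


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------


def spearman_to_pearson(rho: float) -> float:
    """Exact Gaussian-copula mapping from target Spearman rho to Pearson r."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


def simulate_bulk_cohort(config: SimConfig, genes: pd.Index | None = None) -> tuple[BulkCohort, pd.DataFrame]:
    """Simulate a bulk TPM cohort with planted co-expression and survival signal.

    Returns ``(cohort, gene_truth)``; ``gene_truth`` is indexed by gene with a
    ``hazard_coef`` column (0 for genes unlinked to survival).
    """
    rng = np.random.default_rng(config.seed + 1)
    if genes is None:
        genes = pd.Index([f"G{i:05d}" for i in range(config.n_genes)])
        genes = genes.delete([0, 1]).insert(0, "PTPRC").insert(0, "EGFR")
    n, m = config.n_bulk_samples, len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    planted_genes: set[str] = set()
    for lig, rec, rho in config.planted_pairs:
        for g in (lig, rec):
            if g not in gene_pos:
                raise ConfigError(f"planted gene {g!r} not among cohort genes")
            if g in planted_genes:
                raise ConfigError(f"gene {g!r} appears in more than one planted pair")
            planted_genes.add(g)
    for g, _ in config.hazard_genes:
        if g not in gene_pos:
            raise ConfigError(f"hazard gene {g!r} not among cohort genes")

    # latent standard-normal matrix with planted pairwise correlation
    z = rng.standard_normal((n, m))
    for lig, rec, rho in config.planted_pairs:
        r = spearman_to_pearson(rho)
        i, j = gene_pos[lig], gene_pos[rec]
        z[:, j] = r * z[:, i] + np.sqrt(1.0 - r * r) * z[:, j]

    mu = rng.normal(3.0, 1.0, size=m)
    sigma = rng.uniform(0.5, 1.5, size=m)
    tpm = np.exp(mu[None, :] + sigma[None, :] * z)
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")
    values = pd.DataFrame(tpm, index=samples, columns=genes)

    # exponential proportional hazards on the standardized latent expression
    eta = np.zeros(n)
    for g, coef in config.hazard_genes:
        eta += coef * z[:, gene_pos[g]]
    base_rate = 1.0 / 1000.0  # ~1000-day baseline mean survival
    t_death = rng.exponential(1.0 / (base_rate * np.exp(eta)))
    censored = rng.random(n) < config.censoring_rate
    observed = np.where(censored, t_death * rng.random(n), t_death)
    clinical = pd.DataFrame(
        {"survival_days": observed, "event": ~censored}, index=samples
    )

    coef_map = dict(config.hazard_genes)
    gene_truth = pd.DataFrame(
        {"hazard_coef": [coef_map.get(g, 0.0) for g in genes]}, index=genes
    )
    return BulkCohort(values, clinical), gene_truth


# ---------------------------------------------------------------------------
# LR table
# ---------------------------------------------------------------------------


def simulate_lr_table(
    config: SimConfig,
    n_decoys: int,
    genes: pd.Index | None = None,
) -> tuple[LRTable, pd.DataFrame]:
    """Planted pairs plus random decoy pairs; truth flags returned separately.

    Decoy pairs are drawn uniformly from genes not used by any planted pair
    (when the pool allows) and never duplicate each other or the planted rows.
    """
    rng = np.random.default_rng(config.seed + 2)
    if genes is None:
        genes = pd.Index([f"G{i:05d}" for i in range(config.n_genes)])
    planted = [(l, r) for l, r, _ in config.planted_pairs]
    planted_genes = {g for pair in planted for g in pair}
    pool = [g for g in genes if g not in planted_genes]
    if len(pool) < 2 or n_decoys > len(pool) * (len(pool) - 1):
        raise ConfigError("decoy request exceeds available distinct gene pairs")
    seen = set(planted)
    decoys: list[tuple[str, str]] = []
    while len(decoys) < n_decoys:
        lig, rec = rng.choice(len(pool), size=2, replace=False)
        pair = (pool[lig], pool[rec])
        if pair not in seen:
            seen.add(pair)
            decoys.append(pair)
    rows = planted + decoys
    table = LRTable(pd.DataFrame(rows, columns=["ligand", "receptor"]))
    truth = pd.DataFrame(
        {
            "ligand": [p[0] for p in rows],
            "receptor": [p[1] for p in rows],
            "planted": [i < len(planted) for i in range(len(rows))],
        }
    )
    return table, truth
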