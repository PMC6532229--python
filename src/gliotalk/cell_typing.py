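"""Cell clustering, patient-composition malignancy calling and annotation.

The malignancy call exploits a hallmark of glioma single-cell data: malignant
cells cluster by patient (their expression programs are patient-private),
while healthy cells of a given type cluster together across patients. A
cluster dominated by a single patient (purity >= ``purity_min``, default 0.9)
is therefore called neoplastic. The call is validated with a positive marker
expected up in tumor cells (EGFR in the real data) and a negative immune
marker (PTPRC), and healthy clusters are annotated by marker-set scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted

from .data_model import GeneSetCatalog, SingleCellMatrix

logger = logging.getLogger("gliotalk")


class HVGSelector(TransformerMixin, BaseEstimator):
    """Rank genes by variance of log expression; keep the top fraction.

    Fitted attributes: ``ranking_`` (all genes in decreasing dispersion
    order) and ``selected_`` (the top ``ceil(fraction * n_genes)``).
    """

    def __init__(self, fraction: float = 0.05):
        self.fraction = fraction

    def fit(self, X: pd.DataFrame, y=None) -> "HVGSelector":
        """X: genes x cells log-expression frame."""
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if X.shape[1] < 2:
            raise ValueError("need at least 2 cells")
        var = X.var(axis=1, ddof=1)
        if (var <= 0).all():
            raise ValueError("no variable genes: matrix is constant")
        order = np.argsort(-var.to_numpy(), kind="stable")
        self.ranking_ = X.index[order]
        k = math.ceil(self.fraction * X.shape[0])
        self.selected_ = self.ranking_[:k]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_")
        return X.loc[self.selected_]


class CellClusterer(ClusterMixin, BaseEstimator):
    """PCA embedding + k-means partitioning of cells.

    ``k="auto"`` selects k over ``k_range`` by silhouette score on the
    embedding. Deterministic given ``random_state``.
    """

    def __init__(self, k: int | str = "auto", n_pcs: int = 20,
                 k_range: tuple[int, int] = (2, 20), random_state: int = 0):
        self.k = k
        self.n_pcs = n_pcs
        self.k_range = k_range
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "CellClusterer":
        """X: cells x genes (note orientation: one row per observation)."""
        n_cells = X.shape[0]
        if isinstance(self.k, int) and not 2 <= self.k <= n_cells:
            raise ValueError(f"k={self.k} outside [2, n_cells={n_cells}]")
        n_pcs = min(self.n_pcs, n_cells - 1, X.shape[1])
        arr = np.asarray(X, dtype=float)
        sd = arr.std(axis=0)
        sd[sd == 0] = 1.0
        arr = (arr - arr.mean(axis=0)) / sd  # z-score genes so none dominates
        emb = PCA(n_components=n_pcs, random_state=self.random_state).fit_transform(arr)
        if self.k == "auto":
            lo, hi = self.k_range
            hi = min(hi, n_cells - 1)
            best_k, best_score = lo, -np.inf
            for k in range(lo, hi + 1):
                labels = KMeans(k, n_init=5, random_state=self.random_state).fit_predict(emb)
                score = silhouette_score(emb, labels)
                if score > best_score:
                    best_k, best_score = k, score
            k_use = best_k
            logger.info("auto k selection: k=%d (silhouette=%.3f)", best_k, best_score)
        else:
            k_use = int(self.k)
        km = KMeans(k_use, n_init=10, random_state=self.random_state).fit(emb)
        self.embedding_ = emb
        self.k_ = k_use
        self.labels_ = km.labels_
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_


@dataclass
class ClusterReport:
    """Per-cluster composition and malignancy calls.

    ``table`` is indexed by cluster id with columns ``size``, ``purity``
    (max patient fraction), ``entropy`` (nats), ``top_patient`` and
    ``neoplastic``; ``composition`` maps cluster -> patient count Series.
    """

    table: pd.DataFrame
    composition: dict[int, pd.Series]
    purity_min: float

    def neoplastic_clusters(self) -> list[int]:
        return list(self.table.index[self.table["neoplastic"]])


def select_hvg(matrix: SingleCellMatrix, fraction: float = 0.05) -> pd.Index:
    """Top-``fraction`` genes by variance of log expression, in rank order."""
    return HVGSelector(fraction).fit(matrix.values).selected_


def cluster_cells(
    matrix: SingleCellMatrix,
    genes: pd.Index | list[str],
    k: int | str = "auto",
    seed: int = 0,
) -> pd.Series:
    """Cluster cells on the chosen gene subset; returns labels indexed by cell."""
    missing = [g for g in genes if g not in matrix.genes]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    sub = matrix.values.loc[list(genes)].T  # cells x genes
    labels = CellClusterer(k=k, random_state=seed).fit_predict(sub)
    return pd.Series(labels, index=matrix.cells, name="cluster")


def call_neoplastic(
    labels: pd.Series,
    patients: pd.Series,
    purity_min: float = 0.9,
) -> ClusterReport:
    """Call clusters neoplastic when dominated by a single patient.

    A cluster is neoplastic iff purity >= purity_min (ties at the threshold
    are neoplastic). Purity is the largest patient fraction; entropy is the
    Shannon entropy (nats) of the patient composition.
    """
    if not labels.index.equals(patients.index):
        patients = patients.loc[labels.index]
    rows, comp = [], {}
    for cl, idx in labels.groupby(labels).groups.items():
        counts = patients.loc[idx].value_counts()
        total = int(counts.sum())
        if total == 0:
            logger.warning("cluster %s is empty; excluded", cl)
            continue
        p = counts.to_numpy() / total
        entropy = float(-(p * np.log(p)).sum())
        purity = float(p.max())
        rows.append(
            {
                "cluster": cl,
                "size": total,
                "purity": purity,
                "entropy": entropy,
                "top_patient": counts.idxmax(),
                "neoplastic": purity >= purity_min,
            }
        )
        comp[cl] = counts
    table = pd.DataFrame(rows).set_index("cluster").sort_index()
    return ClusterReport(table=table, composition=comp, purity_min=purity_min)


def validate_malignancy(
    matrix: SingleCellMatrix,
    labels: pd.Series,
    report: ClusterReport,
    positive_marker: str = "EGFR",
    negative_marker: str = "PTPRC",
) -> pd.DataFrame:
    """Rank-sum check of marker expression in neoplastic vs healthy cells.

    The positive marker should be higher in neoplastic cells and the negative
    (immune) marker lower; a marker violating its expected direction raises
    the ``inconsistent`` flag in its row.
    """
    for g in (positive_marker, negative_marker):
        if g not in matrix.genes:
            raise KeyError(f"marker gene {g!r} absent from matrix")
    neo = report.neoplastic_clusters()
    neo_cells = labels.index[labels.isin(neo)]
    healthy_cells = labels.index[~labels.isin(neo)]
    rows = []
    for gene, expect_up in ((positive_marker, True), (negative_marker, False)):
        x = matrix.values.loc[gene, neo_cells].to_numpy()
        y = matrix.values.loc[gene, healthy_cells].to_numpy()
        if len(x) == 0 or len(y) == 0:
            raise ValueError("need both neoplastic and healthy cells for validation")
        if np.array_equal(np.unique(x), np.unique(y)) and len(np.unique(x)) == 1:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        mean_neo, mean_healthy = float(x.mean()), float(y.mean())
        higher_in_neo = mean_neo > mean_healthy
        inconsistent = (p >= 0.05) or (higher_in_neo != expect_up)
        rows.append(
            {
                "gene": gene,
                "mean_neoplastic": mean_neo,
                "mean_healthy": mean_healthy,
                "p_value": p,
                "expected_up_in_neoplastic": expect_up,
                "inconsistent": inconsistent,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def marker_score(matrix: SingleCellMatrix, gene_set: list[str]) -> pd.Series:
    """Per-cell mean log expression over the present genes of a set."""
    present = [g for g in gene_set if g in matrix.genes]
    absent = len(gene_set) - len(present)
    if absent:
        logger.warning("marker_score: %d set genes absent from matrix", absent)
    if not present:
        raise KeyError("no gene of the set is present in the matrix")
    return matrix.values.loc[present].mean(axis=0)


def annotate_healthy(
    matrix: SingleCellMatrix,
    labels: pd.Series,
    report: ClusterReport,
    catalog: GeneSetCatalog,
) -> pd.Series:
    """Assign each healthy cluster the cell type with maximal mean marker score.

    Neoplastic cells are labeled ``neoplastic``; a cluster scoring 0 on every
    set is ``unassigned``; exact ties resolve alphabetically with a warning.
    """
    healthy_sets = catalog.healthy_markers()
    if not healthy_sets:
        raise KeyError("catalog provides no 'healthy_markers:<type>' sets")
    scores = {t: marker_score(matrix, genes) for t, genes in sorted(healthy_sets.items())}
    out = pd.Series("neoplastic", index=labels.index, name="cell_type", dtype=object)
    neo = set(report.neoplastic_clusters())
    healthy_clusters = [cl for cl in report.table.index if cl not in neo]
    if not healthy_clusters:
        logger.warning("no healthy clusters to annotate")
    for cl in healthy_clusters:
        cells = labels.index[labels == cl]
        means = pd.Series({t: float(s.loc[cells].mean()) for t, s in scores.items()})
        if (means == 0).all():
            out.loc[cells] = "unassigned"
            continue
        best = means.max()
        winners = sorted(means.index[means == best])
        if len(winners) > 1:
            logger.warning("cluster %s: tie between %s; alphabetical winner", cl, winners)
        out.loc[cells] = winners[0]
    return out
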