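"""TAM subtype separation, M1/M2 polarization scoring and CSC calling.

Tumor-associated myeloid cells split into blood-derived macrophages and
brain-resident microglia. The split runs a PCA on a 237-gene macrophage vs
microglia signature and partitions cells by 2-means in the first two
components; the two groups are then named by which half of a 66-gene
macrophage/microglia marker panel scores higher. Polarization is the mean
expression of M1 and M2 marker sets per macrophage, with the Spearman
correlation between the two scores reported cohort-wide. Cancer stem-like
cells (CSCs) are the tumor cells whose mean expression over a 90-gene glioma
stemness panel reaches the top quantile (default top 25%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .cell_typing import marker_score
from .crosstalk import spearman_test
from .data_model import SingleCellMatrix

logger = logging.getLogger("gliotalk")


@dataclass
class TamReport:
    """Per-TAM-cell subtype assignment and scores.

    ``cells`` is indexed by cell id with columns ``subtype`` (macrophage /
    microglia), ``pc1``, ``pc2``, ``mac_score`` and ``mic_score``;
    ``degenerate`` is True when no two groups were distinguishable and the
    assignment fell back to per-cell marker scores.
    """

    cells: pd.DataFrame
    degenerate: bool = False


@dataclass
class CscReport:
    """Per-tumor-cell stemness score and CSC flag; ``threshold`` is the score cut."""

    cells: pd.DataFrame
    threshold: float
    quantile: float


class TamSubtyper(BaseEstimator):
    """PCA + 2-means split of TAM cells into macrophages and microglia.

    Fit on a cells x signature-genes frame; group naming needs the per-cell
    macrophage and microglia marker scores (passed to :meth:`fit`).
    """

    def __init__(self, random_state: int = 0, silhouette_min: float = 0.05):
        self.random_state = random_state
        self.silhouette_min = silhouette_min

    def fit(self, X: pd.DataFrame, mac_score: pd.Series, mic_score: pd.Series) -> "TamSubtyper":
        n = X.shape[0]
        if n < 4:
            raise ValueError("need at least 4 TAM cells")
        arr = np.asarray(X, dtype=float)
        n_comp = min(2, n - 1, arr.shape[1])
        emb = PCA(n_components=n_comp, random_state=self.random_state).fit_transform(arr)
        if emb.shape[1] < 2:
            emb = np.column_stack([emb, np.zeros(n)])
        degenerate = False
        if np.allclose(emb.std(axis=0), 0):
            degenerate = True
        else:
            groups = KMeans(2, n_init=10, random_state=self.random_state).fit_predict(emb)
            if len(np.unique(groups)) < 2 or silhouette_score(emb, groups) < self.silhouette_min:
                degenerate = True
        if degenerate:
            logger.warning("TAM split degenerate: assigning subtype by marker score alone")
            subtype = np.where(
                mac_score.to_numpy() >= mic_score.to_numpy(), "macrophage", "microglia"
            )
            if np.allclose(mac_score.to_numpy(), mic_score.to_numpy()):
                subtype = np.full(n, "macrophage", dtype=object)
        else:
            diff = mac_score.to_numpy() - mic_score.to_numpy()
            mean0, mean1 = diff[groups == 0].mean(), diff[groups == 1].mean()
            name = {0: "macrophage", 1: "microglia"} if mean0 >= mean1 else {
                0: "microglia", 1: "macrophage"}
            subtype = np.array([name[g] for g in groups], dtype=object)
        self.embedding_ = emb
        self.labels_ = subtype
        self.degenerate_ = degenerate
        return self


def split_tam(
    matrix: SingleCellMatrix,
    tam_cells: list[str] | pd.Index,
    signature: list[str],
    mac_markers: list[str],
    mic_markers: list[str],
    seed: int = 0,
) -> TamReport:
    """Split TAM cells into macrophage/microglia via signature PCA + 2-means."""
    tam_cells = pd.Index(tam_cells)
    sub = matrix.subset_cells(tam_cells)
    present_sig = [g for g in signature if g in matrix.genes]
    if len(present_sig) < 10:
        raise ValueError(f"only {len(present_sig)} signature genes present; need >= 10")
    mac_present = [g for g in mac_markers if g in matrix.genes]
    mic_present = [g for g in mic_markers if g in matrix.genes]
    if not mac_present and not mic_present:
        raise ValueError("markers for both TAM subtypes are absent from the matrix")
    mac_s = marker_score(sub, mac_present) if mac_present else pd.Series(0.0, index=tam_cells)
    mic_s = marker_score(sub, mic_present) if mic_present else pd.Series(0.0, index=tam_cells)
    X = sub.values.loc[present_sig].T  # cells x genes
    model = TamSubtyper(random_state=seed).fit(X, mac_s, mic_s)
    cells = pd.DataFrame(
        {
            "subtype": model.labels_,
            "pc1": model.embedding_[:, 0],
            "pc2": model.embedding_[:, 1],
            "mac_score": mac_s.to_numpy(),
            "mic_score": mic_s.to_numpy(),
        },
        index=tam_cells,
    )
    return TamReport(cells=cells, degenerate=model.degenerate_)


def polarization(
    matrix: SingleCellMatrix,
    macrophages: list[str] | pd.Index,
    m1: list[str],
    m2: list[str],
) -> tuple[pd.DataFrame, float, float]:
    """M1/M2 marker scores per macrophage and their Spearman correlation.

    Returns ``(scores, rho, p)``; a non-significant rho supports mixed
    (non-dichotomous) polarization states.
    """
    macrophages = pd.Index(macrophages)
    if len(macrophages) < 3:
        raise ValueError("need at least 3 macrophages for a correlation")
    sub = matrix.subset_cells(macrophages)
    s1 = marker_score(sub, m1)
    s2 = marker_score(sub, m2)
    rho, p = spearman_test(s1.to_numpy(), s2.to_numpy())
    scores = pd.DataFrame({"m1_score": s1, "m2_score": s2})
    return scores, rho, p


class CscCaller(BaseEstimator):
    """Flag cancer stem-like cells by top-quantile stemness score.

    ``fit`` learns the threshold (the (1 - quantile) empirical quantile of
    scores among tumor cells); ``predict`` flags scores at/above it.
    """

    def __init__(self, quantile: float = 0.25):
        self.quantile = quantile

    def fit(self, scores: pd.Series | np.ndarray, y=None) -> "CscCaller":
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        arr = np.asarray(scores, dtype=float)
        if arr.size < 10:
            raise ValueError("need at least 10 tumor cells")
        self.threshold_ = float(np.quantile(arr, 1.0 - self.quantile))
        return self

    def predict(self, scores: pd.Series | np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) >= self.threshold_


def call_csc(
    matrix: SingleCellMatrix,
    tumor_cells: list[str] | pd.Index,
    stemness: list[str],
    quantile: float = 0.25,
) -> CscReport:
    """Score tumor cells on the stemness panel and flag the top quantile as CSC."""
    tumor_cells = pd.Index(tumor_cells)
    sub = matrix.subset_cells(tumor_cells)
    scores = marker_score(sub, stemness)
    caller = CscCaller(quantile).fit(scores)
    flags = caller.predict(scores)
    if flags.all():
        logger.warning("all tumor cells at/above the stemness threshold (ties)")
    cells = pd.DataFrame({"stemness_score": scores, "is_csc": flags}, index=tumor_cells)
    return CscReport(cells=cells, threshold=caller.threshold_, quantile=quantile)
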