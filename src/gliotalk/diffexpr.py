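"""Two-part (hurdle) differential expression for zero-inflated single-cell data.

Single-cell expression is zero-inflated: a gene is either undetected in a
cell or detected with a continuous positive log value. The hurdle test
therefore combines two likelihood-ratio components per gene:

* **discrete part** — logistic regression of detection (value > 0) on group
  membership against an intercept-only model; with a single binary covariate
  this has the closed-form binomial likelihood-ratio, chi-square(1);
* **continuous part** — a normal linear model on the log values of detected
  cells, group vs intercept-only; the likelihood ratio is
  ``n * log(RSS0 / RSS1)``, chi-square(1). If either group has fewer than two
  detected cells this part contributes statistic 0 with p = 1.

The combined statistic is the sum, referred to chi-square(2) — except that a
structurally degenerate part contributes no degrees of freedom: if detection
is saturated (all cells of both groups detected, or none), or if the
continuous part is unavailable (fewer than two detected cells in a group, or
all detected values identical), the combined p reduces to the remaining
part's chi-square(1) p. No covariates (e.g. cellular detection rate) are
modeled. The log fold-change is the
difference of overall group means of log2 expression (zeros included), so
purely detection-driven changes still carry a sign.

Multiple testing uses Benjamini-Hochberg step-up control of the FDR.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import SingleCellMatrix

logger = logging.getLogger("gliotalk")

_RESULT_COLUMNS = [
    "detection_a", "detection_b", "mean_detected_a", "mean_detected_b",
    "log2_fc", "discrete_stat", "discrete_p", "continuous_stat",
    "continuous_p", "combined_stat", "combined_p",
]


def _binomial_ll(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Bernoulli log-likelihood sum with the 0*log(0) = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(p), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log(1.0 - p), 0.0)
    return t1 + t2


def hurdle_test_genes(
    matrix: SingleCellMatrix,
    group_a: list[str] | pd.Index,
    group_b: list[str] | pd.Index,
    genes: list[str] | pd.Index | None = None,
) -> pd.DataFrame:
    """Vectorized hurdle test for many genes between two cell groups.

    Returns a DataFrame indexed by gene with detection rates, detected-cell
    means, log2 fold-change (A minus B), the two component statistics and
    p-values, and the combined chi-square(2) statistic and p-value.
    """
    group_a, group_b = pd.Index(group_a), pd.Index(group_b)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both cell groups must be non-empty")
    if len(group_a.intersection(group_b)) > 0:
        raise ValueError("cell groups overlap")
    if genes is None:
        genes = matrix.genes
    else:
        genes = pd.Index(genes)
        absent = genes.difference(matrix.genes)
        if len(absent):
            logger.warning("hurdle test: dropping %d absent genes", len(absent))
            genes = genes[genes.isin(matrix.genes)]
        if len(genes) == 0:
            raise KeyError("no requested gene is present in the matrix")

    xa = matrix.values.loc[genes, group_a].to_numpy(dtype=float)
    xb = matrix.values.loc[genes, group_b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    da, db = xa > 0, xb > 0
    ka, kb = da.sum(axis=1).astype(float), db.sum(axis=1).astype(float)

    # discrete part: binomial LRT, detection ~ group vs intercept-only
    p_a, p_b = ka / na, kb / nb
    p_0 = (ka + kb) / (na + nb)
    ll1 = _binomial_ll(ka, na, p_a) + _binomial_ll(kb, nb, p_b)
    ll0 = _binomial_ll(ka, na, p_0) + _binomial_ll(kb, nb, p_0)
    d_stat = np.maximum(2.0 * (ll1 - ll0), 0.0)
    d_p = stats.chi2.sf(d_stat, df=1)

    # continuous part: normal linear model LRT on detected values
    sa1 = np.where(da, xa, 0.0).sum(axis=1)
    sa2 = np.where(da, xa * xa, 0.0).sum(axis=1)
    sb1 = np.where(db, xb, 0.0).sum(axis=1)
    sb2 = np.where(db, xb * xb, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_a = np.where(ka > 0, sa1 / ka, np.nan)
        mean_b = np.where(kb > 0, sb1 / kb, np.nan)
        rss_a = sa2 - np.where(ka > 0, sa1 * sa1 / ka, 0.0)
        rss_b = sb2 - np.where(kb > 0, sb1 * sb1 / kb, 0.0)
        n_det = ka + kb
        grand = np.where(n_det > 0, (sa1 + sb1) / n_det, 0.0)
        rss0 = (sa2 + sb2) - n_det * grand * grand
    rss1 = np.maximum(rss_a, 0.0) + np.maximum(rss_b, 0.0)
    rss0 = np.maximum(rss0, 0.0)
    ok = (ka >= 2) & (kb >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rss1 > 0, rss0 / np.maximum(rss1, 1e-300), np.inf)
        c_stat = np.where(ok, n_det * np.log(ratio), 0.0)
    # both-constant-and-equal degenerate case: no continuous information
    c_stat = np.where(ok & (rss1 <= 0) & (rss0 <= 1e-12), 0.0, c_stat)
    c_stat = np.where(np.isfinite(c_stat), c_stat, 1e6)
    c_stat = np.maximum(c_stat, 0.0)
    c_p = np.where(ok, stats.chi2.sf(c_stat, df=1), 1.0)
    c_stat = np.where(ok, c_stat, 0.0)

    # adaptive df: a structurally degenerate part carries no information
    d_informative = ~((p_a == p_b) & ((p_a == 0.0) | (p_a == 1.0)))
    c_informative = ok & ((rss1 > 0) | (rss0 > 1e-12))
    df = d_informative.astype(int) + c_informative.astype(int)
    comb = d_stat + c_stat
    comb_p = np.ones_like(comb)
    nz = df > 0
    comb_p[nz] = stats.chi2.sf(comb[nz], df=df[nz])

    lfc = xa.mean(axis=1) - xb.mean(axis=1)
    out = pd.DataFrame(
        {
            "detection_a": p_a, "detection_b": p_b,
            "mean_detected_a": mean_a, "mean_detected_b": mean_b,
            "log2_fc": lfc,
            "discrete_stat": d_stat, "discrete_p": np.clip(d_p, np.finfo(float).tiny, 1.0),
            "continuous_stat": c_stat, "continuous_p": np.clip(c_p, np.finfo(float).tiny, 1.0),
            "combined_stat": comb, "combined_p": np.clip(comb_p, np.finfo(float).tiny, 1.0),
        },
        index=genes,
    )[_RESULT_COLUMNS]
    return out


def hurdle_test(
    matrix: SingleCellMatrix,
    group_a: list[str] | pd.Index,
    group_b: list[str] | pd.Index,
    gene: str,
) -> pd.Series:
    """Hurdle test for a single gene; see :func:`hurdle_test_genes`."""
    if gene not in matrix.genes:
        raise KeyError(f"gene {gene!r} absent from matrix")
    return hurdle_test_genes(matrix, group_a, group_b, [gene]).iloc[0]


def bh_adjust(pvals: np.ndarray | list[float] | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def de_screen(
    matrix: SingleCellMatrix,
    group_a: list[str] | pd.Index,
    group_b: list[str] | pd.Index,
    genes: list[str] | pd.Index | None = None,
    direction: str = "up_in_a",
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Screen genes differentially expressed between two groups.

    Runs the hurdle test on the gene list (default: all genes), applies BH
    adjustment, and keeps genes whose (adjusted) combined p < ``alpha`` and
    whose log2 fold-change sign matches ``direction`` (``up_in_a``,
    ``up_in_b`` or ``any``). Sorted by p.
    """
    if direction not in ("up_in_a", "up_in_b", "any"):
        raise ValueError(f"unknown direction {direction!r}")
    try:
        res = hurdle_test_genes(matrix, group_a, group_b, genes)
    except KeyError:
        logger.warning("de_screen: empty gene list after filtering")
        return pd.DataFrame(columns=_RESULT_COLUMNS + ["adjusted_p"])
    res = res.copy()
    res["adjusted_p"] = bh_adjust(res["combined_p"].to_numpy())
    pcol = "adjusted_p" if use_adjusted else "combined_p"
    keep = res[pcol] < alpha
    if direction == "up_in_a":
        keep &= res["log2_fc"] > 0
    elif direction == "up_in_b":
        keep &= res["log2_fc"] < 0
    return res.loc[keep].sort_values(pcol, kind="stable")
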