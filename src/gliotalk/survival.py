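"""Kaplan-Meier estimation, log-rank testing and median-split screening.

Candidate crosstalk genes are screened for survival association by splitting
the bulk cohort at each gene's expression median (values strictly above the
median form the "high" group, ties go to "low") and comparing the two groups
with the log-rank test. Estimation and testing are delegated to lifelines;
the screen reports, per gene, the split value, group sizes, the chi-square(1)
statistic and p-value, and which group has worse survival (from the sign of
the high group's observed-minus-expected event count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .data_model import BulkCohort

logger = logging.getLogger("gliotalk")


@dataclass
class KmCurve:
    """Product-limit survival curve.

    ``times`` start at 0 with S(0) = 1; ``survival`` is non-increasing in
    [0, 1]; ``at_risk`` counts subjects at risk entering each time;
    ``censor_times`` are times with censoring only (marks, not steps).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray


def km_estimate(times: np.ndarray | list[float], events: np.ndarray | list[bool]) -> KmCurve:
    """Kaplan-Meier product-limit estimate under right censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if times.size != events.size:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter().fit(times, events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    table = kmf.event_table
    at_risk = table["at_risk"].reindex(pd.Index(grid)).to_numpy(dtype=float)
    censor_only = table.index[(table["censored"] > 0) & (table["observed"] == 0)]
    return KmCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        censor_times=censor_only.to_numpy(dtype=float),
    )


def logrank_test(
    times: np.ndarray | list[float],
    events: np.ndarray | list[bool],
    groups: np.ndarray | list,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("need exactly two non-empty groups")
    a = groups == labels[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(min(max(res.p_value, np.finfo(float).tiny), 1.0))


def _high_group_o_minus_e(times, events, high) -> float:
    """Observed minus expected events in the high group (direction only)."""
    order = np.argsort(times)
    t, e, h = times[order], events[order], high[order]
    o_minus_e = 0.0
    for tt in np.unique(t[e]):
        at_risk = t >= tt
        n = at_risk.sum()
        n_high = (at_risk & h).sum()
        d = (e & (t == tt)).sum()
        d_high = (e & (t == tt) & h).sum()
        o_minus_e += d_high - d * n_high / n
    return o_minus_e


def median_split_screen(bulk: BulkCohort, genes: list[str] | pd.Index) -> pd.DataFrame:
    """Median-split log-rank survival screen over a gene list.

    Samples strictly above a gene's median expression form the "high" group.
    Returns one row per testable gene, sorted by p-value, with a
    ``significant`` flag at p < 0.05; constant or absent genes are skipped
    with a warning.
    """
    genes = pd.Index(genes)
    absent = genes.difference(bulk.genes)
    if len(absent):
        logger.warning("survival screen: dropping %d absent genes", len(absent))
        genes = genes[genes.isin(bulk.genes)]
    times = bulk.clinical["survival_days"].to_numpy(dtype=float)
    events = bulk.clinical["event"].to_numpy(dtype=bool)
    rows = []
    for gene in genes:
        x = bulk.values[gene].to_numpy(dtype=float)
        med = float(np.median(x))
        high = x > med
        if high.sum() == 0 or high.sum() == high.size:
            logger.warning("gene %s: constant or degenerate split; skipped", gene)
            continue
        chi2, p = logrank_test(times, events, high)
        ome = _high_group_o_minus_e(times, events, high)
        rows.append(
            {
                "gene": gene,
                "split_value": med,
                "n_high": int(high.sum()),
                "n_low": int((~high).sum()),
                "chi2": chi2,
                "p_value": p,
                "direction": "high_worse" if ome > 0 else "low_worse",
                "significant": p < 0.05,
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "split_value", "n_high", "n_low",
                                      "chi2", "p_value", "direction", "significant"])
    out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    logger.info("survival screen: %d/%d genes significant at p < 0.05",
                int(out["significant"].sum()), len(out))
    return out
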