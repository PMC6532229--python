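"""Ligand-receptor crosstalk screens with bulk co-expression validation.

Two screening modes mirror the study design:

* **autocrine** — ligand AND receptor both up-regulated in neoplastic vs
  healthy cells (hurdle DE), then validated by requiring their bulk
  co-expression (Spearman rho > 0.4 at p < 0.05 by default): secreted
  signaling received by the secreting population should leave a co-expression
  footprint in bulk tumors;
* **directional** — ligand up in the sender population vs its reference and
  receptor up in the receiver population vs its reference, both at
  BH-adjusted p < alpha; run with (CSC, differentiated tumor, macrophage,
  microglia) roles for CSC -> macrophage signaling and with roles swapped for
  the reverse direction.

Pathway over-representation of the surviving genes uses the one-sided
hypergeometric upper tail with BH correction across pathways.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import BulkCohort, LRTable, SingleCellMatrix
from .diffexpr import bh_adjust, de_screen

logger = logging.getLogger("gliotalk")


def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks. For n > 8 the p-value uses
    the t approximation with n - 2 degrees of freedom; for n <= 8 it is the
    exact two-sided permutation probability over all n! rank arrangements.
    Ties are allowed (mid-ranks); a constant vector raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        obs = abs(rho) - 1e-12
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= obs:
                count += 1
        p = count / total
    else:
        denom = 1.0 - rho * rho
        if denom <= 0:
            p = float(np.finfo(float).tiny)
        else:
            t = rho * math.sqrt((n - 2) / denom)
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, float(min(max(p, np.finfo(float).tiny), 1.0))


def autocrine_screen(
    de_table: pd.DataFrame,
    lr: LRTable,
    bulk: BulkCohort,
    rho_min: float = 0.4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-stage autocrine ligand-receptor screen.

    Stage 1 keeps LR rows whose ligand and receptor are both in ``de_table``
    (a table of genes up-regulated in neoplastic cells, indexed by gene).
    Stage 2 keeps stage-1 pairs with bulk Spearman rho > ``rho_min`` and
    p < ``alpha``. Both stage flags are recorded; ``pass_overall`` is their
    conjunction.
    """
    if len(lr) == 0:
        raise ValueError("LR table is empty")
    pairs = lr.pairs.copy()
    self_rows = pairs["ligand"] == pairs["receptor"]
    if self_rows.any():
        logger.warning("excluding %d self-pairs (ligand == receptor)", int(self_rows.sum()))
        pairs = pairs.loc[~self_rows].reset_index(drop=True)
    de_genes = set(de_table.index)
    rows = []
    for lig, rec in pairs.itertuples(index=False):
        stage1 = lig in de_genes and rec in de_genes
        rho = p = np.nan
        stage2 = False
        if stage1:
            if lig not in bulk.genes or rec not in bulk.genes:
                logger.warning("pair (%s, %s) missing from bulk cohort; dropped", lig, rec)
                continue
            rho, p = spearman_test(
                bulk.values[lig].to_numpy(), bulk.values[rec].to_numpy()
            )
            stage2 = (rho > rho_min) and (p < alpha)
        rows.append(
            {
                "ligand": lig,
                "receptor": rec,
                "direction": "autocrine",
                "ligand_p": de_table.loc[lig, "combined_p"] if lig in de_genes else np.nan,
                "receptor_p": de_table.loc[rec, "combined_p"] if rec in de_genes else np.nan,
                "ligand_log2_fc": de_table.loc[lig, "log2_fc"] if lig in de_genes else np.nan,
                "receptor_log2_fc": de_table.loc[rec, "log2_fc"] if rec in de_genes else np.nan,
                "bulk_rho": rho,
                "bulk_p": p,
                "pass_de": stage1,
                "pass_coexpression": stage2,
                "pass_overall": stage1 and stage2,
            }
        )
    return pd.DataFrame(rows)


def directional_screen(
    matrix: SingleCellMatrix,
    sender: list[str] | pd.Index,
    sender_ref: list[str] | pd.Index,
    receiver: list[str] | pd.Index,
    receiver_ref: list[str] | pd.Index,
    lr: LRTable,
    alpha: float = 0.05,
    direction_label: str = "sender_to_receiver",
) -> pd.DataFrame:
    """Directional crosstalk: ligand up in sender, receptor up in receiver.

    Both conditions use the hurdle test at BH-adjusted p < ``alpha`` against
    the respective reference population.
    """
    for name, grp in (
        ("sender", sender), ("sender_ref", sender_ref),
        ("receiver", receiver), ("receiver_ref", receiver_ref),
    ):
        if len(grp) == 0:
            raise ValueError(f"{name} cell group is empty")
    if len(lr) == 0:
        raise ValueError("LR table is empty")
    pairs = lr.pairs
    ligands = pairs["ligand"].unique().tolist()
    receptors = pairs["receptor"].unique().tolist()
    lig_up = de_screen(matrix, sender, sender_ref, genes=ligands,
                       direction="up_in_a", alpha=alpha, use_adjusted=True)
    rec_up = de_screen(matrix, receiver, receiver_ref, genes=receptors,
                       direction="up_in_a", alpha=alpha, use_adjusted=True)
    rows = []
    for lig, rec in pairs.itertuples(index=False):
        ok_l, ok_r = lig in lig_up.index, rec in rec_up.index
        if not (ok_l and ok_r):
            continue
        rows.append(
            {
                "ligand": lig,
                "receptor": rec,
                "direction": direction_label,
                "ligand_p": lig_up.loc[lig, "adjusted_p"],
                "receptor_p": rec_up.loc[rec, "adjusted_p"],
                "ligand_log2_fc": lig_up.loc[lig, "log2_fc"],
                "receptor_log2_fc": rec_up.loc[rec, "log2_fc"],
                "pass_overall": True,
            }
        )
    cols = ["ligand", "receptor", "direction", "ligand_p", "receptor_p",
            "ligand_log2_fc", "receptor_log2_fc", "pass_overall"]
    return pd.DataFrame(rows, columns=cols)


def ora_enrichment(
    query: list[str],
    pathways: dict[str, list[str]],
    universe: list[str] | pd.Index,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set in named pathways.

    For each pathway with K universe genes and a query of size n drawn from a
    universe of size N, the p-value is P(X >= overlap) under the
    hypergeometric null; BH correction is applied across pathways.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("universe is empty")
    uset = set(universe)
    dropped = [g for g in query if g not in uset]
    if dropped:
        logger.warning("ORA: dropping %d query genes outside the universe", len(dropped))
    qset = {g for g in query if g in uset}
    n_uni, n_query = len(uset), len(qset)
    rows = []
    for name, genes in pathways.items():
        pset = set(genes) & uset
        overlap = len(pset & qset)
        p = float(stats.hypergeom.sf(overlap - 1, n_uni, len(pset), n_query))
        rows.append({"pathway": name, "pathway_size": len(pset),
                     "overlap": overlap, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("pathway")
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out
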