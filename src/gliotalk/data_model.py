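"""Core data containers and file I/O shared by all pipeline stages.

The pipeline moves four kinds of objects around:

* :class:`SingleCellMatrix` — a genes x cells log-scale expression matrix with
  per-cell annotations (patient of origin, cluster, cell type, CSC flag).
* :class:`BulkCohort` — a samples x genes TPM matrix with per-sample survival
  time (days) and an event indicator.
* :class:`LRTable` — a directed ligand -> receptor pair list keyed by gene
  symbol.
* :class:`GeneSetCatalog` — named marker gene sets (healthy cell-type markers,
  the TAM PCA signature, macrophage/microglia markers, M1/M2 polarization
  markers, the glioma stemness set).

On-disk formats are deliberately plain: TSV matrices (genes as rows, header =
cell/sample ids), MTX-style triplet files with ``.rows``/``.cols`` sidecars,
TSV metadata keyed by id, TSV ligand/receptor tables, and GMT gene sets.
Single-cell values are assumed to be on the log2(TPM/10 + 1) scale; the loader
can apply that transform to raw TPM via ``log_transform=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("gliotalk")

CELL_TYPES = (
    "neoplastic",
    "macrophage",
    "microglia",
    "oligodendrocyte",
    "neuron",
    "endothelial",
    "unassigned",
)

#: set names a complete catalog is expected to provide
REQUIRED_SET_NAMES = (
    "tam_signature_237",
    "mac_micro_markers_66",
    "m1_markers",
    "m2_markers",
    "stemness_90",
)


class ValidationError(ValueError):
    """An object violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


class SchemaError(ValueError):
    """A file is missing required columns."""


def _canonicalize_genes(values: pd.DataFrame, axis: int = 0) -> pd.DataFrame:
    """Upper-case gene symbols and drop duplicates (first occurrence wins)."""
    names = values.index if axis == 0 else values.columns
    upper = names.astype(str).str.upper()
    if axis == 0:
        values = values.set_axis(upper, axis=0)
        dup = values.index.duplicated()
        if dup.any():
            logger.warning("dropping %d duplicate gene symbols (first kept)", int(dup.sum()))
            values = values.loc[~dup]
    else:
        values = values.set_axis(upper, axis=1)
        dup = values.columns.duplicated()
        if dup.any():
            logger.warning("dropping %d duplicate gene symbols (first kept)", int(dup.sum()))
            values = values.loc[:, ~dup]
    return values


@dataclass
class SingleCellMatrix:
    """Genes x cells log-scale expression with per-cell annotations.

    ``values``: DataFrame indexed by gene symbol, columns are cell ids.
    ``cell_meta``: DataFrame indexed by cell id with at least a ``patient``
    column; optional ``cluster`` (int), ``cell_type`` and ``is_csc`` columns
    are added by downstream stages.
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression matrix contains negative values")
        if self.values.index.duplicated().any():
            raise ValidationError("gene symbols are not unique")
        if not self.values.columns.equals(self.cell_meta.index):
            if set(self.values.columns) != set(self.cell_meta.index):
                raise ValidationError("cell ids in values and cell_meta differ")
            self.cell_meta = self.cell_meta.loc[self.values.columns]
        if "patient" not in self.cell_meta.columns:
            raise ValidationError("cell_meta lacks a 'patient' column")
        if self.cell_meta["patient"].isna().any():
            raise ValidationError("every cell must have a patient id")
        if "cluster" in self.cell_meta.columns and self.cell_meta["cluster"].isna().any():
            raise ValidationError("cluster ids, when present, must cover all cells")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cells: Iterable[str]) -> "SingleCellMatrix":
        cells = pd.Index(cells)
        return SingleCellMatrix(self.values[cells], self.cell_meta.loc[cells].copy())


@dataclass
class BulkCohort:
    """Samples x genes TPM expression plus survival clinical data.

    ``clinical`` is indexed by sample id with columns ``survival_days``
    (non-negative float) and ``event`` (bool, True = death observed).
    Samples with missing clinical values are dropped with a logged count.
    """

    values: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        missing = self.clinical[["survival_days", "event"]].isna().any(axis=1)
        if missing.any():
            logger.warning("dropping %d samples with missing clinical values", int(missing.sum()))
            self.clinical = self.clinical.loc[~missing]
            self.values = self.values.loc[self.clinical.index]
        self.validate()

    def validate(self) -> None:
        if not {"survival_days", "event"} <= set(self.clinical.columns):
            raise ValidationError("clinical table needs 'survival_days' and 'event' columns")
        if set(self.values.index) != set(self.clinical.index):
            raise ValidationError("sample ids in values and clinical differ")
        self.clinical = self.clinical.loc[self.values.index]
        if (self.clinical["survival_days"].to_numpy() < 0).any():
            raise ValidationError("survival_days must be >= 0")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate sample ids")
        self.clinical["event"] = self.clinical["event"].astype(bool)

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns


@dataclass
class LRTable:
    """Directed ligand -> receptor pair list.

    Duplicate (ligand, receptor) rows are collapsed; direction is preserved,
    so (A, B) and (B, A) are distinct pairs.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        if not {"ligand", "receptor"} <= set(self.pairs.columns):
            raise SchemaError("LR table needs 'ligand' and 'receptor' columns")
        self.pairs = self.pairs[["ligand", "receptor"]].astype(str)
        self.pairs = self.pairs.apply(lambda c: c.str.upper())
        before = len(self.pairs)
        self.pairs = self.pairs.drop_duplicates(ignore_index=True)
        if len(self.pairs) < before:
            logger.info("collapsed %d duplicate LR rows", before - len(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_ligands(self) -> int:
        return self.pairs["ligand"].nunique()

    @property
    def n_receptors(self) -> int:
        return self.pairs["receptor"].nunique()

    def summary(self) -> dict:
        return {
            "n_pairs": len(self),
            "n_ligands": self.n_ligands,
            "n_receptors": self.n_receptors,
        }


@dataclass
class GeneSetCatalog:
    """Mapping set name -> gene symbol list.

    Healthy cell-type marker sets use the ``healthy_markers:<type>`` naming
    convention; :meth:`healthy_markers` collects them.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            genes = [str(g).upper() for g in genes]
            uniq = list(dict.fromkeys(genes))
            if not uniq:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[name] = uniq
        self.sets = clean

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def healthy_markers(self) -> dict[str, list[str]]:
        prefix = "healthy_markers:"
        return {k[len(prefix):]: v for k, v in self.sets.items() if k.startswith(prefix)}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc


def _read_triplet_matrix(path: Path) -> pd.DataFrame:
    """Read an MTX-style triplet file (1-based ``row col value`` lines).

    Row (gene) and column (cell/sample) names live in ``<path>.rows`` and
    ``<path>.cols`` sidecar files, one name per line.
    """
    rows = Path(str(path) + ".rows").read_text().split()
    cols = Path(str(path) + ".cols").read_text().split()
    mat = np.zeros((len(rows), len(cols)))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("%"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 'row col value'")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if not (1 <= i <= len(rows)) or not (1 <= j <= len(cols)):
                raise ParseError(f"{path}:{lineno}: index ({i}, {j}) out of range")
            mat[i - 1, j - 1] = v
    return pd.DataFrame(mat, index=rows, columns=cols)


def load_expression(
    path: str | Path,
    format: str = "tsv",
    kind: str = "single_cell",
    meta: str | Path | None = None,
    log_transform: bool = False,
) -> SingleCellMatrix | BulkCohort:
    """Load an expression matrix plus its metadata sidecar.

    Parameters
    ----------
    path:
        Matrix file. TSV: genes as rows, header = cell/sample ids. Triplet:
        ``row col value`` lines with ``.rows``/``.cols`` name sidecars.
    format:
        ``"tsv"`` or ``"mtx-triplet"``.
    kind:
        ``"single_cell"`` returns a :class:`SingleCellMatrix` (meta must carry
        a ``patient`` column); ``"bulk"`` returns a :class:`BulkCohort` (meta
        must carry ``survival_days`` and ``event``).
    log_transform:
        Apply log2(TPM/10 + 1) to single-cell values supplied as raw TPM.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        values = _read_tsv_matrix(path)
    elif format == "mtx-triplet":
        values = _read_triplet_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    values = _canonicalize_genes(values, axis=0)
    if meta is None:
        raise ValueError("metadata sidecar is required")
    meta_df = pd.read_csv(meta, sep="\t", index_col=0)
    meta_df.index = meta_df.index.astype(str)
    values.columns = values.columns.astype(str)
    if kind == "single_cell":
        if log_transform:
            values = np.log2(values / 10.0 + 1.0)
        return SingleCellMatrix(values, meta_df)
    if kind == "bulk":
        return BulkCohort(values.T, meta_df)
    raise ValueError(f"unknown kind {kind!r}")


def write_expression(obj: SingleCellMatrix | BulkCohort, path: str | Path, meta_path: str | Path) -> None:
    """Write genes-as-rows TSV plus a metadata TSV (inverse of load_expression)."""
    path, meta_path = Path(path), Path(meta_path)
    if isinstance(obj, SingleCellMatrix):
        obj.values.to_csv(path, sep="\t", float_format="%.17g")
        obj.cell_meta.to_csv(meta_path, sep="\t")
    else:
        obj.values.T.to_csv(path, sep="\t", float_format="%.17g")
        obj.clinical.to_csv(meta_path, sep="\t", float_format="%.17g")


def load_lr_table(path: str | Path) -> LRTable:
    """Load a directed ligand/receptor pair TSV (columns ``ligand``, ``receptor``)."""
    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(df.columns):
        raise SchemaError(f"{path}: missing 'ligand'/'receptor' columns")
    table = LRTable(df)
    logger.info("LR table: %s", table.summary())
    return table


def write_lr_table(table: LRTable, path: str | Path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def load_gene_sets(path: str | Path) -> GeneSetCatalog:
    """Load gene sets from GMT (name <tab> description <tab> genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, genes")
            sets[parts[0]] = parts[2:]
    return GeneSetCatalog(sets)


def write_gene_sets(catalog: GeneSetCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in catalog.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
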