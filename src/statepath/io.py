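"""Expression-matrix, annotation and gene-set I/O plus basic preprocessing.

The working unit is a genes x cells matrix of TPM/RPKM/FPKM-like values.
Downstream stages operate on the log2-transformed matrix, usually restricted
to a user-supplied gene set (lineage signature genes or ANOVA hits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class IdentifierError(ValueError):
    """Duplicate or missing gene/cell identifiers."""


class ScaleError(ValueError):
    """Operation applied to a matrix on the wrong scale (linear vs log2)."""


class EmptySelectionError(ValueError):
    """A gene subset request matched nothing."""


class AnnotationError(ValueError):
    """Cell annotation inconsistent with the expression matrix."""


@dataclass
class ExpressionMatrix:
    """Genes x cells expression matrix with identifier bookkeeping.

    Parameters
    ----------
    data
        DataFrame with gene ids as the index and cell ids as the columns.
    scale
        ``"linear"`` for TPM/RPKM/FPKM-like values (non-negative) or
        ``"log2"`` after log transformation.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate cell ids: {dups[:5]}")
        if not np.issubdtype(self.data.values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.scale == "linear" and (self.data.values < 0).any():
            raise ValueError("linear-scale expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.values


@dataclass
class GeneSetPair:
    """An up/down gene signature (e.g. one lineage contrasted with another)."""

    up_genes: frozenset[str]
    down_genes: frozenset[str]
    name: str = ""

    def __post_init__(self) -> None:
        self.up_genes = frozenset(self.up_genes)
        self.down_genes = frozenset(self.down_genes)
        if not self.up_genes or not self.down_genes:
            raise ValueError("up and down gene sets must be non-empty")
        if self.up_genes & self.down_genes:
            raise ValueError("up and down gene sets must be disjoint")


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    Supported formats: ``tsv``/``csv`` (first column gene ids, header row of
    cell ids) and ``mtx_triplet`` (MatrixMarket coordinate file accompanied by
    ``<stem>.genes.txt`` and ``<stem>.cells.txt`` identifier files, one id per
    line). Returns a linear-scale matrix.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx_triplet"}.get(
            path.suffix, "tsv"
        )
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.isna().any().any():
            raise ValueError(f"ragged rows or missing values in {path}")
        return ExpressionMatrix(df.astype(float), scale="linear")
    if format == "mtx_triplet":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        cells = Path(f"{stem}.cells.txt").read_text().split()
        if mat.shape != (len(genes), len(cells)):
            raise IdentifierError(
                f"matrix shape {mat.shape} does not match "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
        return ExpressionMatrix(df, scale="linear")
    raise ValueError(f"unknown format {format!r}")


def write_expression(m: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write an expression matrix as TSV/CSV or MTX triplet (with id files)."""
    path = Path(path)
    if format in ("tsv", "csv"):
        m.data.to_csv(path, sep="\t" if format == "tsv" else ",")
        return
    if format == "mtx_triplet":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values))
        stem = path.with_suffix("")
        Path(f"{stem}.genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        Path(f"{stem}.cells.txt").write_text("\n".join(m.cell_ids) + "\n")
        return
    raise ValueError(f"unknown format {format!r}")


def read_annotation(path: str | Path) -> pd.Series:
    """Read a two-column TSV (cell_id, group_label) into a cell -> group Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise AnnotationError(f"annotation file {path} needs two columns")
    cells, groups = df.iloc[:, 0], df.iloc[:, 1]
    if cells.duplicated().any():
        raise IdentifierError("duplicate cell ids in annotation")
    return pd.Series(groups.values, index=cells.values, name="group")


def write_annotation(ann: pd.Series, path: str | Path) -> None:
    ann.rename_axis("cell_id").rename("group").to_csv(path, sep="\t")


def check_annotation(m: ExpressionMatrix, ann: pd.Series) -> pd.Series:
    """Validate that ``ann`` covers every cell of ``m``; return it m-ordered."""
    missing = [c for c in m.cell_ids if c not in ann.index]
    if missing:
        raise AnnotationError(f"cells missing from annotation: {missing[:5]}")
    return ann.loc[m.cell_ids]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene ids..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def read_signature(path: str | Path, up_set: str, down_set: str, name: str = "") -> GeneSetPair:
    """Assemble a GeneSetPair from two named sets of a GMT file."""
    sets = read_gmt(path)
    for key in (up_set, down_set):
        if key not in sets:
            raise KeyError(f"gene set {key!r} not found in {path}")
    return GeneSetPair(sets[up_set], sets[down_set], name=name or f"{up_set}_vs_{down_set}")


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(v + pseudocount) transform of a linear-scale matrix."""
    if m.scale != "linear":
        raise ScaleError("matrix is already log2-transformed")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return ExpressionMatrix(np.log2(m.data + pseudocount), scale="log2")


def filter_low_expression(
    m: ExpressionMatrix,
    ann: pd.Series,
    min_value: float = 1.0,
    max_low_fraction: float = 0.95,
) -> ExpressionMatrix:
    """Drop genes that are essentially unexpressed in every annotated group.

    A gene is removed iff, within *each* group, the fraction of cells with
    value < ``min_value`` exceeds ``max_low_fraction`` (strict inequality).
    A gene adequately expressed in any single group therefore survives.
    """
    if m.scale != "linear":
        raise ScaleError("low-expression filtering expects linear-scale values")
    ann = check_annotation(m, ann)
    low = m.data.values < min_value
    remove = np.ones(m.n_genes, dtype=bool)
    for group, cells in ann.groupby(ann).groups.items():
        idx = m.data.columns.get_indexer(cells)
        if len(idx) == 0:
            raise AnnotationError(f"group {group!r} has no cells")
        frac_low = low[:, idx].mean(axis=1)
        remove &= frac_low > max_low_fraction
    return ExpressionMatrix(m.data.loc[~remove], scale=m.scale)


def subset_genes(m: ExpressionMatrix, genes: list[str] | set[str]) -> ExpressionMatrix:
    """Restrict rows to the requested genes (kept in matrix row order).

    Genes absent from the matrix are reported with a warning; an empty
    intersection raises :class:`EmptySelectionError`.
    """
    requested = set(genes)
    keep = [g for g in m.gene_ids if g in requested]
    if not keep:
        raise EmptySelectionError("none of the requested genes are in the matrix")
    absent = requested - set(keep)
    if absent:
        warnings.warn(
            f"{len(absent)} requested genes absent from matrix "
            f"(e.g. {sorted(absent)[:3]})",
            stacklevel=2,
        )
    return ExpressionMatrix(m.data.loc[keep], scale=m.scale)
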