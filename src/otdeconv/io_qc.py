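"""Expression-matrix I/O, quality control, and gene-space alignment.

All matrices in this package are gene-major: rows are genes, columns are
cells (single-cell reference) or samples (bulk).  Column order is
authoritative for cell/sample identity throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneExpressionMatrix",
    "Histogram",
    "QCRules",
    "read_expression_matrix",
    "read_annotations",
    "validate_annotations",
    "apply_qc",
    "normalize_columns_to_simplex",
    "align_genes",
]

ANNOTATION_COLUMNS = ("cell_id", "cell_type", "individual")


class QCError(ValueError):
    """Raised when a QC rule filters out every gene or every cell."""


@dataclass
class GeneExpressionMatrix:
    """A nonnegative genes x columns expression matrix with string ids.

    Parameters
    ----------
    values
        Dense nonnegative array, shape ``(n_genes, n_columns)``.
    gene_ids
        Unique gene identifiers, one per row.
    column_ids
        Unique cell/sample identifiers, one per column.
    is_counts
        Whether ``values`` are raw counts (integers) rather than already
        normalized expression.
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    is_counts: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.column_ids)} column ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise ValueError("duplicate column_ids")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative entry at gene {self.gene_ids[i]!r}, column {self.column_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, is_counts: bool = True) -> "GeneExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), is_counts)

    def subset_genes(self, genes: list[str]) -> "GeneExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return replace(self, values=self.values[rows, :], gene_ids=list(genes))

    def subset_columns(self, columns: list[str]) -> "GeneExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.column_ids)}
        cols = [idx[c] for c in columns]
        return replace(self, values=self.values[:, cols], column_ids=list(columns))

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep)


@dataclass
class Histogram:
    """A probability vector over an ordered gene index (a point on the simplex)."""

    mass: np.ndarray
    gene_ids: list[str] | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.ndim != 1:
            raise ValueError("histogram mass must be a vector")
        if np.any(self.mass < 0):
            raise ValueError("histogram entries must be nonnegative")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError(f"histogram mass sums to {self.mass.sum()!r}, not 1")
        if self.gene_ids is not None and len(self.gene_ids) != self.mass.size:
            raise ValueError("gene_ids length does not match mass")

    def __len__(self) -> int:
        return self.mass.size


@dataclass
class QCRules:
    """Thresholds for the four-step single-cell quality-control filter.

    ``mad_factor`` multiplies the raw median absolute deviation of library
    sizes; ``min_frac`` is the minimum fraction of cells in which a gene must
    have a count above 1 (closed bound); ``min_cells`` is the minimum number
    of cells a cell type must retain.  ``per_individual`` computes the
    library-size outlier rule within each individual instead of pooled.
    """

    mad_factor: float = 3.0
    min_frac: float = 0.05
    min_cells: int = 50
    per_individual: bool = False


def read_expression_matrix(
    path: str | Path,
    format: str = "dense",
    gene_file: str | Path | None = None,
    column_file: str | Path | None = None,
    sep: str | None = None,
    is_counts: bool = True,
) -> GeneExpressionMatrix:
    """Read a genes x columns expression matrix from delimited text or MTX.

    ``format='dense'`` expects a header row of column ids and a first column
    of gene ids; the delimiter is sniffed (tab/comma) unless ``sep`` is given.
    ``format='mtx'`` expects a matrix-market coordinate file with 1-based
    indices plus sidecar ``gene_file`` and ``column_file`` listing one id per
    line.  Duplicate gene ids are collapsed by summation with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense":
        if sep is None:
            with open(path) as fh:
                header = fh.readline()
            sep = "\t" if "\t" in header else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ValueError(f"malformed delimited matrix {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise ValueError(f"malformed header in {path}: no data columns found")
        if not np.issubdtype(np.asarray(df.to_numpy()).dtype, np.number):
            bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]][0]
            raise ValueError(f"non-numeric entries in column {bad!r} of {path}")
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        column_ids = [str(c) for c in df.columns]
    elif format == "mtx":
        if gene_file is None or column_file is None:
            raise ValueError("mtx format requires gene_file and column_file")
        from scipy.io import mmread

        mat = mmread(path)
        gene_ids = [line.strip().split("\t")[0] for line in open(gene_file) if line.strip()]
        column_ids = [line.strip().split("\t")[0] for line in open(column_file) if line.strip()]
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        if values.shape != (len(gene_ids), len(column_ids)):
            raise ValueError(
                f"MTX shape {values.shape} does not match id files "
                f"({len(gene_ids)} genes, {len(column_ids)} columns)"
            )
    else:
        raise ValueError(f"unknown format {format!r}")

    if len(set(gene_ids)) != len(gene_ids):
        dupes = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()].unique().tolist()
        warnings.warn(f"duplicate gene ids collapsed by summation: {dupes[:5]}")
        frame = pd.DataFrame(values, index=gene_ids, columns=column_ids)
        frame = frame.groupby(level=0, sort=False).sum()
        values = frame.to_numpy(dtype=float)
        gene_ids = [str(g) for g in frame.index]
    return GeneExpressionMatrix(values, gene_ids, column_ids, is_counts=is_counts)


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Check an annotation table for the mandatory columns and uniqueness."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    ann = ann.copy()
    for c in ANNOTATION_COLUMNS:
        ann[c] = ann[c].astype(str)
    if ann["cell_id"].duplicated().any():
        dupes = ann.loc[ann["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell ids in annotation: {dupes[:5]}")
    if (ann["cell_type"].str.len() == 0).any() or (ann["individual"].str.len() == 0).any():
        raise ValueError("empty cell_type or individual in annotation")
    return ann


def read_annotations(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    return validate_annotations(pd.read_csv(path, sep=sep))


def _mad(x: np.ndarray) -> float:
    # Raw MAD: no 1.4826 consistency factor.
    return float(np.median(np.abs(x - np.median(x))))


def apply_qc(
    sc: GeneExpressionMatrix,
    ann: pd.DataFrame,
    rules: QCRules | None = None,
) -> tuple[GeneExpressionMatrix, pd.DataFrame, dict]:
    """Apply the four single-cell QC filters, in order.

    1. Drop genes with all-zero or zero-variance rows.
    2. Drop cells whose library size L satisfies ``|L - mean(L)| >
       mad_factor * MAD(L)`` (raw MAD, deviation from the mean).
    3. Keep genes with count > 1 in at least ``min_frac`` of remaining cells.
    4. Keep cell types retaining at least ``min_cells`` cells.

    Returns the filtered matrix, the filtered annotation, and a report dict
    with the number of genes/cells removed by each rule.
    """
    rules = rules or QCRules()
    ann = validate_annotations(ann)
    ann_idx = ann.set_index("cell_id")
    unannotated = [c for c in sc.column_ids if c not in ann_idx.index]
    if unannotated:
        raise ValueError(f"cells without annotation: {unannotated[:5]}")
    ann = ann_idx.loc[sc.column_ids].reset_index()

    report: dict = {}
    values, genes, cells = sc.values, list(sc.gene_ids), list(sc.column_ids)

    # Rule 1: zero or constant genes (all-zero rows have zero variance too).
    var = values.var(axis=1) if values.shape[1] > 1 else values[:, 0] * 0.0
    keep = (var > 0) if values.shape[1] > 1 else (values[:, 0] > 0)
    report["genes_removed_zero_variance"] = int((~keep).sum())
    values = values[keep, :]
    genes = [g for g, k in zip(genes, keep) if k]
    if not genes:
        raise QCError("all genes removed by the zero-variance filter")

    # Rule 2: library-size outliers, |L - mean(L)| > c * MAD(L).
    lib = values.sum(axis=0)
    keep_cells = np.ones(len(cells), dtype=bool)
    if rules.per_individual:
        for ind in ann["individual"].unique():
            mask = (ann["individual"] == ind).to_numpy()
            L = lib[mask]
            keep_cells[mask] = np.abs(L - L.mean()) <= rules.mad_factor * _mad(L)
    else:
        keep_cells = np.abs(lib - lib.mean()) <= rules.mad_factor * _mad(lib)
    report["cells_removed_library_size"] = int((~keep_cells).sum())
    values = values[:, keep_cells]
    cells = [c for c, k in zip(cells, keep_cells) if k]
    ann = ann.loc[keep_cells].reset_index(drop=True)
    if not cells:
        raise QCError("all cells removed by the library-size filter")

    # Rule 3: expressed (count > 1) in at least min_frac of remaining cells.
    frac = (values > 1).mean(axis=1)
    keep = frac >= rules.min_frac
    report["genes_removed_low_detection"] = int((~keep).sum())
    values = values[keep, :]
    genes = [g for g, k in zip(genes, keep) if k]
    if not genes:
        raise QCError("all genes removed by the detection-fraction filter")

    # Rule 4: cell types with at least min_cells cells.
    counts = ann["cell_type"].value_counts()
    keep_types = set(counts[counts >= rules.min_cells].index)
    keep_cells = ann["cell_type"].isin(keep_types).to_numpy()
    report["cells_removed_small_celltype"] = int((~keep_cells).sum())
    report["celltypes_removed"] = sorted(set(counts.index) - keep_types)
    values = values[:, keep_cells]
    cells = [c for c, k in zip(cells, keep_cells) if k]
    ann = ann.loc[keep_cells].reset_index(drop=True)
    if not cells:
        raise QCError("all cells removed by the cell-type-size filter")

    out = GeneExpressionMatrix(values, genes, cells, is_counts=sc.is_counts)
    return out, ann, report


def normalize_columns_to_simplex(
    m: GeneExpressionMatrix, epsilon: float = 0.0
) -> list[Histogram]:
    """Map each column c to ``(c + epsilon) / sum(c + epsilon)``.

    With ``epsilon=0`` this is plain proportional scaling; a small positive
    ``epsilon`` guarantees strictly positive histograms (useful before
    entropic-OT gradients).
    """
    out = []
    for j, cid in enumerate(m.column_ids):
        col = m.values[:, j] + epsilon
        total = col.sum()
        if total <= 0:
            raise ValueError(f"column {cid!r} has zero total mass and epsilon=0")
        out.append(Histogram(col / total, gene_ids=list(m.gene_ids), sample_id=cid))
    return out


def align_genes(
    a: GeneExpressionMatrix,
    b: GeneExpressionMatrix,
    select: str = "all",
    n_top: int = 500,
) -> tuple[GeneExpressionMatrix, GeneExpressionMatrix]:
    """Restrict two matrices to a shared, ordered gene list.

    ``select='all'`` keeps every shared gene in ``a``'s order.
    ``select='top-variable'`` keeps the ``n_top`` shared genes with the
    largest variance of log1p expression in ``b`` (the reference matrix).
    """
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared:
        raise ValueError(
            f"no shared genes; first ids were {a.gene_ids[:3]} vs {b.gene_ids[:3]}"
        )
    if select == "top-variable":
        bsub = b.subset_genes(shared)
        var = np.log1p(bsub.values).var(axis=1)
        order = np.argsort(-var, kind="stable")[: min(n_top, len(shared))]
        keep = set(np.asarray(shared)[np.sort(order)])
        shared = [g for g in shared if g in keep]
    elif select != "all":
        raise ValueError(f"unknown gene selection mode {select!r}")
    return a.subset_genes(shared), b.subset_genes(shared)
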