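"""Cell-type signature matrices built from annotated single-cell references.

A signature matrix C (genes x cell types) holds one reference expression
histogram per cell type, obtained by averaging the raw counts of that type's
cells and renormalizing the mean to the simplex.  One matrix is built per
reference individual (or once from the pooled cells), so that multi-individual
panels can later be combined by the ensemble weighting step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import GeneExpressionMatrix, validate_annotations

__all__ = [
    "SignatureMatrix",
    "build_signatures",
    "build_pooled_signature",
    "impute_missing_celltype",
    "remove_celltypes_ascending",
]


@dataclass
class SignatureMatrix:
    """Genes x cell-types matrix whose columns are probability histograms."""

    values: np.ndarray
    gene_ids: list[str]
    cell_type_ids: list[str]
    individual: str = "pooled"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_type_ids)):
            raise ValueError("signature shape does not match id lists")
        if len(set(self.cell_type_ids)) != len(self.cell_type_ids):
            raise ValueError("duplicate cell_type_ids")
        if np.any(self.values < 0):
            raise ValueError("signature entries must be nonnegative")
        sums = self.values.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = self.cell_type_ids[int(np.argmax(np.abs(sums - 1.0)))]
            raise ValueError(f"signature column {bad!r} does not sum to 1")

    @property
    def n_types(self) -> int:
        return len(self.cell_type_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_type_ids)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep)

    @classmethod
    def read(cls, path: str | Path, individual: str = "pooled", sep: str = "\t") -> "SignatureMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df.to_numpy(float), [str(g) for g in df.index],
                   [str(t) for t in df.columns], individual)

    def subset_genes(self, genes: list[str]) -> "SignatureMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        vals = self.values[rows, :]
        sums = vals.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError("gene subset leaves a cell type with zero total mass")
        return replace(self, values=vals / sums, gene_ids=list(genes))


def _mean_profiles(
    sc: GeneExpressionMatrix, ann: pd.DataFrame, per_cell_normalize: bool
) -> tuple[np.ndarray, list[str]]:
    """Column-normalized mean expression per cell type, types sorted by id."""
    types = sorted(ann["cell_type"].unique())
    cols = np.empty((sc.n_genes, len(types)))
    values = sc.values
    if per_cell_normalize:
        lib = values.sum(axis=0)
        values = values / np.where(lib > 0, lib, 1.0)
    cell_pos = {c: i for i, c in enumerate(sc.column_ids)}
    for t_i, t in enumerate(types):
        ids = ann.loc[ann["cell_type"] == t, "cell_id"]
        mean = values[:, [cell_pos[c] for c in ids]].mean(axis=1)
        total = mean.sum()
        if total <= 0:
            raise ValueError(f"cell type {t!r} has zero total expression")
        cols[:, t_i] = mean / total
    return cols, types


def build_signatures(
    sc: GeneExpressionMatrix,
    ann: pd.DataFrame,
    by_individual: bool = True,
    per_cell_normalize: bool = False,
) -> list[SignatureMatrix]:
    """Average cell expression within each cell type into signature columns.

    The mean is taken over raw counts by default (``per_cell_normalize=True``
    first scales each cell to unit library size), then renormalized to the
    simplex.  With ``by_individual`` one matrix is returned per individual;
    cell types absent from an individual are simply absent from its matrix.
    """
    ann = validate_annotations(ann)
    missing = set(sc.column_ids) - set(ann["cell_id"])
    if missing:
        raise ValueError(f"cells without annotation: {sorted(missing)[:5]}")
    ann = ann[ann["cell_id"].isin(sc.column_ids)]

    if not by_individual:
        vals, types = _mean_profiles(sc, ann, per_cell_normalize)
        return [SignatureMatrix(vals, list(sc.gene_ids), types, "pooled")]

    out = []
    for ind in sorted(ann["individual"].unique()):
        sub = ann[ann["individual"] == ind]
        if len(sub) == 0:
            warnings.warn(f"individual {ind!r} has no cells; skipped")
            continue
        sc_sub = sc.subset_columns(list(sub["cell_id"]))
        vals, types = _mean_profiles(sc_sub, sub, per_cell_normalize)
        out.append(SignatureMatrix(vals, list(sc.gene_ids), types, ind))
    return out


def build_pooled_signature(
    sc: GeneExpressionMatrix, ann: pd.DataFrame, per_cell_normalize: bool = False
) -> SignatureMatrix:
    """Signature from all individuals' cells pooled into one reference."""
    return build_signatures(sc, ann, by_individual=False,
                            per_cell_normalize=per_cell_normalize)[0]


def impute_missing_celltype(
    target: SignatureMatrix,
    donors: list[SignatureMatrix],
    missing: str,
) -> SignatureMatrix:
    """Fill a missing cell type with the mean of other individuals' columns.

    The imputed column is the entrywise mean of the donors' histograms for
    ``missing``, renormalized; existing columns are untouched.  Column order
    of the result is sorted by cell-type id (deterministic union order).
    """
    if missing in target.cell_type_ids:
        warnings.warn(f"cell type {missing!r} already present; imputation is a no-op")
        return target
    donor_cols = []
    for d in donors:
        if missing in d.cell_type_ids:
            if d.gene_ids != target.gene_ids:
                raise ValueError("donor gene index does not match target")
            donor_cols.append(d.values[:, d.cell_type_ids.index(missing)])
    if not donor_cols:
        raise ValueError(f"no donor reference contains cell type {missing!r}")
    imputed = np.mean(donor_cols, axis=0)
    imputed = imputed / imputed.sum()

    types = sorted(target.cell_type_ids + [missing])
    vals = np.empty((len(target.gene_ids), len(types)))
    for j, t in enumerate(types):
        if t == missing:
            vals[:, j] = imputed
        else:
            vals[:, j] = target.values[:, target.cell_type_ids.index(t)]
    return SignatureMatrix(vals, list(target.gene_ids), types, target.individual)


def remove_celltypes_ascending(
    sig: SignatureMatrix, ann: pd.DataFrame, n_remove: int
) -> SignatureMatrix:
    """Drop the ``n_remove`` cell types with the fewest cells for this individual.

    Mimics the missing-cell-type experiment: rare types go first.  Ties in
    cell count are broken lexicographically by type id.
    """
    if n_remove >= sig.n_types:
        raise ValueError(f"cannot remove {n_remove} of {sig.n_types} cell types")
    if n_remove == 0:
        return sig
    ann = validate_annotations(ann)
    if sig.individual != "pooled":
        ann = ann[ann["individual"] == sig.individual]
    counts = ann["cell_type"].value_counts().to_dict()
    order = sorted(sig.cell_type_ids, key=lambda t: (counts.get(t, 0), t))
    drop = set(order[:n_remove])
    keep = [t for t in sig.cell_type_ids if t not in drop]
    cols = [sig.cell_type_ids.index(t) for t in keep]
    return SignatureMatrix(sig.values[:, cols], list(sig.gene_ids), keep, sig.individual)
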