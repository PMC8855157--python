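"""Gene x gene ground-cost matrices for the Wasserstein loss.

The ground cost M encodes how expensive it is to move expression mass from
one gene to another.  Four metrics are supported, all computed from the
reference single-cell expression matrix (rows = genes, columns = cells):

- ``euclidean``:   ||x_i - x_j||_2 across cells
- ``cosine``:      1 - cos(x_i, x_j)
- ``correlation``: 1 - cor(x_i, x_j)  (Pearson)
- ``dissTOM``:     topological-overlap dissimilarity of the soft-thresholded
  co-expression network, d_ij = 1 - (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)
  with a_ij = |cor(x_i, x_j)|^beta, l_ij = sum_{u != i,j} a_iu a_uj and
  connectivity k_i = sum_{u != i} a_iu (WGCNA convention).

Costs are conventionally rescaled to max 1 so that the entropic weight gamma
has a consistent meaning across metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_qc import GeneExpressionMatrix

__all__ = [
    "GroundCost",
    "AdjacencyMatrix",
    "pairwise_gene_cost",
    "power_adjacency",
    "tom_dissimilarity",
    "rescale_cost",
    "ground_cost_from_reference",
]

METRICS = ("euclidean", "cosine", "correlation", "dissTOM")


@dataclass
class GroundCost:
    """Symmetric nonnegative gene x gene transportation-cost matrix."""

    values: np.ndarray
    metric: str
    gene_ids: list[str] | None = None
    rescaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("ground cost must be square")
        if np.any(self.values < 0):
            raise ValueError("ground cost entries must be nonnegative")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("ground cost must be symmetric")
        if self.metric in ("euclidean", "cosine", "correlation") and np.any(
            np.abs(np.diag(self.values)) > 1e-12
        ):
            raise ValueError(f"{self.metric} cost must have zero diagonal")
        if self.rescaled and self.values.size and abs(self.values.max() - 1.0) > 1e-9:
            raise ValueError("rescaled cost must have max entry 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class AdjacencyMatrix:
    """Soft-thresholded co-expression adjacency, entries in [0, 1], diagonal 1."""

    values: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("adjacency must be square")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("adjacency entries must lie in [0, 1]")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("adjacency must be symmetric")


def _safe_correlation(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; zero-variance rows correlate 0 with all."""
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s): correlations set to 0"
        )
    xs = x - x.mean(axis=1, keepdims=True)
    denom = np.where(degenerate, 1.0, sd * np.sqrt(x.shape[1]))
    xs = xs / denom[:, None]
    cor = xs @ xs.T
    cor[degenerate, :] = 0.0
    cor[:, degenerate] = 0.0
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def pairwise_gene_cost(x: GeneExpressionMatrix, metric: str) -> GroundCost:
    """Pairwise gene dissimilarity across reference cells.

    Zero-norm genes under cosine and zero-variance genes under correlation get
    cost 1 against every other gene (similarity treated as 0), with a warning.
    """
    if x.n_columns < 2:
        raise ValueError("need at least 2 cells to compute a gene metric")
    v = x.values
    if metric == "euclidean":
        m = squareform(pdist(v, metric="euclidean"))
    elif metric == "cosine":
        norms = np.linalg.norm(v, axis=1)
        degenerate = norms == 0
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} zero-norm gene(s): cosine similarity set to 0"
            )
        vn = v / np.where(degenerate, 1.0, norms)[:, None]
        cos = np.clip(vn @ vn.T, -1.0, 1.0)
        cos[degenerate, :] = 0.0
        cos[:, degenerate] = 0.0
        m = 1.0 - cos
    elif metric == "correlation":
        m = 1.0 - _safe_correlation(v)
    else:
        raise ValueError(f"unknown metric {metric!r} (dissTOM goes via tom_dissimilarity)")
    m = np.maximum((m + m.T) / 2.0, 0.0)
    np.fill_diagonal(m, 0.0)
    return GroundCost(m, metric, gene_ids=list(x.gene_ids))


def power_adjacency(x: GeneExpressionMatrix, beta: float = 6.0) -> AdjacencyMatrix:
    """Unsigned soft-threshold adjacency a_ij = |cor(x_i, x_j)|^beta, diagonal 1."""
    if x.n_columns < 2:
        raise ValueError("need at least 2 cells to compute adjacency")
    cor = _safe_correlation(x.values)
    a = np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(a, beta)


def tom_dissimilarity(
    a: AdjacencyMatrix,
    convention: str = "wgcna",
    gene_ids: list[str] | None = None,
) -> GroundCost:
    """Topological-overlap dissimilarity of a co-expression adjacency.

    ``convention='wgcna'`` (default) uses connectivity k_i = sum_{u != i} a_iu
    in the denominator's min, matching the topological-overlap literature;
    ``convention='exclusive'`` excludes both endpoints from the connectivity
    sums (values are clipped to [0, 1] where the variant overshoots).
    """
    A = a.values.copy()
    b = A.copy()
    np.fill_diagonal(b, 0.0)
    l = b @ b  # l_ij = sum_{u != i,j} a_iu a_uj when diag(b) = 0
    k = b.sum(axis=1)
    if convention == "wgcna":
        kmin = np.minimum.outer(k, k)
    elif convention == "exclusive":
        # connectivity excludes both endpoints: k_i - a_ij vs k_j - a_ij
        kmin = np.minimum(k[:, None] - b, k[None, :] - b)
    else:
        raise ValueError(f"unknown dissTOM convention {convention!r}")
    denom = kmin + 1.0 - b
    denom = np.where(denom <= 0, 1.0, denom)
    tom = (l + b) / denom
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return GroundCost(d, "dissTOM", gene_ids=gene_ids)


def rescale_cost(m: GroundCost) -> GroundCost:
    """Divide all entries by the max so the largest cost is 1 (idempotent)."""
    mx = m.values.max()
    if mx <= 0:
        raise ValueError("cannot rescale an all-zero ground cost")
    return replace(m, values=m.values / mx, rescaled=True)


def ground_cost_from_reference(
    x: GeneExpressionMatrix,
    metric: str = "dissTOM",
    beta: float = 6.0,
    rescale: bool = True,
    tom_convention: str = "wgcna",
) -> GroundCost:
    """Convenience front end: reference cells -> (rescaled) ground cost."""
    if metric == "dissTOM":
        cost = tom_dissimilarity(power_adjacency(x, beta), convention=tom_convention,
                                 gene_ids=list(x.gene_ids))
    elif metric in METRICS:
        cost = pairwise_gene_cost(x, metric)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return rescale_cost(cost) if rescale else cost
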