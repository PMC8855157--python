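"""Ensemble weighting of per-individual deconvolution results.

When single-cell references from several individuals are available, each
individual's reference yields its own proportion estimate P(r) and fitted
bulk prediction Yhat(r) = C(r) P(r).  The ensemble step finds simplex
weights w minimizing the squared reconstruction error

    || Y - sum_r w_r Yhat(r) ||^2   s.t.  sum_r w_r = 1,  w_r >= 0,

a small simplex-constrained quadratic program solved exactly by active-set
enumeration over the R references.  The weight w_r acts as a similarity
between the bulk individual's expression and reference individual r; the
combined proportions are the w-weighted average of the P(r) on the union
cell-type set (missing types contribute zero), renormalized per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .deconv import DeconvConfig, ProportionMatrix, solve_proportions
from .ground_cost import GroundCost
from .io_qc import Histogram
from .ot_core import _as_mass
from .reference import SignatureMatrix

__all__ = ["EnsembleResult", "solve_ensemble_weights", "ensemble_deconvolve"]


@dataclass
class EnsembleResult:
    """Weights, per-individual estimates, and the combined proportion matrix."""

    weights: np.ndarray
    individuals: list[str]
    per_individual_P: list[ProportionMatrix]
    combined_P: ProportionMatrix
    fitted_bulk: list[np.ndarray]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12):
            raise ValueError("ensemble weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("ensemble weights must sum to 1")


def solve_ensemble_weights(
    y: list[Histogram | np.ndarray] | np.ndarray,
    fitted: list[np.ndarray],
) -> np.ndarray:
    """Exact simplex-constrained least squares over reference weights.

    ``y`` is the stacked bulk matrix (genes x samples, or a list of
    histograms); ``fitted`` the per-reference predictions of the same shape.
    All samples are pooled into one quadratic program.  Rank-deficient ties
    are resolved toward the uniform weight vector.
    """
    if isinstance(y, list):
        Y = np.column_stack([_as_mass(col) for col in y])
    else:
        Y = np.asarray(y, dtype=float)
    R = len(fitted)
    if R == 0:
        raise ValueError("no fitted references supplied")
    A = np.column_stack([np.asarray(F, dtype=float).ravel() for F in fitted])
    b = Y.ravel()
    if A.shape[0] != b.size:
        raise ValueError("fitted predictions do not match the bulk shape")
    if R == 1:
        return np.ones(1)

    G = A.T @ A
    h = A.T @ b
    best: tuple[float, float, np.ndarray] | None = None
    uniform = np.full(R, 1.0 / R)
    for size in range(1, R + 1):
        for active in combinations(range(R), size):
            idx = list(active)
            # equality-constrained LS on the active set via KKT
            K = np.zeros((size + 1, size + 1))
            K[:size, :size] = G[np.ix_(idx, idx)]
            K[:size, size] = 1.0
            K[size, :size] = 1.0
            rhs = np.concatenate([h[idx], [1.0]])
            # lstsq handles rank-deficient ties (identical predictors) with
            # the minimum-norm solution, which is the closest to uniform
            sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
            w_active = sol[:size]
            if not np.all(np.isfinite(w_active)):
                continue
            if np.any(w_active < -1e-10) or abs(w_active.sum() - 1.0) > 1e-6:
                continue
            w = np.zeros(R)
            w[idx] = np.maximum(w_active, 0.0)
            w /= w.sum()
            resid = float(np.sum((A @ w - b) ** 2))
            dist_uniform = float(np.sum((w - uniform) ** 2))
            if best is None or resid < best[0] - 1e-12 * (1.0 + best[0]) or (
                abs(resid - best[0]) <= 1e-12 * (1.0 + best[0])
                and dist_uniform < best[1]
            ):
                best = (resid, dist_uniform, w)
    if best is None:  # pragma: no cover - the full set always yields a candidate
        raise RuntimeError("ensemble weight QP found no feasible active set")
    return best[2]


def _combine_proportions(
    per_individual: list[ProportionMatrix],
    weights: np.ndarray,
    sample_ids: list[str],
) -> ProportionMatrix:
    """w-weighted average on the union (sorted) cell-type set, renormalized."""
    union = sorted({t for P in per_individual for t in P.cell_type_ids})
    m = len(sample_ids)
    combined = np.zeros((len(union), m))
    for w, P in zip(weights, per_individual):
        rows = [union.index(t) for t in P.cell_type_ids]
        combined[rows, :] += w * P.values
    sums = combined.sum(axis=0)
    combined = combined / np.where(sums > 0, sums, 1.0)
    return ProportionMatrix(combined, union, list(sample_ids))


def ensemble_deconvolve(
    yset: list[Histogram | np.ndarray],
    refs: list[SignatureMatrix],
    costs: GroundCost | list[GroundCost],
    cfg: DeconvConfig | None = None,
    sample_ids: list[str] | None = None,
) -> EnsembleResult:
    """Per-individual deconvolution followed by ensemble weighting.

    ``costs`` may be one shared ground cost or one per reference individual
    (each computed from that individual's own cells).  Per-individual
    results are retained for audit.
    """
    cfg = cfg or DeconvConfig()
    if not refs:
        raise ValueError("need at least one reference individual")
    if isinstance(costs, (GroundCost, np.ndarray)):
        costs = [costs] * len(refs)
    if len(costs) != len(refs):
        raise ValueError("need one ground cost per reference (or a shared one)")
    if sample_ids is None:
        sample_ids = [
            getattr(y, "sample_id", None) or f"sample_{j}" for j, y in enumerate(yset)
        ]

    Y = np.column_stack([_as_mass(y) for y in yset])
    per_P: list[ProportionMatrix] = []
    fitted: list[np.ndarray] = []
    for ref, cost in zip(refs, costs):
        try:
            P = solve_proportions(yset, ref, cost, cfg, sample_ids=sample_ids)
        except Exception as exc:
            raise RuntimeError(
                f"deconvolution failed for reference individual {ref.individual!r}"
            ) from exc
        per_P.append(P)
        fitted.append(ref.values @ P.values)

    weights = solve_ensemble_weights(Y, fitted)
    combined = _combine_proportions(per_P, weights, sample_ids)
    return EnsembleResult(
        weights=weights,
        individuals=[r.individual for r in refs],
        per_individual_P=per_P,
        combined_P=combined,
        fitted_bulk=fitted,
    )
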