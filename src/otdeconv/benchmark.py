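"""Pseudo-bulk benchmarking protocol, synthetic data generation, and metrics.

The benchmarking protocol mirrors standard practice for reference-based
deconvolution: per individual, cells are split evenly into a reference half
(used to build signatures and ground costs) and a testing half; pseudo-bulk
mixtures are formed by repeatedly sampling a fraction of the testing cells
uniformly at random (default 60%, 200 replicates) and summing their counts
per gene, recording the realized cell-type composition of each draw as the
ground truth.  Estimates are scored by the root-mean-squared error over all
cell-type x sample entries and the Pearson correlation of the flattened
matrices.

The synthetic generator emulates multi-individual, multi-cell-type count
data: per-type expression rate profiles shared by all individuals
(log-normal across genes), per-individual multiplicative gene effects
(log-normal, controlling batch strength), and multinomial per-cell counts
at a fixed depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconv import ProportionMatrix
from .io_qc import GeneExpressionMatrix

__all__ = [
    "PseudoBulkSet",
    "SyntheticScenario",
    "SyntheticDataset",
    "split_cells",
    "generate_pseudobulk",
    "generate_synthetic_truth",
    "align_proportions",
    "rmse",
    "pearson_correlation",
]


@dataclass
class PseudoBulkSet:
    """Simulated bulk mixtures with recorded ground truth and provenance."""

    mixtures: GeneExpressionMatrix
    truth: ProportionMatrix
    source_individual: str
    sampling_fraction: float
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        if self.mixtures.n_columns != self.n_replicates:
            raise ValueError("mixture count does not match n_replicates")
        if self.truth.values.shape[1] != self.n_replicates:
            raise ValueError("truth column count does not match n_replicates")


@dataclass
class SyntheticScenario:
    """Parameters of the synthetic multi-individual single-cell world.

    ``cells_per_type`` may be a single integer or one count per cell type;
    ``individual_effect_sd`` is the log-scale standard deviation of the
    per-individual multiplicative gene effects (0 disables batch structure);
    ``type_effect_sd`` controls how distinct the type profiles are;
    ``dirichlet_alpha`` is the concentration of the truth proportions used
    for paired bulk mixtures.
    """

    n_genes: int = 200
    n_types: int = 5
    n_individuals: int = 3
    cells_per_type: int | tuple[int, ...] = 100
    depth: int = 2000
    individual_effect_sd: float = 0.3
    type_effect_sd: float = 1.0
    dirichlet_alpha: float = 1.0
    n_bulk: int = 0
    bulk_depth: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = self.cells_per_type
        if isinstance(counts, int):
            counts = (counts,) * self.n_types
        counts = tuple(int(c) for c in counts)
        if len(counts) != self.n_types:
            raise ValueError("cells_per_type must give one count per type")
        if any(c <= 0 for c in counts):
            raise ValueError("all cell counts must be positive")
        self.cells_per_type = counts
        if self.depth <= 0 or self.n_genes <= 0:
            raise ValueError("depth and n_genes must be positive")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")


@dataclass
class SyntheticDataset:
    """Output bundle of :func:`generate_synthetic_truth`."""

    sc: GeneExpressionMatrix
    annotations: pd.DataFrame
    type_profiles: dict[str, np.ndarray]  # individual -> genes x types rates
    cell_types: list[str]
    individuals: list[str]
    bulks: GeneExpressionMatrix | None = None
    truth: ProportionMatrix | None = None


def split_cells(
    ann: pd.DataFrame, seed: int
) -> tuple[list[str], list[str]]:
    """Even, stratified reference/testing split of annotated cells.

    Per individual and per cell type, a seeded 50/50 split; when the count
    is odd the reference side receives the extra cell.  Singleton types go
    entirely to the reference with a warning.
    """
    rng = np.random.default_rng(seed)
    reference: list[str] = []
    testing: list[str] = []
    for (ind, ctype), group in ann.groupby(["individual", "cell_type"], sort=True):
        ids = list(group["cell_id"])
        if len(ids) == 1:
            warnings.warn(
                f"cell type {ctype!r} of individual {ind!r} has a single cell; "
                "assigned to the reference set"
            )
            reference.extend(ids)
            continue
        perm = rng.permutation(len(ids))
        n_ref = (len(ids) + 1) // 2
        reference.extend(ids[i] for i in perm[:n_ref])
        testing.extend(ids[i] for i in perm[n_ref:])
    return reference, testing


def generate_pseudobulk(
    sc_testing: GeneExpressionMatrix,
    ann: pd.DataFrame,
    n_replicates: int = 200,
    fraction: float = 0.6,
    seed: int = 0,
    source_individual: str = "",
) -> PseudoBulkSet:
    """Sum counts of random cell subsets into pseudo-bulk mixtures.

    Each replicate draws ``floor(fraction * N)`` testing cells without
    replacement (uniformly over cells, not stratified) and sums their counts
    per gene; the recorded truth is the realized cell-type composition of
    the draw.  Replicate r uses seed ``seed + r``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    N = sc_testing.n_columns
    n_draw = int(np.floor(fraction * N))
    if n_draw < 1:
        raise ValueError(f"fraction {fraction} of {N} cells draws no cell")
    ann_idx = ann.set_index("cell_id")
    types = sorted(ann_idx.loc[sc_testing.column_ids, "cell_type"].unique())
    type_of = ann_idx.loc[sc_testing.column_ids, "cell_type"].to_numpy()

    mix = np.empty((sc_testing.n_genes, n_replicates))
    truth = np.zeros((len(types), n_replicates))
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        chosen = rng.choice(N, size=n_draw, replace=False)
        mix[:, r] = sc_testing.values[:, chosen].sum(axis=1)
        for t_i, t in enumerate(types):
            truth[t_i, r] = np.sum(type_of[chosen] == t)
    truth /= n_draw

    mixtures = GeneExpressionMatrix(
        mix,
        list(sc_testing.gene_ids),
        [f"mix_{r}" for r in range(n_replicates)],
        is_counts=True,
    )
    truth_P = ProportionMatrix(truth, types, list(mixtures.column_ids))
    return PseudoBulkSet(
        mixtures, truth_P, source_individual, fraction, n_replicates, seed
    )


def generate_synthetic_truth(s: SyntheticScenario) -> SyntheticDataset:
    """Draw a fully seeded synthetic multi-individual single-cell dataset.

    Per-type rate profiles are shared across individuals and modulated by
    per-individual log-normal gene effects; each cell's counts are
    multinomial at the scenario depth.  With ``n_bulk > 0`` paired bulk
    mixtures for the first individual are also drawn (Dirichlet truth
    proportions, multinomial counts at ``bulk_depth``).
    """
    rng = np.random.default_rng(s.seed)
    genes = [f"gene_{i}" for i in range(s.n_genes)]
    types = [f"type_{t}" for t in range(s.n_types)]
    individuals = [f"indiv_{r}" for r in range(s.n_individuals)]

    base = np.exp(rng.normal(0.0, 1.0, size=s.n_genes))
    type_rates = base[:, None] * np.exp(
        rng.normal(0.0, s.type_effect_sd, size=(s.n_genes, s.n_types))
    )

    profiles: dict[str, np.ndarray] = {}
    cols: list[np.ndarray] = []
    cell_ids: list[str] = []
    records: list[dict] = []
    for ind in individuals:
        effect = np.exp(rng.normal(0.0, s.individual_effect_sd, size=s.n_genes))
        rates = type_rates * effect[:, None]
        profiles[ind] = rates
        for t_i, ctype in enumerate(types):
            probs = rates[:, t_i] / rates[:, t_i].sum()
            counts = rng.multinomial(s.depth, probs, size=s.cells_per_type[t_i]).T
            cols.append(counts)
            for j in range(s.cells_per_type[t_i]):
                cid = f"{ind}_{ctype}_c{j}"
                cell_ids.append(cid)
                records.append(
                    {"cell_id": cid, "cell_type": ctype, "individual": ind}
                )
    sc = GeneExpressionMatrix(
        np.concatenate(cols, axis=1), genes, cell_ids, is_counts=True
    )
    ann = pd.DataFrame.from_records(records)

    bulks = None
    truth = None
    if s.n_bulk > 0:
        P = rng.dirichlet(np.full(s.n_types, s.dirichlet_alpha), size=s.n_bulk).T
        rates = profiles[individuals[0]]
        type_probs = rates / rates.sum(axis=0)
        counts = np.empty((s.n_genes, s.n_bulk))
        for j in range(s.n_bulk):
            mean = type_probs @ P[:, j]
            counts[:, j] = rng.multinomial(s.bulk_depth, mean / mean.sum())
        bulks = GeneExpressionMatrix(
            counts, genes, [f"bulk_{j}" for j in range(s.n_bulk)], is_counts=True
        )
        truth = ProportionMatrix(P, types, list(bulks.column_ids))
    return SyntheticDataset(sc, ann, profiles, types, individuals, bulks, truth)


def align_proportions(
    truth: ProportionMatrix, est: ProportionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-fill both matrices onto the union cell-type set (sorted)."""
    if truth.sample_ids != est.sample_ids and len(truth.sample_ids) != len(
        est.sample_ids
    ):
        raise ValueError("sample counts differ between truth and estimate")
    union = sorted(set(truth.cell_type_ids) | set(est.cell_type_ids))
    m = len(truth.sample_ids)

    def embed(P: ProportionMatrix) -> np.ndarray:
        out = np.zeros((len(union), m))
        for i, t in enumerate(P.cell_type_ids):
            out[union.index(t), :] = P.values[i, :]
        return out

    return embed(truth), embed(est)


def rmse(truth: ProportionMatrix, est: ProportionMatrix) -> float:
    """Root-mean-squared error pooled over all k x m proportion entries."""
    T, E = align_proportions(truth, est)
    return float(np.sqrt(np.mean((T - E) ** 2)))


def pearson_correlation(
    truth: ProportionMatrix, est: ProportionMatrix, per_sample: bool = False
) -> float:
    """Pearson correlation of the flattened proportion matrices.

    With ``per_sample=True`` the correlation is computed within each sample
    column and averaged instead (the other common reading of cor(P, P_hat)).
    """
    T, E = align_proportions(truth, est)
    if per_sample:
        cors = []
        for j in range(T.shape[1]):
            if T[:, j].std() == 0 or E[:, j].std() == 0:
                raise ValueError(
                    f"Pearson correlation undefined for constant column {j}"
                )
            cors.append(np.corrcoef(T[:, j], E[:, j])[0, 1])
        return float(np.mean(cors))
    t, e = T.ravel(), E.ravel()
    if t.std() == 0 or e.std() == 0:
        raise ValueError("Pearson correlation undefined for constant proportions")
    return float(np.corrcoef(t, e)[0, 1])
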