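import numpy as np
import pandas as pd
import pytest

from otdeconv import (
    GeneExpressionMatrix,
    SignatureMatrix,
    SyntheticScenario,
    generate_synthetic_truth,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_sc():
    """4 genes x 6 cells, two cell types, two individuals."""
    values = np.array(
        [
            [5, 6, 1, 0, 4, 5],
            [1, 2, 8, 9, 2, 1],
            [3, 3, 3, 4, 3, 2],
            [0, 1, 0, 1, 1, 0],
        ],
        dtype=float,
    )
    return GeneExpressionMatrix(
        values,
        ["g1", "g2", "g3", "g4"],
        ["c1", "c2", "c3", "c4", "c5", "c6"],
    )


@pytest.fixture
def small_ann():
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3", "c4", "c5", "c6"],
            "cell_type": ["A", "A", "B", "B", "A", "A"],
            "individual": ["i1", "i1", "i1", "i2", "i2", "i2"],
        }
    )


@pytest.fixture
def random_cost(rng):
    def make(n, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        m = r.uniform(0.0, 1.0, size=(n, n))
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        return m / m.max()

    return make


@pytest.fixture
def random_signature(rng):
    def make(n, k, seed=1, alpha=0.5):
        r = np.random.default_rng(seed)
        C = r.dirichlet(np.full(n, alpha), size=k).T
        return SignatureMatrix(
            C, [f"g{i}" for i in range(n)], [f"t{j}" for j in range(k)], "sim"
        )

    return make


@pytest.fixture(scope="session")
def multi_individual_data():
    """Shared seeded 3-individual dataset with batch effects."""
    scenario = SyntheticScenario(
        n_genes=100,
        n_types=4,
        n_individuals=3,
        cells_per_type=60,
        depth=2000,
        individual_effect_sd=0.3,
        seed=0,
    )
    return generate_synthetic_truth(scenario)
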