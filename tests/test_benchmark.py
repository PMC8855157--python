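import numpy as np
import pandas as pd
import pytest

from otdeconv import (
    GeneExpressionMatrix,
    ProportionMatrix,
    SyntheticScenario,
    generate_pseudobulk,
    generate_synthetic_truth,
    pearson_correlation,
    rmse,
    split_cells,
)


def _ann(counts, individual="i1"):
    rows = []
    for ctype, n in counts.items():
        for i in range(n):
            rows.append(
                {"cell_id": f"{individual}_{ctype}{i}", "cell_type": ctype,
                 "individual": individual}
            )
    return pd.DataFrame(rows)


class TestSplitCells:
    def test_even_split(self):
        ref, test = split_cells(_ann({"A": 10}), seed=0)
        assert len(ref) == 5 and len(test) == 5
        assert set(ref) | set(test) == set(_ann({"A": 10})["cell_id"])
        assert not set(ref) & set(test)

    def test_odd_count_gives_reference_the_extra_cell(self):
        ref, test = split_cells(_ann({"A": 11}), seed=0)
        assert len(ref) == 6 and len(test) == 5

    def test_stratified_by_type(self):
        ann = _ann({"A": 10, "B": 20})
        ref, test = split_cells(ann, seed=1)
        by_type = ann.set_index("cell_id")["cell_type"]
        assert sum(by_type[c] == "A" for c in test) == 5
        assert sum(by_type[c] == "B" for c in test) == 10

    def test_singleton_type_goes_to_reference_with_warning(self):
        with pytest.warns(UserWarning, match="single cell"):
            ref, test = split_cells(_ann({"A": 4, "B": 1}), seed=0)
        assert "i1_B0" in ref

    def test_seeded_determinism(self):
        ann = _ann({"A": 9, "B": 7})
        assert split_cells(ann, seed=5) == split_cells(ann, seed=5)


class TestGeneratePseudobulk:
    @pytest.fixture
    def testing_cells(self, rng):
        values = rng.poisson(5, size=(12, 10)).astype(float)
        cells = [f"c{i}" for i in range(10)]
        sc = GeneExpressionMatrix(values, [f"g{i}" for i in range(12)], cells)
        ann = pd.DataFrame(
            {"cell_id": cells, "cell_type": ["A"] * 6 + ["B"] * 4,
             "individual": ["i1"] * 10}
        )
        return sc, ann

    def test_full_fraction_is_degenerate(self, testing_cells):
        sc, ann = testing_cells
        pb = generate_pseudobulk(sc, ann, n_replicates=3, fraction=1.0, seed=0)
        total = sc.values.sum(axis=1)
        for r in range(3):
            np.testing.assert_array_equal(pb.mixtures.values[:, r], total)
            np.testing.assert_allclose(pb.truth.values[:, r], [0.6, 0.4])

    def test_truth_equals_realized_draw_composition(self, testing_cells):
        sc, ann = testing_cells
        pb = generate_pseudobulk(sc, ann, n_replicates=1, fraction=0.5, seed=7)
        # recompute the seeded draw independently
        draw = np.random.default_rng(7).choice(10, size=5, replace=False)
        types = ann.set_index("cell_id").loc[
            [sc.column_ids[i] for i in draw], "cell_type"
        ]
        np.testing.assert_allclose(
            pb.truth.values[:, 0],
            [np.mean(types == "A"), np.mean(types == "B")],
        )
        np.testing.assert_array_equal(
            pb.mixtures.values[:, 0], sc.values[:, draw].sum(axis=1)
        )

    def test_column_sum_is_sum_of_sampled_library_sizes(self, testing_cells):
        sc, ann = testing_cells
        pb = generate_pseudobulk(sc, ann, n_replicates=5, fraction=0.6, seed=3)
        for r in range(5):
            assert pb.mixtures.values[:, r].sum() == pytest.approx(
                pb.mixtures.values[:, r].sum()
            )
            np.testing.assert_allclose(pb.truth.values[:, r].sum(), 1.0)

    def test_too_small_fraction_rejected(self, testing_cells):
        sc, ann = testing_cells
        with pytest.raises(ValueError, match="draws no cell"):
            generate_pseudobulk(sc, ann, n_replicates=1, fraction=0.05, seed=0)

    def test_replicate_seeds_are_offset(self, testing_cells):
        sc, ann = testing_cells
        a = generate_pseudobulk(sc, ann, n_replicates=3, fraction=0.5, seed=0)
        b = generate_pseudobulk(sc, ann, n_replicates=1, fraction=0.5, seed=2)
        np.testing.assert_array_equal(a.mixtures.values[:, 2], b.mixtures.values[:, 0])


class TestGenerateSyntheticTruth:
    def test_same_seed_is_bitwise_identical(self):
        s = SyntheticScenario(n_genes=30, n_types=3, n_individuals=2,
                              cells_per_type=10, seed=4)
        a = generate_synthetic_truth(s)
        b = generate_synthetic_truth(s)
        np.testing.assert_array_equal(a.sc.values, b.sc.values)
        assert a.annotations.equals(b.annotations)

    def test_no_individual_effect_shares_profiles(self):
        s = SyntheticScenario(n_genes=40, n_types=2, n_individuals=2,
                              cells_per_type=10, individual_effect_sd=0.0, seed=5)
        d = generate_synthetic_truth(s)
        p0 = d.type_profiles[d.individuals[0]]
        p1 = d.type_profiles[d.individuals[1]]
        np.testing.assert_allclose(p0, p1)

    def test_large_dirichlet_alpha_concentrates_on_uniform(self):
        s = SyntheticScenario(n_genes=30, n_types=4, n_individuals=1,
                              cells_per_type=5, dirichlet_alpha=1e5,
                              n_bulk=5, seed=6)
        d = generate_synthetic_truth(s)
        np.testing.assert_allclose(d.truth.values, 0.25, atol=0.01)

    def test_per_type_cell_counts(self):
        s = SyntheticScenario(n_genes=20, n_types=3, n_individuals=1,
                              cells_per_type=(5, 7, 9), seed=7)
        d = generate_synthetic_truth(s)
        counts = d.annotations["cell_type"].value_counts()
        assert counts["type_0"] == 5 and counts["type_1"] == 7 and counts["type_2"] == 9


class TestMetrics:
    def test_rmse_exact_on_identical(self):
        P = ProportionMatrix(np.array([[0.6], [0.4]]), ["a", "b"], ["s1"])
        assert rmse(P, P) == 0.0

    def test_rmse_hand_value_single_column(self):
        t = ProportionMatrix(np.array([[0.6], [0.4]]), ["a", "b"], ["s1"])
        e = ProportionMatrix(np.array([[0.5], [0.5]]), ["a", "b"], ["s1"])
        assert rmse(t, e) == pytest.approx(0.1)

    def test_rmse_hand_value_two_columns(self):
        t = ProportionMatrix(np.array([[0.6, 0.5], [0.4, 0.5]]), ["a", "b"], ["s1", "s2"])
        e = ProportionMatrix(np.array([[0.5, 0.5], [0.5, 0.5]]), ["a", "b"], ["s1", "s2"])
        assert rmse(t, e) == pytest.approx(np.sqrt(0.02 / 4))

    def test_rmse_zero_fills_union_types(self):
        t = ProportionMatrix(np.array([[0.6], [0.4]]), ["a", "b"], ["s1"])
        e = ProportionMatrix(np.array([[1.0]]), ["a"], ["s1"])
        assert rmse(t, e) == pytest.approx(np.sqrt((0.16 + 0.16) / 2))

    def test_pearson_perfect_on_identity(self, rng):
        vals = rng.dirichlet(np.ones(3), size=4).T
        P = ProportionMatrix(vals, ["a", "b", "c"], list("wxyz"))
        assert pearson_correlation(P, P) == pytest.approx(1.0)

    def test_pearson_affine_invariance(self, rng):
        vals = rng.dirichlet(np.ones(4), size=3).T
        t = ProportionMatrix(vals, list("abcd"), list("xyz"))
        shifted = 0.5 * vals + 0.125
        e = ProportionMatrix(shifted, list("abcd"), list("xyz"))
        assert pearson_correlation(t, e) == pytest.approx(1.0)

    def test_pearson_anti_correlated_two_type_case(self):
        t = ProportionMatrix(np.array([[0.7, 0.2], [0.3, 0.8]]), ["a", "b"], ["s1", "s2"])
        e = ProportionMatrix(1.0 - t.values, ["a", "b"], ["s1", "s2"])
        assert pearson_correlation(t, e) == pytest.approx(-1.0)

    def test_pearson_per_sample_variant_averages_columns(self, rng):
        vals = rng.dirichlet(np.ones(4), size=3).T
        t = ProportionMatrix(vals, list("abcd"), list("xyz"))
        noisy = vals + rng.normal(0, 0.01, size=vals.shape)
        noisy = np.abs(noisy)
        noisy /= noisy.sum(axis=0)
        e = ProportionMatrix(noisy, list("abcd"), list("xyz"))
        expected = np.mean(
            [np.corrcoef(vals[:, j], noisy[:, j])[0, 1] for j in range(3)]
        )
        assert pearson_correlation(t, e, per_sample=True) == pytest.approx(expected)

    def test_pearson_undefined_for_constant(self):
        t = ProportionMatrix(np.full((2, 2), 0.5), ["a", "b"], ["s1", "s2"])
        with pytest.raises(ValueError, match="undefined"):
            pearson_correlation(t, t)
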