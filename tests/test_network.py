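"""Adjacency, TOM, connectivity, filtering and soft-threshold selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bjnet import (
    ExpressionMatrix,
    adjacency,
    comparability,
    connectivity,
    filter_genes_and_samples,
    intersect_common_genes,
    scale_free_fit,
    soft_threshold_scan,
    tom_similarity,
)

from conftest import random_symmetric_adjacency, truth_series


def tom_brute_force(a):
    """Triple-loop evaluation of TOM_ij = (l_ij + a_ij)/(min(k_i,k_j)+1-a_ij)."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def expr_from(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"S{j}" for j in range(values.shape[1])],
    )
    return ExpressionMatrix(frame, log_transformed=True)


class TestAdjacency:
    @pytest.mark.parametrize(
        "cor,power,expected",
        [(-0.5, 2, 0.25), (-0.5, 1, 0.5), (1.0, 7, 1.0)],
    )
    def test_unsigned_power(self, cor, power, expected):
        c = np.array([[1.0, cor], [cor, 1.0]])
        a = adjacency(c, power)
        assert a[0, 1] == pytest.approx(expected)
        assert a[0, 0] == 0.0  # diagonal defined 0 for sums

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            adjacency(np.eye(2), 0)
        with pytest.raises(ValueError):
            adjacency(np.array([[1.0, 1.5], [1.5, 1.0]]), 2)


class TestConnectivity:
    def test_clique_star_and_empty(self):
        clique = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(connectivity(clique), [2, 2, 2])
        np.testing.assert_allclose(connectivity(np.zeros((4, 4))), 0)
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 0.5
        k = connectivity(star)
        assert k[0] == pytest.approx(2.0)
        np.testing.assert_allclose(k[1:], 0.5)


class TestTom:
    def test_perfect_clique(self):
        a = np.ones((3, 3)) - np.eye(3)
        assert tom_similarity(a)[0, 1] == pytest.approx(1.0)

    def test_single_edge(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        assert tom_similarity(a)[0, 1] == pytest.approx(0.5)

    def test_isolated_node(self):
        rng = np.random.default_rng(0)
        a = random_symmetric_adjacency(rng, 6)
        a[2, :] = a[:, 2] = 0.0
        tom = tom_similarity(a)
        assert np.all(tom[2, [i for i in range(6) if i != 2]] == 0.0)
        assert tom[2, 2] == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            a = random_symmetric_adjacency(rng, 30)
            np.testing.assert_allclose(
                tom_similarity(a), tom_brute_force(a), atol=1e-10
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 15))
    def test_tom_bounded_unit_interval(self, seed, n):
        a = random_symmetric_adjacency(np.random.default_rng(seed), n)
        tom = tom_similarity(a)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        dist = 1.0 - tom
        assert dist.min() >= 0.0 and dist.max() <= 1.0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        a = random_symmetric_adjacency(rng, 12)
        perm = rng.permutation(12)
        tom = tom_similarity(a)
        tom_p = tom_similarity(a[np.ix_(perm, perm)])
        np.testing.assert_allclose(tom_p, tom[np.ix_(perm, perm)], atol=1e-12)
        np.testing.assert_allclose(
            connectivity(a[np.ix_(perm, perm)]), connectivity(a)[perm]
        )

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.9
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)

    def test_planted_module_has_elevated_tom(self, small_networks, small_data):
        _, _, _, _, truth = small_data
        net = small_networks["PB"]
        t = truth_series(truth, "PB").reindex(net.gene_ids)
        mod = np.array([lbl == "M1" for lbl in t])
        bg = np.array([lbl == "background" for lbl in t])
        tom = net.tom.copy()
        np.fill_diagonal(tom, np.nan)
        within = np.nanmean(tom[np.ix_(mod, mod)])
        across = np.nanmean(tom[np.ix_(mod, bg)])
        assert within > across


class TestFiltering:
    def test_constant_gene_removed(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(5, 1, (10, 6))
        vals[3] = 2.0
        m = expr_from(vals)
        filtered, removed_genes, _ = filter_genes_and_samples(m)
        assert "g3" in removed_genes
        assert filtered.n_genes == 9

    def test_clean_matrix_untouched(self):
        rng = np.random.default_rng(2)
        m = expr_from(rng.normal(5, 1, (30, 8)))
        filtered, removed_genes, removed_samples = filter_genes_and_samples(
            m, sample_outlier_z=5.0
        )
        assert removed_genes == [] and removed_samples == []
        pd.testing.assert_frame_equal(filtered.data, m.data)

    def test_outlier_sample_detected(self):
        # 20 samples share per-gene baselines; 1 is independent noise
        rng = np.random.default_rng(3)
        base = rng.normal(5, 2, size=(200, 1))
        coherent = base + 0.3 * rng.standard_normal((200, 20))
        outlier = rng.normal(5, 2, size=(200, 1))
        m = expr_from(np.hstack([coherent, outlier]))
        # oracle: standardized connectivity of the sample correlation network
        c = np.corrcoef(m.values.T)
        np.fill_diagonal(c, 0.0)
        k = ((1 + c) / 2).sum(axis=1)
        z = (k - k.mean()) / k.std()
        assert z[-1] < -2.5
        _, _, removed_samples = filter_genes_and_samples(m, sample_outlier_z=2.5)
        assert removed_samples == ["S20"]

    def test_missing_values_imputed_after_gene_gate(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(5, 1, (10, 6))
        vals[0, 0] = np.nan  # 1/6 missing: below the gate, imputed
        vals[1, :5] = np.nan  # 5/6 missing: removed
        m = expr_from(vals)
        filtered, removed_genes, _ = filter_genes_and_samples(m, max_missing_frac=0.5)
        assert "g1" in removed_genes
        assert not filtered.data.isna().any().any()
        assert filtered.data.loc["g0", "S0"] == pytest.approx(
            np.nanmean(vals[0])
        )


class TestIntersect:
    def test_common_sorted_intersection(self):
        a = expr_from(np.arange(6.0).reshape(3, 2))
        b = ExpressionMatrix(a.data.iloc[[2, 1]].copy(), log_transformed=True)
        ia, ib = intersect_common_genes(a, b)
        assert ia.gene_ids == ib.gene_ids == ["g1", "g2"]

    def test_disjoint_rejected(self):
        a = expr_from(np.ones((2, 2)), prefix="a")
        b = expr_from(np.ones((2, 2)), prefix="b")
        with pytest.raises(ValueError, match="common"):
            intersect_common_genes(a, b)


class TestComparability:
    def test_identical_datasets(self):
        rng = np.random.default_rng(6)
        m = expr_from(rng.normal(5, 1, (50, 10)))
        (r_mean, _), (r_k, _) = comparability(m, m)
        assert r_mean == pytest.approx(1.0)
        assert r_k == pytest.approx(1.0)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(7)
        a = expr_from(rng.normal(5, 1, (2000, 12)))
        b = expr_from(rng.normal(5, 1, (2000, 12)))
        (r_mean, _), (r_k, _) = comparability(a, b)
        assert abs(r_mean) < 0.1
        assert abs(r_k) < 0.1

    def test_partially_preserved_cultivars_intermediate(self, small_data):
        expr, _, _, _, _ = small_data
        a = expr["PB"].to_log2(1.0)
        b = expr["PJK"].to_log2(1.0)
        (r_mean, p_mean), (r_k, _) = comparability(a, b)
        assert r_mean > 0.9 and p_mean < 1e-10  # shared baselines
        assert 0.0 < r_k < 1.0


class TestSoftThreshold:
    def test_power_law_degrees_fit_well(self):
        # inverse-transform sample of p(k) ~ k^-2.5 on [1, 100]
        rng = np.random.default_rng(8)
        gamma, kmin, kmax = 2.5, 1.0, 100.0
        u = rng.random(20_000)
        a, b = kmin ** (1 - gamma), kmax ** (1 - gamma)
        k = (a + u * (b - a)) ** (1 / (1 - gamma))
        r2, slope = scale_free_fit(k, n_bins=10)
        assert slope < 0
        assert r2 >= 0.95

    def test_mean_k_decreasing_in_power(self):
        rng = np.random.default_rng(9)
        m = expr_from(rng.normal(0, 1, (300, 15)))
        scan = soft_threshold_scan(m, powers=range(1, 21), r2_threshold=0.99)
        mean_k = scan.table["mean_k"].to_numpy()
        assert (np.diff(mean_k) < 0).all()

    def test_too_few_genes_rejected(self):
        m = expr_from(np.random.default_rng(0).normal(0, 1, (2, 10)))
        with pytest.raises(ValueError, match="20 genes"):
            soft_threshold_scan(m)

    def test_degenerate_connectivity_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            scale_free_fit(np.full(100, 3.0))

    def test_chosen_power_follows_selection_rule(self, small_data):
        expr, _, _, _, _ = small_data
        logm = expr["PB"].to_log2(1.0)
        keep = [g for g in logm.gene_ids if g != "BjUbq9"]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = soft_threshold_scan(logm.subset_genes(keep), powers=range(1, 13))
        table = scan.table
        passing = table.loc[table["scale_free_r2"] >= 0.80, "power"]
        if len(passing):
            assert scan.chosen_power == passing.iloc[0]
        else:
            assert scan.chosen_power == int(
                table.loc[table["scale_free_r2"].idxmax(), "power"]
            )
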