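"""Trait encoding, module-trait gating, GS, K and hub tables."""

import numpy as np
import pandas as pd
import pytest

from bjnet import (
    ExpressionMatrix,
    ModulePartition,
    encode_trait,
    gene_significance,
    module_trait_correlation,
    scaled_connectivity,
    top_hub_tfs,
)
from bjnet.io import AnnotationMap
from bjnet.modules import EigengeneSet
from bjnet.network import _cor_test

from conftest import match_planted


def design_from(doses):
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(len(doses))],
            "cultivar": "PB",
            "kno3_mM": doses,
            "timepoint": "2h",
        }
    ).set_index("sample_id", drop=False)


def eigenset(values, samples):
    return EigengeneSet(eigengenes=pd.DataFrame(values, index=samples).T)


class TestEncodeTrait:
    def test_binary(self):
        t = encode_trait(design_from([0, 0.25, 2, 4]), "binary")
        np.testing.assert_array_equal(t.values, [0, 1, 1, 1])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            encode_trait(design_from([2, 2, 2]), "dose_log")

    def test_dose_log_monotone(self):
        t = encode_trait(design_from([0, 0.25, 2, 4]), "dose_log")
        assert t["S3"] > t["S2"] > t["S1"] > t["S0"]

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="scheme"):
            encode_trait(design_from([0, 4]), "nope")


class TestModuleTrait:
    def test_identity_and_orthogonal(self):
        rng = np.random.default_rng(20)
        trait = pd.Series(rng.normal(0, 1, 21), index=[f"S{i}" for i in range(21)])
        tc = trait.values - trait.values.mean()
        ortho = rng.normal(0, 1, 21)
        ortho -= ortho.mean()
        ortho -= (ortho @ tc) / (tc @ tc) * tc  # zero Pearson correlation
        eig = eigenset({"a": trait.values, "b": ortho}, trait.index)
        results = {r.module: r for r in module_trait_correlation(eig, trait)}
        assert results["a"].r == pytest.approx(1.0)
        assert results["a"].significant and results["a"].direction == 1
        assert abs(results["b"].r) < 1e-10 and not results["b"].significant

    def test_gate_applies_to_absolute_r(self):
        trait = pd.Series(np.linspace(-1, 1, 21), index=[f"S{i}" for i in range(21)])
        eig = eigenset({"down": -trait.values}, trait.index)
        (res,) = module_trait_correlation(eig, trait)
        assert res.significant and res.direction == -1

    def test_responsive_modules_pass_gate(self, small_data, small_partitions, small_eigengenes):
        expr, design, _, _, truth = small_data
        sub = design[design["cultivar"] == "PB"]
        trait = encode_trait(sub, "dose_log")
        results = {
            r.module: r
            for r in module_trait_correlation(small_eigengenes["PB"], trait)
        }
        mapping = match_planted(truth, "PB", small_partitions["PB"])
        for planted in truth.responsive_modules:
            assert results[mapping[planted]].significant
            assert results[mapping[planted]].direction == 1  # planted positive slope


class TestGeneSignificance:
    def test_exact_and_inverted_tracking(self):
        trait = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("abcd"))
        frame = pd.DataFrame(
            [[0, 1, 2, 3], [3, 2, 1, 0]], index=["up", "down"], columns=list("abcd"),
            dtype=float,
        )
        gs = gene_significance(ExpressionMatrix(frame, log_transformed=True), trait)
        assert gs["up"] == pytest.approx(1.0)
        assert gs["down"] == pytest.approx(1.0)

    def test_zero_variance_gene_warns_and_zero(self):
        trait = pd.Series([0.0, 1.0, 2.0], index=list("abc"))
        frame = pd.DataFrame([[5, 5, 5]], index=["flat"], columns=list("abc"), dtype=float)
        with pytest.warns(UserWarning, match="zero-variance"):
            gs = gene_significance(ExpressionMatrix(frame, log_transformed=True), trait)
        assert gs["flat"] == 0.0

    def test_null_distribution_at_n21(self):
        rng = np.random.default_rng(21)
        trait = pd.Series(rng.normal(0, 1, 21), index=[f"S{i}" for i in range(21)])
        frame = pd.DataFrame(
            rng.normal(0, 1, (500, 21)),
            index=[f"g{i}" for i in range(500)], columns=trait.index,
        )
        gs = gene_significance(ExpressionMatrix(frame, log_transformed=True), trait)
        assert abs(gs.mean() - 0.18) < 0.04  # E|r| for independent noise, n=21
        assert (gs < 0.6).mean() > 0.99


class TestScaledConnectivity:
    def test_clique_all_ones(self):
        a = np.ones((3, 3)) - np.eye(3)
        part = ModulePartition(pd.Series({"g0": "m", "g1": "m", "g2": "m"}))
        k = scaled_connectivity(a, ["g0", "g1", "g2"], part)
        np.testing.assert_allclose(k[["g0", "g1", "g2"]], 1.0)

    def test_star_module(self):
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 0.8
        genes = [f"g{i}" for i in range(5)]
        part = ModulePartition(pd.Series("m", index=genes))
        k = scaled_connectivity(a, genes, part)
        assert k["g0"] == pytest.approx(1.0)
        assert k["g1"] == pytest.approx(0.25)  # 0.8 / 3.2

    def test_singleton_module_convention(self):
        a = np.zeros((2, 2))
        part = ModulePartition(pd.Series({"g0": "m", "g1": "grey"}))
        k = scaled_connectivity(a, ["g0", "g1"], part)
        assert k["g0"] == 1.0
        assert "g1" not in k.index  # grey genes carry no K

    def test_every_module_tops_at_one(self, small_networks, small_partitions):
        net = small_networks["PB"]
        part = small_partitions["PB"]
        k = scaled_connectivity(net.adjacency, net.gene_ids, part)
        for module in part.module_names:
            kmod = k[part.members(module)]
            assert kmod.max() == pytest.approx(1.0)
            assert (kmod <= 1.0 + 1e-12).all()

    def test_planted_hubs_reach_top(self, small_data, small_networks, small_partitions):
        _, _, _, _, truth = small_data
        net = small_networks["PB"]
        part = small_partitions["PB"]
        k = scaled_connectivity(net.adjacency, net.gene_ids, part)
        mapping = match_planted(truth, "PB", part)
        for planted, hubs in truth.hub_genes.items():
            members = part.members(mapping[planted])
            ranked = k[members].sort_values(ascending=False)
            for hub in hubs:
                assert list(ranked.index).index(hub) < 5


class TestTopHubTfs:
    def _setup(self):
        genes = ["a", "b", "c", "d"]
        part = ModulePartition(pd.Series("m", index=genes))
        k = pd.Series({"a": 1.0, "b": 0.9, "c": 0.9, "d": 0.99})
        gs = pd.Series({"a": 0.2, "b": 0.5, "c": 0.4, "d": 0.3})
        return part, k, gs

    def test_only_tf_genes_rank(self):
        part, k, gs = self._setup()
        tf = AnnotationMap("TF", {"c": {"MYB"}})
        table = top_hub_tfs(k, gs, tf, part)
        assert list(table["gene_id"]) == ["c"]
        assert table.loc[0, "rank"] == 1

    def test_order_by_k_then_gs(self):
        part, k, gs = self._setup()
        tf = AnnotationMap("TF", {g: {"WRKY"} for g in ("b", "c", "d")})
        table = top_hub_tfs(k, gs, tf, part, n_top=3)
        assert list(table["gene_id"]) == ["d", "b", "c"]  # GS breaks the 0.9 tie

    def test_module_without_tfs_is_empty_not_error(self):
        part, k, gs = self._setup()
        tf = AnnotationMap("TF", {"zzz": {"NAC"}})
        table = top_hub_tfs(k, gs, tf, part)
        assert table.empty

    def test_n_top_validated(self):
        part, k, gs = self._setup()
        with pytest.raises(ValueError):
            top_hub_tfs(k, gs, AnnotationMap("TF", {}), part, n_top=0)


def test_t_transform_p_matches_permutation_null():
    rng = np.random.default_rng(22)
    n, n_perm = 21, 1000
    for _ in range(5):
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n) + 0.3 * x
        r, p = _cor_test(x, y)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = (np.sum(np.abs(null) >= abs(r)) + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < max(3 * se, 0.01) + 1 / n_perm
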