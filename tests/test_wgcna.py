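"""Network construction, TOM, module detection, eigengenes, hubs."""

import numpy as np
import pandas as pd
import pytest

import coexreg as cr
from coexreg.wgcna import GREY, ModuleAssignment, scale_free_fit


def expr_from_profiles(profiles, prefix="g"):
    return pd.DataFrame(
        profiles,
        index=[f"{prefix}{i:03d}" for i in range(1, len(profiles) + 1)],
        columns=[f"s{i}" for i in range(1, len(profiles[0]) + 1)],
    )


def brute_force_tom(a):
    """Independent double-loop evaluation of the TOM formula."""
    n = a.shape[0]
    k = a.sum(axis=1) - 1.0
    tom = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


class TestSignedAdjacency:
    def test_extremes_of_the_correlation(self):
        x = np.linspace(0, 1, 6)
        expr = expr_from_profiles([x, 2 * x + 1, -x])
        adj = cr.signed_adjacency(expr, power=12)
        assert adj.iloc[0, 1] == pytest.approx(1.0)
        assert adj.iloc[0, 2] == pytest.approx(0.0)

    def test_zero_correlation_value(self):
        # orthogonal profiles: cor = 0 -> a = (1/2)^12
        expr = expr_from_profiles([[1, -1, 1, -1], [1, 1, -1, -1]])
        adj = cr.signed_adjacency(expr, power=12)
        assert adj.iloc[0, 1] == pytest.approx(0.5 ** 12)

    def test_monotone_decreasing_in_power(self):
        rng = np.random.default_rng(0)
        expr = expr_from_profiles(rng.normal(size=(10, 8)).tolist())
        a6 = cr.signed_adjacency(expr, 6).to_numpy()
        a12 = cr.signed_adjacency(expr, 12).to_numpy()
        off = ~np.eye(10, dtype=bool)
        assert (a12[off] <= a6[off] + 1e-12).all()

    def test_zero_variance_gene_warns_and_maps_to_half_power(self):
        expr = expr_from_profiles([[1, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.warns(UserWarning, match="zero-variance"):
            adj = cr.signed_adjacency(expr, power=2)
        assert adj.iloc[0, 1] == pytest.approx(0.25)


class TestSoftThreshold:
    def test_fit_discriminates_structure_from_noise(self):
        """Heterogeneous co-expression modules give a markedly better
        scale-free fit than unstructured expression."""
        cfg = cr.SyntheticConfig(
            n_genes=280, n_samples=12, n_modules=5,
            module_sizes=[120, 60, 30, 15, 8], noise_gene_fraction=47 / 280,
            stage_association={}, seed=2,
        )
        counts, _ = cr.generate_count_matrix(cfg)
        filtered, _ = cr.filter_low_counts(counts)
        expr = cr.vst_transform(filtered, cr.estimate_size_factors(filtered))
        structured = cr.pick_soft_threshold(expr)

        rng = np.random.default_rng(0)
        noise = expr_from_profiles(rng.normal(size=(280, 12)).tolist())
        with pytest.warns(UserWarning):
            unstructured = cr.pick_soft_threshold(noise)
        assert max(structured.r_squared) > max(unstructured.r_squared) + 0.3
        assert structured.chosen_power in structured.powers

    def test_zero_target_picks_smallest_power(self, default_expr):
        expr, _ = default_expr
        result = cr.pick_soft_threshold(expr, powers=(3, 6, 9), r2_target=0.0)
        assert result.chosen_power == 3

    def test_single_candidate_below_target_warns(self):
        rng = np.random.default_rng(0)
        expr = expr_from_profiles(rng.normal(size=(30, 6)).tolist())
        with pytest.warns(UserWarning, match="R\\^2"):
            result = cr.pick_soft_threshold(expr, powers=(2,), r2_target=0.999)
        assert result.chosen_power == 2
        assert not result.target_met


class TestTOM:
    def test_unweighted_triangle_is_fully_overlapping(self):
        a = np.ones((3, 3))
        adj = pd.DataFrame(a, index=list("abc"), columns=list("abc"))
        tom = cr.tom_similarity(adj)
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_isolated_pair_zero(self):
        a = np.eye(4)
        adj = pd.DataFrame(a, index=list("abcd"), columns=list("abcd"))
        tom = cr.tom_similarity(adj)
        assert tom.iloc[0, 1] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        names = [f"g{i}" for i in range(n)]
        tom = cr.tom_similarity(pd.DataFrame(a, index=names, columns=names))
        expected = brute_force_tom(a)
        np.testing.assert_allclose(tom.to_numpy(), np.clip(expected, 0, 1), atol=1e-12)

    def test_range_and_symmetry(self, default_expr):
        expr, _ = default_expr
        tom = cr.tom_similarity(cr.signed_adjacency(expr, 12)).to_numpy()
        assert ((tom >= 0) & (tom <= 1)).all()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)


class TestModuleDetection:
    def test_two_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        z1, z2 = rng.normal(size=(2, 12))
        block = lambda z: [
            np.sqrt(0.9) * z + np.sqrt(0.1) * rng.normal(size=12) for _ in range(50)
        ]
        expr = expr_from_profiles(block(z1) + block(z2))
        tom = cr.tom_similarity(cr.signed_adjacency(expr, 12))
        assignment = cr.detect_modules(1 - tom, min_module_size=30)
        truth = ["A"] * 50 + ["B"] * 50
        assert len(assignment.modules) == 2
        assert adjusted_rand_score(truth, assignment.labels.tolist()) == 1.0

    def test_min_module_size_one_leaves_nothing_grey(self):
        rng = np.random.default_rng(1)
        expr = expr_from_profiles(rng.normal(size=(20, 6)).tolist())
        tom = cr.tom_similarity(cr.signed_adjacency(expr, 6))
        assignment = cr.detect_modules(1 - tom, min_module_size=1)
        refined = cr.refine_modules(expr, assignment)
        assert (refined.labels != GREY).all()

    def test_fewer_genes_than_floor_all_grey(self):
        rng = np.random.default_rng(2)
        expr = expr_from_profiles(rng.normal(size=(5, 6)).tolist())
        tom = cr.tom_similarity(cr.signed_adjacency(expr, 6))
        with pytest.warns(UserWarning, match="grey"):
            assignment = cr.detect_modules(1 - tom, min_module_size=30)
        assert (assignment.labels == GREY).all()

    def test_largest_module_named_turquoise(self, default_expr):
        expr, _ = default_expr
        tom = cr.tom_similarity(cr.signed_adjacency(expr, 12))
        assignment = cr.detect_modules(1 - tom, 30)
        sizes = assignment.sizes()
        non_grey = {m: s for m, s in sizes.items() if m != GREY}
        assert non_grey["turquoise"] == max(non_grey.values())


class TestEigengenes:
    def test_identical_profiles_give_perfect_correlation(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        expr = expr_from_profiles([profile * c for c in (1, 2, 3)] * 10)
        labels = pd.Series("blue", index=expr.index)
        me = cr.module_eigengenes(expr, ModuleAssignment(labels, 1))
        r = np.corrcoef(me.loc["blue"], profile)[0, 1]
        assert r == pytest.approx(1.0)

    def test_single_gene_module_is_zscore(self):
        profile = np.array([1.0, 4.0, 2.0, 3.0])
        expr = expr_from_profiles([profile])
        labels = pd.Series("m", index=expr.index)
        me = cr.module_eigengenes(expr, ModuleAssignment(labels, 1))
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(me.loc["m"].to_numpy(), z, atol=1e-12)

    def test_unit_variance_and_orientation(self, default_expr):
        expr, _ = default_expr
        tom = cr.tom_similarity(cr.signed_adjacency(expr, 12))
        assignment = cr.refine_modules(expr, cr.detect_modules(1 - tom, 30))
        me = cr.module_eigengenes(expr, assignment)
        for module in me.index:
            vec = me.loc[module]
            assert vec.std(ddof=1) == pytest.approx(1.0)
            members = assignment.members(module)
            mean_profile = expr.loc[members].mean(axis=0)
            assert np.corrcoef(vec, mean_profile)[0, 1] >= 0

    def test_recovers_planted_latent_factor(self, default_expr):
        expr, truth = default_expr
        tom = cr.tom_similarity(cr.signed_adjacency(expr, 12))
        assignment = cr.refine_modules(expr, cr.detect_modules(1 - tom, 30))
        me = cr.module_eigengenes(expr, assignment)
        planted = truth.latent_factors.loc["module_1"]
        members = {g for g, m in truth.gene_module.items() if m == "module_1"}
        detected = (
            assignment.labels.loc[assignment.labels.index.isin(members)].mode().iloc[0]
        )
        r = abs(np.corrcoef(me.loc[detected], planted)[0, 1])
        assert r >= 0.9


class TestMergeCloseModules:
    def test_split_planted_module_remerges(self, default_expr):
        expr, truth = default_expr
        members = [g for g, m in truth.gene_module.items() if m == "module_1"]
        members = [g for g in members if g in expr.index]
        labels = pd.Series(GREY, index=expr.index)
        labels[members[: len(members) // 2]] = "half_a"
        labels[members[len(members) // 2:]] = "half_b"
        merged = cr.merge_close_modules(expr, ModuleAssignment(labels, 10), 0.25)
        assert len(merged.modules) == 1

    def test_zero_cut_is_identity(self, default_expr):
        expr, truth = default_expr
        labels = pd.Series(
            [truth.gene_module[g] for g in expr.index], index=expr.index
        ).replace("none", GREY)
        merged = cr.merge_close_modules(expr, ModuleAssignment(labels, 30), 0.0)
        assert merged.labels.equals(labels)

    def test_distinct_planted_factors_not_merged(self, default_expr):
        expr, truth = default_expr
        labels = pd.Series(
            [truth.gene_module[g] for g in expr.index], index=expr.index
        ).replace("none", GREY)
        merged = cr.merge_close_modules(expr, ModuleAssignment(labels, 30), 0.25)
        assert len(merged.modules) == 4


class TestModuleTraitCorrelation:
    def test_indicator_equal_eigengene(self):
        ind = np.array([1, 1, 0, 0, 0, 0], dtype=float)
        me = pd.DataFrame([ind], index=["m"], columns=[f"s{i}" for i in range(6)])
        traits = pd.DataFrame({"egg": ind}, index=me.columns)
        r, p = cr.module_trait_correlation(me, traits)
        assert r.loc["m", "egg"] == pytest.approx(1.0)
        assert p.loc["m", "egg"] == pytest.approx(0.0)

    def test_orthogonal_gives_zero(self):
        me = pd.DataFrame(
            [[1, -1, 1, -1]], index=["m"], columns=[f"s{i}" for i in range(4)]
        )
        traits = pd.DataFrame({"t": [1, 1, 0, 0]}, index=me.columns)
        r, p = cr.module_trait_correlation(me, traits)
        assert r.loc["m", "t"] == pytest.approx(0.0)
        assert p.loc["m", "t"] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        me = pd.DataFrame([[1, 2]], index=["m"], columns=["a", "b"])
        traits = pd.DataFrame({"t": [0, 1]}, index=["a", "b"])
        with pytest.raises(ValueError, match="3 samples"):
            cr.module_trait_correlation(me, traits)


class TestKeyModuleSelection:
    def test_positive_and_significant_only(self):
        r = pd.DataFrame({"larva3": [0.9, -0.8, 0.2]}, index=["a", "b", "c"])
        p = pd.DataFrame({"larva3": [0.001, 0.001, 0.6]}, index=["a", "b", "c"])
        assert cr.select_key_modules(r, p, "larva3") == ["a"]

    def test_alpha_one_keeps_all_positive(self):
        r = pd.DataFrame({"s": [0.3, 0.1, -0.5]}, index=["a", "b", "c"])
        p = pd.DataFrame({"s": [0.9, 0.99, 0.01]}, index=["a", "b", "c"])
        assert cr.select_key_modules(r, p, "s", alpha=1.0) == ["a", "b"]

    def test_no_positive_modules_empty(self):
        r = pd.DataFrame({"s": [-0.3, 0.0]}, index=["a", "b"])
        p = pd.DataFrame({"s": [0.001, 0.001]}, index=["a", "b"])
        assert cr.select_key_modules(r, p, "s") == []


class TestHubGenes:
    def test_gene_equal_to_eigengene_is_hub(self, default_expr):
        expr, _ = default_expr
        tom = cr.tom_similarity(cr.signed_adjacency(expr, 12))
        assignment = cr.refine_modules(expr, cr.detect_modules(1 - tom, 30))
        me = cr.module_eigengenes(expr, assignment)
        kme = cr.module_membership(expr, me)
        hubs = cr.select_hub_genes(kme, assignment, 0.80)
        assert any(hubs.values())
        for module, genes in hubs.items():
            for g in genes:
                assert kme.loc[g, module] >= 0.80

    def test_threshold_above_one_empties_hubs(self, default_expr):
        expr, _ = default_expr
        tom = cr.tom_similarity(cr.signed_adjacency(expr, 12))
        assignment = cr.refine_modules(expr, cr.detect_modules(1 - tom, 30))
        me = cr.module_eigengenes(expr, assignment)
        kme = cr.module_membership(expr, me)
        hubs = cr.select_hub_genes(kme, assignment, 1.01)
        assert all(len(v) == 0 for v in hubs.values())

    def test_exact_threshold_is_inclusive(self):
        kme = pd.DataFrame({"m": [0.80, 0.7999999]}, index=["g1", "g2"])
        assignment = ModuleAssignment(pd.Series("m", index=["g1", "g2"]), 1)
        hubs = cr.select_hub_genes(kme, assignment, 0.80)
        assert hubs["m"] == ["g1"]


def test_scale_free_fit_on_powerlaw_degrees():
    """A power-law degree sample fits well; a uniform one fits poorly."""
    rng = np.random.default_rng(0)
    powerlaw = rng.pareto(2.0, size=2000) + 1
    uniform = rng.uniform(1, 10, size=2000)
    assert scale_free_fit(powerlaw) > scale_free_fit(uniform)
    assert scale_free_fit(powerlaw) > 0.8
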