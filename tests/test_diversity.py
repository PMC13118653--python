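import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa

from oracles import anova2_partial_eta2_brute, dispersion_f_brute, permanova_brute
from rivasm.diversity import (
    alpha_diversity,
    betadisper,
    bray_curtis,
    chao1,
    faith_pd,
    pcoa,
    permanova,
    rarefaction_curve,
    shannon,
    spearman_trend,
    two_way_anova_partial_eta2,
)
from rivasm.tables import CommunityTable, tss_normalize
from rivasm.trees import tree_from_newick


class TestAlphaIndices:
    @pytest.mark.parametrize(
        "vec, expected",
        [
            ([0.25, 0.25, 0.25, 0.25], math.log(4)),
            ([1.0], 0.0),
            ([0.5, 0.5, 0.0], math.log(2)),
        ],
    )
    def test_shannon(self, vec, expected):
        assert shannon(vec) == pytest.approx(expected, abs=1e-9)

    def test_shannon_all_zero_raises(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([1, 1, 2, 2, 3], 6.0),       # S + F1^2/(2 F2)
            ([5, 3, 2], 3.0),              # no singletons -> S
            ([1, 1, 1], 6.0),              # bias-corrected branch (F2 = 0)
        ],
    )
    def test_chao1(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    def test_chao1_never_below_observed(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 6, size=30)
            if counts.sum() == 0:
                continue
            assert chao1(counts) >= (counts > 0).sum()

    def test_chao1_rejects_fractions(self):
        with pytest.raises(ValueError):
            chao1([1.5, 2.0])

    @pytest.mark.parametrize(
        "present, expected",
        [([1, 1, 0], 3.0), ([1, 1, 1], 5.0), ([0, 0, 1], 2.0)],
    )
    def test_faith_pd_hand_traced(self, toy_tree, present, expected):
        assert faith_pd(present, ["A", "B", "C"], toy_tree) == pytest.approx(expected)

    def test_faith_pd_monotone_in_taxa(self, toy_tree):
        pd_ab = faith_pd([1, 1, 0], ["A", "B", "C"], toy_tree)
        pd_abc = faith_pd([1, 1, 1], ["A", "B", "C"], toy_tree)
        assert pd_abc >= pd_ab

    def test_faith_pd_missing_taxon_errors(self, toy_tree):
        with pytest.raises(ValueError):
            faith_pd([1], ["Z"], toy_tree)

    def test_alpha_table(self, toy_tree):
        t = CommunityTable(np.array([[4, 1], [4, 0], [0, 1]]), ["A", "B", "C"], ["s1", "s2"])
        out = alpha_diversity(t, toy_tree)
        assert out.loc["s1", "shannon"] == pytest.approx(math.log(2))
        assert out.loc["s1", "faith_pd"] == pytest.approx(3.0)
        assert out.loc["s2", "faith_pd"] == pytest.approx(4.0)


class TestRarefactionCurve:
    def test_depth_at_library_size_recovers_observed_richness(self):
        t = CommunityTable(np.array([[50], [50]]), ["A", "B"], ["s"])
        out = rarefaction_curve(t, [100], reps=0)
        assert out["mean_richness"].iloc[0] == pytest.approx(2.0)

    def test_depth_one_gives_one(self):
        t = CommunityTable(np.array([[50], [50]]), ["A", "B"], ["s"])
        out = rarefaction_curve(t, [1], reps=0)
        assert out["mean_richness"].iloc[0] == pytest.approx(1.0)

    def test_empirical_matches_hypergeometric_expectation(self):
        from scipy.stats import hypergeom

        t = CommunityTable(np.array([[50], [50]]), ["A", "B"], ["s"])
        analytic = rarefaction_curve(t, [10], reps=0)["mean_richness"].iloc[0]
        expected = 2 * (1 - hypergeom(100, 50, 10).pmf(0))
        assert analytic == pytest.approx(expected, abs=1e-9)
        empirical = rarefaction_curve(t, [10], reps=500, seed=1)["mean_richness"].iloc[0]
        se = 2 * hypergeom(100, 50, 10).pmf(0) * (1 - hypergeom(100, 50, 10).pmf(0)) / 500
        assert abs(empirical - expected) < 3 * math.sqrt(se) + 0.05

    def test_empty_depths_error(self, toy_table):
        with pytest.raises(ValueError):
            rarefaction_curve(toy_table, [])


class TestBrayCurtis:
    def test_hand_values(self):
        rel = pd.DataFrame({"x": [0.4, 0.6], "y": [0.2, 0.8]}, index=["A", "B"])
        d = bray_curtis(rel)
        assert d["x", "y"] == pytest.approx(0.2)

    def test_identical_zero_disjoint_one(self):
        rel = pd.DataFrame(
            {"a": [1.0, 0.0], "b": [1.0, 0.0], "c": [0.0, 1.0]}, index=["A", "B"]
        )
        d = bray_curtis(rel)
        assert d["a", "b"] == pytest.approx(0.0)
        assert d["a", "c"] == pytest.approx(1.0)

    def test_bounds_and_symmetry_random(self):
        rng = np.random.default_rng(0)
        rel = pd.DataFrame(rng.dirichlet(np.ones(20), size=8).T)
        rel.columns = [str(c) for c in rel.columns]
        d = np.asarray(bray_curtis(rel).data)
        assert ((d >= 0) & (d <= 1)).all()
        assert np.allclose(d, d.T)


class TestPcoa:
    def test_two_point_geometry(self):
        d = DistanceMatrix(np.array([[0, 0.6], [0.6, 0]]), ids=["a", "b"])
        res = pcoa(d)
        coords = np.abs(res.coordinates.iloc[:, 0].to_numpy())
        np.testing.assert_allclose(coords, [0.3, 0.3], atol=1e-9)

    def test_equilateral_triple_two_equal_eigenvalues(self):
        m = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(m, ids=list("abc")))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-9)

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [str(i) for i in range(10)]
        res = pcoa(DistanceMatrix(d, ids=ids))
        rec = res.coordinates.to_numpy()
        d2 = np.sqrt(((rec[:, None, :] - rec[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d, d2, atol=1e-8)

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(2)
        rel = pd.DataFrame(rng.dirichlet(np.ones(15), size=8).T)
        rel.columns = [str(c) for c in rel.columns]
        d = bray_curtis(rel)
        ours = pcoa(d)
        ref = skbio_pcoa(d, method="eigh")
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues)[::-1][:5],
            np.sort(ref.eigvals.to_numpy())[::-1][:5],
            atol=1e-8,
        )


class TestPermanova:
    def _clustered(self):
        # two groups of 3; within-group distance 0, between-group 1
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        return DistanceMatrix(d, ids=list("abcdef")), ["g1"] * 3 + ["g2"] * 3

    def test_exhaustive_matches_brute_force(self):
        d, groups = self._clustered()
        res = permanova(d, groups, n_perm="exhaustive")
        f_b, r2_b, p_b = permanova_brute(np.asarray(d.data), groups)
        assert res.pseudo_f == pytest.approx(f_b)
        assert res.r2 == pytest.approx(r2_b)
        assert res.p_perm == pytest.approx(p_b)

    def test_agrees_with_skbio_f(self):
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(3)
        rel = pd.DataFrame(rng.dirichlet(np.ones(25), size=12).T)
        rel.columns = [str(c) for c in rel.columns]
        d = bray_curtis(rel)
        groups = ["a"] * 6 + ["b"] * 6
        ours = permanova(d, groups, n_perm=99, seed=0)
        ref = sk_permanova(d, grouping=groups, permutations=99)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_single_group_errors(self):
        d, _ = self._clustered()
        with pytest.raises(ValueError):
            permanova(d, ["g"] * 6, n_perm=9)

    def test_identical_samples_error(self):
        d = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.raises(ValueError):
            permanova(d, ["x", "x", "y", "y"], n_perm=9)

    def test_strata_confine_permutations(self):
        # group coincides with strata: stratified permutation keeps labels
        # constant within blocks -> F never changes -> p = 1
        d, groups = self._clustered()
        res = permanova(d, groups, n_perm=99, seed=0, strata=groups)
        assert res.p_perm == pytest.approx(1.0)


class TestBetadisper:
    def test_mirror_groups_have_equal_dispersion(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 2))
        mirrored = np.vstack([pts, pts + 10.0])
        d = np.sqrt(((mirrored[:, None] - mirrored[None, :]) ** 2).sum(-1))
        ids = [str(i) for i in range(10)]
        res = betadisper(DistanceMatrix(d, ids=ids), ["a"] * 5 + ["b"] * 5, n_perm=99, seed=0)
        assert res.group_means["a"] == pytest.approx(res.group_means["b"], abs=1e-9)
        assert res.f == pytest.approx(0.0, abs=1e-9)

    def test_f_matches_anova_oracle_on_distances(self):
        rng = np.random.default_rng(5)
        tight = rng.normal(scale=0.1, size=(4, 2))
        spread = rng.normal(scale=0.9, size=(4, 2)) + 5
        pts = np.vstack([tight, spread])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [str(i) for i in range(8)]
        labels = ["t"] * 4 + ["s"] * 4
        res = betadisper(DistanceMatrix(d, ids=ids), labels, n_perm=99, seed=0)
        f_oracle = dispersion_f_brute(res.distances.to_numpy(), labels)
        assert res.f == pytest.approx(f_oracle, rel=1e-9)

    def test_all_identical_errors(self):
        d = DistanceMatrix(np.zeros((6, 6)), ids=list("abcdef"))
        with pytest.raises(ValueError):
            betadisper(d, ["a"] * 3 + ["b"] * 3, n_perm=9)

    def test_singleton_group_excluded(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(7, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [str(i) for i in range(7)]
        res = betadisper(DistanceMatrix(d, ids=ids), ["a"] * 3 + ["b"] * 3 + ["c"], n_perm=9, seed=0)
        assert res.excluded == ["c"]


class TestTwoWayAnova:
    def test_pure_main_effect(self):
        a = ["x"] * 4 + ["y"] * 4
        b = ["p", "q"] * 4
        y = [1.0 if f == "x" else 2.0 for f in a]
        res = two_way_anova_partial_eta2(y, a, b)
        assert res.loc["A", "partial_eta2"] == pytest.approx(1.0)
        assert res.loc["B", "partial_eta2"] == pytest.approx(0.0, abs=1e-9)

    def test_additive_cell_means_no_interaction(self):
        a = ["x", "x", "y", "y"]
        b = ["p", "q", "p", "q"]
        y = [10.0, 10.0, 20.0, 20.0]
        res = two_way_anova_partial_eta2(y, a, b)
        assert res.loc["A:B", "sum_sq"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(7)
        a = np.repeat(["x", "y"], 12)
        b = np.tile(np.repeat(["p", "q", "r"], 4), 2)
        y = rng.normal(size=24)
        res = two_way_anova_partial_eta2(y, a, b)
        oracle = anova2_partial_eta2_brute(y, a, b)
        for term in ("A", "B", "A:B"):
            assert res.loc[term, "partial_eta2"] == pytest.approx(oracle[term], rel=1e-8)

    def test_single_level_factor_errors(self):
        with pytest.raises(ValueError):
            two_way_anova_partial_eta2([1, 2], ["a", "a"], ["p", "q"])


class TestSpearman:
    def test_monotone_extremes(self):
        up = spearman_trend([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        down = spearman_trend([5, 4, 3, 2, 1], [1, 2, 3, 4, 5])
        assert up["rho"] == pytest.approx(1.0)
        assert down["rho"] == pytest.approx(-1.0)

    def test_hand_rank_arithmetic(self):
        res = spearman_trend([3, 1, 2], [1, 2, 3])
        assert res["rho"] == pytest.approx(-0.5)

    def test_exact_p_matches_enumeration_for_perfect_trend(self):
        res = spearman_trend([1, 2, 3, 4], [1, 2, 3, 4])
        # P(rho >= 1 or <= -1) over 4! permutations = 2/24
        assert res["p"] == pytest.approx(2 / 24)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            spearman_trend([1.0, 1.0, 1.0], [1, 2, 3])
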