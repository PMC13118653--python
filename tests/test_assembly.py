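import numpy as np
import pandas as pd
import pytest

from rivasm import assembly
from rivasm.assembly import (
    beta_mntd,
    beta_nti,
    null_assemble,
    partition_processes,
    rc_bray,
    summarize_fractions,
)
from rivasm.tables import CommunityTable
from rivasm.trees import patristic_matrix, tree_from_newick


@pytest.fixture
def toy_pdm(toy_tree):
    return patristic_matrix(toy_tree, ["A", "B", "C"])


class TestBetaMntd:
    def test_identical_communities_zero(self, toy_pdm):
        assert beta_mntd([0.5, 0.5, 0], [0.5, 0.5, 0], toy_pdm) == pytest.approx(0.0)

    def test_single_taxon_reduces_to_patristic(self, toy_pdm):
        assert beta_mntd([1, 0, 0], [0, 0, 1], toy_pdm) == pytest.approx(4.0)

    def test_hand_arithmetic(self, toy_pdm):
        # {A:0.5, B:0.5} vs {C:1}: 0.5*[0.5*4 + 0.5*4 + 1*4] = 4
        assert beta_mntd([0.5, 0.5, 0], [0, 0, 1], toy_pdm) == pytest.approx(4.0)

    def test_empty_community_errors(self, toy_pdm):
        with pytest.raises(ValueError):
            beta_mntd([0, 0, 0], [1, 0, 0], toy_pdm)


def random_table(rng, tree, n_samples=8, lib=500, conc=20.0):
    otus = [t.name for t in tree.tips()]
    pool = rng.dirichlet(np.ones(len(otus)))
    cols = [rng.multinomial(lib, rng.dirichlet(conc * pool + 1e-6)) for _ in range(n_samples)]
    return CommunityTable(np.column_stack(cols), otus, [f"s{i}" for i in range(n_samples)])


class TestBetaNti:
    def test_relabel_invariance(self):
        from rivasm.simulate import simulate_tree

        rng = np.random.default_rng(0)
        tree = simulate_tree(30, seed=1)
        table = random_table(rng, tree)
        base = beta_nti(table, tree, n_null=99, seed=5)
        # permute the OTU registry (rows move together with their labels)
        perm = rng.permutation(table.n_otus)
        shuffled = CommunityTable(
            table.counts[perm], [table.otu_ids[i] for i in perm], table.sample_ids
        )
        again = beta_nti(shuffled, tree, n_null=99, seed=5)
        pd.testing.assert_frame_equal(base, again)

    def test_identical_communities_degenerate_and_near_identical_negative(self):
        # shared taxa keep zero nearest-taxon distance under every tip
        # shuffle, so exactly identical communities have a zero-variance
        # null (NaN); a single-taxon membership difference restores a
        # negative standardized score
        from rivasm.simulate import simulate_tree

        tree = simulate_tree(40, seed=2)
        otus = [t.name for t in tree.tips()]
        col = np.zeros(40, dtype=int)
        col[:8] = [10, 8, 6, 5, 4, 3, 2, 1]
        table = CommunityTable(np.column_stack([col, col]), otus, ["a", "b"])
        res = beta_nti(table, tree, n_null=99, seed=1)
        assert res["beta_mntd_obs"].iloc[0] == pytest.approx(0.0)
        assert np.isnan(res["beta_nti"].iloc[0])

        col2 = col.copy()
        col2[8] = 3  # one extra taxon in community b
        near = CommunityTable(np.column_stack([col, col2]), otus, ["a", "b"])
        res2 = beta_nti(near, tree, n_null=99, seed=1)
        assert res2["beta_nti"].iloc[0] < 0

    def test_star_tree_yields_na_with_reason(self):
        star = tree_from_newick("(A:1,B:1,C:1,D:1);")
        table = CommunityTable(
            np.array([[5, 0], [5, 0], [0, 5], [0, 5]]), ["A", "B", "C", "D"], ["x", "y"]
        )
        res = beta_nti(table, star, n_null=99, seed=0)
        assert np.isnan(res["beta_nti"].iloc[0])
        assert res["note"].iloc[0] == "zero null variance"

    def test_deterministic_and_pair_order_independent(self):
        from rivasm.simulate import simulate_tree

        rng = np.random.default_rng(3)
        tree = simulate_tree(25, seed=3)
        table = random_table(rng, tree, n_samples=5)
        full = beta_nti(table, tree, n_null=99, seed=9)
        pair = [("s3", "s1")]
        sub = beta_nti(table, tree, pair_set=pair, n_null=99, seed=9)
        row = full[(full.sample_i == "s3") & (full.sample_j == "s1")]
        if row.empty:
            row = full[(full.sample_i == "s1") & (full.sample_j == "s3")]
        assert sub["beta_nti"].iloc[0] == pytest.approx(row["beta_nti"].iloc[0])

    def test_requires_enough_nulls(self):
        star = tree_from_newick("(A:1,B:1,C:1);")
        table = CommunityTable(np.eye(3, dtype=int), ["A", "B", "C"], ["x", "y", "z"])
        with pytest.raises(ValueError):
            beta_nti(table, star, n_null=10)


class TestRcBray:
    def test_identical_communities_approach_minus_one(self):
        rng = np.random.default_rng(0)
        n = 40
        col = rng.multinomial(800, rng.dirichlet(np.ones(n)))
        other = rng.multinomial(800, rng.dirichlet(np.ones(n)))
        counts = np.column_stack([col, col, other])
        table = CommunityTable(counts, [f"o{i}" for i in range(n)], ["a", "b", "c"])
        res = rc_bray(table, pair_set=[("a", "b")], n_null=199, seed=1)
        assert res["rc_bray"].iloc[0] < -0.9

    def test_bounds_and_determinism(self):
        rng = np.random.default_rng(1)
        n = 30
        cols = [rng.multinomial(500, rng.dirichlet(np.ones(n))) for _ in range(6)]
        table = CommunityTable(np.column_stack(cols), [f"o{i}" for i in range(n)],
                               [f"s{i}" for i in range(6)])
        r1 = rc_bray(table, n_null=99, seed=7)
        assert r1["rc_bray"].between(-1, 1).all()
        # evaluating a single pair reproduces the full-run value exactly
        single = rc_bray(table, pair_set=[("s4", "s2")], n_null=99, seed=7)
        row = r1[(r1.sample_i == "s2") & (r1.sample_j == "s4")]
        assert single["rc_bray"].iloc[0] == pytest.approx(row["rc_bray"].iloc[0])

    def test_null_assemble_preserves_richness_and_total(self):
        rng = np.random.default_rng(2)
        w_occ = rng.integers(1, 10, 50).astype(float)
        w_ab = rng.integers(1, 100, 50).astype(float)
        draws = null_assemble(rng, richness=12, total=300, w_occ=w_occ, w_ab=w_ab, n_draws=25)
        assert ((draws > 0).sum(axis=1) == 12).all()
        assert (draws.sum(axis=1) == 300).all()

    def test_single_otu_metacommunity_errors(self):
        table = CommunityTable(np.array([[5, 5]]), ["only"], ["a", "b"])
        with pytest.raises(ValueError):
            rc_bray(table, n_null=99)


class TestPartition:
    @pytest.mark.parametrize(
        "z, rc, expected",
        [
            (2.5, 0.99, "heterogeneous_selection"),
            (-2.5, 0.0, "homogeneous_selection"),
            (0.5, 0.97, "dispersal_limitation"),
            (0.5, -0.97, "homogenizing_dispersal"),
            (0.5, 0.2, "undominated"),
            (2.0, 0.99, "dispersal_limitation"),   # boundary: |z| must exceed t
        ],
    )
    def test_decision_rule(self, z, rc, expected):
        calls = pd.DataFrame({"beta_nti": [z], "rc_bray": [rc]})
        out = partition_processes(calls)
        assert out["process"].iloc[0] == expected

    def test_na_propagates(self):
        calls = pd.DataFrame({"beta_nti": [np.nan], "rc_bray": [0.5]})
        out = partition_processes(calls)
        assert pd.isna(out["process"].iloc[0])

    def test_fraction_counting(self):
        calls = pd.DataFrame(
            {
                "beta_nti": [0.0, 0.0, 0.0, -3.0],
                "rc_bray": [0.99, 0.99, 0.0, 0.0],
            }
        )
        out = summarize_fractions(partition_processes(calls))
        assert out.fractions["dispersal_limitation"] == pytest.approx(0.5)
        assert out.fractions["undominated"] == pytest.approx(0.25)
        assert out.fractions["homogeneous_selection"] == pytest.approx(0.25)
        assert out.stochastic == pytest.approx(0.75)
        assert out.fractions.sum() == pytest.approx(1.0)

    def test_all_na_errors(self):
        calls = pd.DataFrame({"beta_nti": [np.nan], "rc_bray": [np.nan]})
        with pytest.raises(ValueError):
            summarize_fractions(partition_processes(calls))


def test_selection_raises_homogeneous_fraction_monotonically():
    """Strong conserved selection under a shared environment should push the
    homogeneous-selection fraction above the no-selection control, growing
    with selection strength."""
    import math

    from rivasm.simulate import preset, simulate_survey
    from rivasm.trees import prune_to_table

    fractions = []
    for sigma in (float("inf"), 0.8, 0.35):
        cfg = preset(
            "selection",
            n_taxa=800,
            n_replicates=2,
            pool_sdlog=1.5,
            lib_meanlog=math.log(1500.0),
            lib_min=800,
            seed=11,
        )
        for season in cfg.seasons:
            cfg.sigma_sel[season] = sigma
        sim = simulate_survey(cfg)
        table = sim["table"].drop_empty_otus()
        tree = prune_to_table(sim["tree"], table)
        meta = sim["metadata"]
        sm = meta[meta["season"] == "winter"]
        sub = table.select_samples(list(sm["sample_id"]))
        res = beta_nti(sub, tree, n_null=199, seed=4)
        fractions.append((res["beta_nti"] < -2).mean())
    assert fractions[2] > fractions[0]
    assert fractions[2] >= fractions[1] >= fractions[0]
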