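"""Null-model core: betaMNTD, betaNTI, RC_bray and process classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from assemblage.assembly import (
    PROCESSES,
    beta_mntd,
    beta_nti,
    classify_pair,
    classify_processes,
    cophenetic_distances,
    niche_optima,
    phylogenetic_signal_correlogram,
    raup_crick_bray,
)
from assemblage.core import OtuTable, Phylogeny, SampleMetadata

from conftest import random_table, tree_for_table


def brute_force_bmntd(counts, dist, weighted=True):
    """Independent double-loop betaMNTD oracle."""
    n, t = counts.shape
    out = np.zeros((n, n))
    for k in range(n):
        for m in range(n):
            if k == m:
                continue
            pk = np.flatnonzero(counts[k])
            pm = np.flatnonzero(counts[m])
            if weighted:
                fk = counts[k, pk] / counts[k].sum()
                fm = counts[m, pm] / counts[m].sum()
            else:
                fk = np.full(len(pk), 1 / len(pk))
                fm = np.full(len(pm), 1 / len(pm))
            ak = sum(
                f * min(dist[i, j] for j in pm) for f, i in zip(fk, pk)
            )
            am = sum(
                f * min(dist[j, i] for i in pk) for f, j in zip(fm, pm)
            )
            out[k, m] = 0.5 * (ak + am)
    return out


class TestCophenetic:
    def test_two_and_three_tip_path_sums(self):
        dm = cophenetic_distances(Phylogeny.from_newick("(A:1,B:1);"))
        assert dm["A", "B"] == pytest.approx(2.0)
        dm3 = cophenetic_distances(Phylogeny.from_newick("((A:1,B:1):1,C:2);"))
        assert dm3["A", "C"] == pytest.approx(4.0)
        assert dm3["A", "B"] == pytest.approx(2.0)
        assert dm3["A", "A"] == 0.0


class TestNicheOptima:
    def test_weighted_mean_and_range_bound(self):
        table = OtuTable(
            pd.DataFrame(
                [[10, 5], [0, 5]], index=["s1", "s2"], columns=["A", "B"]
            )
        )
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "latitude": [0.0, 0.0],
                    "longitude": [0.0, 1.0],
                    "temperature": [5.0, 15.0],
                },
                index=["s1", "s2"],
            )
        )
        opt = niche_optima(table, meta, ["temperature"])
        assert opt.loc["A", "temperature"] == pytest.approx(5.0)
        assert opt.loc["B", "temperature"] == pytest.approx(10.0)  # midpoint
        assert (opt["temperature"] >= 5.0).all() and (opt["temperature"] <= 15.0).all()


class TestBetaMntd:
    def test_hand_cases(self):
        tree = Phylogeny.from_newick("((A:1,B:3):1,C:1);")
        dm = cophenetic_distances(tree)
        assert dm["A", "C"] == pytest.approx(3.0)
        # k={A}, m={B}: 0.5*(d+d) = d(A,B) = 4
        table = OtuTable(
            pd.DataFrame(
                [[5, 0, 0], [0, 5, 0], [1, 1, 0], [0, 0, 3]],
                index=["a_only", "b_only", "ab", "c_only"],
                columns=["A", "B", "C"],
            )
        )
        b = beta_mntd(table, dm)
        assert b["a_only", "b_only"] == pytest.approx(4.0)
        # k={A,B} equal weights vs m={C}: 0.5*[(0.5*3 + 0.5*5) + 3] = 3.5
        assert b["ab", "c_only"] == pytest.approx(0.5 * ((0.5 * 3 + 0.5 * 5) + 3))

    def test_identical_communities_score_zero(self):
        table = random_table(3, 10, seed=1)
        dup = OtuTable(
            pd.concat([table.data, table.data.iloc[[0]].set_axis(["copy"])])
        )
        tree = tree_for_table(table, seed=2)
        b = beta_mntd(dup, tree)
        assert b["S0", "copy"] == 0.0

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, weighted):
        table = random_table(5, 12, seed=8, depth=200)
        tree = tree_for_table(table, seed=4)
        dm = cophenetic_distances(tree)
        ours = beta_mntd(table, dm, weighted=weighted)
        dist = np.asarray(dm.filter(table.otu_ids).data)
        expected = brute_force_bmntd(table.counts, dist, weighted)
        assert np.allclose(np.asarray(ours.filter(table.sample_ids).data), expected)


class TestBetaNti:
    def test_star_phylogeny_null_is_degenerate(self, caplog):
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")
        table = OtuTable(
            pd.DataFrame(
                [[1, 1, 0, 0], [0, 0, 1, 1]],
                index=["s1", "s2"],
                columns=list("ABCD"),
            )
        )
        with caplog.at_level("WARNING"):
            res = beta_nti(table, star, n_null=99, seed=1)
        assert np.isnan(res.pairs["bnti"]).all()
        assert "undefined" in caplog.text

    def test_deterministic_and_branch_scale_invariant(self):
        table = random_table(4, 10, seed=5, depth=100)
        tree = tree_for_table(table, seed=6)
        a = beta_nti(table, tree, n_null=199, seed=9)
        b = beta_nti(table, tree, n_null=199, seed=9)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)
        dm = cophenetic_distances(tree)
        import skbio

        scaled = skbio.DistanceMatrix(dm.data * 10.0, ids=list(dm.ids))
        c = beta_nti(table, scaled, n_null=199, seed=9)
        assert np.allclose(a.pairs["bnti"], c.pairs["bnti"], equal_nan=True)

    def test_sampled_null_matches_exhaustive_enumeration(self):
        """4-taxon instance: compare with the all-permutations null."""
        tree = Phylogeny.from_newick("((A:1,B:2):1,(C:1.5,D:0.5):2);")
        dm = cophenetic_distances(tree)
        dist = np.asarray(dm.filter(list("ABCD")).data)
        counts = np.array([[5, 3, 0, 0], [0, 1, 4, 2], [2, 0, 0, 6]])
        table = OtuTable(
            pd.DataFrame(counts, index=["s1", "s2", "s3"], columns=list("ABCD"))
        )
        obs = brute_force_bmntd(counts, dist)
        exhaustive = np.array(
            [
                brute_force_bmntd(counts, dist[np.ix_(p, p)])
                for p in itertools.permutations(range(4))
            ]
        )
        mean, sd = exhaustive.mean(axis=0), exhaustive.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore"):  # diagonal is 0/0, never used
            z_exact = (obs - mean) / sd
        res = beta_nti(table, dm, n_null=999, seed=13)
        for _, row in res.pairs.iterrows():
            i = table.sample_ids.index(row["sample_a"])
            j = table.sample_ids.index(row["sample_b"])
            se = np.sqrt(1 / 999 + z_exact[i, j] ** 2 / (2 * 998))
            assert row["bnti"] == pytest.approx(z_exact[i, j], abs=3 * se + 0.05)


class TestRaupCrick:
    def test_bounds_and_symmetric_pair_order(self):
        table = random_table(6, 30, seed=3)
        rc = raup_crick_bray(table, n_null=99, seed=7)
        assert rc["rc_bray"].between(-1, 1).all()
        # each unordered pair appears exactly once
        pairs = set(map(tuple, rc[["sample_a", "sample_b"]].to_numpy()))
        assert len(pairs) == 15

    def test_identical_pair_in_diverse_metacommunity_is_negative(self):
        rng = np.random.default_rng(11)
        base = rng.multinomial(500, rng.dirichlet(np.full(60, 0.2)), size=8)
        base[1] = base[0]  # two identical samples
        table = OtuTable(
            pd.DataFrame(
                base,
                index=[f"s{i}" for i in range(8)],
                columns=[f"o{i}" for i in range(60)],
            )
        )
        rc = raup_crick_bray(table, n_null=199, seed=5)
        row = rc[(rc["sample_a"] == "s0") & (rc["sample_b"] == "s1")]
        assert float(row["rc_bray"].iloc[0]) <= -0.9


class TestClassification:
    @pytest.mark.parametrize(
        "bnti, rc, expected",
        [
            (2.5, 0.0, "heterogeneous_selection"),
            (-2.5, 0.0, "homogeneous_selection"),
            (0.5, 0.97, "dispersal_limitation"),
            (0.5, -0.99, "homogenizing_dispersal"),
            (0.5, 0.30, "drift"),
            (2.0, 0.99, "dispersal_limitation"),  # boundary: not > 2
            (-2.0, -0.99, "homogenizing_dispersal"),
            (0.0, 0.95, "drift"),  # boundary: not > 0.95
            (0.0, -0.95, "drift"),
            (float("nan"), 0.0, "undefined"),
        ],
    )
    def test_decision_table(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    def test_fractions_sum_to_one_and_undefined_excluded(self):
        rng = np.random.default_rng(2)
        pairs = pd.DataFrame(
            {
                "bnti": np.concatenate([rng.normal(0, 3, 200), [np.nan] * 5]),
                "rc_bray": np.concatenate(
                    [rng.uniform(-1, 1, 200), rng.uniform(-1, 1, 5)]
                ),
            }
        )
        labeled, fractions = classify_processes(pairs)
        assert sum(fractions.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert fractions.n_undefined == 5
        assert fractions.n_pairs == 200
        assert set(labeled["process"]) <= set(PROCESSES) | {"undefined"}
        stochastic = (
            fractions.fractions["dispersal_limitation"]
            + fractions.fractions["homogenizing_dispersal"]
            + fractions.fractions["drift"]
        )
        assert fractions.stochasticity_ratio == pytest.approx(stochastic)


class TestPhylogeneticSignal:
    def test_perfect_signal_detected_in_first_class(self):
        from assemblage.simulate import evolve_niche_optima, simulate_phylogeny

        tree = simulate_phylogeny(80, seed=3)
        optima = evolve_niche_optima(tree, sigma_bm=5.0, root_value=0.0, seed=4)
        dm = cophenetic_distances(tree)
        result = phylogenetic_signal_correlogram(
            optima.to_frame("opt"), dm, n_classes=6, n_permutations=199, seed=5
        )
        first_tested = result[result["tested"]].iloc[0]
        assert first_tested["mantel_r"] > 0
        assert first_tested["significant"]

    def test_classes_are_ordered_and_bounded(self):
        from assemblage.simulate import simulate_phylogeny

        tree = simulate_phylogeny(40, seed=9)
        rng = np.random.default_rng(1)
        optima = pd.DataFrame(
            {"opt": rng.normal(size=40)},
            index=[f"OTU_{i + 1}" for i in range(40)],
        )
        res = phylogenetic_signal_correlogram(
            optima, cophenetic_distances(tree), 5, 99, seed=2
        )
        assert (res["lower"].to_numpy()[1:] >= res["upper"].to_numpy()[:-1] - 1e-12).all()
        tested = res[res["tested"]]
        assert tested["mantel_r"].abs().max() <= 1.0
        assert (tested["p_value"] >= 1 / 100).all()
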