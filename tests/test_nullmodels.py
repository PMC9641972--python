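"""Tests for betaMNTD / betaNTI / RC-Bray and the process classification.

Oracles used here:
* a brute-force double-loop betaMNTD implementation;
* exhaustive enumeration of all tip-label permutations for the betaNTI null
  on small trees;
* R's picante::comdistnt as an independent cross-implementation check.
"""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from ecoassembly import (
    OtuTable,
    assembly_partition,
    beta_mntd,
    beta_mntd_matrix,
    bnti_matrix,
    bnti_pair,
    classify_pair,
    cophenetic_distances,
    partition_processes,
    rc_bray_matrix,
    rc_bray_pair,
    simulate_metacommunity,
    simulate_neutral_samples,
    simulate_phylogeny,
)


def brute_force_beta_mntd(com1, com2, D, weighted=True):
    """Literal double-loop evaluation of the betaMNTD definition."""
    p1 = np.flatnonzero(com1)
    p2 = np.flatnonzero(com2)
    if weighted:
        f1 = com1 / com1.sum()
        f2 = com2 / com2.sum()
    else:
        f1 = (com1 > 0) / len(p1)
        f2 = (com2 > 0) / len(p2)
    s1 = sum(f1[i] * min(D[i, j] for j in p2) for i in p1)
    s2 = sum(f2[j] * min(D[j, i] for i in p1) for j in p2)
    return 0.5 * (s1 + s2)


class TestBetaMntd:
    def test_shared_taxon_set_gives_zero(self, balanced_tree):
        D = cophenetic_distances(balanced_tree).data
        com1 = np.array([3.0, 1.0, 0.0, 2.0])
        com2 = np.array([1.0, 5.0, 0.0, 9.0])
        assert beta_mntd(com1, com2, D) == pytest.approx(0.0)

    def test_single_taxon_pair_is_tree_distance(self, balanced_tree):
        dm = cophenetic_distances(balanced_tree)
        D = dm.data
        a = dm.ids.index("A")
        c = dm.ids.index("C")
        com1 = np.zeros(4)
        com1[a] = 5
        com2 = np.zeros(4)
        com2[c] = 2
        assert beta_mntd(com1, com2, D) == pytest.approx(dm["A", "C"])
        assert dm["A", "C"] == pytest.approx(4.0)

    def test_symmetry_and_empty_community_error(self, balanced_tree):
        D = cophenetic_distances(balanced_tree).data
        r = np.random.default_rng(0)
        com1 = r.integers(0, 5, 4).astype(float)
        com1[0] += 1
        com2 = r.integers(0, 5, 4).astype(float)
        com2[1] += 1
        assert beta_mntd(com1, com2, D) == pytest.approx(beta_mntd(com2, com1, D))
        with pytest.raises(ValueError):
            beta_mntd(np.zeros(4), com2, D)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_on_random_fixtures(self, weighted):
        tree = simulate_phylogeny(10, seed=1)
        dm = cophenetic_distances(tree)
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 6, size=(10, 5))
        counts[rng.integers(0, 10, 5), np.arange(5)] += 1
        table = OtuTable(list(dm.ids), [f"s{j}" for j in range(5)], counts)
        mat = beta_mntd_matrix(table, dm, weighted=weighted)
        for a in range(5):
            for b in range(a + 1, 5):
                expect = brute_force_beta_mntd(
                    counts[:, a].astype(float), counts[:, b].astype(float),
                    dm.data, weighted,
                )
                assert mat.iloc[a, b] == pytest.approx(expect)


class TestBnti:
    def test_star_phylogeny_is_degenerate(self):
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        res = bnti_pair([1, 1, 0, 0], [0, 0, 1, 1], D, n_null=99, seed=0)
        assert res.degenerate and np.isnan(res.bnti)

    def test_identical_communities_never_exceed_null(self):
        tree = simulate_phylogeny(12, seed=3)
        dm = cophenetic_distances(tree)
        com = np.zeros(12, dtype=int)
        com[[0, 3, 5]] = [4, 2, 1]
        res = bnti_pair(com, com, dm.data, n_null=199, seed=1)
        assert res.beta_mntd_obs == pytest.approx(0.0)
        assert res.null_mean >= 0.0

    def test_invariant_to_branch_length_scaling(self):
        tree = simulate_phylogeny(15, seed=4)
        scaled = tree.copy()
        for n in scaled.traverse(include_self=False):
            n.length *= 7.5
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 4, size=(15, 2))
        counts[[0, 1], [0, 1]] += 1
        table = OtuTable(
            [t.name for t in tree.tips()], ["x", "y"], counts
        )
        r1 = bnti_matrix(table, cophenetic_distances(tree), n_null=199, seed=9)[0]
        r2 = bnti_matrix(table, cophenetic_distances(scaled), n_null=199, seed=9)[0]
        assert r1.bnti == pytest.approx(r2.bnti, rel=1e-9)

    def test_fixed_seed_reproduces_bitwise(self):
        tree = simulate_phylogeny(10, seed=6)
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 5, size=(10, 4))
        counts[0] += 1
        table = OtuTable([t.name for t in tree.tips()],
                         [f"s{j}" for j in range(4)], counts)
        a = bnti_matrix(table, tree, n_null=99, seed=3)
        b = bnti_matrix(table, tree, n_null=99, seed=3)
        assert [(r.bnti, r.null_mean, r.null_sd) for r in a] == [
            (r.bnti, r.null_mean, r.null_sd) for r in b
        ]

    def test_sampled_null_matches_exhaustive_enumeration(self):
        """On a 6-tip tree the full 720-permutation null is enumerable; the
        999-sample z-score must sit close to the exhaustive one."""
        tree = simulate_phylogeny(6, seed=8)
        dm = cophenetic_distances(tree)
        D = dm.data
        com1 = np.array([3, 0, 1, 0, 2, 0], dtype=float)
        com2 = np.array([0, 2, 0, 4, 0, 1], dtype=float)
        obs = beta_mntd(com1, com2, D)
        nulls = []
        for perm in itertools.permutations(range(6)):
            Dp = D[np.ix_(perm, perm)]
            nulls.append(beta_mntd(com1, com2, Dp))
        z_exact = (obs - np.mean(nulls)) / np.std(nulls)
        res = bnti_pair(com1.astype(int), com2.astype(int), D, n_null=999, seed=11)
        assert res.bnti == pytest.approx(z_exact, abs=0.25)


class TestRcBray:
    def _pool(self, seed=0, n_taxa=60, n_samples=20):
        p = simulate_metacommunity(n_taxa, seed=seed)
        return simulate_neutral_samples(
            p, N=500, m=0.5, n_samples=n_samples, seed=seed + 1
        )

    def test_rc_within_bounds(self):
        pool = self._pool()
        res = rc_bray_matrix(pool.subset(samples=pool.sample_ids[:4]),
                             metacommunity=pool, n_null=99, seed=0)
        assert all(-1 <= r.rc <= 1 for r in res)

    def test_identical_samples_rc_near_minus_one(self):
        rcs = []
        for seed in range(10):
            pool = self._pool(seed=seed)
            com = pool.counts[:, 0]
            rcs.append(
                rc_bray_pair(com, com, pool, n_null=199, seed=seed).rc
            )
        assert np.mean(rcs) < -0.9

    def test_disjoint_sparse_samples_rc_near_plus_one(self):
        """Disjoint rare-taxon communities in a pool with a ubiquitous core:
        null assemblages almost surely share core taxa (BC < 1), so the
        observed disjoint pair sits above the whole null distribution."""
        rcs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            counts = np.zeros((80, 20), dtype=int)
            counts[:6, :] = rng.integers(100, 200, size=(6, 20))
            for j in range(20):
                rare = rng.choice(np.arange(6, 80), size=8, replace=False)
                counts[rare, j] = rng.integers(1, 5, size=8)
            pool = OtuTable([f"t{i}" for i in range(80)],
                            [f"s{j}" for j in range(20)], counts)
            com1 = np.zeros(80, dtype=int)
            com2 = np.zeros(80, dtype=int)
            com1[10:18] = rng.integers(5, 30, 8)
            com2[30:38] = rng.integers(5, 30, 8)
            rcs.append(rc_bray_pair(com1, com2, pool, n_null=199, seed=seed).rc)
        assert np.mean(rcs) > 0.9

    def test_richness_exceeding_pool_rejected(self):
        pool = OtuTable(["a", "b", "c"], ["s1", "s2"],
                        np.array([[1, 1], [0, 0], [0, 1]]))
        com = np.array([1, 1, 1])
        with pytest.raises(ValueError, match="richness"):
            rc_bray_pair(com, com, pool, n_null=9, seed=0)


class TestClassification:
    @pytest.mark.parametrize(
        "bnti,rc,expect",
        [
            (-3.0, 0.2, "homogeneous_selection"),
            (3.0, 0.2, "heterogeneous_selection"),
            (0.5, 0.99, "dispersal_limitation"),
            (0.5, -0.99, "homogenizing_dispersal"),
            (0.0, 0.0, "drift"),
            # boundary values fall to the stochastic / drift side
            (2.0, 0.0, "drift"),
            (-2.0, 0.0, "drift"),
            (0.0, 0.95, "drift"),
            (0.0, -0.95, "drift"),
        ],
    )
    def test_five_way_thresholds(self, bnti, rc, expect):
        assert classify_pair(bnti, rc) == expect

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(float("nan"), 0.0)

    def test_partition_all_drift(self):
        part = partition_processes([(0.0, 0.0)] * 10, group="g")
        assert part.fractions["drift"] == 1.0
        assert sum(part.fractions.values()) == pytest.approx(1.0)

    def test_partition_hand_tally(self):
        pairs = [(-3, 0), (-2.5, 0.99), (3, 0), (0, 0.99), (0, 0.97),
                 (0, -0.99), (0, 0), (1.9, 0.2)]
        part = partition_processes(pairs)
        assert part.fractions == pytest.approx(
            dict(
                homogeneous_selection=2 / 8,
                heterogeneous_selection=1 / 8,
                homogenizing_dispersal=1 / 8,
                dispersal_limitation=2 / 8,
                drift=2 / 8,
            )
        )

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            partition_processes([])


class TestAssemblyPartition:
    def test_groups_processed_independently_and_deterministically(self):
        p = simulate_metacommunity(40, seed=0)
        tree = simulate_phylogeny(40, seed=1)
        table = simulate_neutral_samples(
            p, N=400, m=0.5, n_samples=8, seed=2,
            taxa_ids=[t.name for t in tree.tips()],
        )
        groups = pd.Series(
            ["g1"] * 4 + ["g2"] * 4, index=table.sample_ids
        )
        out1 = assembly_partition(table, tree, groups, n_null=99, seed=5)
        out2 = assembly_partition(table, tree, groups, n_null=99, seed=5)
        pd.testing.assert_frame_equal(out1[0], out2[0])
        assert set(out1[1]) == {"g1", "g2"}
        for part in out1[1].values():
            assert part.n_pairs == 6
            assert sum(part.fractions.values()) == pytest.approx(1.0)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestPicanteCrossCheck:
    def test_beta_mntd_matches_picante_comdistnt(self, tmp_path):
        """Independent oracle: picante's comdistnt (abundance-weighted)."""
        tree = simulate_phylogeny(10, seed=21)
        rng = np.random.default_rng(22)
        counts = rng.integers(0, 8, size=(10, 4))
        counts[rng.integers(0, 10, 4), np.arange(4)] += 1
        table = OtuTable([t.name for t in tree.tips()],
                         [f"s{j}" for j in range(4)], counts)
        ours = beta_mntd_matrix(table, tree)
        from ecoassembly.community_data import write_newick

        write_newick(tree, tmp_path / "tree.nwk")
        comm = table.to_dataframe().T  # samples x taxa for picante
        comm.to_csv(tmp_path / "comm.csv")
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(picante))\n'
            f'setwd("{tmp_path}")\n'
            'tree <- read.tree("tree.nwk")\n'
            'tree$tip.label <- gsub("\'", "", tree$tip.label)\n'
            'comm <- as.matrix(read.csv("comm.csv", row.names=1, check.names=FALSE))\n'
            'd <- comdistnt(comm, cophenetic(tree), abundance.weighted=TRUE)\n'
            'write.csv(as.matrix(d), "out.csv")\n'
        )
        subprocess.run(
            ["Rscript", "--vanilla", str(script)], check=True,
            capture_output=True, timeout=300,
        )
        theirs = pd.read_csv(tmp_path / "out.csv", index_col=0)
        np.testing.assert_allclose(
            ours.loc[theirs.index, theirs.columns].to_numpy(),
            theirs.to_numpy(), atol=1e-8,
        )
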