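import numpy as np
import pytest

from ecoassembly import (
    SimRegime,
    brownian_traits,
    cophenetic_distances,
    generate_study_layout,
    mantel,
    simulate_clustered_phylogeny,
    simulate_dispersal_limited,
    simulate_metacommunity,
    simulate_neutral_samples,
    simulate_phylogeny,
    simulate_selected_samples,
)
from ecoassembly.community_data import tree_to_newick, write_metadata
from ecoassembly.diversity import bray_curtis
from ecoassembly.envassoc import haversine_matrix


class TestPhylogeny:
    def test_two_tips(self):
        tree = simulate_phylogeny(2, seed=0)
        assert tree.count(tips=True) == 2

    def test_same_seed_same_newick(self):
        assert tree_to_newick(simulate_phylogeny(30, seed=9)) == tree_to_newick(
            simulate_phylogeny(30, seed=9)
        )

    def test_branch_lengths_strictly_positive(self):
        tree = simulate_phylogeny(50, seed=3)
        assert all(
            n.length > 0 for n in tree.traverse(include_self=False)
        )

    def test_cophenetic_matrix_shape_and_symmetry(self):
        dm = cophenetic_distances(simulate_phylogeny(100, seed=1))
        assert dm.data.shape == (100, 100)
        np.testing.assert_allclose(dm.data, dm.data.T)

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_phylogeny(1, seed=0)

    def test_clustered_tree_crowns_tighter_than_stems(self):
        tree = simulate_clustered_phylogeny(60, cluster_size=5, seed=4)
        dm = cophenetic_distances(tree)
        ids = list(dm.ids)
        # tips are named crown by crown
        within, between = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                ca = (int(a.split("_")[1]) - 1) // 5
                cb = (int(b.split("_")[1]) - 1) // 5
                (within if ca == cb else between).append(dm[a, b])
        assert max(within) < min(between)

    def test_clustered_tree_tip_count_with_remainder(self):
        tree = simulate_clustered_phylogeny(23, cluster_size=5, seed=0)
        assert tree.count(tips=True) == 23


class TestMetacommunity:
    def test_single_taxon(self):
        np.testing.assert_allclose(simulate_metacommunity(1, seed=0), [1.0])

    def test_sums_to_one(self):
        assert simulate_metacommunity(500, seed=2).sum() == pytest.approx(
            1.0, abs=1e-12
        )

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            simulate_metacommunity(10, (0.0, -1.0), seed=0)

    def test_lognormal_dominance_structure(self):
        """With sigma=1.5 the top decile of taxa holds most of the mass."""
        shares = []
        for seed in range(20):
            p = np.sort(simulate_metacommunity(200, (0.0, 1.5), seed=seed))
            shares.append(p[-20:].sum())
        assert np.mean(shares) > 0.5


class TestNeutralSampler:
    def test_column_sums_equal_n(self):
        p = simulate_metacommunity(50, seed=1)
        t = simulate_neutral_samples(p, N=500, m=0.3, n_samples=8, seed=2)
        assert set(t.sample_totals) == {500}

    def test_m_one_reduces_to_multinomial_mean(self):
        p = simulate_metacommunity(30, (0.0, 1.0), seed=3)
        t = simulate_neutral_samples(p, N=2000, m=1.0, n_samples=100, seed=4)
        obs = t.counts.mean(axis=1) / 2000
        se = np.sqrt(p * (1 - p) / 2000 / 100)
        assert np.all(np.abs(obs - p) < 3 * se + 1e-9)

    def test_smaller_m_gives_shallower_occupancy(self):
        """Weak immigration lets taxa drift to local extinction, so the
        occurrence-frequency curve sits lower at small m."""
        p = simulate_metacommunity(200, seed=5)
        occ = {}
        for m in (0.05, 0.9):
            t = simulate_neutral_samples(p, N=1000, m=m, n_samples=60, seed=6)
            occ[m] = (t.counts > 0).mean(axis=1).mean()
        assert occ[0.05] < occ[0.9]

    def test_short_burn_in_warns_but_conserves_totals(self):
        p = simulate_metacommunity(20, seed=0)
        with pytest.warns(UserWarning, match="insufficient mixing"):
            t = simulate_neutral_samples(
                p, N=100, m=0.5, n_samples=3, burn_in=50, seed=1
            )
        assert set(t.sample_totals) == {100}

    def test_domain_errors(self):
        p = simulate_metacommunity(20, seed=0)
        with pytest.raises(ValueError):
            simulate_neutral_samples(p, N=5, m=0.5, n_samples=2, seed=0)
        with pytest.raises(ValueError):
            simulate_neutral_samples(p, N=100, m=0.0, n_samples=2, seed=0)


class TestSelectionSampler:
    def test_env_length_mismatch_rejected(self):
        tree = simulate_phylogeny(20, seed=0)
        with pytest.raises(ValueError, match="length"):
            simulate_selected_samples(
                tree, np.zeros(4), sigma=1.0, N=100, n_samples=5, seed=0
            )

    def test_large_sigma_approaches_neutral_sampling(self):
        """As the niche width grows the filter vanishes and per-taxon mean
        abundances converge to the metacommunity (total-variation sense)."""
        tree = simulate_phylogeny(40, seed=1)
        p = simulate_metacommunity(40, (0.0, 1.0), seed=2)
        tv = []
        for sigma in (0.5, 50.0):
            t = simulate_selected_samples(
                tree, np.full(30, 1.0), sigma=sigma, N=2000, seed=3,
                meta_p=p, standardize_traits=True,
            )
            # meta_p maps positionally onto tip order == t.taxa_ids order
            mean_rel = t.counts.mean(axis=1) / 2000
            tv.append(0.5 * np.abs(mean_rel - p).sum())
        assert tv[1] < tv[0]
        assert tv[1] < 0.05

    def test_shared_filter_raises_overlap_above_neutral(self):
        """Identical environments concentrate every sample on the same pool,
        so pairwise Jaccard overlap exceeds the neutral baseline."""
        tree = simulate_clustered_phylogeny(100, seed=4)
        p = simulate_metacommunity(100, (0.0, 1.0), seed=5)

        def mean_jaccard(table):
            pres = table.counts > 0
            vals = []
            for i in range(pres.shape[1]):
                for j in range(i + 1, pres.shape[1]):
                    inter = (pres[:, i] & pres[:, j]).sum()
                    union = (pres[:, i] | pres[:, j]).sum()
                    vals.append(inter / union)
            return np.mean(vals)

        sel = simulate_selected_samples(
            tree, np.full(10, 1.0), sigma=0.3, N=1000, seed=6,
            meta_p=p, standardize_traits=True,
        )
        neu = simulate_neutral_samples(p, N=1000, m=0.2, n_samples=10, seed=7)
        assert mean_jaccard(sel) > mean_jaccard(neu)

    def test_brownian_trait_variance_grows_with_depth(self):
        """Across seeds, tip trait dispersion scales with total tree depth
        (Brownian property: variance accrues along branches)."""
        slopes = []
        for seed in range(20):
            tree = simulate_phylogeny(30, seed=seed)
            depths, var = [], []
            for scale in (0.5, 1.0, 2.0, 4.0):
                scaled = tree.copy()
                for n in scaled.traverse(include_self=False):
                    n.length *= scale
                tr = np.array(list(brownian_traits(scaled, seed=seed).values()))
                depths.append(scale)
                var.append(tr.var())
            slopes.append(np.polyfit(depths, var, 1)[0])
        assert np.mean(np.array(slopes) > 0) > 0.9


class TestDispersalSampler:
    def _coords(self, n, rng):
        return np.column_stack(
            [rng.uniform(37.0, 40.0, n), rng.uniform(118.0, 122.0, n)]
        )

    def test_column_sums_and_site_count(self, rng):
        p = simulate_metacommunity(80, seed=0)
        t = simulate_dispersal_limited(p, self._coords(10, rng), 50.0, 800, seed=1)
        assert t.n_samples == 10
        assert set(t.sample_totals) == {800}

    def test_fewer_than_two_sites_rejected(self):
        p = simulate_metacommunity(10, seed=0)
        with pytest.raises(ValueError):
            simulate_dispersal_limited(p, np.array([[38.0, 119.0]]), 50.0, 100)

    def test_distance_decay_appears_at_small_scale_only(self, rng):
        """Small decay scales produce a positive Bray-Curtis/geography Mantel
        correlation; a near-infinite scale collapses all sites to one pool."""
        p = simulate_metacommunity(150, seed=2)
        r_small, p_small, r_big = [], [], []
        for seed in range(10):
            coords = self._coords(12, np.random.default_rng(100 + seed))
            geo = haversine_matrix(coords, ids=[f"S{i + 1:03d}" for i in range(12)])
            t1 = simulate_dispersal_limited(p, coords, 150.0, 2000, seed=seed)
            m1 = mantel(bray_curtis(t1), geo, n_perm=199, seed=seed)
            r_small.append(m1.r)
            p_small.append(m1.p_value)
            t2 = simulate_dispersal_limited(p, coords, 1e7, 2000, seed=seed)
            r_big.append(mantel(bray_curtis(t2), geo, n_perm=199, seed=seed).r)
        assert np.median(r_small) > 0.3
        assert np.median(p_small) <= 0.05
        assert abs(np.median(r_big)) < 0.2


class TestStudyLayout:
    def test_layout_shape_and_groups(self):
        table, tree, meta = generate_study_layout(seed=1, n_taxa=100, N=500)
        assert table.n_samples == 75
        groups = meta.groups()
        assert set(groups) == {"Sur_FL", "Sur_PA", "Bot_FL", "Bot_PA", "Sed"}
        assert all((groups == g).sum() == 15 for g in set(groups))
        assert {t.name for t in tree.tips()} == set(table.taxa_ids)

    def test_layout_deterministic_bytes(self, tmp_path):
        out = []
        for run in range(2):
            table, tree, meta = generate_study_layout(seed=7, n_taxa=60, N=300)
            mpath = tmp_path / f"meta{run}.csv"
            write_metadata(meta, mpath)
            out.append(
                (table.counts.tobytes(), tree_to_newick(tree), mpath.read_bytes())
            )
        assert out[0] == out[1]

    def test_sediment_has_no_water_column_covariates(self):
        _, _, meta = generate_study_layout(seed=2, n_taxa=60, N=300)
        env = meta.frame.loc[meta.groups() == "Sed", meta.env_columns]
        assert env.isna().all().all()
        env_w = meta.frame.loc[meta.groups() != "Sed", meta.env_columns]
        assert env_w.notna().all().all()


class TestSimRegime:
    def test_invalid_kind_and_params(self):
        with pytest.raises(ValueError):
            SimRegime("bogus")
        with pytest.raises(ValueError):
            SimRegime("neutral", params={"m": 0.0})
        with pytest.raises(ValueError):
            SimRegime("homogeneous_selection", params={"sigma": -1})
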