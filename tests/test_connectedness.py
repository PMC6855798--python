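import numpy as np
import pandas as pd
import pytest

from taskconn.connectedness import (apply_cutoff, cluster_cutoff_from_sizes,
                                    global_connectedness,
                                    permutation_cluster_cutoff, permute_design,
                                    threshold_and_label, voxelwise_lme, StatMap)
from taskconn.lme import THREEWAY_TERM
from taskconn.synthetic import (EffectSpec, block_community_map, make_design,
                                simulate_voxel_dataset)


def brute_force_connectedness(flat):
    n = flat.shape[1]
    out = np.zeros(n)
    for i in range(n):
        rs = [np.corrcoef(flat[:, i], flat[:, j])[0, 1]
              for j in range(n) if j != i]
        out[i] = np.arctanh(np.clip(np.mean(rs), -1 + 1e-7, 1 - 1e-7))
    return out


class TestGlobalConnectedness:
    def test_matches_brute_force_double_loop(self, rng):
        data = rng.standard_normal((40, 5, 5, 6))
        mask = rng.random((5, 5, 6)) < 0.8  # ~120 voxels
        vol, eff = global_connectedness(data, mask)
        flat = data.reshape(40, -1)[:, eff.ravel()]
        assert np.allclose(vol[eff], brute_force_connectedness(flat),
                           atol=1e-8)

    def test_identical_series_saturate(self):
        base = np.sin(np.arange(20.0))
        data = np.tile(base[:, None, None, None], (1, 2, 2, 2))
        vol, eff = global_connectedness(data, np.ones((2, 2, 2), bool))
        assert np.allclose(vol[eff], np.arctanh(1 - 1e-7))

    def test_three_voxel_hand_example(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([4.0, 3, 2, 1])
        c = np.array([1.0, 3, 2, 4])
        data = np.stack([a, b, c], axis=1).reshape(4, 3, 1, 1)
        vol, _ = global_connectedness(data, np.ones((3, 1, 1), bool))
        r_ac = np.corrcoef(a, c)[0, 1]
        assert r_ac == pytest.approx(0.8)
        # clamping applies to the mean correlation, not each pair, so the
        # perfectly anticorrelated pair contributes exactly -1
        expected = np.arctanh((-1.0 + 0.8) / 2)
        assert vol[0, 0, 0] == pytest.approx(expected, abs=1e-9)

    def test_appending_noise_voxel_lowers_mean_correlation(self, rng):
        drops = 0
        for s in range(100):
            r = np.random.default_rng(s)
            shared = r.standard_normal(30)
            data = shared[:, None] * 0.8 + 0.6 * r.standard_normal((30, 4))
            with_noise = np.column_stack([data, r.standard_normal(30)])
            v_small, _ = global_connectedness(
                data.reshape(30, 4, 1, 1), np.ones((4, 1, 1), bool))
            v_big, _ = global_connectedness(
                with_noise.reshape(30, 5, 1, 1), np.ones((5, 1, 1), bool))
            if np.tanh(v_big[:4]).mean() < np.tanh(v_small).mean():
                drops += 1
        assert drops >= 95

    def test_zero_variance_voxel_removed_with_warning(self, rng):
        data = rng.standard_normal((30, 2, 2, 1))
        data[:, 0, 0, 0] = 5.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            vol, eff = global_connectedness(data, np.ones((2, 2, 1), bool))
        assert not eff[0, 0, 0]
        assert np.isnan(vol[0, 0, 0])


def _null_voxel_study(seed, n_per_group=4, grid=(8, 8, 8), n_time=40):
    effects = EffectSpec(delta_3way=0.0, delta_task=0.0)
    cmap = block_community_map(grid, 1)
    design = make_design(n_per_group, seed=seed)
    vols, mask, scans = simulate_voxel_dataset(design, grid, cmap, effects,
                                               n_time, seed=seed + 1)
    maps = []
    for v in vols:
        m, mask = global_connectedness(v, mask)
        maps.append(m)
    return maps, mask, scans


class TestVoxelwiseLME:
    def test_identical_maps_give_zero_t_unit_p(self):
        maps, mask, scans = _null_voxel_study(3)
        same = [maps[0]] * len(scans)
        sm = voxelwise_lme(same, scans.drop(columns="tsnr"), mask)
        assert np.allclose(sm.tstat[mask], 0.0)
        assert np.allclose(sm.p[mask], 1.0)

    def test_fast_backend_close_to_mixedlm(self):
        maps, mask, scans = _null_voxel_study(5, grid=(8, 8, 8))
        small_mask = np.zeros_like(mask)
        small_mask[:2, :2, :2] = True
        fast = voxelwise_lme(maps, scans, small_mask, backend="ols_within")
        slow = voxelwise_lme(maps, scans, small_mask, backend="mixedlm")
        # same fixed-effect point estimates; t statistics agree closely
        assert np.allclose(fast.beta[small_mask], slow.beta[small_mask],
                           atol=5e-3)
        assert np.corrcoef(fast.tstat[small_mask],
                           slow.tstat[small_mask])[0, 1] > 0.99

    def test_effect_planted_in_community_peaks_inside_it(self):
        hits = 0
        n_runs = 15
        grid = (12, 12, 12)
        cmap = block_community_map(grid, 2)
        effects = EffectSpec(delta_3way=1.2, delta_task=0.0, subject_sd=0.0,
                             noise_sd=0.02)
        for s in range(n_runs):
            design = make_design(8, seed=s)
            vols, mask, scans = simulate_voxel_dataset(
                design, grid, cmap, effects, 80, seed=1000 + s,
                planted_communities=[1])
            maps = []
            for v in vols:
                m, mask = global_connectedness(v, mask)
                maps.append(m)
            sm = voxelwise_lme(maps, scans, mask)
            peak = np.unravel_index(np.nanargmax(np.abs(
                np.nan_to_num(sm.tstat))), grid)
            if cmap[peak] == 1:
                hits += 1
        assert hits >= int(0.9 * n_runs)


class TestClustering:
    def _statmap(self, pvol, tvol=None):
        mask = np.ones(pvol.shape, bool)
        t = tvol if tvol is not None else np.where(pvol < 0.05, 3.0, 0.0)
        return StatMap(beta=t * 0.1, tstat=t, p=pvol, mask=mask,
                       term=THREEWAY_TERM)

    def test_single_voxel_cluster(self):
        p = np.ones((4, 4, 4))
        p[1, 1, 1] = 0.01
        cs = threshold_and_label(self._statmap(p))
        assert cs.n_clusters == 1
        assert cs.table["size"].iloc[0] == 1

    def test_corner_touch_splits_under_6_connectivity(self):
        p = np.ones((4, 4, 4))
        p[0, 0, 0] = p[1, 1, 1] = 0.01
        assert threshold_and_label(self._statmap(p), connectivity=6).n_clusters == 2
        assert threshold_and_label(self._statmap(p), connectivity=26).n_clusters == 1

    def test_component_count_matches_flood_fill_oracle(self, rng):
        p = np.where(rng.random((10, 10, 10)) < 0.25, 0.01, 0.9)
        cs = threshold_and_label(self._statmap(p))
        supra = p < 0.05
        # brute-force BFS flood fill with face adjacency
        seen = np.zeros_like(supra)
        count = 0
        for start in np.argwhere(supra):
            if seen[tuple(start)]:
                continue
            count += 1
            stack = [tuple(start)]
            seen[tuple(start)] = True
            while stack:
                x, y, z = stack.pop()
                for dx, dy, dz in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if 0 <= nx < 10 and 0 <= ny < 10 and 0 <= nz < 10 \
                            and supra[nx, ny, nz] and not seen[nx, ny, nz]:
                        seen[nx, ny, nz] = True
                        stack.append((nx, ny, nz))
        assert cs.n_clusters == count
        assert cs.table["size"].sum() == supra.sum()

    def test_no_suprathreshold_voxels_is_empty_not_error(self):
        cs = threshold_and_label(self._statmap(np.ones((3, 3, 3))))
        assert cs.n_clusters == 0

    def test_apply_cutoff_boundary(self):
        # sizes (40, 37) at cutoff 38: only the 40-voxel cluster survives
        p = np.ones((20, 10, 10))
        p[0:2, 0:4, 0:5] = 0.01   # 40 voxels
        p[10:11, 2:9, 3:8] = 0.01  # 35 voxels... make exactly 37
        p[10, 2:9, 3:8] = 0.9
        p[10, 0:4, 0:9] = 0.01  # 36
        p[10, 4, 0] = 0.01      # 37
        cs = threshold_and_label(self._statmap(p))
        assert sorted(cs.sizes.tolist()) == [37, 40]
        survived = apply_cutoff(cs, 38)
        assert survived.sizes.tolist() == [40]
        assert apply_cutoff(cs, 1).n_clusters == cs.n_clusters
        assert apply_cutoff(cs, 100).n_clusters == 0


class TestPermutationNull:
    def test_cutoff_boundaries_and_monotonicity(self, rng):
        sizes = rng.integers(0, 50, size=500)
        assert cluster_cutoff_from_sizes(sizes, alpha=1.0) == 1
        c05 = cluster_cutoff_from_sizes(sizes, alpha=0.05)
        c01 = cluster_cutoff_from_sizes(sizes, alpha=0.01)
        assert c01 >= c05
        # definition check: smallest k with exceedance <= alpha
        assert np.mean(sizes >= c05) <= 0.05
        assert np.mean(sizes >= c05 - 1) > 0.05

    def test_permute_design_preserves_structure(self, rng):
        scans = make_design(4, seed=0)
        scans["tsnr"] = np.arange(len(scans), dtype=float)
        out = permute_design(scans, np.random.default_rng(3))
        # each subject still has all four cells and its tsnr values
        assert out.groupby("subject").apply(
            lambda s: set(zip(s["condition"], s["task"])) ==
            {("stim", "retrieval"), ("stim", "rest"),
             ("sham", "retrieval"), ("sham", "rest")},
            include_groups=False).all()
        assert (out.groupby("subject")["group"].nunique() == 1).all()
        assert sorted(out.groupby("subject")["group"].first()) == \
            sorted(scans.groupby("subject")["group"].first())
        assert np.array_equal(out["tsnr"], scans["tsnr"])

    def test_fixed_seed_reproduces_cutoff(self):
        maps, mask, scans = _null_voxel_study(9)
        a = permutation_cluster_cutoff(maps, scans, mask, n_permutations=100,
                                       seed=5)
        b = permutation_cluster_cutoff(maps, scans, mask, n_permutations=100,
                                       seed=5)
        assert a.cutoff == b.cutoff
        assert np.array_equal(a.max_sizes[THREEWAY_TERM],
                              b.max_sizes[THREEWAY_TERM])

    def test_too_few_permutations_rejected(self):
        maps, mask, scans = _null_voxel_study(11)
        with pytest.raises(ValueError, match="permutations"):
            permutation_cluster_cutoff(maps, scans, mask, n_permutations=10)

    def test_padding_outside_mask_leaves_cutoff_unchanged(self):
        maps, mask, scans = _null_voxel_study(13)
        padded_maps = [np.pad(m, 2, constant_values=np.nan) for m in maps]
        padded_mask = np.pad(mask, 2, constant_values=False)
        a = permutation_cluster_cutoff(maps, scans, mask, n_permutations=100,
                                       seed=7)
        b = permutation_cluster_cutoff(padded_maps, scans, padded_mask,
                                       n_permutations=100, seed=7)
        assert a.cutoff == b.cutoff
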