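import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from taskconn.connectedness import ClusterSet, StatMap, threshold_and_label
from taskconn.drivers import (classify_allegiance, driver_inference,
                              overlap_fraction, seed_driver_map, yates_chi2)
from taskconn.experiments import atlas_from_communities
from taskconn.synthetic import (EffectSpec, block_community_map, make_design,
                                simulate_voxel_dataset)


def make_clusters(label_volume):
    ids = [int(i) for i in np.unique(label_volume) if i]
    table = pd.DataFrame({"id": ids,
                          "size": [int((label_volume == i).sum()) for i in ids]})
    return ClusterSet(labels=label_volume, table=table, p_threshold=0.05,
                      connectivity=6)


class TestSeedDriverMap:
    def test_seed_voxel_self_correlation_saturates(self, rng):
        data = rng.standard_normal((30, 4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        vol = seed_driver_map(data, np.array([[1, 1, 1]]), mask)
        assert vol[1, 1, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_matches_per_voxel_correlation_oracle(self, rng):
        data = rng.standard_normal((40, 5, 5, 4))
        mask = rng.random((5, 5, 4)) < 0.9
        seed_vox = np.array([[0, 0, 0], [1, 2, 3]])
        mask[0, 0, 0] = mask[1, 2, 3] = True
        vol = seed_driver_map(data, seed_vox, mask)
        seed = data[:, seed_vox[:, 0], seed_vox[:, 1], seed_vox[:, 2]].mean(axis=1)
        for idx in np.argwhere(mask)[:20]:
            r = np.corrcoef(seed, data[:, idx[0], idx[1], idx[2]])[0, 1]
            assert vol[tuple(idx)] == pytest.approx(np.arctanh(r), abs=1e-10)

    def test_negating_seed_negates_correlations(self, rng):
        data = rng.standard_normal((30, 3, 3, 3))
        mask = np.ones((3, 3, 3), bool)
        vox = np.array([[0, 0, 0]])
        pos = seed_driver_map(data, vox, mask)
        flipped = data.copy()
        flipped[:, 0, 0, 0] *= -1
        neg = seed_driver_map(flipped, vox, mask)
        other = mask.copy()
        other[0, 0, 0] = False
        assert np.allclose(np.tanh(pos[other]), -np.tanh(neg[other]), atol=1e-10)

    def test_zero_variance_seed_rejected(self):
        data = np.ones((20, 2, 2, 2))
        with pytest.raises(ValueError, match="zero-variance"):
            seed_driver_map(data, np.array([[0, 0, 0]]),
                            np.ones((2, 2, 2), bool))


class TestDriverInference:
    def test_extent_boundary_keeps_only_20(self):
        p = np.ones((30, 8, 8))
        p[0, 0:4, 0:5] = 1e-5   # 20 voxels
        p[15, 0:19, 0] = 1e-5   # 19 voxels
        sm = StatMap(beta=np.where(p < 0.001, 1.0, 0.0),
                     tstat=np.where(p < 0.001, 5.0, 0.0), p=p,
                     mask=np.ones_like(p, bool), term="condition:task:group")
        clusters = threshold_and_label(sm, p_two_tailed=0.001)
        from taskconn.connectedness import apply_cutoff
        survived = apply_cutoff(clusters, 20)
        assert survived.sizes.tolist() == [20]

    def test_null_maps_rarely_yield_drivers(self):
        # p<0.001 with 20-voxel extent on pure-noise maps
        effects = EffectSpec(delta_3way=0.0, delta_task=0.0)
        cmap = block_community_map((10, 10, 10), 1)
        survivors = 0
        n_runs = 25
        for s in range(n_runs):
            design = make_design(4, seed=s)
            vols, mask, scans = simulate_voxel_dataset(
                design, (10, 10, 10), cmap, effects, 40, seed=500 + s)
            maps = [seed_driver_map(v, np.array([[0, 0, 0]]), mask)
                    for v in vols]
            clusters = driver_inference(maps, scans, mask)
            survivors += clusters.n_clusters > 0
        assert survivors <= max(2, int(0.1 * n_runs))


class TestAllegiance:
    def _setup(self):
        grid = (12, 12, 12)
        cmap = block_community_map(grid, 2)
        atlas = atlas_from_communities(cmap, {1: "PMN", 2: "ATN"},
                                       radius_mm=2.0)
        return grid, cmap, atlas

    def test_cluster_inside_pmn_sphere(self):
        grid, cmap, atlas = self._setup()
        labels = np.where(cmap == 1, 1, 0)
        out = classify_allegiance(make_clusters(labels), atlas,
                                  np.zeros(grid, int))
        assert out["label"].tolist() == ["PMN"]

    def test_apriori_spheres_take_precedence_over_reference(self):
        grid, cmap, atlas = self._setup()
        # cluster overlapping a few ATN-sphere voxels and many reference
        from taskconn.roi import sphere_voxels
        atn = atlas.regions[atlas.regions["network"] == "ATN"].iloc[0]
        atn_vox = sphere_voxels([atn["x_mm"], atn["y_mm"], atn["z_mm"]],
                                atn["radius_mm"], grid)
        labels = np.zeros(grid, int)
        for v in atn_vox[:3]:
            labels[tuple(v)] = 1
        reference = np.zeros(grid, int)
        free = np.argwhere((cmap == 0))
        for v in free[:10]:
            labels[tuple(v)] = 1
            reference[tuple(v)] = 7
        out = classify_allegiance(make_clusters(labels), atlas, reference)
        assert out["label"].tolist() == ["ATN"]

    def test_zero_overlap_unassigned_and_reference_fallback(self):
        grid, cmap, atlas = self._setup()
        labels = np.zeros(grid, int)
        labels[11, 11, 11] = 1
        out = classify_allegiance(make_clusters(labels), atlas,
                                  np.zeros(grid, int))
        assert out["label"].tolist() == ["unassigned"]
        reference = np.zeros(grid, int)
        reference[11, 11, 11] = 3
        out = classify_allegiance(make_clusters(labels), atlas, reference,
                                  reference_legend={3: "visual"})
        assert out["label"].tolist() == ["visual"]

    def test_space_mismatch_rejected(self):
        grid, cmap, atlas = self._setup()
        labels = np.zeros(grid, int)
        with pytest.raises(ValueError, match="space"):
            classify_allegiance(make_clusters(labels), atlas,
                                np.zeros((5, 5, 5), int))


class TestOverlapFraction:
    def test_full_and_disjoint_references(self):
        labels = np.zeros((6, 6, 6), int)
        labels[0, 0, 0] = 1
        labels[3, 3, 3] = 2
        clusters = make_clusters(labels)
        assert overlap_fraction(clusters, labels > 0) == 1.0
        assert overlap_fraction(clusters, np.zeros((6, 6, 6), bool)) == 0.0

    def test_three_of_four(self):
        labels = np.zeros((8, 8, 8), int)
        for i, x in enumerate([0, 2, 4, 6], start=1):
            labels[x, 0, 0] = i
        reference = np.zeros((8, 8, 8), bool)
        reference[[0, 2, 4], 0, 0] = True
        assert overlap_fraction(make_clusters(labels), reference) == 0.75

    def test_empty_clusterset_undefined(self):
        clusters = make_clusters(np.zeros((4, 4, 4), int))
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert overlap_fraction(clusters, np.ones((4, 4, 4), bool)) is None


class TestYatesChi2:
    def test_published_allegiance_table(self):
        stat, df, p = yates_chi2([[31, 5], [12, 13]])
        assert stat == pytest.approx(8.56, abs=0.01)
        assert df == 1
        assert p == pytest.approx(0.003, abs=0.001)

    def test_balanced_table_is_zero(self):
        stat, _, p = yates_chi2([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == 1.0

    def test_diagonal_table(self):
        stat, _, _ = yates_chi2([[10, 0], [0, 10]])
        assert stat == pytest.approx(16.2)

    def test_matches_scipy_continuity_correction(self, rng):
        for _ in range(20):
            table = rng.integers(1, 40, size=(2, 2))
            stat, _, p = yates_chi2(table)
            ref = chi2_contingency(table, correction=True)
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_transpose_and_swap_invariance(self):
        table = np.array([[31, 5], [12, 13]])
        base = yates_chi2(table)[0]
        assert yates_chi2(table.T)[0] == pytest.approx(base)
        assert yates_chi2(table[::-1, ::-1])[0] == pytest.approx(base)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            yates_chi2([[0, 0], [5, 5]])
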