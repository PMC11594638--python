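import numpy as np
import pytest

from pvsmap.image import RegionAtlas
from pvsmap.segment import (
    SegmentationParams,
    apply_exclusions,
    calibrate_threshold,
    cluster_filter,
    combine_vesselness,
    segment_pvs,
    threshold_map,
)
from pvsmap.vesselness import VesselnessMap


def vmap(values):
    return VesselnessMap(np.asarray(values, dtype=float),
                         np.zeros(np.shape(values)), (0.9, 0.9, 0.9))


def flood_fill_label(mask, connectivity):
    """Brute-force connected components by BFS, the labeling oracle."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            p = stack.pop()
            for off in offsets:
                q = tuple(np.add(p, off))
                if any(c < 0 or c >= s for c, s in zip(q, mask.shape)):
                    continue
                if mask[q] and not labels[q]:
                    labels[q] = current
                    stack.append(q)
    return labels, current


class TestCombine:
    def test_empty_wmh_is_identity(self):
        rng = np.random.default_rng(0)
        v1 = vmap(rng.uniform(size=(6, 6, 6)))
        v2 = vmap(rng.uniform(size=(6, 6, 6)))
        out = combine_vesselness(v1, v2, np.zeros((6, 6, 6), dtype=bool))
        assert np.array_equal(out, v1.values)

    def test_min_rule_kills_single_sequence_response(self):
        v1 = vmap(np.full((4, 4, 4), 0.8))
        v2 = vmap(np.zeros((4, 4, 4)))
        wmh = np.ones((4, 4, 4), dtype=bool)
        out = combine_vesselness(v1, v2, wmh)
        assert np.all(out == 0.0)

    def test_combined_dominated_by_t2_inside_wmh(self):
        rng = np.random.default_rng(1)
        v1 = vmap(rng.uniform(size=(6, 6, 6)))
        v2 = vmap(rng.uniform(size=(6, 6, 6)))
        wmh = rng.uniform(size=(6, 6, 6)) > 0.5
        out = combine_vesselness(v1, v2, wmh)
        assert np.all(out[wmh] <= v1.values[wmh] + 1e-15)
        assert np.array_equal(out[~wmh], v1.values[~wmh])

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            combine_vesselness(vmap(np.zeros((4, 4, 4))), vmap(np.zeros((5, 5, 5))),
                               np.zeros((4, 4, 4), dtype=bool))


@pytest.fixture
def tiny_atlas():
    labels = np.zeros((8, 8, 8), dtype=np.int16)
    labels[1:7, 1:7, 1:4] = 1   # WM
    labels[1:7, 1:7, 4:6] = 2   # BG
    labels[1:7, 1:7, 6:7] = 3   # BS
    icv = np.zeros((8, 8, 8), dtype=bool)
    icv[1:7, 1:7, 1:7] = True
    return RegionAtlas(labels, icv, (0.9, 0.9, 0.9))


class TestThreshold:
    def test_threshold_one_gives_empty_mask(self, tiny_atlas, noiseless_phantom):
        p = noiseless_phantom
        params = SegmentationParams(threshold_nawm=0.999999, threshold_wmh=0.999999)
        mask, _ = threshold_map(p["v_t2"].values, p["atlas"],
                                np.zeros(p["atlas"].shape, dtype=bool), params)
        assert not mask.any()

    def test_threshold_to_zero_approaches_support(self, noiseless_phantom):
        p = noiseless_phantom
        params = SegmentationParams(threshold_nawm=1e-12, threshold_wmh=1e-12)
        mask, _ = threshold_map(p["v_t2"].values, p["atlas"],
                                np.zeros(p["atlas"].shape, dtype=bool), params)
        support = (p["v_t2"].values >= 1e-12) & p["atlas"].icv_mask
        assert np.array_equal(mask, support)

    def test_lowering_threshold_monotone(self, tiny_atlas):
        rng = np.random.default_rng(2)
        v = rng.uniform(size=(8, 8, 8))
        wmh = np.zeros((8, 8, 8), dtype=bool)
        m_hi, _ = threshold_map(v, tiny_atlas, wmh, SegmentationParams(threshold_nawm=0.6))
        m_lo, _ = threshold_map(v, tiny_atlas, wmh, SegmentationParams(threshold_nawm=0.3))
        assert not (m_hi & ~m_lo).any()

    def test_provenance_distinguishes_rules(self, tiny_atlas):
        v = np.full((8, 8, 8), 0.5)
        wmh = np.zeros((8, 8, 8), dtype=bool)
        wmh[1:7, 1:7, 2] = True
        mask, prov = threshold_map(v, tiny_atlas, wmh, SegmentationParams())
        assert set(np.unique(prov[mask])) == {1, 2}
        assert np.all(prov[mask & wmh] == 2)


class TestClusterFilter:
    def test_five_voxel_cluster_removed_six_kept(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[1, 1, 1:6] = True      # 5 voxels -> removed
        mask[8, 8, 1:7] = True      # 6 voxels -> kept
        out = cluster_filter(mask, SegmentationParams())
        assert not out.mask[1, 1, 1:6].any()
        assert out.mask[8, 8, 1:7].all()
        assert out.n_clusters == 1
        assert list(out.cluster_sizes.values()) == [6]

    def test_empty_input_empty_output(self):
        out = cluster_filter(np.zeros((5, 5, 5), dtype=bool), SegmentationParams())
        assert not out.mask.any()
        assert out.n_clusters == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labeling_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        params = SegmentationParams(min_cluster_voxels=0, connectivity=connectivity)
        for _ in range(12):
            mask = rng.uniform(size=(20, 20, 20)) > 0.8
            out = cluster_filter(mask, params)
            oracle_labels, oracle_n = flood_fill_label(mask, connectivity)
            assert out.n_clusters == oracle_n
            assert np.array_equal(out.mask, mask)
            # identical partitions up to label permutation
            pairs = set(zip(out.cluster_labels[mask], oracle_labels[mask]))
            assert len(pairs) == oracle_n

    def test_size_cutoff_against_oracle_sizes(self):
        rng = np.random.default_rng(7)
        params = SegmentationParams(min_cluster_voxels=5, connectivity=26)
        for _ in range(8):
            mask = rng.uniform(size=(20, 20, 20)) > 0.85
            out = cluster_filter(mask, params)
            oracle_labels, oracle_n = flood_fill_label(mask, 26)
            sizes = np.bincount(oracle_labels.ravel())[1:]
            expected = sum(s for s in sizes if s > 5)
            assert int(out.mask.sum()) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        mask = rng.uniform(size=(16, 16, 16)) > 0.8
        once = cluster_filter(mask, SegmentationParams())
        twice = cluster_filter(once.mask, SegmentationParams())
        assert np.array_equal(once.mask, twice.mask)


class TestExclusions:
    def test_empty_exclusions_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.uniform(size=(6, 6, 6)) > 0.5
        empty = np.zeros((6, 6, 6), dtype=bool)
        assert np.array_equal(apply_exclusions(mask, empty, empty), mask)

    def test_full_exclusion_empties_mask(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        assert not apply_exclusions(mask, np.ones((4, 4, 4), dtype=bool)).any()

    def test_no_overlap_with_exclusions(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            mask = rng.uniform(size=(8, 8, 8)) > 0.4
            lac = rng.uniform(size=(8, 8, 8)) > 0.7
            stroke = rng.uniform(size=(8, 8, 8)) > 0.8
            out = apply_exclusions(mask, lac, stroke)
            assert not (out & lac).any()
            assert not (out & stroke).any()
            assert out.sum() <= mask.sum()

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_exclusions(np.ones((4, 4, 4), dtype=bool),
                             np.ones((5, 5, 5), dtype=bool))


class TestPipelineOrder:
    def test_exclusion_before_cluster_filter(self, tiny_atlas):
        # a 7-voxel candidate cluster loses 2 voxels to a lacune, drops to 5
        # and must then be removed by the cluster filter
        v = np.zeros((8, 8, 8))
        v[2, 2, 1:4] = 0.9   # inside WM (z 1:4)
        v[2, 3, 1:4] = 0.9
        v[2, 4, 1] = 0.9
        lacune = np.zeros((8, 8, 8), dtype=bool)
        lacune[2, 2, 1] = True
        lacune[2, 3, 1] = True
        wmh = np.zeros((8, 8, 8), dtype=bool)
        out = segment_pvs(vmap(v), vmap(np.zeros((8, 8, 8))), tiny_atlas,
                          wmh, lacune, None, SegmentationParams())
        assert not out.mask.any()

    def test_segmentation_reproducible(self, noiseless_phantom):
        p = noiseless_phantom
        params = SegmentationParams(threshold_nawm=0.15, threshold_wmh=0.15)
        m1 = segment_pvs(p["v_t2"], p["v_flair"], p["atlas"], p["wmh"],
                         p["lacunes"], None, params)
        m2 = segment_pvs(p["v_t2"], p["v_flair"], p["atlas"], p["wmh"],
                         p["lacunes"], None, params)
        assert np.array_equal(m1.mask, m2.mask)
        assert m1.cluster_sizes == m2.cluster_sizes

    def test_mask_respects_invariants(self, noiseless_phantom):
        p = noiseless_phantom
        params = SegmentationParams(threshold_nawm=0.15, threshold_wmh=0.15)
        out = segment_pvs(p["v_t2"], p["v_flair"], p["atlas"], p["wmh"],
                          p["lacunes"], None, params)
        assert not (out.mask & ~p["atlas"].icv_mask).any()
        assert not (out.mask & p["lacunes"]).any()
        assert all(s > params.min_cluster_voxels for s in out.cluster_sizes.values())


class TestCalibration:
    def _subjects(self, scale_list, tiny_atlas):
        # synthetic vesselness maps whose suprathreshold volume grows with
        # a per-subject burden factor
        subs = []
        rng = np.random.default_rng(9)
        wm = tiny_atlas.region_mask("wm")
        idx = np.argwhere(wm)
        for burden in scale_list:
            v = np.zeros((8, 8, 8))
            chosen = idx[rng.permutation(len(idx))[: 6 + 8 * burden]]
            for c in chosen:
                v[tuple(c)] = 0.2 + 0.1 * burden
            subs.append(dict(
                v_t2=vmap(v), v_flair_dark=vmap(np.ones((8, 8, 8))),
                atlas=tiny_atlas,
                wmh_mask=np.zeros((8, 8, 8), dtype=bool),
                lacune_mask=np.zeros((8, 8, 8), dtype=bool),
            ))
        return subs

    def test_recovers_burden_ordering(self, tiny_atlas):
        burdens = [0, 1, 2, 3, 4, 5]
        subs = self._subjects(burdens, tiny_atlas)
        params = SegmentationParams(min_cluster_voxels=0)
        t = calibrate_threshold(subs, burdens, np.array([0.25, 0.45, 0.65]), params)
        # the chosen threshold must order fractional volumes like the scores
        from pvsmap.segment import segment_pvs as seg
        from scipy.stats import spearmanr
        p = SegmentationParams(threshold_nawm=t, threshold_wmh=t, min_cluster_voxels=0)
        fracs = []
        for s in subs:
            m = seg(s["v_t2"], s["v_flair_dark"], s["atlas"], s["wmh_mask"],
                    s["lacune_mask"], None, p)
            fracs.append(m.mask.sum())
        assert spearmanr(fracs, burdens).statistic == pytest.approx(1.0)

    def test_singleton_grid_returned_unchanged(self, tiny_atlas):
        subs = self._subjects([0, 3], tiny_atlas)
        assert calibrate_threshold(subs, [0, 3], np.array([0.42])) == 0.42

    def test_ties_break_to_higher_threshold(self, tiny_atlas):
        # both candidates below every nonzero vesselness value -> identical
        # masks -> identical correlations -> higher threshold wins
        subs = self._subjects([0, 1, 2, 3], tiny_atlas)
        params = SegmentationParams(min_cluster_voxels=0)
        t = calibrate_threshold(subs, [0, 1, 2, 3], np.array([0.05, 0.1]), params)
        assert t == 0.1

    def test_constant_scores_rejected(self, tiny_atlas):
        subs = self._subjects([1, 2], tiny_atlas)
        with pytest.raises(ValueError):
            calibrate_threshold(subs, [2, 2], np.array([0.1, 0.2]))
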