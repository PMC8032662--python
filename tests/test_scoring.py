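"""Latent calibration, modified Z-scores, aggregation, and component
filtering — each checked against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mranomaly import LatentCalibration, PatchGrid, ScoringConfig, modified_z, patch_score
from mranomaly.patches import PatchSet
from mranomaly.scoring import (
    aggregate_scores,
    calibrate,
    flag_components,
    latent_differences,
    project_voxel_scores,
    score_volume,
)


def _brute_components(flagged_anchors, stride, cross_slice=True):
    """Reference connected components by breadth-first search."""
    nodes = [tuple(a) for a in flagged_anchors]
    nodeset = set(nodes)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp, queue = [], [start]
        seen.add(start)
        while queue:
            s, r, c = queue.pop()
            comp.append((s, r, c))
            neighbors = [(s, r + stride, c), (s, r - stride, c),
                         (s, r, c + stride), (s, r, c - stride)]
            if cross_slice:
                neighbors += [(s + 1, r, c), (s - 1, r, c)]
            for nb in neighbors:
                if nb in nodeset and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(sorted(comp))
    return sorted(comps)


class TestCalibration:
    def test_median_mad_hand_example(self):
        # element with differences [1,2,3,4,100]: median 3, MAD 1
        d = np.array([[1.0], [2.0], [3.0], [4.0], [100.0]])
        med = np.median(d, axis=0)
        mad = np.median(np.abs(d - med), axis=0)
        assert med[0] == 3.0 and mad[0] == 1.0
        cal = LatentCalibration(median=med, mad=mad, n_patches_used=5)
        np.testing.assert_allclose(modified_z(np.array([100.0]), cal), [97.0])

    def test_calibrate_matches_brute_force(self, trained_tiny, rng):
        patches = PatchSet(rng.normal(0.5, 0.3, (200, 2, 15, 15)).astype(np.float32))
        cal = calibrate(trained_tiny.generator_, patches)
        d = latent_differences(trained_tiny.generator_, patches.patches)
        for i in range(cal.latent_dim):
            col = np.sort(d[:, i])
            med = (col[99] + col[100]) / 2  # textbook even-count median
            assert cal.median[i] == pytest.approx(med, rel=1e-10)
            assert cal.mad[i] == pytest.approx(
                np.median(np.abs(d[:, i] - med)), rel=1e-10
            )
        assert cal.n_patches_used == 200

    def test_degenerate_distribution_floored_to_epsilon(self):
        cal = LatentCalibration(median=np.array([2.0]), mad=np.array([0.0]),
                                n_patches_used=10, epsilon=1e-6)
        assert cal.mad[0] == 1e-6
        # identical differences score zero at the center, finite elsewhere
        assert modified_z(np.array([2.0]), cal)[0] == 0.0
        assert np.isfinite(modified_z(np.array([2.1]), cal)).all()

    def test_order_invariance(self, trained_tiny, rng):
        patches = rng.normal(0.5, 0.3, (64, 2, 15, 15)).astype(np.float32)
        perm = rng.permutation(64)
        a = calibrate(trained_tiny.generator_, PatchSet(patches))
        b = calibrate(trained_tiny.generator_, PatchSet(patches[perm]))
        np.testing.assert_allclose(a.median, b.median, atol=1e-9)
        np.testing.assert_allclose(a.mad, b.mad, atol=1e-9)


class TestModifiedZ:
    def test_center_scores_zero(self, rng):
        med = rng.standard_normal(10)
        cal = LatentCalibration(median=med, mad=np.ones(10), n_patches_used=5)
        np.testing.assert_array_equal(modified_z(med, cal), np.zeros(10))

    def test_unit_case(self):
        cal = LatentCalibration(median=np.zeros(1), mad=np.ones(1), n_patches_used=5)
        assert modified_z(np.array([3.0]), cal)[0] == 3.0

    def test_matches_brute_force_oracle(self, rng):
        cal = LatentCalibration(
            median=rng.standard_normal(20),
            mad=np.abs(rng.standard_normal(20)) + 0.1,
            n_patches_used=50,
        )
        d = rng.standard_normal((30, 20))
        scores = modified_z(d, cal)
        for i in range(30):
            for j in range(20):
                assert scores[i, j] == pytest.approx(
                    abs(d[i, j] - cal.median[j]) / cal.mad[j], rel=1e-12
                )

    def test_consistency_constant_switch(self, rng):
        cal = LatentCalibration(median=np.zeros(5), mad=np.ones(5), n_patches_used=5)
        d = rng.standard_normal(5)
        plain = modified_z(d, cal)
        scaled = modified_z(d, cal, use_consistency_constant=True)
        np.testing.assert_allclose(scaled, 0.6745 * plain)

    def test_length_mismatch_rejected(self):
        cal = LatentCalibration(median=np.zeros(5), mad=np.ones(5), n_patches_used=5)
        with pytest.raises(ValueError, match="latent_dim"):
            modified_z(np.zeros(4), cal)


class TestPatchScore:
    def test_median_of_three(self):
        assert patch_score(np.array([0.0, 1.0, 4.5])) == 1.0

    def test_constant_vector_any_percentile(self):
        for n in (10, 50, 75):
            assert patch_score(np.full(33, 2.5), ScoringConfig(percentile=n)) == 2.5

    def test_zero_vector(self):
        assert patch_score(np.zeros(100)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            patch_score(np.array([]))

    def test_aggregation_is_order_invariant(self, rng):
        elem = rng.random((5, 40))
        perm = rng.permutation(40)
        np.testing.assert_allclose(
            aggregate_scores(elem, 50), aggregate_scores(elem[:, perm], 50)
        )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        v=arrays(np.float64, st.integers(2, 40), elements=st.floats(0, 100)),
        n=st.floats(1, 99),
    )
    def test_bounded_by_extremes_and_monotone(self, v, n):
        s = patch_score(v, ScoringConfig(percentile=n))
        assert v.min() - 1e-9 <= s <= v.max() + 1e-9
        if n + 5 < 100:
            assert s <= patch_score(v, ScoringConfig(percentile=n + 5)) + 1e-9

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        d=arrays(np.float64, st.integers(1, 16), elements=st.floats(-50, 50)),
        scale=st.floats(0.1, 10),
    )
    def test_modified_z_is_nonnegative_and_scale_covariant(self, d, scale):
        cal = LatentCalibration(
            median=np.zeros(d.size), mad=np.full(d.size, scale), n_patches_used=9
        )
        s = modified_z(d, cal)
        assert (s >= 0).all()
        np.testing.assert_allclose(s, np.abs(d) / scale, rtol=1e-12)

    def test_matches_sorting_oracle(self, rng):
        for _ in range(20):
            v = rng.random(rng.integers(3, 50))
            n = float(rng.uniform(1, 99))
            assert patch_score(v, ScoringConfig(percentile=n)) == pytest.approx(
                np.percentile(np.sort(v), n), rel=1e-12
            )


class TestComponents:
    def _grid(self, anchors, stride=4):
        return PatchGrid(np.asarray(anchors), patch_size=15, stride=stride)

    def test_isolated_single_patch_filtered(self):
        grid = self._grid([(0, 0, 0), (0, 8, 8)])
        scores = np.array([5.0, 1.0])
        comps = flag_components(grid, scores, ScoringConfig(), (1, 40, 40))
        assert comps == []

    def test_two_adjacent_flagged_points_form_one_finding(self):
        grid = self._grid([(0, 0, 0), (0, 0, 4), (0, 20, 20)])
        scores = np.array([5.0, 4.0, 9.9])
        comps = flag_components(grid, scores, ScoringConfig(), (1, 40, 40))
        assert len(comps) == 1
        assert comps[0].n_patches == 2
        assert comps[0].peak_score == 5.0

    def test_cross_slice_linking_switchable(self):
        grid = self._grid([(0, 8, 8), (1, 8, 8)])
        scores = np.array([4.0, 4.0])
        linked = flag_components(grid, scores, ScoringConfig(), (2, 40, 40))
        assert len(linked) == 1 and linked[0].n_patches == 2
        split = flag_components(
            grid, scores, ScoringConfig(cross_slice_adjacency=False), (2, 40, 40)
        )
        assert split == []  # two isolated singles, both filtered

    def test_threshold_is_strict(self):
        grid = self._grid([(0, 0, 0), (0, 0, 4)])
        comps = flag_components(grid, np.array([3.0, 3.0]), ScoringConfig(), (1, 40, 40))
        assert comps == []  # score exactly 3 is not flagged

    def test_matches_brute_force_on_random_grids(self, rng):
        cfg = ScoringConfig(min_component_patches=1)  # compare raw components
        for _ in range(30):
            shape = (3, 41, 41)
            rows = np.arange(0, 27, 4)
            anchors = np.array(
                [(s, r, c) for s in range(3) for r in rows for c in rows]
            )
            scores = rng.random(len(anchors)) * 6
            comps = flag_components(self._grid(anchors), scores, cfg, shape)
            got = sorted(sorted(map(tuple, c.anchors)) for c in comps)
            flagged = anchors[scores > cfg.threshold]
            assert got == _brute_components(flagged, stride=4)

    def test_lower_threshold_never_unflags(self, rng):
        anchors = np.array([(0, r, c) for r in range(0, 24, 4) for c in range(0, 24, 4)])
        scores = rng.random(len(anchors)) * 6
        n_hi = (scores > 4.0).sum()
        n_lo = (scores > 2.0).sum()
        assert n_lo >= n_hi


class TestVoxelProjection:
    def test_max_over_covering_patches_brute_force(self, rng):
        anchors = np.array([(0, 0, 0), (0, 4, 4), (0, 8, 0), (1, 0, 0)])
        grid = PatchGrid(anchors, patch_size=15, stride=4)
        scores = rng.random(4) * 5
        shape = (2, 24, 24)
        vox = project_voxel_scores(grid, scores, shape)
        ref = np.zeros(shape)
        for (s, r, c), sc in zip(anchors, scores):
            patch_ref = ref[s, r : r + 15, c : c + 15]
            ref[s, r : r + 15, c : c + 15] = np.maximum(patch_ref, sc)
        # independent check voxel by voxel
        for s in range(2):
            for r in range(24):
                for c in range(24):
                    covering = [
                        sc
                        for (as_, ar, ac), sc in zip(anchors, scores)
                        if as_ == s and ar <= r < ar + 15 and ac <= c < ac + 15
                    ]
                    expect = max(covering) if covering else 0.0
                    assert vox[s, r, c] == pytest.approx(expect)
        np.testing.assert_allclose(vox, ref)


class TestScoreVolume:
    def test_structure_and_self_consistency(self, trained_tiny, small_volume):
        smap = trained_tiny.score_volume(small_volume)
        assert len(smap.grid_scores) == len(smap.grid)
        assert smap.voxel_scores.shape == small_volume.spatial_shape
        assert np.isfinite(smap.voxel_scores).all()
        for comp in smap.flagged_components:
            assert comp.n_patches >= 2
            assert (smap.grid_scores[comp.anchor_indices] > smap.threshold).all()
        # normal tissue close to the calibration distribution scores low
        frac_low = (smap.grid_scores <= 3.0).mean()
        assert frac_low >= 0.99

    def test_latent_dim_mismatch_rejected(self, trained_tiny, small_volume):
        from mranomaly.scoring import score_volume as sv

        bad_cal = LatentCalibration(
            median=np.zeros(5), mad=np.ones(5), n_patches_used=1
        )
        with pytest.raises(ValueError, match="latent_dim"):
            sv(trained_tiny.generator_, bad_cal, small_volume)
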