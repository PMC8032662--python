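"""Detection matching, pooling, the percentile sweep, and the
nearest-neighbor analysis of missed lesions."""

import numpy as np
import pytest

from mranomaly import LesionAnnotation, PatchGrid, ScoringConfig, aggregate, match_detections
from mranomaly.evaluation import nearest_neighbor_misses, rescore_percentile, sweep
from mranomaly.patches import PatchSet, dense_grid, extract_patches
from mranomaly.scoring import AnomalyScoreMap, SuspectedAnomaly, score_volume


def _component(anchors, patch_size=15):
    anchors = np.asarray(anchors)
    centers = anchors + np.array([0, patch_size // 2, patch_size // 2])
    return SuspectedAnomaly(
        anchor_indices=np.arange(len(anchors)),
        anchors=anchors,
        patch_size=patch_size,
        peak_score=5.0,
        centroid=centers.mean(axis=0),
    )


def _score_map(components, shape=(4, 40, 40)):
    grid = PatchGrid(np.zeros((0, 3)), patch_size=15, stride=4, source_id="vol")
    return AnomalyScoreMap(
        grid=grid,
        grid_scores=np.zeros(0),
        voxel_scores=np.zeros(shape, dtype=np.float32),
        flagged_components=components,
        source_id="vol",
    )


def _annotation(shape, blobs):
    labels = np.zeros(shape, dtype=np.int32)
    for lid, sl in enumerate(blobs, start=1):
        labels[sl] = lid
    counts = np.bincount(labels.ravel(), minlength=len(blobs) + 1)[1:]
    return LesionAnnotation(labels=labels, lesion_volumes=counts * 0.00324,
                            spacing=np.array([4.0, 0.9, 0.9]))


class TestMatching:
    def test_empty_annotation_keeps_component_count(self):
        smap = _score_map([_component([(0, 0, 0), (0, 0, 4)])] * 3)
        ann = _annotation((4, 40, 40), [])
        rep = match_detections(smap, ann)
        assert rep.n_lesions == 0
        assert np.isnan(rep.sensitivity)
        assert rep.n_suspected == 3

    def test_lesion_inside_footprint_detected(self):
        comp = _component([(1, 4, 4), (1, 8, 4)])
        ann = _annotation((4, 40, 40), [np.s_[1, 10:14, 10:14]])
        rep = match_detections(_score_map([comp]), ann)
        assert rep.detected.tolist() == [True]
        assert rep.sensitivity == 1.0
        assert rep.matches[0] == [0]

    def test_lesion_outside_footprint_missed(self):
        comp = _component([(0, 0, 0), (0, 0, 4)])
        ann = _annotation((4, 40, 40), [np.s_[3, 30:34, 30:34]])
        rep = match_detections(_score_map([comp]), ann)
        assert rep.detected.tolist() == [False]
        assert rep.sensitivity == 0.0

    def test_one_component_can_detect_two_lesions(self):
        comp = _component([(0, 0, 0), (0, 4, 0)])
        ann = _annotation((4, 40, 40), [np.s_[0, 1:3, 1:3], np.s_[0, 16:18, 5:7]])
        rep = match_detections(_score_map([comp]), ann)
        assert rep.detected.all()

    def test_min_overlap_voxels_config(self):
        comp = _component([(0, 0, 0), (0, 0, 4)])
        # lesion pokes one voxel into the footprint (col 18 is the last covered)
        ann = _annotation((4, 40, 40), [np.s_[0, 5:6, 18:25]])
        assert match_detections(_score_map([comp]), ann).detected[0]
        rep = match_detections(_score_map([comp]), ann, min_overlap_voxels=2)
        assert not rep.detected[0]

    def test_relabeling_invariance(self):
        comp = _component([(0, 0, 0), (0, 0, 4)])
        blobs = [np.s_[0, 2:4, 2:4], np.s_[2, 30:32, 30:32]]
        rep1 = match_detections(_score_map([comp]), _annotation((4, 40, 40), blobs))
        rep2 = match_detections(
            _score_map([comp]), _annotation((4, 40, 40), blobs[::-1])
        )
        assert rep1.sensitivity == rep2.sensitivity
        assert rep1.volume_fraction == rep2.volume_fraction


class TestAggregate:
    def test_pooled_sensitivity(self):
        from mranomaly import DetectionReport

        r1 = DetectionReport(
            lesion_ids=np.array([1, 2]), lesion_volumes=np.array([1.0, 1.0]),
            detected=np.array([True, True]), matches=[[0], [0]],
            volume_ids=["a", "a"], n_suspected=10, n_volumes=1,
        )
        r2 = DetectionReport(
            lesion_ids=np.array([1, 2]), lesion_volumes=np.array([1.0, 1.0]),
            detected=np.array([False, False]), matches=[[], []],
            volume_ids=["b", "b"], n_suspected=8, n_volumes=1,
        )
        pooled = aggregate([r1, r2])
        assert pooled.sensitivity == 0.5
        assert pooled.suspected_per_image == 9.0

    def test_volume_fraction_pooled(self):
        from mranomaly import DetectionReport

        rep = DetectionReport(
            lesion_ids=np.array([1, 2]), lesion_volumes=np.array([9.0, 1.0]),
            detected=np.array([True, False]), matches=[[0], []],
            volume_ids=["a", "a"], n_suspected=1, n_volumes=1,
        )
        assert rep.volume_fraction == pytest.approx(0.9)

    def test_single_report_fixed_point(self):
        from mranomaly import DetectionReport

        rep = DetectionReport(
            lesion_ids=np.array([1]), lesion_volumes=np.array([0.5]),
            detected=np.array([True]), matches=[[0]],
            volume_ids=["a"], n_suspected=4, n_volumes=1,
        )
        pooled = aggregate([rep])
        assert pooled.summary() == rep.summary()


class TestSweep:
    def test_cached_rescoring_equals_full_reinference(self, trained_tiny, small_volume):
        base = trained_tiny.score_volume(small_volume)  # percentile 50 cached
        for pct in (25.0, 75.0):
            fast = rescore_percentile(
                base, pct, ScoringConfig(percentile=pct), small_volume.spatial_shape
            )
            slow = score_volume(
                trained_tiny.generator_, trained_tiny.calibration_, small_volume,
                ScoringConfig(percentile=pct),
            )
            np.testing.assert_allclose(fast.grid_scores, slow.grid_scores, atol=1e-9)
            assert len(fast.flagged_components) == len(slow.flagged_components)

    def test_percentile_monotonicity_per_patch(self, trained_tiny, small_volume):
        smap = trained_tiny.score_volume(small_volume)
        pcts = list(range(10, 80, 5))
        scores = np.stack(
            [np.percentile(smap.elementwise, p, axis=1) for p in pcts]
        )
        assert (np.diff(scores, axis=0) >= -1e-12).all()

    def test_grid_shape_and_single_cell_consistency(self, trained_tiny, small_volume):
        ann = _annotation(small_volume.spatial_shape, [np.s_[4, 20:24, 20:24]])
        smap = trained_tiny.score_volume(small_volume)
        df = sweep({8: [smap]}, [ann], percentiles=list(range(10, 80, 5)))
        assert len(df) == 14
        one = sweep({8: [smap]}, [ann], percentiles=[50.0])
        rep = match_detections(smap, ann)
        assert one.loc[0, "sensitivity"] == rep.sensitivity
        assert one.loc[0, "suspected_per_image"] == rep.suspected_per_image


class TestNearestNeighbor:
    def test_identical_patch_found_at_distance_zero(self, trained_tiny, rng):
        train = rng.normal(0.5, 0.3, (100, 2, 15, 15)).astype(np.float32)
        missed = train[[17]].copy()
        res = nearest_neighbor_misses(
            PatchSet(missed), PatchSet(train), trained_tiny.generator_
        )
        assert res[0][1] == 17
        assert res[0][2] == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("space", ["latent", "pixel"])
    def test_matches_exhaustive_scan(self, trained_tiny, rng, space):
        train = rng.normal(0.5, 0.3, (200, 2, 15, 15)).astype(np.float32)
        missed = rng.normal(0.5, 0.4, (7, 2, 15, 15)).astype(np.float32)
        res = nearest_neighbor_misses(
            PatchSet(missed), PatchSet(train), trained_tiny.generator_, space
        )
        if space == "latent":
            enc = lambda x: trained_tiny.generator_.forward(x, train=False).z
            q, ref = enc(missed), enc(train)
        else:
            q = missed.reshape(7, -1).astype(np.float64)
            ref = train.reshape(200, -1).astype(np.float64)
        for qi, ti, dist in res:
            dists = np.linalg.norm(ref - q[qi], axis=1)
            assert dist == pytest.approx(dists.min(), rel=1e-6)
            assert ti == int(np.argmin(dists))  # first minimum = lowest index

    def test_tie_breaks_to_lowest_training_index(self, trained_tiny):
        train = np.zeros((5, 2, 15, 15), dtype=np.float32)
        missed = np.zeros((1, 2, 15, 15), dtype=np.float32)
        res = nearest_neighbor_misses(
            PatchSet(missed), PatchSet(train), trained_tiny.generator_, "pixel"
        )
        assert res[0][1] == 0
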