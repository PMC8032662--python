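"""Desk-scale phantom study: train, calibrate, score, evaluate.

Runs the full pipeline on a synthetic cohort — lesion-free training and
training-validation phantoms, lesioned test phantoms — with a small model
(latent 32, two narrow convolution blocks) and a reduced patch budget so
one run completes in minutes on a single CPU. The study conditions
(cohort sizes, lesion contrast and radii, percentile 50, threshold 3)
follow the pipeline defaults; only capacity and patch counts are scaled
down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detector import GanomalyPatchDetector
from .evaluation import DetectionReport, aggregate, match_detections
from .patches import PatchGrid, PatchSet, extract_patches, sample_training_patches
from .phantom import Cohort, make_cohort
from .scoring import AnomalyScoreMap
from .volumes import LesionAnnotation, MultiChannelVolume, normalize_intensity

__all__ = ["PhantomStudyResult", "run_phantom_study", "lesion_center_patches"]


@dataclass
class PhantomStudyResult:
    detector: GanomalyPatchDetector
    cohort: Cohort
    test_volumes: list[MultiChannelVolume]
    annotations: list[LesionAnnotation]
    score_maps: list[AnomalyScoreMap]
    report: DetectionReport
    lesion_scores: np.ndarray  # anomaly scores of lesion-center patches
    normal_scores: np.ndarray  # grid scores of lesion-free patches
    ranksum_p: float  # one-sided rank-sum: lesion > normal


def lesion_center_patches(
    volume: MultiChannelVolume, annotation: LesionAnnotation, patch_size: int = 15
) -> PatchSet:
    """One patch per lesion, centered on the lesion's voxel centroid."""
    half = patch_size // 2
    _, rows, cols = volume.spatial_shape
    anchors = []
    for lid in annotation.lesion_ids:
        vox = np.argwhere(annotation.labels == lid)
        s, r, c = np.round(vox.mean(axis=0)).astype(int)
        r = int(np.clip(r - half, 0, rows - patch_size))
        c = int(np.clip(c - half, 0, cols - patch_size))
        anchors.append((s, r, c))
    grid = PatchGrid(
        np.asarray(anchors, dtype=np.int64).reshape(-1, 3),
        patch_size=patch_size,
        stride=1,
        source_id=volume.volume_id,
    )
    return extract_patches(volume, grid)


def _normal_grid_scores(
    smap: AnomalyScoreMap, annotation: LesionAnnotation
) -> np.ndarray:
    """Grid scores of patches whose footprint misses every lesion."""
    k = smap.grid.patch_size
    keep = np.ones(len(smap.grid), dtype=bool)
    labels = annotation.labels
    for i, (s, r, c) in enumerate(smap.grid.anchors):
        if labels[s, r : r + k, c : c + k].any():
            keep[i] = False
    return smap.grid_scores[keep]


def run_phantom_study(
    seed: int,
    n_train: int = 16,
    n_trainval: int = 4,
    n_test: int = 10,
    n_train_patches: int = 20_000,
    n_trainval_patches: int = 2_000,
    latent_dim: int = 32,
    channel_widths: tuple[int, ...] = (8, 16),
    max_epochs: int = 15,
    percentile: float = 50.0,
    threshold: float = 3.0,
) -> PhantomStudyResult:
    """One seeded end-to-end run; returns the pooled detection report and
    the lesion-vs-normal score separation test."""
    cohort = make_cohort(n_train=n_train, n_trainval=n_trainval, n_test=n_test, seed=seed)
    train_vols = [normalize_intensity(v) for v in cohort.train]
    trainval_vols = [normalize_intensity(v) for v in cohort.trainval]
    test = [(normalize_intensity(v), a) for v, a in cohort.test]

    tp = sample_training_patches(train_vols, n_train_patches, rng_seed=seed + 101)
    vp = sample_training_patches(trainval_vols, n_trainval_patches, rng_seed=seed + 202)

    det = GanomalyPatchDetector(
        latent_dim=latent_dim,
        channel_widths=channel_widths,
        max_epochs=max_epochs,
        percentile=percentile,
        threshold=threshold,
        random_state=seed,
    )
    det.fit(tp.patches, X_val=vp.patches)

    reports, smaps = [], []
    lesion_scores, normal_scores = [], []
    for vol, ann in test:
        smap = det.score_volume(vol)
        smaps.append(smap)
        reports.append(match_detections(smap, ann))
        if ann.n_lesions:
            lesion_scores.append(det.anomaly_scores(lesion_center_patches(vol, ann).patches))
        normal_scores.append(_normal_grid_scores(smap, ann))
    pooled = aggregate(reports)
    lesion_scores = np.concatenate(lesion_scores) if lesion_scores else np.zeros(0)
    normal_scores = np.concatenate(normal_scores)
    if lesion_scores.size and normal_scores.size:
        p = float(
            stats.mannwhitneyu(lesion_scores, normal_scores, alternative="greater").pvalue
        )
    else:
        p = float("nan")
    return PhantomStudyResult(
        detector=det,
        cohort=cohort,
        test_volumes=[v for v, _ in test],
        annotations=[a for _, a in test],
        score_maps=smaps,
        report=pooled,
        lesion_scores=lesion_scores,
        normal_scores=normal_scores,
        ranksum_p=p,
    )
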