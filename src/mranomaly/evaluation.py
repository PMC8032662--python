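"""Lesion-level detection metrics, the latent-size/percentile sweep, and
nearest-neighbor analysis of missed lesions.

A lesion counts as detected when at least ``min_overlap_voxels`` (default
1) of its annotated voxels fall inside the voxel footprint of a retained
suspected anomaly. Sensitivity and detected-volume fraction are pooled
over lesions across volumes, not averaged per volume; the suspected-
anomaly rate is the total component count divided by the number of
volumes. Sweeping the aggregation percentile re-aggregates cached
elementwise modified Z-scores and never re-runs inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Generator
from .patches import PatchSet
from .scoring import (
    AnomalyScoreMap,
    LatentCalibration,
    ScoringConfig,
    aggregate_scores,
    flag_components,
)
from .volumes import LesionAnnotation

__all__ = [
    "DetectionReport",
    "match_detections",
    "aggregate",
    "sweep",
    "nearest_neighbor_misses",
    "DEFAULT_SWEEP_PERCENTILES",
]

# percentile grid examined by the sweep: 10..75 in steps of 5
DEFAULT_SWEEP_PERCENTILES = tuple(range(10, 80, 5))


@dataclass
class DetectionReport:
    """Per-lesion detection flags plus pooled summary statistics."""

    lesion_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    lesion_volumes: np.ndarray = field(default_factory=lambda: np.zeros(0))
    detected: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    matches: list = field(default_factory=list)  # per lesion: component indices
    volume_ids: list = field(default_factory=list)  # per lesion: source volume
    n_suspected: int = 0
    n_volumes: int = 1

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_ids)

    @property
    def sensitivity(self) -> float:
        if self.n_lesions == 0:
            return float("nan")
        return float(self.detected.sum() / self.n_lesions)

    @property
    def volume_fraction(self) -> float:
        total = self.lesion_volumes.sum()
        if total <= 0:
            return float("nan")
        return float(self.lesion_volumes[self.detected].sum() / total)

    @property
    def suspected_per_image(self) -> float:
        return self.n_suspected / self.n_volumes

    def summary(self) -> dict:
        return {
            "n_volumes": self.n_volumes,
            "n_lesions": self.n_lesions,
            "n_detected": int(self.detected.sum()),
            "sensitivity": self.sensitivity,
            "volume_fraction": self.volume_fraction,
            "n_suspected": self.n_suspected,
            "suspected_per_image": self.suspected_per_image,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "volume_id": self.volume_ids,
                "lesion_id": self.lesion_ids,
                "volume_ml": self.lesion_volumes,
                "detected": self.detected,
                "matching_components": [list(m) for m in self.matches],
            }
        )


def match_detections(
    score_map: AnomalyScoreMap,
    annotation: LesionAnnotation,
    min_overlap_voxels: int = 1,
) -> DetectionReport:
    """Match retained suspected anomalies against annotated lesions.

    One suspected anomaly may detect several lesions and one lesion may be
    covered by several suspected anomalies; lesions are what is counted.
    """
    labels = annotation.labels
    spatial_shape = labels.shape
    n_lesions = annotation.n_lesions
    overlap = np.zeros((n_lesions + 1, len(score_map.flagged_components)), dtype=np.int64)
    for ci, comp in enumerate(score_map.flagged_components):
        k = comp.patch_size
        seen = np.zeros(spatial_shape, dtype=bool)
        for s, r, c in comp.anchors:
            box = labels[s, r : r + k, c : c + k]
            seen_box = seen[s, r : r + k, c : c + k]
            fresh = box[~seen_box]
            if fresh.size:
                overlap[:, ci] += np.bincount(fresh.ravel(), minlength=n_lesions + 1)[
                    : n_lesions + 1
                ]
            seen[s, r : r + k, c : c + k] = True
    lesion_ids = np.arange(1, n_lesions + 1)
    detected = np.zeros(n_lesions, dtype=bool)
    matches: list[list[int]] = []
    for li in range(n_lesions):
        hit = np.nonzero(overlap[li + 1] >= min_overlap_voxels)[0]
        matches.append(hit.tolist())
        detected[li] = hit.size > 0
    return DetectionReport(
        lesion_ids=lesion_ids,
        lesion_volumes=np.asarray(annotation.lesion_volumes, dtype=float),
        detected=detected,
        matches=matches,
        volume_ids=[score_map.source_id] * n_lesions,
        n_suspected=score_map.n_suspected,
        n_volumes=1,
    )


def aggregate(reports: list[DetectionReport]) -> DetectionReport:
    """Pool per-volume reports over lesions (not averaged per volume)."""
    if not reports:
        raise ValueError("need at least one report to aggregate")
    return DetectionReport(
        lesion_ids=np.concatenate([r.lesion_ids for r in reports]),
        lesion_volumes=np.concatenate([r.lesion_volumes for r in reports]),
        detected=np.concatenate([r.detected for r in reports]),
        matches=[m for r in reports for m in r.matches],
        volume_ids=[v for r in reports for v in r.volume_ids],
        n_suspected=sum(r.n_suspected for r in reports),
        n_volumes=sum(r.n_volumes for r in reports),
    )


def rescore_percentile(
    score_map: AnomalyScoreMap,
    percentile: float,
    config: ScoringConfig,
    spatial_shape: tuple[int, int, int],
) -> DetectionReport | AnomalyScoreMap:
    """Re-aggregate a cached elementwise score matrix at a new percentile."""
    if score_map.elementwise is None:
        raise ValueError("score map carries no cached elementwise scores")
    if len(score_map.grid) == 0:
        return AnomalyScoreMap(
            grid=score_map.grid,
            grid_scores=np.zeros(0),
            voxel_scores=score_map.voxel_scores,
            flagged_components=[],
            source_id=score_map.source_id,
            elementwise=score_map.elementwise,
            threshold=config.threshold,
        )
    grid_scores = aggregate_scores(score_map.elementwise, percentile)
    comps = flag_components(score_map.grid, grid_scores, config, spatial_shape)
    return AnomalyScoreMap(
        grid=score_map.grid,
        grid_scores=grid_scores,
        voxel_scores=score_map.voxel_scores,  # projection kept from base run
        flagged_components=comps,
        source_id=score_map.source_id,
        elementwise=score_map.elementwise,
        threshold=config.threshold,
    )


def sweep(
    score_maps_by_latent: dict[int, list[AnomalyScoreMap]],
    annotations: list[LesionAnnotation],
    percentiles=DEFAULT_SWEEP_PERCENTILES,
    config: ScoringConfig | None = None,
    min_overlap_voxels: int = 1,
) -> pd.DataFrame:
    """Operating points over latent sizes x percentiles.

    ``score_maps_by_latent`` maps each latent size to the per-volume score
    maps produced by one trained model (with cached elementwise scores);
    ``annotations`` aligns with the volumes. Returns one row per
    (latent_dim, percentile) cell with pooled sensitivity, suspected
    anomalies per image, and detected-volume fraction.
    """
    config = config or ScoringConfig()
    rows = []
    for latent_dim, maps in sorted(score_maps_by_latent.items()):
        if len(maps) != len(annotations):
            raise ValueError("one score map per annotated volume is required")
        for pct in percentiles:
            reports = []
            for smap, ann in zip(maps, annotations):
                remapped = rescore_percentile(
                    smap, pct, config, ann.labels.shape
                )
                reports.append(
                    match_detections(remapped, ann, min_overlap_voxels)
                )
            pooled = aggregate(reports)
            rows.append(
                {
                    "latent_dim": latent_dim,
                    "percentile": pct,
                    "sensitivity": pooled.sensitivity,
                    "suspected_per_image": pooled.suspected_per_image,
                    "volume_fraction": pooled.volume_fraction,
                }
            )
    return pd.DataFrame(rows)


def nearest_neighbor_misses(
    missed_patches: PatchSet,
    train_patches: PatchSet,
    generator: Generator | None = None,
    feature_space: str = "latent",
    batch_size: int = 512,
) -> list[tuple[int, int, float]]:
    """For each missed-lesion patch, the closest training patch.

    Distances are Euclidean in the generator's latent space z by default
    (``feature_space='pixel'`` compares raw tiles instead). Ties go to the
    lowest training-patch index. Returns (missed index, train index,
    distance) triples.
    """
    if len(missed_patches) == 0 or len(train_patches) == 0:
        raise ValueError("both patch sets must be nonempty")
    if feature_space == "latent":
        if generator is None:
            raise ValueError("latent-space search requires a trained generator")
        q = _encode_all(generator, missed_patches.patches, batch_size)
        ref = _encode_all(generator, train_patches.patches, batch_size)
    elif feature_space == "pixel":
        q = missed_patches.patches.reshape(len(missed_patches), -1).astype(np.float64)
        ref = train_patches.patches.reshape(len(train_patches), -1).astype(np.float64)
    else:
        raise ValueError("feature_space must be 'latent' or 'pixel'")
    out = []
    ref_sq = (ref**2).sum(axis=1)
    for i in range(0, len(q), 256):
        block = q[i : i + 256]
        d2 = (block**2).sum(axis=1)[:, None] - 2.0 * block @ ref.T + ref_sq[None, :]
        np.maximum(d2, 0.0, out=d2)
        best = d2.argmin(axis=1)  # argmin takes the first minimum: lowest index
        for j, b in enumerate(best):
            out.append((i + j, int(b), float(np.sqrt(d2[j, b]))))
    return out


def _encode_all(generator: Generator, patches: np.ndarray, batch_size: int) -> np.ndarray:
    zs = []
    for i in range(0, len(patches), batch_size):
        zs.append(generator.forward(patches[i : i + batch_size], train=False).z)
    return np.concatenate(zs).astype(np.float64)
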