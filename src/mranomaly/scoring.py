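"""Latent-space anomaly scoring.

After training, the per-element median and median absolute deviation
(MAD) of the latent difference d = z - ẑ are calibrated over the training
patches. At inference each patch's elementwise modified Z-score is

    score_i = |d_i - median_i| / MAD_i

(the deviation from the median in MAD units; the classical 0.6745
consistency constant is off by default and available as a switch), and
the patch anomaly score is the Nth percentile of these elementwise scores
(default N = 50). Patch scores are projected back onto the volume by
taking, per voxel, the maximum score over all covering patches. Grid
points with score strictly greater than the threshold (default 3) are
grouped into connected components on the (slice, row, col) patch lattice;
single isolated flagged patches are discarded as spurious.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import Generator
from .patches import PatchGrid, PatchSet, dense_grid, extract_patches
from .volumes import MultiChannelVolume

__all__ = [
    "LatentCalibration",
    "ScoringConfig",
    "SuspectedAnomaly",
    "AnomalyScoreMap",
    "calibrate",
    "calibration_from_differences",
    "latent_differences",
    "modified_z",
    "patch_score",
    "aggregate_scores",
    "flag_components",
    "project_voxel_scores",
    "score_volume",
]

# consistency constant making MAD estimate the normal sigma
MAD_NORMAL_CONSTANT = 0.6745


@dataclass
class LatentCalibration:
    """Per-element median and MAD of z - ẑ over the training patches."""

    median: np.ndarray
    mad: np.ndarray
    n_patches_used: int
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.median = np.asarray(self.median, dtype=np.float64)
        self.mad = np.asarray(self.mad, dtype=np.float64)
        if self.median.shape != self.mad.shape:
            raise ValueError("median and MAD vectors must have equal length")
        if self.epsilon <= 0:
            raise ValueError("MAD floor must be positive")
        self.mad = np.maximum(self.mad, self.epsilon)

    @property
    def latent_dim(self) -> int:
        return self.median.shape[0]


@dataclass
class ScoringConfig:
    percentile: float = 50.0
    threshold: float = 3.0
    stride: int = 4
    patch_size: int = 15
    min_component_patches: int = 2
    use_consistency_constant: bool = False
    cross_slice_adjacency: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile < 100.0):
            raise ValueError("percentile must be in (0, 100)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class SuspectedAnomaly:
    """A retained connected group of flagged patch-grid points."""

    anchor_indices: np.ndarray  # indices into the grid's anchor list
    anchors: np.ndarray  # (m, 3) member (slice, row, col) anchors
    patch_size: int
    peak_score: float
    centroid: np.ndarray  # voxel coordinates of the mean patch center

    @property
    def n_patches(self) -> int:
        return len(self.anchors)

    def footprint_mask(self, spatial_shape: tuple[int, int, int]) -> np.ndarray:
        """Union of the member patches' voxel footprints."""
        m = np.zeros(spatial_shape, dtype=bool)
        k = self.patch_size
        for s, r, c in self.anchors:
            m[s, r : r + k, c : c + k] = True
        return m

    def footprint_voxels(self, spatial_shape) -> int:
        return int(self.footprint_mask(spatial_shape).sum())


@dataclass
class AnomalyScoreMap:
    """Per-grid-point and per-voxel anomaly scores for one volume."""

    grid: PatchGrid
    grid_scores: np.ndarray
    voxel_scores: np.ndarray
    flagged_components: list[SuspectedAnomaly]
    source_id: str = ""
    elementwise: np.ndarray | None = None  # (n_anchors, latent_dim) cache
    threshold: float = 3.0

    @property
    def n_suspected(self) -> int:
        return len(self.flagged_components)


def latent_differences(
    generator: Generator, patches: np.ndarray, batch_size: int = 512
) -> np.ndarray:
    """d = z - ẑ for every patch, evaluation mode, batched."""
    outs = []
    for i in range(0, len(patches), batch_size):
        out = generator.forward(patches[i : i + batch_size], train=False)
        outs.append(out.z - out.z_hat)
    return np.concatenate(outs, axis=0).astype(np.float64)


def calibrate(
    generator: Generator,
    train_patches: PatchSet,
    epsilon: float = 1e-6,
    batch_size: int = 512,
) -> LatentCalibration:
    """Median/MAD of the latent difference per element over training patches.

    Runs with the deployed (best-epoch) weights in evaluation mode, over
    the unaugmented training patches.
    """
    if len(train_patches) == 0:
        raise ValueError("cannot calibrate on an empty patch set")
    d = latent_differences(generator, train_patches.patches, batch_size)
    return calibration_from_differences(d, epsilon)


def calibration_from_differences(
    d: np.ndarray, epsilon: float = 1e-6
) -> LatentCalibration:
    """Median/MAD per latent element from an (n, latent_dim) difference matrix."""
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] == 0:
        raise ValueError("need a nonempty (n, latent_dim) difference matrix")
    med = np.median(d, axis=0)
    mad = np.median(np.abs(d - med), axis=0)
    return LatentCalibration(
        median=med, mad=mad, n_patches_used=d.shape[0], epsilon=epsilon
    )


def modified_z(
    d: np.ndarray,
    cal: LatentCalibration,
    use_consistency_constant: bool = False,
) -> np.ndarray:
    """Elementwise |d - median| / MAD, optionally scaled by 0.6745.

    Accepts a single difference vector or an (n, latent_dim) matrix.
    """
    d = np.asarray(d, dtype=np.float64)
    if d.shape[-1] != cal.latent_dim:
        raise ValueError(
            f"difference length {d.shape[-1]} != calibration latent_dim {cal.latent_dim}"
        )
    scores = np.abs(d - cal.median) / cal.mad
    if use_consistency_constant:
        scores = MAD_NORMAL_CONSTANT * scores
    return scores


def patch_score(scores: np.ndarray, config: ScoringConfig | None = None) -> float:
    """Nth percentile (linear interpolation) of the elementwise scores."""
    config = config or ScoringConfig()
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("empty elementwise score vector")
    return float(np.percentile(scores, config.percentile))


def aggregate_scores(elementwise: np.ndarray, percentile: float) -> np.ndarray:
    """Row-wise Nth percentile: one anomaly score per patch."""
    if elementwise.shape[1] == 0:
        raise ValueError("empty elementwise score matrix")
    return np.percentile(elementwise, percentile, axis=1)


def _lattice(grid: PatchGrid, flagged: np.ndarray, spatial_shape):
    """Embed flagged anchors into a dense (slice, row/stride, col/stride) grid."""
    s = grid.stride
    n_slices, rows, cols = spatial_shape
    lat = np.zeros(
        (n_slices, (rows - 1) // s + 1, (cols - 1) // s + 1), dtype=bool
    )
    idx = np.full(lat.shape, -1, dtype=np.int64)
    a = grid.anchors
    lat[a[flagged, 0], a[flagged, 1] // s, a[flagged, 2] // s] = True
    idx[a[:, 0], a[:, 1] // s, a[:, 2] // s] = np.arange(len(a))
    return lat, idx


def flag_components(
    grid: PatchGrid,
    grid_scores: np.ndarray,
    config: ScoringConfig,
    spatial_shape: tuple[int, int, int],
) -> list[SuspectedAnomaly]:
    """Group flagged grid points into lattice-connected components and
    drop those smaller than ``min_component_patches``.

    Adjacency is one stride step along exactly one in-plane axis, plus —
    when ``cross_slice_adjacency`` — the same in-plane position on an
    adjacent slice (6-connectivity on the patch lattice).
    """
    flagged = grid_scores > config.threshold
    if not flagged.any():
        return []
    lat, idx = _lattice(grid, flagged, spatial_shape)
    structure = ndimage.generate_binary_structure(3, 1)
    if not config.cross_slice_adjacency:
        structure = structure.copy()
        structure[0] = structure[2] = False
    labels, n = ndimage.label(lat, structure=structure)
    out: list[SuspectedAnomaly] = []
    for comp in range(1, n + 1):
        members_lat = np.argwhere(labels == comp)
        member_idx = idx[members_lat[:, 0], members_lat[:, 1], members_lat[:, 2]]
        member_idx = np.sort(member_idx)
        if len(member_idx) < config.min_component_patches:
            continue
        anchors = grid.anchors[member_idx]
        centers = anchors + np.array([0, grid.patch_size // 2, grid.patch_size // 2])
        out.append(
            SuspectedAnomaly(
                anchor_indices=member_idx,
                anchors=anchors,
                patch_size=grid.patch_size,
                peak_score=float(grid_scores[member_idx].max()),
                centroid=centers.mean(axis=0),
            )
        )
    return out


def project_voxel_scores(
    grid: PatchGrid,
    grid_scores: np.ndarray,
    spatial_shape: tuple[int, int, int],
) -> np.ndarray:
    """Per-voxel maximum over the scores of all covering patches.

    Voxels covered by no patch keep a score of 0.
    """
    vox = np.zeros(spatial_shape, dtype=np.float32)
    k = grid.patch_size
    order = np.argsort(grid_scores, kind="stable")
    for i in order:  # ascending: the max lands last
        s, r, c = grid.anchors[i]
        vox[s, r : r + k, c : c + k] = np.maximum(
            vox[s, r : r + k, c : c + k], grid_scores[i]
        )
    return vox


def score_volume(
    generator: Generator,
    cal: LatentCalibration,
    volume: MultiChannelVolume,
    config: ScoringConfig | None = None,
    batch_size: int = 512,
) -> AnomalyScoreMap:
    """Dense-grid anomaly scoring of one normalized volume."""
    config = config or ScoringConfig()
    if cal.latent_dim != generator.config.latent_dim:
        raise ValueError(
            f"calibration latent_dim {cal.latent_dim} != model "
            f"latent_dim {generator.config.latent_dim}"
        )
    grid = dense_grid(volume, patch_size=config.patch_size, stride=config.stride)
    if len(grid) == 0:
        empty = np.zeros(volume.spatial_shape, dtype=np.float32)
        return AnomalyScoreMap(
            grid=grid,
            grid_scores=np.zeros(0),
            voxel_scores=empty,
            flagged_components=[],
            source_id=volume.volume_id,
            elementwise=np.zeros((0, cal.latent_dim)),
            threshold=config.threshold,
        )
    patches = extract_patches(volume, grid)
    d = latent_differences(generator, patches.patches, batch_size)
    elementwise = modified_z(d, cal, config.use_consistency_constant)
    grid_scores = aggregate_scores(elementwise, config.percentile)
    voxel_scores = project_voxel_scores(grid, grid_scores, volume.spatial_shape)
    comps = flag_components(grid, grid_scores, config, volume.spatial_shape)
    return AnomalyScoreMap(
        grid=grid,
        grid_scores=grid_scores,
        voxel_scores=voxel_scores,
        flagged_components=comps,
        source_id=volume.volume_id,
        elementwise=elementwise,
        threshold=config.threshold,
    )
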