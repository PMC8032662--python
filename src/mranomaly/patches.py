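"""2D two-channel patch sampling: random masked draws and dense grids.

Patches are purely in-plane (15x15 voxels by default) because the slice
direction is coarse (4 mm) relative to the in-plane resolution (0.9 mm).
A patch is admissible when it lies fully inside the slice bounds and its
center voxel is inside the brain mask; both channels are sampled at the
identical window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import MultiChannelVolume

__all__ = [
    "PatchGrid",
    "PatchSet",
    "sample_training_patches",
    "dense_grid",
    "extract_patches",
    "augment_flips",
    "valid_centers",
]

DEFAULT_PATCH_SIZE = 15
DEFAULT_STRIDE = 4


@dataclass
class PatchGrid:
    """Anchor coordinates of patches on one volume.

    anchors : (n, 3) int array of (slice, row, col) top-left corners
    """

    anchors: np.ndarray
    patch_size: int = DEFAULT_PATCH_SIZE
    stride: int = DEFAULT_STRIDE
    source_id: str = ""

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=np.int64).reshape(-1, 3)
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def __len__(self) -> int:
        return self.anchors.shape[0]


@dataclass
class PatchSet:
    """Array of two-channel tiles plus (optionally) their grid."""

    patches: np.ndarray  # (n, channels, patch, patch)
    grid: PatchGrid | None = None

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        if self.patches.ndim != 4:
            raise ValueError("patches must be (n, channels, size, size)")
        if self.grid is not None and len(self.grid) != len(self):
            raise ValueError("patch count does not match anchor count")
        if not np.all(np.isfinite(self.patches)):
            raise ValueError("patch values must be finite")

    def __len__(self) -> int:
        return self.patches.shape[0]


def valid_centers(
    volume: MultiChannelVolume, patch_size: int = DEFAULT_PATCH_SIZE
) -> np.ndarray:
    """(n, 3) array of center voxels admitting a fully in-slice patch."""
    half = patch_size // 2
    _, rows, cols = volume.spatial_shape
    ok = np.zeros_like(volume.mask)
    # center at (r, c) needs anchor r-half >= 0 and r-half+patch <= rows
    ok[:, half : rows - (patch_size - 1 - half), half : cols - (patch_size - 1 - half)] = True
    ok &= volume.mask
    return np.argwhere(ok)


def sample_training_patches(
    volumes: list[MultiChannelVolume],
    n_total: int,
    rng_seed: int,
    patch_size: int = DEFAULT_PATCH_SIZE,
) -> PatchSet:
    """Draw ``n_total`` patches uniformly over all valid center positions.

    Uniform over the pooled set of (volume, center) placements, sampled
    with replacement; reproducible from ``rng_seed``.
    """
    half = patch_size // 2
    centers_per_vol = [valid_centers(v, patch_size) for v in volumes]
    counts = np.array([len(c) for c in centers_per_vol])
    if counts.sum() == 0:
        raise ValueError("no valid patch centers inside any brain mask")
    rng = np.random.default_rng(rng_seed)
    flat = rng.integers(0, counts.sum(), size=n_total)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    vol_of_draw = np.searchsorted(offsets, flat, side="right") - 1
    n_ch = volumes[0].n_channels
    out = np.empty((n_total, n_ch, patch_size, patch_size), dtype=np.float32)
    anchors = np.empty((n_total, 3), dtype=np.int64)
    for vi, vol in enumerate(volumes):
        sel = np.nonzero(vol_of_draw == vi)[0]
        if sel.size == 0:
            continue
        ctrs = centers_per_vol[vi][flat[sel] - offsets[vi]]
        for idx, (s, r, c) in zip(sel, ctrs):
            r0, c0 = r - half, c - half
            out[idx] = vol.channels[:, s, r0 : r0 + patch_size, c0 : c0 + patch_size]
            anchors[idx] = (s, r0, c0)
    grid = PatchGrid(anchors, patch_size=patch_size, stride=1, source_id="training")
    return PatchSet(out, grid=grid)


def dense_grid(
    volume: MultiChannelVolume,
    patch_size: int = DEFAULT_PATCH_SIZE,
    stride: int = DEFAULT_STRIDE,
) -> PatchGrid:
    """Stride-``stride`` grid over every slice, center-in-mask anchors only.

    Anchors start at in-plane offset 0; a grid point is kept when the full
    patch fits inside the slice and the patch center voxel is masked.
    """
    half = patch_size // 2
    n_slices, rows, cols = volume.spatial_shape
    r_anchor = np.arange(0, rows - patch_size + 1, stride)
    c_anchor = np.arange(0, cols - patch_size + 1, stride)
    rr, cc = np.meshgrid(r_anchor, c_anchor, indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    anchors = []
    for s in range(n_slices):
        keep = volume.mask[s, rr + half, cc + half]
        if keep.any():
            sl = np.column_stack(
                [np.full(keep.sum(), s, dtype=np.int64), rr[keep], cc[keep]]
            )
            anchors.append(sl)
    anchors = (
        np.concatenate(anchors) if anchors else np.empty((0, 3), dtype=np.int64)
    )
    return PatchGrid(
        anchors, patch_size=patch_size, stride=stride, source_id=volume.volume_id
    )


def extract_patches(volume: MultiChannelVolume, grid: PatchGrid) -> PatchSet:
    """Copy the tile under every anchor, channel-aligned, in anchor order."""
    k = grid.patch_size
    n_slices, rows, cols = volume.spatial_shape
    if len(grid) and (
        grid.anchors.min() < 0
        or grid.anchors[:, 0].max() >= n_slices
        or (grid.anchors[:, 1] + k).max() > rows
        or (grid.anchors[:, 2] + k).max() > cols
    ):
        raise ValueError("grid anchor out of volume bounds")
    out = np.empty((len(grid), volume.n_channels, k, k), dtype=np.float32)
    for i, (s, r, c) in enumerate(grid.anchors):
        out[i] = volume.channels[:, s, r : r + k, c : c + k]
    return PatchSet(out, grid=grid)


def augment_flips(patchset: PatchSet, rng_seed: int) -> PatchSet:
    """Independent 50% horizontal and vertical flips per patch.

    Both channels of a patch flip together. Fresh randomness is obtained
    by deriving ``rng_seed`` from a base seed plus the epoch index.
    """
    rng = np.random.default_rng(rng_seed)
    n = len(patchset)
    hor = rng.random(n) < 0.5
    ver = rng.random(n) < 0.5
    out = patchset.patches.copy()
    out[hor] = out[hor][:, :, :, ::-1]
    out[ver] = out[ver][:, :, ::-1, :]
    return PatchSet(out, grid=patchset.grid)
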