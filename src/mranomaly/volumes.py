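"""Volume containers, NIfTI I/O, and percentile intensity normalization.

The unit of inference is a :class:`MultiChannelVolume`: a stack of
co-registered channels (e.g. T1-weighted and T2-FLAIR) over one spatial
grid, with a binary brain mask and the physical voxel spacing. Intensity
normalization maps the 5th percentile of masked voxels to 0 and the 95th
to 1, per channel, without clipping — lesions are intensity outliers and
must stay outside [0, 1] if they are.

Volumes are expected to have had bias-field correction (e.g. N4) applied
externally before entering the pipeline; see :func:`n4_hook`.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "MultiChannelVolume",
    "LesionAnnotation",
    "load_volume",
    "normalize_intensity",
    "load_annotation",
    "write_score_map",
    "n4_hook",
]

# percentiles of the masked intensity distribution pinned to 0 and 1
NORM_LO_PCT = 5.0
NORM_HI_PCT = 95.0


@dataclass
class MultiChannelVolume:
    """Co-registered channel stack + spacing + brain mask.

    channels : float array, (n_channels, slices, rows, cols)
    spacing  : (3,) voxel size in mm along (slice, row, col)
    mask     : bool array, (slices, rows, cols); True inside the brain
    """

    channels: np.ndarray
    spacing: np.ndarray
    mask: np.ndarray
    volume_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.channels.ndim != 4:
            raise ValueError("channels must be 4D (channel, slice, row, col)")
        if self.mask.shape != self.spatial_shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match "
                f"spatial shape {self.spatial_shape}"
            )
        if not self.mask.any():
            raise ValueError("brain mask is empty")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive components")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class LesionAnnotation:
    """Labelled lesions on one volume's spatial grid.

    labels         : int array, 0 = background, 1..n_lesions lesion ids
    lesion_volumes : per-id physical volume in ml, index 0 <-> label 1
    """

    labels: np.ndarray
    lesion_volumes: np.ndarray = field(default_factory=lambda: np.zeros(0))
    spacing: np.ndarray | None = None

    @property
    def n_lesions(self) -> int:
        return int(self.lesion_volumes.shape[0])

    @property
    def lesion_ids(self) -> np.ndarray:
        return np.arange(1, self.n_lesions + 1)


def _read_nifti(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, zooms, img.affine


def load_volume(channel_paths, mask_path, volume_id: str = "") -> MultiChannelVolume:
    """Stack co-registered channel files and binarize the brain mask.

    Channel order follows the order of ``channel_paths``. Spacing and
    affine come from the first channel header; all spatial shapes must
    agree exactly.
    """
    channels = []
    spacing = affine = None
    ref_shape = None
    for p in channel_paths:
        data, zooms, aff = _read_nifti(p)
        if ref_shape is None:
            ref_shape, spacing, affine = data.shape, zooms, aff
        elif data.shape != ref_shape:
            raise ValueError(
                f"channel shape mismatch: {p} has {data.shape}, expected {ref_shape}"
            )
        channels.append(data.astype(np.float32))
    mask_data, _, _ = _read_nifti(mask_path)
    if mask_data.shape != ref_shape:
        raise ValueError(
            f"mask shape mismatch: {mask_path} has {mask_data.shape}, "
            f"expected {ref_shape}"
        )
    return MultiChannelVolume(
        channels=np.stack(channels),
        spacing=spacing,
        mask=mask_data != 0,
        volume_id=volume_id or str(channel_paths[0]),
        affine=affine,
    )


def normalize_intensity(volume: MultiChannelVolume) -> MultiChannelVolume:
    """Pin the masked 5th/95th intensity percentiles to 0/1 per channel.

    The affine map is computed on masked voxels only but applied to the
    whole channel; values are deliberately not clipped. Raises if a
    channel is constant within the mask (degenerate percentiles).
    """
    out = np.empty_like(volume.channels)
    masked = volume.channels[:, volume.mask]
    for c in range(volume.n_channels):
        lo, hi = np.percentile(masked[c], [NORM_LO_PCT, NORM_HI_PCT])
        if hi <= lo:
            raise ValueError(
                f"channel {c} of volume '{volume.volume_id}' is degenerate: "
                f"5th and 95th masked percentiles coincide ({lo})"
            )
        out[c] = (volume.channels[c] - lo) / (hi - lo)
    return replace(volume, channels=out)


def load_annotation(path, spacing) -> LesionAnnotation:
    """Read a lesion annotation volume and split it into labelled lesions.

    A binary input is split into connected components (26-connectivity in
    3D — lesions may continue on the adjacent thick slice); an input that
    already carries distinct positive integer labels is relabelled to the
    contiguous range 1..n. Physical volumes are voxel counts times the
    voxel volume.
    """
    data, zooms, _ = _read_nifti(path)
    spacing = np.asarray(spacing if spacing is not None else zooms, dtype=float)
    return annotation_from_array(data, spacing)


def annotation_from_array(data: np.ndarray, spacing) -> LesionAnnotation:
    data = np.asarray(data)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError("annotation labels must be integers")
        data = np.round(data).astype(np.int32)
    if data.min() < 0:
        raise ValueError("annotation labels must be nonnegative")
    spacing = np.asarray(spacing, dtype=float)
    uniq = np.unique(data[data > 0])
    if uniq.size <= 1:
        # binary (or empty): split into 26-connected components
        labels, n = ndimage.label(data > 0, structure=np.ones((3, 3, 3), dtype=int))
    else:
        labels = np.zeros_like(data, dtype=np.int32)
        for new_id, old in enumerate(uniq, start=1):
            labels[data == old] = new_id
        n = len(uniq)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1 : n + 1]
    voxel_ml = float(np.prod(spacing)) / 1000.0
    return LesionAnnotation(
        labels=labels.astype(np.int32),
        lesion_volumes=counts * voxel_ml,
        spacing=spacing,
    )


def write_score_map(voxel_scores: np.ndarray, volume: MultiChannelVolume, path) -> None:
    """Write a per-voxel score array as NIfTI in the source volume geometry."""
    affine = volume.affine
    if affine is None:
        affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(voxel_scores, dtype=np.float32), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def n4_hook(in_path, out_path, command: str = "N4BiasFieldCorrection") -> None:
    """Invoke an external N4 bias-field correction tool as a subprocess.

    Bias correction is an off-the-shelf preprocessing step, not part of
    this package; this hook merely shells out to an installed tool.
    """
    subprocess.run([command, "-i", str(in_path), "-o", str(out_path)], check=True)
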