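"""Synthetic two-channel brain-slice phantoms with insertable lesions.

The phantom emulates the acquisition geometry the pipeline targets —
fine in-plane resolution with thick slices (0.9 x 0.9 x 4.0 mm voxels) —
and the visual signature of a chronic infarct: a hypointense core in
channel 1 (T1-like) and a hypointense core with a hyperintense rim in
channel 2 (FLAIR-like). Brains are per-slice ellipses (an ellipsoid
across slices); tissue intensity is a base level plus a smooth random
bias field, partially shared between channels, plus white noise. Lesions
are additive-contrast discs — the claims under test are statistical
(outlier detection), not radiological realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import LesionAnnotation, MultiChannelVolume

__all__ = [
    "PhantomConfig",
    "LesionSpec",
    "generate_normal",
    "insert_lesions",
    "make_cohort",
]


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (18, 80, 80)  # slices, rows, cols
    spacing: tuple[float, float, float] = (4.0, 0.9, 0.9)  # mm, slice first
    ellipse_semiaxes: tuple[float, float, float] = (8.5, 34.0, 30.0)  # voxels
    base_intensity: tuple[float, float] = (100.0, 80.0)
    field_amplitude: float = 8.0
    field_correlation_voxels: float = 12.0  # in-plane Gaussian smoothing sigma
    field_shared_fraction: float = 0.5  # variance fraction shared across channels
    noise_sd: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape[1:]) < 15:
            raise ValueError("in-plane shape must admit a 15x15 patch")
        if min(self.ellipse_semiaxes) <= 0:
            raise ValueError("degenerate brain ellipse")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


@dataclass
class LesionSpec:
    count_range: tuple[int, int] = (2, 4)
    radius_range_mm: tuple[float, float] = (3.0, 6.0)  # in-plane radius
    core_contrast_ch1: float = -25.0  # hypointense core, channel 1
    core_contrast_ch2: float = -20.0  # hypointense core, channel 2
    rim_contrast_ch2: float = 25.0  # hyperintense rim, channel 2
    rim_thickness_mm: float = 1.8
    max_placement_tries: int = 200

    def __post_init__(self) -> None:
        if self.radius_range_mm[0] <= 0:
            raise ValueError("lesion radii must be positive")
        if not (self.core_contrast_ch1 < 0 < self.rim_contrast_ch2):
            raise ValueError(
                "core contrast must be negative and rim contrast positive"
            )


def _smooth_field(rng: np.random.Generator, cfg: PhantomConfig) -> np.ndarray:
    """Unit-variance smooth random field (in-plane correlated, mildly
    correlated across slices)."""
    raw = rng.standard_normal(cfg.shape)
    sig = cfg.field_correlation_voxels
    f = ndimage.gaussian_filter(raw, sigma=(1.0, sig, sig), mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def _brain_mask(cfg: PhantomConfig) -> np.ndarray:
    ns, nr, nc = cfg.shape
    zz, rr, cc = np.meshgrid(
        np.arange(ns), np.arange(nr), np.arange(nc), indexing="ij"
    )
    az, ar, ac = cfg.ellipse_semiaxes
    r2 = (
        ((zz - (ns - 1) / 2) / az) ** 2
        + ((rr - (nr - 1) / 2) / ar) ** 2
        + ((cc - (nc - 1) / 2) / ac) ** 2
    )
    return r2 <= 1.0


def generate_normal(config: PhantomConfig) -> MultiChannelVolume:
    """Lesion-free two-channel phantom, deterministic per seed."""
    rng = np.random.default_rng(config.rng_seed)
    mask = _brain_mask(config)
    shared = _smooth_field(rng, config)
    w_shared = np.sqrt(config.field_shared_fraction)
    w_own = np.sqrt(1.0 - config.field_shared_fraction)
    channels = []
    for base in config.base_intensity:
        own = _smooth_field(rng, config)
        fld = w_shared * shared + w_own * own
        noise = rng.standard_normal(config.shape)
        ch = base + config.field_amplitude * fld + config.noise_sd * noise
        channels.append(ch.astype(np.float32))
    return MultiChannelVolume(
        channels=np.stack(channels),
        spacing=np.asarray(config.spacing),
        mask=mask,
        volume_id=f"phantom-{config.rng_seed}",
    )


def _lesion_footprints(
    center: np.ndarray,
    radius_mm: float,
    rim_mm: float,
    spacing: np.ndarray,
    shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean core and rim masks for one lesion.

    In-plane the lesion is a disc of ``radius_mm``; on adjacent slices the
    effective radius shrinks as on a sphere, so lesions thicker than one
    slice span neighbours.
    """
    sz, sr, sc = spacing
    core = np.zeros(shape, dtype=bool)
    rim = np.zeros(shape, dtype=bool)
    cz, cr, cc = center
    max_dz = int(radius_mm // sz) + 1
    rows = np.arange(shape[1])
    cols = np.arange(shape[2])
    rr, cc_grid = np.meshgrid(rows, cols, indexing="ij")
    for dz in range(-max_dz, max_dz + 1):
        z = cz + dz
        if z < 0 or z >= shape[0]:
            continue
        chord = radius_mm**2 - (dz * sz) ** 2
        if chord <= 0:
            continue
        r_eff = np.sqrt(chord)
        d2 = ((rr - cr) * sr) ** 2 + ((cc_grid - cc) * sc) ** 2
        core[z] |= d2 <= r_eff**2
        rim[z] |= (d2 > r_eff**2) & (d2 <= (r_eff + rim_mm) ** 2)
    return core, rim


def insert_lesions(
    volume: MultiChannelVolume, spec: LesionSpec, rng_seed: int
) -> tuple[MultiChannelVolume, LesionAnnotation]:
    """Place non-overlapping disc lesions; return modified volume + labels.

    Channel 1 cores are shifted by ``core_contrast_ch1`` (hypointense),
    channel 2 cores by ``core_contrast_ch2`` and rims by
    ``rim_contrast_ch2`` (hyperintense ring). Annotation labels mark the
    cores only.
    """
    rng = np.random.default_rng(rng_seed)
    n_lesions = int(rng.integers(spec.count_range[0], spec.count_range[1] + 1))
    channels = volume.channels.copy()
    labels = np.zeros(volume.spatial_shape, dtype=np.int32)
    spacing = volume.spacing
    if n_lesions > 0:
        # keep centers away from the mask edge by the largest extent
        margin_vox = int(
            np.ceil((spec.radius_range_mm[1] + spec.rim_thickness_mm) / spacing[1:].min())
        )
        eroded = ndimage.binary_erosion(
            volume.mask,
            structure=np.ones((1, 3, 3), dtype=bool),
            iterations=max(margin_vox, 1),
        )
        candidates = np.argwhere(eroded)
        if candidates.size == 0:
            raise ValueError("eroded mask admits no lesion centers")
        occupied = np.zeros(volume.spatial_shape, dtype=bool)
        placed = 0
        tries = 0
        while placed < n_lesions:
            tries += 1
            if tries > spec.max_placement_tries:
                raise ValueError(
                    f"could not place {n_lesions} non-overlapping lesions "
                    f"within {spec.max_placement_tries} tries"
                )
            center = candidates[rng.integers(len(candidates))]
            radius = rng.uniform(*spec.radius_range_mm)
            core, rim = _lesion_footprints(
                center, radius, spec.rim_thickness_mm, spacing, volume.spatial_shape
            )
            extent = core | rim
            if (extent & occupied).any() or (extent & ~volume.mask).any():
                continue
            placed += 1
            occupied |= extent
            channels[0][core] += spec.core_contrast_ch1
            channels[1][core] += spec.core_contrast_ch2
            channels[1][rim] += spec.rim_contrast_ch2
            labels[core] = placed
    voxel_ml = volume.voxel_volume_ml
    counts = np.bincount(labels.ravel(), minlength=n_lesions + 1)[1 : n_lesions + 1]
    annotation = LesionAnnotation(
        labels=labels,
        lesion_volumes=counts * voxel_ml,
        spacing=spacing,
    )
    out = MultiChannelVolume(
        channels=channels,
        spacing=spacing,
        mask=volume.mask,
        volume_id=volume.volume_id + "+lesions",
        affine=volume.affine,
    )
    return out, annotation


@dataclass
class Cohort:
    train: list[MultiChannelVolume]
    trainval: list[MultiChannelVolume]
    test: list[tuple[MultiChannelVolume, LesionAnnotation]]
    manifest: dict = field(default_factory=dict)


def make_cohort(
    n_train: int,
    n_trainval: int,
    n_test: int,
    seed: int,
    config: PhantomConfig | None = None,
    lesion_spec: LesionSpec | None = None,
) -> Cohort:
    """Reproducible phantom cohort: lesion-free training and
    training-validation volumes, lesioned test volumes with annotations.

    Per-volume seeds are arithmetic offsets from the cohort seed, with
    the three splits in disjoint seed blocks.
    """
    config = config or PhantomConfig()
    lesion_spec = lesion_spec or LesionSpec()
    base = int(seed) * 1_000_00  # disjoint block per cohort seed
    manifest = {"seed": int(seed), "volumes": []}

    def _normal(i: int, split: str) -> MultiChannelVolume:
        from dataclasses import replace as _rp

        vol_seed = base + {"train": 0, "trainval": 20_000, "test": 40_000}[split] + i
        cfg = _rp(config, rng_seed=vol_seed)
        vol = generate_normal(cfg)
        vol.volume_id = f"{split}-{i:03d}"
        manifest["volumes"].append(
            {"id": vol.volume_id, "split": split, "seed": vol_seed, "lesions": []}
        )
        return vol

    train = [_normal(i, "train") for i in range(n_train)]
    trainval = [_normal(i, "trainval") for i in range(n_trainval)]
    test = []
    for i in range(n_test):
        vol = _normal(i, "test")
        lesioned, ann = insert_lesions(vol, lesion_spec, rng_seed=base + 60_000 + i)
        lesioned.volume_id = vol.volume_id
        manifest["volumes"][-1]["lesions"] = [
            {"lesion_id": int(lid), "volume_ml": float(v)}
            for lid, v in zip(ann.lesion_ids, ann.lesion_volumes)
        ]
        test.append((lesioned, ann))
    return Cohort(train=train, trainval=trainval, test=test, manifest=manifest)


def save_manifest(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort.manifest, fh, indent=2)
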