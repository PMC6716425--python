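"""Synthetic paired MR/PET striatal phantoms with ground-truth labels.

The generator emulates a dopamine-transporter PET + T1-MR cohort: bilateral
caudate, putamen and pallidum compartments with elevated tracer uptake over
background, a parieto-occipital reference slab, disease-dependent uptake
reduction that is strongest in the posterior putamen, additive noise, and a
known rigid MR->PET misalignment per subject.

Geometry lives in world millimetres (RAS, +y anterior). SARs are axis-aligned
ellipsoids; the occipital reference is a box slab. The PET volume is the
piecewise-constant uptake field defined on the MR grid, resampled through the
subject's true rigid transform with nearest-neighbour interpolation, plus
noise — so noise-free region means match the configuration exactly.
"""

from __future__ import annotations

import csv
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    ALL_LABELS,
    OCCIPITAL,
    SAR_LABELS,
    ImageVolume,
    LabelMap,
    RigidTransform,
    save_nifti,
)


class GeometryError(ValueError):
    """Raised when configured regions overlap or do not fit on the grid."""


def _default_geometry() -> dict:
    """Ellipsoid centres/semi-axes (mm) for the six SARs plus the occipital
    slab. Caudate elongated anterior-posterior, putamen lateral, pallidum
    medial and small, occipital a posterior box. The two hemispheres are
    mildly asymmetric (as real striata are), which also anchors the
    segmentation network's left/right assignment."""
    geo = {
        "r_caudate": {"center": (9.5, 16.0, 4.5), "semi_axes": (3.7, 11.5, 5.2)},
        "l_caudate": {"center": (-9.0, 14.0, 3.8), "semi_axes": (3.4, 10.5, 4.9)},
        "r_putamen": {"center": (18.5, 1.0, 0.5), "semi_axes": (4.6, 13.5, 6.2)},
        "l_putamen": {"center": (-18.5, -1.0, -0.5), "semi_axes": (4.4, 12.5, 5.8)},
        "r_pallidum": {"center": (10.0, -1.5, 0.3), "semi_axes": (3.1, 5.2, 4.6)},
        "l_pallidum": {"center": (-10.0, -2.5, -0.3), "semi_axes": (2.9, 4.8, 4.3)},
        "occipital": {"center": (0.0, -30.0, 0.0), "half_size": (20.0, 5.0, 10.0)},
    }
    return geo


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic cohort.

    ``noise_sd`` is a fraction of each modality's reference intensity
    (occipital uptake for PET, brain tissue mean for MR). ``pd_effect`` is the
    fractional uptake reduction per tissue; inside the putamen it is modulated
    by a linear anterior->posterior gradient spanning
    ``putamen_gradient_range`` (posterior end = 1, i.e. full effect).
    """

    grid_shape: tuple = (48, 48, 48)
    voxel_spacing: tuple = (2.0, 2.0, 2.0)
    pet_grid_shape: tuple = (32, 32, 32)
    pet_voxel_spacing: tuple = (3.0, 3.0, 3.0)
    region_geometry: dict = field(default_factory=_default_geometry)
    brain_semi_axes: tuple = (42.0, 44.0, 40.0)
    brain_center: tuple = (0.0, -2.0, 0.0)
    uptake_nl: dict = field(default_factory=lambda: {"caudate": 3.0, "putamen": 3.0, "pallidum": 2.5})
    occipital_uptake: float = 1.0
    brain_uptake: float = 0.9
    background_uptake: float = 0.05
    pd_effect: dict = field(default_factory=lambda: {"caudate": 0.15, "putamen": 0.40, "pallidum": 0.25})
    putamen_gradient_range: tuple = (0.5, 1.0)
    noise_sd: float = 0.05
    mr_contrast: dict = field(default_factory=lambda: {
        "background": 0.0, "brain": 100.0, "caudate": 150.0,
        "putamen": 165.0, "pallidum": 180.0})
    misalignment_range: dict = field(default_factory=lambda: {"rotation_deg": 6.0, "translation_mm": 5.0})
    geometry_jitter_sd: float = 0.03
    bias_field: bool = False
    seed: int = 0

    def __post_init__(self):
        for name, eff in self.pd_effect.items():
            if not 0.0 <= eff < 1.0:
                raise ValueError(f"pd_effect[{name}] must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, spec in self.region_geometry.items():
            axes = spec.get("semi_axes", spec.get("half_size"))
            if any(a <= 0 for a in axes):
                raise ValueError(f"{name}: semi-axes must be positive")

    def mr_grid(self) -> ImageVolume:
        shape = np.asarray(self.grid_shape)
        spacing = np.asarray(self.voxel_spacing, dtype=float)
        origin = -(shape - 1) * spacing / 2.0
        return ImageVolume(np.zeros(tuple(shape)), spacing, origin, "MR")

    def pet_grid(self) -> ImageVolume:
        shape = np.asarray(self.pet_grid_shape)
        spacing = np.asarray(self.pet_voxel_spacing, dtype=float)
        origin = -(shape - 1) * spacing / 2.0
        return ImageVolume(np.zeros(tuple(shape)), spacing, origin, "PET")


@dataclass
class SyntheticSubject:
    mr: ImageVolume
    pet: ImageVolume
    labels_mr_space: LabelMap
    true_transform: RigidTransform   # MR world -> PET world
    group: str
    id: str


def _stable_int(value) -> int:
    return zlib.crc32(str(value).encode()) & 0x7FFFFFFF


def _jittered_geometry(cfg: PhantomConfig, rng: np.random.Generator) -> dict:
    """Per-subject, group-independent scaling of region semi-axes."""
    geo = {}
    for name, spec in cfg.region_geometry.items():
        spec = dict(spec)
        key = "semi_axes" if "semi_axes" in spec else "half_size"
        scale = 1.0 + np.clip(rng.normal(0.0, cfg.geometry_jitter_sd, 3),
                              -2.5 * cfg.geometry_jitter_sd, 2.5 * cfg.geometry_jitter_sd)
        spec[key] = tuple(np.asarray(spec[key]) * scale)
        geo[name] = spec
    return geo


def _region_masks(geometry: dict, grid: ImageVolume) -> dict[str, np.ndarray]:
    coords = grid.grid_world_coords()
    masks = {}
    for name, spec in geometry.items():
        c = np.asarray(spec["center"], dtype=float)[:, None, None, None]
        if "semi_axes" in spec:
            a = np.asarray(spec["semi_axes"], dtype=float)[:, None, None, None]
            masks[name] = (((coords - c) / a) ** 2).sum(axis=0) <= 1.0
        else:
            h = np.asarray(spec["half_size"], dtype=float)[:, None, None, None]
            masks[name] = (np.abs(coords - c) <= h).all(axis=0)
    return masks


def _build_labels(geometry: dict, grid: ImageVolume) -> LabelMap:
    masks = _region_masks(geometry, grid)
    data = np.zeros(grid.shape, dtype=np.int32)
    total = np.zeros(grid.shape, dtype=np.int32)
    for name, mask in masks.items():
        label = ALL_LABELS[name]
        if not mask.any():
            raise GeometryError(f"region {name!r} contains no voxels; grid too small?")
        data[mask] = label
        total += mask.astype(np.int32)
    if (total > 1).any():
        overlapping = [n for n in masks if (masks[n] & (total > 1)).any()]
        raise GeometryError(f"overlapping regions: {sorted(overlapping)}")
    # a region clipped by the grid boundary would silently lose voxels
    lo = grid.voxel_to_world((0, 0, 0))
    hi = grid.voxel_to_world(np.array(grid.shape) - 1)
    for name, spec in geometry.items():
        c = np.asarray(spec["center"], dtype=float)
        ext = np.asarray(spec.get("semi_axes", spec.get("half_size")), dtype=float)
        if (c - ext < lo).any() or (c + ext > hi).any():
            raise GeometryError(f"region {name!r} extends outside the grid")
    return LabelMap(data, grid.spacing, grid.origin)


def _tissue_of(region: str) -> str:
    return region.split("_", 1)[1]


def uptake_field(cfg: PhantomConfig, geometry: dict, labels: LabelMap,
                 grid: ImageVolume, group: str) -> np.ndarray:
    """Noise-free PET uptake on the MR grid.

    NL means come straight from the configuration; for PD subjects each SAR is
    scaled by (1 - pd_effect * g) with g = 1 everywhere except inside the
    putamen, where g ramps linearly from the anterior tip (gradient_range[0])
    to the posterior tip (gradient_range[1] = full effect posteriorly).
    """
    coords = grid.grid_world_coords()
    bc = np.asarray(cfg.brain_center, dtype=float)[:, None, None, None]
    ba = np.asarray(cfg.brain_semi_axes, dtype=float)[:, None, None, None]
    brain = (((coords - bc) / ba) ** 2).sum(axis=0) <= 1.0

    field_ = np.where(brain, cfg.brain_uptake, cfg.background_uptake)
    field_[labels.data == OCCIPITAL] = cfg.occipital_uptake
    g_lo, g_hi = cfg.putamen_gradient_range
    for region, label in SAR_LABELS.items():
        tissue = _tissue_of(region)
        mask = labels.data == label
        base = cfg.uptake_nl[tissue]
        if group == "PD":
            grad = np.ones(np.count_nonzero(mask))
            if tissue == "putamen":
                cy = geometry[region]["center"][1]
                sy = geometry[region]["semi_axes"][1]
                y = coords[1][mask]
                # anterior tip (y = cy + sy) -> g_lo, posterior tip -> g_hi
                frac = np.clip((cy + sy - y) / (2.0 * sy), 0.0, 1.0)
                grad = g_lo + (g_hi - g_lo) * frac
            field_[mask] = base * (1.0 - cfg.pd_effect[tissue] * grad)
        else:
            field_[mask] = base
    return field_


def _nn_resample_through(field_: np.ndarray, src_grid: ImageVolume,
                         transform: RigidTransform, tgt_grid: ImageVolume) -> np.ndarray:
    """Nearest-neighbour pull-resampling of an MR-grid field onto the target
    grid through ``transform`` (source world -> target world)."""
    pts = tgt_grid.grid_world_coords().reshape(3, -1).T
    src_pts = transform.inverse().apply(pts)
    vox = np.rint(src_grid.world_to_voxel(src_pts)).astype(int)
    inside = np.all((vox >= 0) & (vox < np.asarray(src_grid.shape)), axis=1)
    out = np.zeros(len(pts), dtype=field_.dtype)
    v = vox[inside]
    out[inside] = field_[v[:, 0], v[:, 1], v[:, 2]]
    return out.reshape(tgt_grid.shape)


def generate_subject(config: PhantomConfig, group: str, id) -> SyntheticSubject:
    """Generate one paired MR/PET subject with gold-standard labels.

    Deterministic in (config, group, id): the per-subject RNG stream is
    derived from ``config.seed`` and a stable hash of ``id``.
    """
    if group not in ("NL", "PD"):
        raise ValueError(f"group must be 'NL' or 'PD', got {group!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _stable_int(id)]))

    geometry = _jittered_geometry(config, rng)
    mr_grid = config.mr_grid()
    labels = _build_labels(geometry, mr_grid)

    # MR: tissue-mean model (occipital reference has brain contrast)
    coords = mr_grid.grid_world_coords()
    bc = np.asarray(config.brain_center, dtype=float)[:, None, None, None]
    ba = np.asarray(config.brain_semi_axes, dtype=float)[:, None, None, None]
    brain = (((coords - bc) / ba) ** 2).sum(axis=0) <= 1.0
    mr_data = np.where(brain, config.mr_contrast["brain"], config.mr_contrast["background"])
    for region, label in SAR_LABELS.items():
        mr_data[labels.data == label] = config.mr_contrast[_tissue_of(region)]
    if config.bias_field:
        x = coords[0] / (coords[0].max() - coords[0].min() + 1e-9)
        mr_data = mr_data * (1.0 + 0.2 * x)
    mr_noise = config.noise_sd * config.mr_contrast["brain"]
    if mr_noise > 0:
        mr_data = mr_data + rng.normal(0.0, mr_noise, mr_data.shape)
    mr = ImageVolume(mr_data, mr_grid.spacing, mr_grid.origin, "MR")

    # true MR->PET rigid offset, uniform within the configured range
    rmax = config.misalignment_range["rotation_deg"]
    tmax = config.misalignment_range["translation_mm"]
    true_t = RigidTransform(
        rotations=rng.uniform(-rmax, rmax, 3),
        translations=rng.uniform(-tmax, tmax, 3),
        center=mr_grid.world_center(),
    )

    pet_grid = config.pet_grid()
    uptake = uptake_field(config, geometry, labels, mr_grid, group)
    pet_data = _nn_resample_through(uptake, mr_grid, true_t, pet_grid)
    pet_data[pet_data == 0.0] = config.background_uptake
    if config.noise_sd > 0:
        pet_data = pet_data + rng.normal(0.0, config.noise_sd * config.occipital_uptake, pet_data.shape)
    pet = ImageVolume(pet_data, pet_grid.spacing, pet_grid.origin, "PET")

    return SyntheticSubject(mr=mr, pet=pet, labels_mr_space=labels,
                            true_transform=true_t, group=group, id=str(id))


def generate_cohort(config: PhantomConfig, n_pd: int, n_nl: int, seed: int) -> list[SyntheticSubject]:
    """Generate ``n_pd`` PD + ``n_nl`` NL subjects with per-subject seeds."""
    if n_pd < 0 or n_nl < 0:
        raise ValueError("cohort counts must be non-negative")
    cfg = replace(config, seed=seed)
    subjects = [generate_subject(cfg, "PD", f"pd_{i:03d}") for i in range(n_pd)]
    subjects += [generate_subject(cfg, "NL", f"nl_{i:03d}") for i in range(n_nl)]
    return subjects


def build_pet_template(config: PhantomConfig, scale: float = 1.05,
                       smooth_vox: float = 1.0) -> tuple[ImageVolume, LabelMap]:
    """Pre-labeled PET template for the single-modality arm.

    Synthetic stand-in for a population atlas: the noise-free NL uptake field
    of the cohort's mean geometry, isotropically scaled by ``scale`` to mimic
    atlas-to-subject anatomical mismatch, lightly smoothed, with matching
    labels, both on the PET grid with no misalignment.
    """
    geo = {}
    for name, spec in config.region_geometry.items():
        spec = dict(spec)
        key = "semi_axes" if "semi_axes" in spec else "half_size"
        spec[key] = tuple(np.asarray(spec[key]) * scale)
        spec["center"] = tuple(np.asarray(spec["center"]) * scale)
        geo[name] = spec
    # the whole anatomy scales coherently, brain envelope included
    cfg = replace(config,
                  brain_semi_axes=tuple(np.asarray(config.brain_semi_axes) * scale),
                  brain_center=tuple(np.asarray(config.brain_center) * scale))
    mr_grid = cfg.mr_grid()
    labels_mr = _build_labels(geo, mr_grid)
    uptake = uptake_field(cfg, geo, labels_mr, mr_grid, "NL")
    identity = RigidTransform(center=mr_grid.world_center())
    pet_grid = config.pet_grid()
    data = _nn_resample_through(uptake, mr_grid, identity, pet_grid)
    data[data == 0.0] = config.background_uptake
    if smooth_vox > 0:
        data = gaussian_filter(data, smooth_vox)
    lab = _nn_resample_through(labels_mr.data, mr_grid, identity, pet_grid)
    template = ImageVolume(data, pet_grid.spacing, pet_grid.origin, "PET")
    return template, LabelMap(lab.astype(np.int32), pet_grid.spacing, pet_grid.origin)


def segmentation_phantom_config(**overrides) -> PhantomConfig:
    """Compact 32^3 MR configuration (2 mm voxels, 64 mm field of view) for
    desk-scale segmentation experiments. The occipital slab and brain
    envelope are pulled inward so every region fits the smaller grid."""
    geo = _default_geometry()
    geo["occipital"] = {"center": (0.0, -26.0, 0.0), "half_size": (12.0, 3.0, 8.0)}
    params = dict(
        grid_shape=(32, 32, 32),
        voxel_spacing=(2.0, 2.0, 2.0),
        pet_grid_shape=(24, 24, 24),
        pet_voxel_spacing=(3.0, 3.0, 3.0),
        region_geometry=geo,
        brain_semi_axes=(30.0, 30.0, 28.0),
        brain_center=(0.0, -1.0, 0.0),
    )
    params.update(overrides)
    return PhantomConfig(**params)


# ---------------------------------------------------------------------------
# Cohort I/O

def write_subject(subject: SyntheticSubject, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mr_path": out_dir / "mr.nii.gz",
        "pet_path": out_dir / "pet.nii.gz",
        "labels_path": out_dir / "labels.nii.gz",
    }
    save_nifti(subject.mr, paths["mr_path"])
    save_nifti(subject.pet, paths["pet_path"])
    save_nifti(subject.labels_mr_space, paths["labels_path"])
    sidecar = {
        "id": subject.id,
        "group": subject.group,
        "true_transform": json.loads(subject.true_transform.to_json()),
    }
    (out_dir / "subject.json").write_text(json.dumps(sidecar, indent=2))
    return {"id": subject.id, "group": subject.group,
            **{k: str(v) for k, v in paths.items()}}


def write_cohort(subjects, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [write_subject(s, out_dir / s.id) for s in subjects]
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "group", "mr_path", "pet_path", "labels_path"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest
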