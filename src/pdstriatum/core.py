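"""Core spatial containers: image volumes, label maps, rigid/affine transforms.

All world coordinates are RAS millimetres. Image grids are axis-aligned
(diagonal NIfTI affine: ``world = voxel * spacing + origin``); voxel indices
are 0-based. Anterior-posterior is the second world axis (+y = anterior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

# Label dictionary shared by the whole pipeline: six striatal anatomical
# regions (SARs), bilateral, plus the parieto-occipital reference region.
BACKGROUND = 0
R_CAUDATE, L_CAUDATE = 1, 2
R_PUTAMEN, L_PUTAMEN = 3, 4
R_PALLIDUM, L_PALLIDUM = 5, 6
OCCIPITAL = 7

SAR_LABELS = {
    "r_caudate": R_CAUDATE,
    "l_caudate": L_CAUDATE,
    "r_putamen": R_PUTAMEN,
    "l_putamen": L_PUTAMEN,
    "r_pallidum": R_PALLIDUM,
    "l_pallidum": L_PALLIDUM,
}
ALL_LABELS = {**SAR_LABELS, "occipital": OCCIPITAL, "background": BACKGROUND}


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing (mm), world origin (mm) and a
    modality tag ("MR" or "PET")."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    modality: str = "MR"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume requires a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world 4x4 affine (RAS)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def world_center(self) -> np.ndarray:
        return self.voxel_to_world((np.array(self.shape) - 1) / 2.0)

    def grid_world_coords(self) -> np.ndarray:
        """(3, D, H, W) array of world coordinates of every voxel centre."""
        idx = np.indices(self.shape, dtype=float)
        return idx * self.spacing[:, None, None, None] + self.origin[:, None, None, None]


@dataclass
class LabelMap:
    """Integer label volume voxel-aligned to an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    labels: dict[str, int] = field(default_factory=lambda: dict(ALL_LABELS))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMap data must be integer")
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)

    @property
    def shape(self):
        return self.data.shape

    @property
    def affine(self):
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def voxel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.data == label))

    def same_grid(self, other) -> bool:
        return (
            self.shape == tuple(other.shape)
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def _euler_matrix(rotations_deg) -> np.ndarray:
    """R = Rz @ Ry @ Rx for rotations (rx, ry, rz) in degrees."""
    rx, ry, rz = rotations_deg
    return Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True).as_matrix()


def _matrix_to_euler(mat) -> np.ndarray:
    rz, ry, rx = Rotation.from_matrix(mat).as_euler("ZYX", degrees=True)
    return np.array([rx, ry, rz])


@dataclass
class RigidTransform:
    """6-parameter rigid map ``y = R (p - c) + c + t`` between world spaces.

    rotations are (rx, ry, rz) in degrees about the world axes (applied
    x-first), translations in mm, ``center`` the rotation centre in mm.
    """

    rotations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=np.float64)
        self.translations = np.asarray(self.translations, dtype=np.float64)
        self.center = np.asarray(self.center, dtype=np.float64)

    @property
    def rotation_matrix(self) -> np.ndarray:
        return _euler_matrix(self.rotations)

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix of the map."""
        R = self.rotation_matrix
        mat = np.eye(4)
        mat[:3, :3] = R
        mat[:3, 3] = self.center + self.translations - R @ self.center
        return mat

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        R = self.rotation_matrix
        return (pts - self.center) @ R.T + self.center + self.translations

    def inverse(self) -> "RigidTransform":
        R = self.rotation_matrix
        return RigidTransform(
            rotations=_matrix_to_euler(R.T),
            translations=-R.T @ self.translations,
            center=self.center.copy(),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "rigid",
                "rotations_deg": self.rotations.tolist(),
                "translations_mm": self.translations.tolist(),
                "center_mm": self.center.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        d = json.loads(text)
        return cls(d["rotations_deg"], d["translations_mm"], d["center_mm"])

    @classmethod
    def from_matrix(cls, mat: np.ndarray, center=None) -> "RigidTransform":
        mat = np.asarray(mat, dtype=float)
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        R = mat[:3, :3]
        # t solves mat @ [p;1] = R(p-c)+c+t
        t = mat[:3, 3] - c + R @ c
        return cls(_matrix_to_euler(R), t, c)


@dataclass
class AffineTransform:
    """12-parameter affine map ``y = A (p - c) + c + t`` between world spaces."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.translations = np.asarray(self.translations, dtype=np.float64)
        self.center = np.asarray(self.center, dtype=np.float64)
        if abs(np.linalg.det(self.matrix)) <= 1e-9:
            raise ValueError("affine linear part is singular")

    def as_matrix(self) -> np.ndarray:
        mat = np.eye(4)
        mat[:3, :3] = self.matrix
        mat[:3, 3] = self.center + self.translations - self.matrix @ self.center
        return mat

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.center) @ self.matrix.T + self.center + self.translations

    def inverse(self) -> "AffineTransform":
        Ainv = np.linalg.inv(self.matrix)
        return AffineTransform(Ainv, -Ainv @ self.translations, self.center.copy())

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "affine",
                "matrix": self.matrix.tolist(),
                "translations_mm": self.translations.tolist(),
                "center_mm": self.center.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AffineTransform":
        d = json.loads(text)
        return cls(d["matrix"], d["translations_mm"], d["center_mm"])


def transform_from_json(text: str):
    d = json.loads(text)
    if d.get("type") == "affine":
        return AffineTransform.from_json(text)
    return RigidTransform.from_json(text)


# ---------------------------------------------------------------------------
# Resampling

def resample_intensity(vol: ImageVolume, transform, target: ImageVolume | LabelMap,
                       order: int = 1, cval: float = 0.0) -> ImageVolume:
    """Pull-resample ``vol`` through ``transform`` (source->target world map)
    onto the grid of ``target`` with spline interpolation of given order."""
    tgt_world = ImageVolume(np.zeros(target.shape), target.spacing, target.origin)
    pts = tgt_world.grid_world_coords().reshape(3, -1).T
    src_pts = transform.inverse().apply(pts)
    vox = vol.world_to_voxel(src_pts).T.reshape((3,) + tuple(target.shape))
    data = map_coordinates(vol.data, vox, order=order, mode="constant", cval=cval)
    return ImageVolume(data, target.spacing, target.origin, modality=vol.modality)


def save_nifti(obj: ImageVolume | LabelMap, path) -> None:
    data = obj.data
    if isinstance(obj, LabelMap):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(np.asarray(data), obj.affine)
    img.header.set_zooms(tuple(obj.spacing))
    nib.save(img, str(path))


def load_image(path, modality: str = "MR") -> ImageVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = np.diag(aff)[:3].copy()
    if not np.allclose(aff[:3, :3], np.diag(spacing), atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned RAS affines are supported")
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, aff[:3, 3], modality)


def load_labels(path, labels: dict[str, int] | None = None) -> LabelMap:
    img = nib.load(str(path))
    aff = img.affine
    spacing = np.diag(aff)[:3].copy()
    data = np.asarray(img.dataobj)
    return LabelMap(np.rint(data).astype(np.int32), spacing, aff[:3, 3],
                    labels or dict(ALL_LABELS))
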