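"""Striatal radiomics: subregion partitioning, SOR statistics, volumes.

Each subject is reduced to a 90-dimensional feature vector:

* the caudate nucleus and the putamen (bilateral) are each split into three
  spatially coherent substructures by k-means on voxel physical coordinates,
  ordered anterior -> posterior so subregion indices correspond across
  subjects; the pallidum is kept whole;
* for each of the resulting 14 regions, six intensity statistics of the PET
  signal (max, min, median, Q1, Q3, mean) are normalized to the
  striatal-to-occipital ratio SOR = (striatum - occipital) / occipital
  against the occipital statistic of the same kind -> 84 SOR features;
* the six whole-SAR volumes (mm^3), measured on the original-resolution MR
  label map -> 6 volume features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import OCCIPITAL, SAR_LABELS, ImageVolume, LabelMap

STATISTIC_NAMES = ("max", "min", "median", "q1", "q3", "mean")

# canonical region order: R/L caudate sub1-3, R/L putamen sub1-3, R/L pallidum
SUBDIVIDED = ("r_caudate", "l_caudate", "r_putamen", "l_putamen")
WHOLE = ("r_pallidum", "l_pallidum")
VOLUME_ORDER = ("r_caudate", "l_caudate", "r_putamen", "l_putamen", "r_pallidum", "l_pallidum")


def feature_names() -> list[str]:
    """The fixed, canonical 90-feature name list."""
    names = []
    for region in SUBDIVIDED:
        for sub in (1, 2, 3):
            names += [f"{region}_sub{sub}_{st}_sor" for st in STATISTIC_NAMES]
    for region in WHOLE:
        names += [f"{region}_whole_{st}_sor" for st in STATISTIC_NAMES]
    names += [f"{region}_volume" for region in VOLUME_ORDER]
    return names


@dataclass
class SubRegionPartition:
    """k-means split of one anatomical region into ordered substructures."""

    parent_label: int
    assignment: np.ndarray       # (n_voxels,) subregion index in {1..k}
    voxel_indices: np.ndarray    # (n_voxels, 3) voxel coordinates of the parent
    centroids: np.ndarray        # (k, 3) physical centroids, anterior-first

    @property
    def k(self) -> int:
        return len(self.centroids)

    def voxels_of(self, subregion: int) -> np.ndarray:
        return self.voxel_indices[self.assignment == subregion]


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]
    subject_id: str
    group: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.subject_id)


def subdivide_region(labels: LabelMap, region_id: int, k: int = 3,
                     seed: int = 0, n_restarts: int = 10) -> SubRegionPartition:
    """Split a labeled region into ``k`` substructures by k-means on voxel
    physical coordinates (mm). Subregion indices are relabeled by
    anterior->posterior centroid order (index 1 = most anterior), so they
    correspond across subjects with comparable geometry."""
    vox = np.argwhere(labels.data == region_id)
    if len(vox) == 0:
        raise ValueError(f"region {region_id} is empty")
    if len(vox) < k:
        raise ValueError(f"region {region_id} has {len(vox)} voxels < k={k}")
    coords = vox * labels.spacing + labels.origin
    for attempt in range(5):
        km = KMeans(n_clusters=k, n_init=n_restarts,
                    random_state=(seed + attempt) % (2 ** 32), algorithm="lloyd")
        raw = km.fit_predict(coords)
        if len(np.unique(raw)) == k:
            break
    else:
        raise RuntimeError(f"k-means failed to fill {k} clusters for region {region_id}")
    centroids = km.cluster_centers_
    # anterior = +y (second world axis); sort descending
    order = np.argsort(-centroids[:, 1], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return SubRegionPartition(
        parent_label=region_id,
        assignment=relabel[raw],
        voxel_indices=vox,
        centroids=centroids[order],
    )


def region_statistics(pet: ImageVolume, voxel_set: np.ndarray) -> dict[str, float]:
    """(max, min, median, Q1, Q3, mean) of PET intensity over ``voxel_set``
    ((n, 3) voxel indices). Quantiles interpolate linearly between order
    statistics."""
    if len(voxel_set) == 0:
        raise ValueError("empty voxel set")
    vals = pet.data[voxel_set[:, 0], voxel_set[:, 1], voxel_set[:, 2]]
    return {
        "max": float(vals.max()),
        "min": float(vals.min()),
        "median": float(np.median(vals)),
        "q1": float(np.quantile(vals, 0.25)),
        "q3": float(np.quantile(vals, 0.75)),
        "mean": float(vals.mean()),
    }


def sor(stat_region: float, stat_occipital: float) -> float:
    """Striatal-to-occipital ratio: (striatum - occipital) / occipital."""
    if stat_occipital <= 0:
        raise ValueError("occipital reference statistic must be positive")
    return (stat_region - stat_occipital) / stat_occipital


def region_volume(labels: LabelMap, region_id: int, spacing=None) -> float:
    """Region volume in mm^3: voxel count times voxel volume."""
    import warnings

    spacing = labels.spacing if spacing is None else np.asarray(spacing, dtype=float)
    n = labels.voxel_count(region_id)
    if n == 0:
        warnings.warn(f"region {region_id} absent; volume 0", stacklevel=2)
    return float(n * np.prod(spacing))


def extract_features(pet: ImageVolume, pet_labels: LabelMap, mr_labels: LabelMap,
                     seed: int = 0, occipital_mode: str = "matched") -> FeatureVector:
    """Build the 90-feature vector of one subject.

    ``pet_labels`` must carry the six SARs plus the occipital reference on
    the PET grid; ``mr_labels`` the six SARs on the original-resolution MR
    grid (volumes are measured there, without downsampling).
    ``occipital_mode``: "matched" divides each statistic by the occipital
    statistic of the same kind; "mean" divides everything by the occipital
    mean.
    """
    if pet_labels.voxel_count(OCCIPITAL) == 0:
        raise ValueError("occipital reference label missing from PET labels")
    empty = [name for name, lab in SAR_LABELS.items() if pet_labels.voxel_count(lab) == 0]
    if empty:
        raise ValueError(f"empty SAR region(s) on the PET grid: {empty}")

    occ_vox = np.argwhere(pet_labels.data == OCCIPITAL)
    occ_stats = region_statistics(pet, occ_vox)

    def _sor_block(voxels) -> list[float]:
        stats = region_statistics(pet, voxels)
        out = []
        for st in STATISTIC_NAMES:
            ref = occ_stats[st] if occipital_mode == "matched" else occ_stats["mean"]
            out.append(sor(stats[st], ref))
        return out

    values: list[float] = []
    for region in SUBDIVIDED:
        part = subdivide_region(pet_labels, SAR_LABELS[region], k=3, seed=seed)
        for sub in (1, 2, 3):
            values += _sor_block(part.voxels_of(sub))
    for region in WHOLE:
        values += _sor_block(np.argwhere(pet_labels.data == SAR_LABELS[region]))
    for region in VOLUME_ORDER:
        values.append(region_volume(mr_labels, SAR_LABELS[region]))
    return FeatureVector(np.asarray(values), feature_names(), subject_id="", group=None)


def features_to_frame(vectors) -> pd.DataFrame:
    """Stack FeatureVectors into a subjects x features table with id/group."""
    rows = []
    for v in vectors:
        row = {"id": v.subject_id, "group": v.group}
        row.update(dict(zip(v.names, v.values)))
        rows.append(row)
    return pd.DataFrame(rows)
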