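"""End-to-end orchestration: segment, register, extract, classify.

Three arms are supported:

* ``multi_modality`` — the network segments the SARs on MR, a rigid MR->PET
  registration propagates the labels (plus the occipital reference from the
  prior label map) onto the PET, features come from the PET and volumes from
  the MR-space segmentation;
* ``manual_labels`` — identical, but the gold-standard MR label map bypasses
  the segmentation network;
* ``single_modality_template`` — no MR: a pre-labeled PET template is aligned
  to the subject PET by an affine registration following a pre-rigid stage,
  and the template labels provide the regions (volumes are then measured on
  the propagated PET-grid labels).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analysis import CVOptions, FeatureTable, leave_n_out_cv
from .core import OCCIPITAL, ImageVolume, LabelMap, load_image, load_labels
from .features import FeatureVector, extract_features, features_to_frame
from .phantom import SyntheticSubject
from .registration import RegistrationOptions, propagate_labels, register_affine, register_rigid
from .segmentation import SegNet, predict

logger = logging.getLogger("pdstriatum")

ARMS = ("multi_modality", "manual_labels", "single_modality_template")


@dataclass
class PipelineConfig:
    arm: str = "manual_labels"
    seed: int = 0
    ns: tuple = (1,)
    registration: RegistrationOptions = field(default_factory=RegistrationOptions.fast)
    cv: CVOptions = field(default_factory=CVOptions)
    network: "SegNet | None" = None                  # required for multi_modality
    template: "ImageVolume | None" = None            # required for single_modality_template
    template_labels: "LabelMap | None" = None

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")

    def validate(self):
        if self.arm == "multi_modality" and self.network is None:
            raise ValueError("multi_modality arm requires a trained network")
        if self.arm == "single_modality_template" and (
                self.template is None or self.template_labels is None):
            raise ValueError("single_modality_template arm requires template + labels")


def _merge_occipital(sar_labels: LabelMap, prior: LabelMap) -> LabelMap:
    """Add the occipital reference from the prior label map to a SAR-only
    segmentation (the network does not delineate the reference region)."""
    data = sar_labels.data.copy()
    occ = (prior.data == OCCIPITAL) & (data == 0)
    data[occ] = OCCIPITAL
    return LabelMap(data, sar_labels.spacing, sar_labels.origin, dict(prior.labels))


def subject_features(subject: SyntheticSubject, config: PipelineConfig) -> FeatureVector:
    """Run one subject through the configured arm's stage sequence."""
    config.validate()
    seed = config.seed
    if config.arm in ("multi_modality", "manual_labels"):
        if config.arm == "multi_modality":
            mr_labels = predict(config.network, subject.mr)
            mr_labels = _merge_occipital(mr_labels, subject.labels_mr_space)
        else:
            mr_labels = subject.labels_mr_space
        reg = register_rigid(subject.mr, subject.pet, config.registration)
        pet_labels = propagate_labels(mr_labels, reg.transform, subject.pet)
        vol_labels = mr_labels
    else:
        pre = register_rigid(config.template, subject.pet, config.registration)
        reg = register_affine(config.template, subject.pet, init=pre.transform,
                              opts=config.registration)
        pet_labels = propagate_labels(config.template_labels, reg.transform, subject.pet)
        vol_labels = pet_labels
    fv = extract_features(subject.pet, pet_labels, vol_labels, seed=seed)
    fv.subject_id = subject.id
    fv.group = subject.group
    return fv


def cohort_features(subjects, config: PipelineConfig) -> tuple[FeatureTable, list[dict]]:
    """Per-subject feature extraction with per-subject failure records."""
    vectors, failures = [], []
    for subj in subjects:
        try:
            vectors.append(subject_features(subj, config))
        except Exception as exc:   # noqa: BLE001 - per-subject isolation
            logger.warning("subject %s excluded: %s", subj.id, exc)
            failures.append({"id": subj.id, "error": str(exc)})
    if not vectors:
        raise RuntimeError("empty cohort: every subject failed")
    return FeatureTable(features_to_frame(vectors)), failures


def run_pipeline(subjects, config: PipelineConfig, out_dir=None) -> dict:
    """Execute the arm end to end: features CSV, leave-n-out report, JSON.

    ``subjects`` is a list of SyntheticSubject (use :func:`load_manifest` for
    on-disk cohorts). Deterministic for a fixed config seed.
    """
    table, failures = cohort_features(subjects, config)
    results = [leave_n_out_cv(table, n, config.cv, seed=config.seed) for n in config.ns]
    report = {
        "arm": config.arm,
        "seed": config.seed,
        "n_subjects": len(table),
        "failures": failures,
        "cv": [vars(r) for r in results],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.frame.to_csv(out_dir / "features.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return {"table": table, "results": results, "report": report}


def load_manifest(manifest_path) -> list[SyntheticSubject]:
    """Read a cohort manifest CSV (id, group, mr_path, pet_path, labels_path)
    into in-memory subjects; unreadable rows are skipped with a log record."""
    from .core import RigidTransform

    subjects = []
    manifest_path = Path(manifest_path)
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            try:
                mr = load_image(row["mr_path"], "MR")
                pet = load_image(row["pet_path"], "PET")
                labels = load_labels(row["labels_path"])
                sidecar = Path(row["mr_path"]).parent / "subject.json"
                if sidecar.exists():
                    t = json.loads(sidecar.read_text())["true_transform"]
                    true_t = RigidTransform(t["rotations_deg"], t["translations_mm"],
                                            t["center_mm"])
                else:
                    true_t = RigidTransform()
                subjects.append(SyntheticSubject(
                    mr=mr, pet=pet, labels_mr_space=labels,
                    true_transform=true_t, group=row["group"], id=row["id"]))
            except Exception as exc:   # noqa: BLE001
                logger.warning("manifest row %s skipped: %s", row.get("id"), exc)
    if not subjects:
        raise RuntimeError(f"no readable subjects in {manifest_path}")
    return subjects


def content_hash(*arrays) -> str:
    """Short content hash used to tag cached stage outputs in logs."""
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]
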