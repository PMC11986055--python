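"""High-resolution anatomy I/O, label merging and BIDS output.

The simulator consumes a high-resolution T2w-like intensity volume together
with a co-registered integer label map of the fetal brain (eight tissue
classes in the style of refined fetal tissue annotations: white matter,
intra-axial CSF, cerebellum, extra-axial CSF, cortical grey matter, deep
grey matter, brainstem and corpus callosum).  For the relaxometry model the
fine labels are merged into the three classes that carry reference T1/T2
values: grey matter, white matter and cerebrospinal fluid.

All geometry is handled through the NIfTI affine (RAS world coordinates,
millimetres); voxel indices are 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from ._errors import (
    DegenerateInputError,
    FormatError,
    GeometryError,
    NamingError,
    ValidationError,
)

#: Integer codes of the eight-class fetal label dictionary (0 = background).
LABELS = {
    0: "background",
    1: "white_matter",
    2: "intra_axial_csf",
    3: "cerebellum",
    4: "extra_axial_csf",
    5: "cortical_gm",
    6: "deep_gm",
    7: "brainstem",
    8: "corpus_callosum",
}

#: Three-class simulation codes.
CLASS_BACKGROUND, CLASS_GM, CLASS_WM, CLASS_CSF = 0, 1, 2, 3
CLASS_NAMES = {CLASS_BACKGROUND: "background", CLASS_GM: "GM",
               CLASS_WM: "WM", CLASS_CSF: "CSF"}

#: Default fine-label -> {GM, WM, CSF} merge.  Cerebellum is folded into GM
#: and brainstem into WM for T2w contrast similarity; both assignments are
#: configurable because the three-class model does not prescribe them.
DEFAULT_MERGE = {
    1: CLASS_WM,   # white matter
    2: CLASS_CSF,  # intra-axial CSF (ventricles)
    3: CLASS_GM,   # cerebellum
    4: CLASS_CSF,  # extra-axial CSF
    5: CLASS_GM,   # cortical GM
    6: CLASS_GM,   # deep GM
    7: CLASS_WM,   # brainstem
    8: CLASS_WM,   # corpus callosum
}

GA_HARD_RANGE = (18.0, 40.0)
GA_COHORT_RANGE = (20.0, 34.8)


@dataclass
class HRAnatomy:
    """A high-resolution intensity volume plus co-registered labels.

    Attributes
    ----------
    intensity : float ndarray, T2w-like units (non-negative).
    labels : int ndarray on the same grid, codes from :data:`LABELS`.
    affine : 4x4 voxel-to-world (RAS, mm).
    ga_weeks : gestational age in weeks.
    subject_id : free-form identifier.
    condition : "neurotypical", "pathological" or "unknown".
    """

    intensity: np.ndarray
    labels: np.ndarray
    affine: np.ndarray
    ga_weeks: float
    subject_id: str = "unknown"
    condition: str = "unknown"
    label_dict: Mapping[int, str] = field(default_factory=lambda: dict(LABELS))

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.intensity.ndim != 3 or self.labels.ndim != 3:
            raise ValidationError("intensity and labels must be 3D volumes")
        if self.intensity.shape != self.labels.shape:
            raise GeometryError(
                f"intensity shape {self.intensity.shape} != "
                f"label shape {self.labels.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if np.any(self.spacing <= 0):
            raise ValidationError("voxel spacing must be positive")
        if not np.issubdtype(self.labels.dtype, np.integer):
            frac = np.abs(self.labels - np.round(self.labels))
            if np.any(frac > 1e-6):
                raise FormatError("label volume carries non-integer values")
            self.labels = np.round(self.labels).astype(np.int32)
        codes = set(np.unique(self.labels).tolist())
        unknown = sorted(codes - set(self.label_dict))
        if unknown:
            raise ValidationError(
                f"unknown label code(s) {unknown}; declared codes are "
                f"{sorted(self.label_dict)}")
        lo, hi = GA_HARD_RANGE
        if not (lo <= self.ga_weeks <= hi):
            raise ValidationError(
                f"ga_weeks={self.ga_weeks} outside plausible range [{lo}, {hi}]")
        clo, chi = GA_COHORT_RANGE
        if not (clo <= self.ga_weeks <= chi):
            warnings.warn(
                f"ga_weeks={self.ga_weeks} outside the reference cohort range "
                f"[{clo}, {chi}]", stacklevel=2)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm, derived from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensity.shape


@dataclass
class TissueClassMap:
    """Three-class (GM/WM/CSF) merge of an :class:`HRAnatomy` label map."""

    classes: np.ndarray
    affine: np.ndarray

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.classes.shape


def _congruent(aff_a: np.ndarray, aff_b: np.ndarray, tol: float = 1e-3) -> bool:
    return bool(np.all(np.abs(np.asarray(aff_a) - np.asarray(aff_b)) <= tol))


def load_hr_anatomy(image_path, label_path, ga_weeks: float,
                    subject_id: str = "unknown",
                    condition: str = "unknown",
                    label_dict: Mapping[int, str] | None = None) -> HRAnatomy:
    """Load an intensity/label NIfTI pair and validate their congruence.

    The two headers must agree on shape and affine (1e-3 tolerance on
    affine entries).  The intensity payload is cast to float64 and the
    labels to integers; fractional label values beyond 1e-6 are rejected.
    """
    img = nib.load(str(image_path))
    lab = nib.load(str(label_path))
    if img.ndim != 3 or lab.ndim != 3:
        raise FormatError("expected 3D NIfTI volumes")
    if img.shape != lab.shape:
        raise GeometryError(
            f"image grid {img.shape} != label grid {lab.shape}")
    if not _congruent(img.affine, lab.affine):
        raise GeometryError("image and label affines differ beyond 1e-3")
    return HRAnatomy(
        intensity=np.asanyarray(img.dataobj, dtype=np.float64),
        labels=np.asanyarray(lab.dataobj),
        affine=np.asarray(img.affine),
        ga_weeks=float(ga_weeks),
        subject_id=str(subject_id),
        condition=condition,
        label_dict=dict(label_dict) if label_dict is not None else dict(LABELS),
    )


def save_anatomy(anatomy: HRAnatomy, image_path, label_path) -> None:
    """Write the intensity and label volumes of an anatomy as NIfTI."""
    nib.save(nib.Nifti1Image(anatomy.intensity.astype(np.float32),
                             anatomy.affine), str(image_path))
    nib.save(nib.Nifti1Image(anatomy.labels.astype(np.int16),
                             anatomy.affine), str(label_path))


def merge_to_three_classes(anatomy: HRAnatomy,
                           mapping: Mapping[int, int] | None = None
                           ) -> TissueClassMap:
    """Merge the fine label map into GM / WM / CSF.

    ``mapping`` sends each non-background fine code to one of
    ``CLASS_GM``, ``CLASS_WM``, ``CLASS_CSF``; :data:`DEFAULT_MERGE` is
    used when omitted.  Every non-background code present in the volume
    must be covered and the non-background voxel count is conserved.
    """
    mapping = dict(DEFAULT_MERGE if mapping is None else mapping)
    present = set(np.unique(anatomy.labels).tolist()) - {0}
    missing = sorted(present - set(mapping))
    if missing:
        raise ValidationError(f"merge mapping misses label code(s) {missing}")
    bad = sorted(c for c, v in mapping.items()
                 if v not in (CLASS_GM, CLASS_WM, CLASS_CSF))
    if bad:
        raise ValidationError(
            f"merge targets must be GM/WM/CSF codes; offending keys {bad}")
    lut = np.zeros(max(mapping, default=0) + 1, dtype=np.int16)
    for code, cls in mapping.items():
        lut[code] = cls
    return TissueClassMap(classes=lut[anatomy.labels],
                          affine=anatomy.affine.copy())


def extract_mask(tcm: TissueClassMap, class_name: str) -> np.ndarray:
    """Return the boolean mask of one class ("GM", "WM", "CSF" or "brain")."""
    code = {"GM": CLASS_GM, "WM": CLASS_WM, "CSF": CLASS_CSF}.get(class_name)
    if class_name == "brain":
        mask = tcm.classes != CLASS_BACKGROUND
    elif code is None:
        raise ValidationError(
            f"unknown class {class_name!r}; expected GM/WM/CSF/brain")
    else:
        mask = tcm.classes == code
    if not mask.any():
        raise DegenerateInputError(f"{class_name} mask is empty")
    return mask


# ---------------------------------------------------------------------------
# BIDS output
# ---------------------------------------------------------------------------

def _series_entities(series) -> tuple[str, str, str, int]:
    """(subject, acq tag, orientation, run) of an LR series."""
    preset = f"{series.params.name.lower()}{str(series.params.field_tesla).replace('.', 'p')}T"
    return series.subject_id, preset, series.orientation, series.run_index


def _bids_stem(subject: str, acq: str, orientation: str, run: int) -> str:
    return f"sub-{subject}_acq-{acq}_dir-{orientation}_run-{run}"


def write_bids_dataset(series: Sequence, out_dir,
                       annotations: Sequence | None = None,
                       masks: Sequence | None = None) -> pd.DataFrame:
    """Write LR series (plus optional label/mask volumes) as a BIDS tree.

    Images go to ``sub-<ID>/anat/..._T2w.nii.gz`` with a JSON sidecar per
    series carrying the full acquisition parameter set and seed;
    annotations and brain masks go to a ``derivatives/labels`` tree.
    Returns a manifest with one row per series.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "dataset_description.json").write_text(json.dumps({
        "Name": "fetalmrsim simulated series",
        "BIDSVersion": "1.8.0",
        "DatasetType": "raw",
    }, indent=2))
    seen: set[tuple] = set()
    rows = []
    annotations = annotations if annotations is not None else [None] * len(series)
    masks = masks if masks is not None else [None] * len(series)
    if not (len(annotations) == len(masks) == len(series)):
        raise ValidationError("series, annotations and masks lengths differ")
    for s, ann, msk in zip(series, annotations, masks):
        subject, acq, orientation, run = _series_entities(s)
        key = (subject, acq, orientation, run)
        if key in seen:
            raise NamingError(f"duplicate series entities {key}")
        seen.add(key)
        stem = _bids_stem(subject, acq, orientation, run)
        anat = out / f"sub-{subject}" / "anat"
        anat.mkdir(parents=True, exist_ok=True)
        img_path = anat / f"{stem}_T2w.nii.gz"
        nib.save(nib.Nifti1Image(s.data.astype(np.float32), s.affine), img_path)
        sidecar = dict(s.params.to_dict())
        sidecar.update({"Seed": s.seed, "Orientation": s.orientation,
                        "Run": s.run_index})
        (anat / f"{stem}_T2w.json").write_text(json.dumps(sidecar, indent=2))
        deriv = out / "derivatives" / "labels" / f"sub-{subject}" / "anat"
        if ann is not None:
            deriv.mkdir(parents=True, exist_ok=True)
            nib.save(nib.Nifti1Image(np.asarray(ann).astype(np.int16),
                                     s.affine), deriv / f"{stem}_dseg.nii.gz")
        if msk is not None:
            deriv.mkdir(parents=True, exist_ok=True)
            nib.save(nib.Nifti1Image(np.asarray(msk).astype(np.uint8),
                                     s.affine), deriv / f"{stem}_mask.nii.gz")
        rows.append({"subject": subject, "orientation": orientation,
                     "run": run, "preset": acq,
                     "path": str(img_path.relative_to(out))})
    manifest = pd.DataFrame(
        rows, columns=["subject", "orientation", "run", "preset", "path"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def parse_bids_name(path) -> dict:
    """Recover the entity dict from a BIDS file name written by this module."""
    stem = Path(path).name
    for suffix in ("_T2w.nii.gz", "_T2w.json", "_dseg.nii.gz", "_mask.nii.gz"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    entities = {}
    for part in stem.split("_"):
        if "-" in part:
            k, v = part.split("-", 1)
            entities[k] = v
    return entities
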