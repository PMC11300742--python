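"""Domain types and NIfTI I/O for 3-label glioma segmentation masks.

The annotation scheme stores one integer label per voxel of a 3D grid:

    0  background
    1  enhancing tumor (annotated on contrast-enhanced T1)
    2  abnormal-ADC region (tumor with intermediate ADC plus high-ADC edema)
    3  FLAIR-T2 hyperintensity

Labels are mutually exclusive: a voxel carries the innermost compartment it
belongs to, so the stored volume is a partition of the annotated region.
Per-sequence compartments select single labels; the whole tumor (WT) is the
union of all three, mirroring BraTS whole-tumor-as-superset semantics.

Masks are expected to arrive on a common grid (co-registration and
resampling happen upstream); :func:`validate_pair` enforces this and no
resampling is ever performed here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd

ALLOWED_LABELS = frozenset({0, 1, 2, 3})

STATUSES = ("newly_diagnosed", "recurrent")
FOCALITIES = ("unifocal", "multifocal")

MANIFEST_COLUMNS = ("case_id", "reference_path", "candidate_path", "status", "focality")


class MaskValidationError(ValueError):
    """A mask volume violates the label-scheme contract."""


class GridMismatchError(ValueError):
    """Two masks do not live on the same voxel grid."""


class Compartment(enum.Enum):
    """Tumor compartments of the 3-label scheme.

    ``ET``, ``ADC_ABN`` and ``FLAIR_HYPER`` are the per-sequence labels;
    ``WT`` (whole tumor) is the union of all three.
    """

    ET = frozenset({1})
    ADC_ABN = frozenset({2})
    FLAIR_HYPER = frozenset({3})
    WT = frozenset({1, 2, 3})

    @property
    def label_set(self) -> frozenset:
        return self.value


#: The three per-sequence compartments, in label order.
SEQUENCE_COMPARTMENTS = (Compartment.ET, Compartment.ADC_ABN, Compartment.FLAIR_HYPER)


@dataclass
class MaskVolume:
    """A 3D integer label grid together with its voxel-to-world mapping.

    Parameters
    ----------
    voxels
        3D integer array with values in ``{0, 1, 2, 3}``.
    affine
        4x4 voxel-index-to-physical-space affine (NIfTI convention, mm).
    """

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise MaskValidationError(
                f"mask must be 3D, got shape {self.voxels.shape}"
            )
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise MaskValidationError("mask voxels must be integer-typed")
        if self.affine.shape != (4, 4):
            raise MaskValidationError("affine must be 4x4")
        present = set(np.unique(self.voxels).tolist())
        if not present <= ALLOWED_LABELS:
            raise MaskValidationError(
                f"unexpected label(s) {sorted(present - ALLOWED_LABELS)}; "
                f"allowed labels are {sorted(ALLOWED_LABELS)}"
            )
        if np.any(self.spacing <= 0):
            raise MaskValidationError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @classmethod
    def from_voxels(
        cls, voxels: np.ndarray, spacing: Iterable[float] = (1.0, 1.0, 1.0)
    ) -> "MaskVolume":
        """Build a mask on an axis-aligned grid with the given spacing."""
        affine = np.diag(list(spacing) + [1.0])
        return cls(np.asarray(voxels), affine)


@dataclass
class CaseRecord:
    """One patient study: reference (manual) and candidate (model) masks
    plus the two subgroup factors used in the cohort analysis."""

    case_id: str
    reference: MaskVolume
    candidate: MaskVolume
    status: str
    focality: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}, got {self.status!r}")
        if self.focality not in FOCALITIES:
            raise ValueError(
                f"focality must be one of {FOCALITIES}, got {self.focality!r}"
            )
        validate_pair(self.reference, self.candidate)


def load_mask(path, expected_labels: frozenset = ALLOWED_LABELS) -> MaskVolume:
    """Read a NIfTI label volume, rejecting non-integer data and labels
    outside ``expected_labels``."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    rounded = np.round(data)
    if np.max(np.abs(data - rounded)) > 1e-6:
        raise MaskValidationError(f"{path}: non-integer voxel values")
    voxels = rounded.astype(np.int16)
    present = set(np.unique(voxels).tolist())
    unexpected = present - set(expected_labels)
    if unexpected:
        raise MaskValidationError(
            f"{path}: unexpected label(s) {sorted(unexpected)}"
        )
    return MaskVolume(voxels, img.affine)


def save_mask(mask: MaskVolume, path) -> None:
    """Write a mask as integer-typed NIfTI; reload reproduces voxels and
    spacing bit-exactly."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def extract_compartment(mask: MaskVolume, compartment: Compartment) -> np.ndarray:
    """Binary mask of voxels whose label belongs to the compartment."""
    return np.isin(mask.voxels, list(compartment.label_set))


def validate_pair(a: MaskVolume, b: MaskVolume, rtol: float = 1e-3):
    """Check that two masks share grid shape, spacing and orientation.

    No implicit resampling: any mismatch is an error.
    """
    if a.voxels.shape != b.voxels.shape:
        raise GridMismatchError(
            f"shape mismatch: {a.voxels.shape} vs {b.voxels.shape}"
        )
    if not np.allclose(a.spacing, b.spacing, rtol=rtol):
        raise GridMismatchError(
            f"spacing mismatch: {a.spacing} vs {b.spacing}"
        )
    scale = max(np.abs(a.affine[:3, :3]).max(), 1e-12)
    if not np.allclose(a.affine[:3, :3], b.affine[:3, :3], atol=rtol * scale):
        raise GridMismatchError("orientation mismatch between affines")
    return a, b


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest CSV (case_id, reference_path, candidate_path,
    status, focality); relative paths are resolved against the CSV's folder."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    base = path.parent
    for col in ("reference_path", "candidate_path"):
        df[col] = [
            str(p) if Path(p).is_absolute() else str(base / p) for p in df[col]
        ]
    return df


def load_case(row) -> CaseRecord:
    """Materialize one manifest row into a validated :class:`CaseRecord`."""
    return CaseRecord(
        case_id=str(row["case_id"]),
        reference=load_mask(row["reference_path"]),
        candidate=load_mask(row["candidate_path"]),
        status=str(row["status"]),
        focality=str(row["focality"]),
    )
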