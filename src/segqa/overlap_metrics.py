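"""Voxel-overlap measures between candidate and reference compartments.

Three quantities drive the downstream quality score:

* Dice similarity coefficient, ``2|R ∩ C| / (|R| + |C|)``;
* missing fraction, ``|R \\ C| / |R|`` — the share of the reference
  compartment the candidate fails to cover;
* false-inclusion fraction, ``|C \\ R| / |R|`` — candidate voxels outside
  the reference, normalized by reference volume so the penalty trigger
  scales with lesion size.

Conventions: Dice of two empty masks is 1.0 (perfect agreement on
absence) and of one empty mask is 0.0; missing fraction of an empty
reference is 0.0 (nothing to miss); false inclusion against an empty
reference is ``inf`` (pure false inclusion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .mask_model import (
    CaseRecord,
    Compartment,
    GridMismatchError,
    MaskVolume,
    extract_compartment,
    validate_pair,
)

__all__ = [
    "OverlapResult",
    "dice",
    "missing_fraction",
    "false_inclusion_fraction",
    "compartment_overlap",
    "case_overlaps",
]


@dataclass(frozen=True)
class OverlapResult:
    """Overlap summary for one compartment of one case."""

    dice: float
    missing_fraction: float
    false_inclusion_fraction: float
    ref_volume_mm3: float
    cand_volume_mm3: float


def _check(ref: np.ndarray, cand: np.ndarray):
    ref = np.asarray(ref, dtype=bool)
    cand = np.asarray(cand, dtype=bool)
    if ref.shape != cand.shape:
        raise GridMismatchError(f"shape mismatch: {ref.shape} vs {cand.shape}")
    return ref, cand


def dice(ref: np.ndarray, cand: np.ndarray, both_empty: float = 1.0) -> float:
    ref, cand = _check(ref, cand)
    n_ref = int(ref.sum())
    n_cand = int(cand.sum())
    if n_ref + n_cand == 0:
        return float(both_empty)
    inter = int(np.logical_and(ref, cand).sum())
    return 2.0 * inter / (n_ref + n_cand)


def missing_fraction(ref: np.ndarray, cand: np.ndarray) -> float:
    ref, cand = _check(ref, cand)
    n_ref = int(ref.sum())
    if n_ref == 0:
        return 0.0
    missed = int(np.logical_and(ref, ~cand).sum())
    return missed / n_ref


def false_inclusion_fraction(ref: np.ndarray, cand: np.ndarray) -> float:
    ref, cand = _check(ref, cand)
    n_ref = int(ref.sum())
    extra = int(np.logical_and(cand, ~ref).sum())
    if n_ref == 0:
        return float("inf") if extra > 0 else 0.0
    return extra / n_ref


def compartment_overlap(
    reference: MaskVolume, candidate: MaskVolume, compartment: Compartment
) -> OverlapResult:
    """All overlap measures for one compartment of a validated mask pair."""
    r = extract_compartment(reference, compartment)
    c = extract_compartment(candidate, compartment)
    vv = reference.voxel_volume_mm3
    return OverlapResult(
        dice=dice(r, c),
        missing_fraction=missing_fraction(r, c),
        false_inclusion_fraction=false_inclusion_fraction(r, c),
        ref_volume_mm3=float(r.sum()) * vv,
        cand_volume_mm3=float(c.sum()) * vv,
    )


def case_overlaps(case: CaseRecord) -> Dict[Compartment, OverlapResult]:
    """Overlap results for ET, ADC_ABN, FLAIR_HYPER and WT of one case."""
    validate_pair(case.reference, case.candidate)
    return {
        comp: compartment_overlap(case.reference, case.candidate, comp)
        for comp in Compartment
    }
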