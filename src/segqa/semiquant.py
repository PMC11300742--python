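"""Algorithmized two-step 5-point semi-quantitative segmentation score.

The original scale is a radiologist's visual judgment: step 1 asks whether
the segmentation is generally consistent with the lesion's morphology
across all sequences; step 2 refines the score from visually estimated
per-sequence missing volume. This module replaces the visual estimates
with computed overlap quantities:

* step 1 "general consistency" is operationalized as whole-tumor Dice at
  or above a threshold (default 0.7, the conventional cut for good
  segmentation performance);
* step 2 uses the maximum per-sequence missing fraction ``M``:

  =================  ==========================  =====
  branch             condition                   score
  =================  ==========================  =====
  consistent         M ≤ tol (default 0.05)        5
  consistent         M < 1/4                       4
  consistent         M ≥ 1/4                       3
  inconsistent       M < 1/4                       3
  inconsistent       1/4 ≤ M ≤ 1/2                 2
  inconsistent       M > 1/2                       1
  =================  ==========================  =====

* a 1-point penalty (floored at 1) applies when the candidate erroneously
  includes volume outside the reference — false-inclusion fraction above a
  threshold (default 0.10 of reference volume).

Boundary handling follows the scale's wording literally: "less than a
quarter" is strict, "a quarter to a half" is inclusive at both ends,
"more than half" is strict. A perfect-voxel score-5 requirement would be
unrealistically strict for what is a visual completeness criterion, hence
the small tolerance on "complete consistency".
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping

import yaml

from .mask_model import Compartment, SEQUENCE_COMPARTMENTS, CaseRecord
from .overlap_metrics import OverlapResult, case_overlaps

__all__ = [
    "ScoringConfig",
    "SemiquantScore",
    "step1_consistency",
    "step2_score",
    "apply_penalty",
    "score_case",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds of the algorithmized scale. All are unitless fractions."""

    consistency_dice_threshold: float = 0.7
    complete_consistency_missing_tol: float = 0.05
    quarter: float = 0.25
    half: float = 0.50
    penalty_inclusion_threshold: float = 0.10
    #: compartment whose Dice drives step 1 ("WT" union by default;
    #: "FLAIR_HYPER" restricts to the outermost label only)
    consistency_compartment: str = "WT"

    def __post_init__(self) -> None:
        if not (
            0.0
            < self.complete_consistency_missing_tol
            < self.quarter
            < self.half
            < 1.0
        ):
            raise ValueError(
                "thresholds must satisfy 0 < complete_tol < quarter < half < 1"
            )
        if self.consistency_compartment not in Compartment.__members__:
            raise ValueError(
                f"unknown compartment {self.consistency_compartment!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "ScoringConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class SemiquantScore:
    """Ordinal 1-5 rating with its full decision path."""

    score: int
    initially_consistent: bool
    per_sequence_missing: Dict[str, float]
    pre_penalty_score: int
    penalty_applied: bool
    wt_dice: float
    false_inclusion: float


def step1_consistency(
    overlaps: Mapping[Compartment, OverlapResult], cfg: ScoringConfig
) -> bool:
    """General morphological consistency: gate on whole-tumor Dice.

    The threshold is inclusive: Dice exactly at the cut counts as
    consistent.
    """
    comp = Compartment[cfg.consistency_compartment]
    if comp not in overlaps:
        raise KeyError(f"missing compartment {comp.name} in overlaps")
    return overlaps[comp].dice >= cfg.consistency_dice_threshold


def _max_missing(per_sequence_missing: Mapping, cfg: ScoringConfig) -> float:
    vals = []
    for comp in SEQUENCE_COMPARTMENTS:
        key = comp if comp in per_sequence_missing else comp.name
        if key not in per_sequence_missing:
            raise KeyError(f"missing sequence entry {comp.name}")
        vals.append(float(per_sequence_missing[key]))
    return max(vals)


def step2_score(
    consistent: bool, per_sequence_missing: Mapping, cfg: ScoringConfig
) -> int:
    """Sequence-by-sequence review: score from the worst missing fraction."""
    m = _max_missing(per_sequence_missing, cfg)
    if consistent:
        if m <= cfg.complete_consistency_missing_tol:
            return 5
        if m < cfg.quarter:
            return 4
        return 3
    if m < cfg.quarter:
        return 3
    if m <= cfg.half:
        return 2
    return 1


def apply_penalty(score: int, false_inclusion: float, cfg: ScoringConfig) -> int:
    """Deduct one point (floored at the scale minimum) for erroneous
    inclusion of volume outside the reference."""
    if false_inclusion > cfg.penalty_inclusion_threshold:
        return max(1, score - 1)
    return score


def score_case(case: CaseRecord, cfg: ScoringConfig | None = None) -> SemiquantScore:
    """Run the full two-step assessment on one case."""
    cfg = cfg or ScoringConfig()
    overlaps = case_overlaps(case)
    consistent = step1_consistency(overlaps, cfg)
    missing = {
        comp.name: overlaps[comp].missing_fraction
        for comp in SEQUENCE_COMPARTMENTS
    }
    pre = step2_score(consistent, missing, cfg)
    fi = overlaps[Compartment.WT].false_inclusion_fraction
    final = apply_penalty(pre, fi, cfg)
    return SemiquantScore(
        score=final,
        initially_consistent=consistent,
        per_sequence_missing=missing,
        pre_penalty_score=pre,
        penalty_applied=final != pre,
        wt_dice=overlaps[Compartment.WT].dice,
        false_inclusion=fi,
    )
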