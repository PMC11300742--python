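"""Synthetic 3D phantom masks and controlled degradations.

Real glioma MRI for this analysis is not publicly available, so the
pipeline is exercised on phantoms that reproduce the *structure* the
evaluation assumes: per focus, three nested ellipsoidal regions
(enhancing core within the abnormal-ADC region within the FLAIR
hyperintensity), stored as a mutually exclusive label partition;
optionally several well-separated foci (multifocal disease) and a
resection-cavity morphology (enhancing rim around an excluded core,
the hard postoperative regime).

Candidate masks are produced by degrading a reference with a prescribed
overlap target: boundary erosion or dilation steered through the
Euclidean distance transform (a tiny deterministic jitter breaks distance
ties so any voxel count is achievable), rigid translation, or dropping a
focus (a missed satellite lesion). Achieved overlap is checked against
the target within a declared tolerance.

All randomness flows from explicit per-spec seeds; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .mask_model import (
    CaseRecord,
    Compartment,
    MaskVolume,
    save_mask,
)
from .overlap_metrics import dice as _dice_fn
from .overlap_metrics import missing_fraction as _missing_fn

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "make_reference_case",
    "degrade",
    "make_cohort",
    "write_cohort",
    "simulate_rater_pair",
]


class InfeasibleGeometryError(ValueError):
    """Requested foci do not fit in the grid without overlap."""


class TargetUnattainableError(ValueError):
    """Degradation could not reach the requested overlap target."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one reference phantom.

    ``radii`` gives (low, high) sampling ranges in mm for the outer
    semi-axis of each nested compartment shell (ET, ADC-abnormal,
    FLAIR), innermost first; per-axis ratios are drawn from
    ``axis_ratio_range`` for mild anisotropy. ``cavity`` carves an empty
    resection core out of the enhancing region, leaving a rim.
    """

    grid_shape: Tuple[int, int, int] = (44, 44, 44)
    n_foci: int = 1
    radii: Tuple[Tuple[float, float], ...] = ((2.5, 3.5), (4.5, 6.0), (7.0, 9.0))
    axis_ratio_range: Tuple[float, float] = (0.8, 1.25)
    cavity: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_foci < 1:
            raise ValueError("n_foci must be >= 1")
        if len(self.radii) != 3:
            raise ValueError("radii needs one (low, high) range per compartment")
        prev_hi = 0.0
        for lo, hi in self.radii:
            if not (0 < lo <= hi):
                raise ValueError("radius ranges must be positive and ordered")
            if lo < prev_hi * 0.99:
                # shells must be nestable: each range sits outward of the last
                raise ValueError("compartment radius ranges must be nested")
            prev_hi = lo


@dataclass(frozen=True)
class DegradationSpec:
    """How to corrupt a reference into a candidate.

    Exactly one of ``missing_fraction`` / ``wt_dice`` is the target for
    modes erode / dilate / translate (dilate accepts only ``wt_dice``
    since it removes nothing). ``drop_focus`` needs no target: the
    smallest focus is removed; with a ``missing_fraction`` target the
    focus closest to that volume share is chosen.
    """

    mode: str
    missing_fraction: Optional[float] = None
    wt_dice: Optional[float] = None
    tolerance: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("erode", "dilate", "translate", "drop_focus"):
            raise ValueError(f"unknown degradation mode {self.mode!r}")
        n_targets = (self.missing_fraction is not None) + (self.wt_dice is not None)
        if self.mode == "drop_focus":
            if self.wt_dice is not None:
                raise ValueError("drop_focus takes a missing_fraction target only")
        elif n_targets != 1:
            raise ValueError("exactly one of missing_fraction / wt_dice required")
        if self.mode == "dilate" and self.wt_dice is None:
            raise ValueError("dilate only supports a wt_dice target")
        for v in (self.missing_fraction, self.wt_dice):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError("targets must lie in [0, 1]")


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    rho = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return rho <= 1.0


def _focus_regions(shape, center, outer_radii, axis_factors):
    """Nested solid regions (ET, ADC, FLAIR) of one focus."""
    return [
        _ellipsoid(shape, center, r * axis_factors) for r in outer_radii
    ]


def _build_reference(spec: PhantomSpec):
    """Labels plus the per-focus nested regions (for invariant checks)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    labels = np.zeros(shape, dtype=np.int16)
    placed: List[Tuple[np.ndarray, float]] = []
    foci = []
    for _ in range(spec.n_foci):
        r_outer = None
        for _attempt in range(400):
            radii = np.array([rng.uniform(lo, hi) for lo, hi in spec.radii])
            radii = np.sort(radii)  # enforce nesting even for touching ranges
            factors = rng.uniform(*spec.axis_ratio_range, size=3)
            factors /= factors.prod() ** (1 / 3)  # volume-preserving anisotropy
            extent = radii[-1] * factors.max()
            margin = extent + 1.5
            if any(margin * 2 >= s for s in shape):
                continue
            center = np.array(
                [rng.uniform(margin, s - 1 - margin) for s in shape]
            )
            ok = all(
                np.linalg.norm(center - c0) > extent + e0 + 1.0
                for c0, e0 in placed
            )
            if ok:
                r_outer = (center, radii, factors)
                placed.append((center, extent))
                break
        if r_outer is None:
            raise InfeasibleGeometryError(
                f"could not place {spec.n_foci} non-overlapping foci in {shape}"
            )
        center, radii, factors = r_outer
        regions = _focus_regions(shape, center, radii, factors)
        labels[regions[2]] = 3
        labels[regions[1]] = 2
        labels[regions[0]] = 1
        if spec.cavity:
            core = _ellipsoid(shape, center, radii[0] * 0.55 * factors)
            labels[core] = 0
        foci.append(regions)
    return labels, foci


def make_reference_case(spec: PhantomSpec) -> MaskVolume:
    """Deterministic reference phantom with nested compartments per focus."""
    labels, _ = _build_reference(spec)
    return MaskVolume.from_voxels(labels)


def nested_regions(spec: PhantomSpec) -> List[List[np.ndarray]]:
    """Per-focus [ET, ADC, FLAIR] solid regions, for nesting checks."""
    _, foci = _build_reference(spec)
    return foci


def _keep_top(values: np.ndarray, region: np.ndarray, k: int, rng) -> np.ndarray:
    """Boolean mask keeping the k region voxels with the largest value;
    a tiny jitter makes every k achievable despite tied distances."""
    idx = np.flatnonzero(region)
    v = values.ravel()[idx] + rng.uniform(0, 1e-4, size=idx.size)
    order = np.argsort(v)[::-1]
    keep = np.zeros(values.size, dtype=bool)
    keep[idx[order[:k]]] = True
    return keep.reshape(values.shape)


def degrade(reference: MaskVolume, spec: DegradationSpec) -> MaskVolume:
    """Produce a candidate mask hitting the requested overlap target."""
    rng = np.random.default_rng(spec.seed)
    ref = reference.voxels
    wt = ref > 0
    n = int(wt.sum())
    if n == 0:
        raise ValueError("reference has no tumor voxels to degrade")

    if spec.mode == "erode":
        if spec.wt_dice is not None:
            d = spec.wt_dice
            m = (2 - 2 * d) / (2 - d)  # dice of an eroded subset = 2(1-m)/(2-m)
        else:
            m = spec.missing_fraction
        k = int(round((1 - m) * n))
        if k == n:
            cand = ref.copy()
        else:
            dist = ndimage.distance_transform_edt(wt, sampling=reference.spacing)
            keep = _keep_top(dist, wt, k, rng)
            cand = np.where(keep, ref, 0).astype(ref.dtype)
        achieved = _achieved(wt, cand > 0, spec)
        _check_tol(achieved, spec)
        return MaskVolume(cand, reference.affine)

    if spec.mode == "dilate":
        d = spec.wt_dice
        a = int(round(2 * n * (1 - d) / max(d, 1e-9)))
        outside = ~wt
        dist_out, idx = ndimage.distance_transform_edt(
            outside, sampling=reference.spacing, return_indices=True
        )
        add = _keep_top(-dist_out, outside, a, rng)
        cand = ref.copy()
        # added voxels inherit the label of the nearest reference voxel
        src = tuple(ix[add] for ix in idx)
        cand[add] = ref[src]
        achieved = _achieved(wt, cand > 0, spec)
        _check_tol(achieved, spec)
        return MaskVolume(cand, reference.affine)

    if spec.mode == "translate":
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        target_kind, target = (
            ("wt_dice", spec.wt_dice)
            if spec.wt_dice is not None
            else ("missing_fraction", spec.missing_fraction)
        )
        best = None
        max_shift = max(ref.shape)
        seen = set()
        for s in np.arange(0, max_shift, 0.5):
            off = tuple(int(round(x)) for x in direction * s)
            if off in seen:
                continue
            seen.add(off)
            cand = _shift(ref, off)
            achieved = (
                _dice_fn(wt, cand > 0)
                if target_kind == "wt_dice"
                else _missing_fn(wt, cand > 0)
            )
            err = abs(achieved - target)
            if best is None or err < best[0]:
                best = (err, cand)
            if err == 0:
                break
        err, cand = best
        if err > spec.tolerance:
            raise TargetUnattainableError(
                f"translate: best achievable within {err:.3f} of target"
            )
        return MaskVolume(cand, reference.affine)

    # drop_focus
    comp_labels, n_comp = ndimage.label(wt)
    if n_comp < 2:
        raise TargetUnattainableError("drop_focus needs at least two foci")
    sizes = ndimage.sum_labels(wt, comp_labels, index=np.arange(1, n_comp + 1))
    if spec.missing_fraction is not None:
        fracs = sizes / n
        pick = int(np.argmin(np.abs(fracs - spec.missing_fraction))) + 1
    else:
        pick = int(np.argmin(sizes)) + 1
    cand = np.where(comp_labels == pick, 0, ref).astype(ref.dtype)
    if spec.missing_fraction is not None:
        achieved = _missing_fn(wt, cand > 0)
        if abs(achieved - spec.missing_fraction) > spec.tolerance:
            raise TargetUnattainableError(
                f"drop_focus achieved missing fraction {achieved:.3f}"
            )
    return MaskVolume(cand, reference.affine)


def _shift(arr: np.ndarray, offset) -> np.ndarray:
    out = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, off in enumerate(offset):
        size = arr.shape[ax]
        if abs(off) >= size:
            return out
        if off >= 0:
            src[ax] = slice(0, size - off)
            dst[ax] = slice(off, size)
        else:
            src[ax] = slice(-off, size)
            dst[ax] = slice(0, size + off)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _achieved(wt_ref: np.ndarray, wt_cand: np.ndarray, spec: DegradationSpec) -> float:
    if spec.wt_dice is not None:
        return _dice_fn(wt_ref, wt_cand)
    return _missing_fn(wt_ref, wt_cand)


def _check_tol(achieved: float, spec: DegradationSpec) -> None:
    target = spec.wt_dice if spec.wt_dice is not None else spec.missing_fraction
    if abs(achieved - target) > spec.tolerance:
        raise TargetUnattainableError(
            f"{spec.mode}: achieved {achieved:.3f}, target {target:.3f} "
            f"(tolerance {spec.tolerance})"
        )


# -- cohort assembly ---------------------------------------------------------

#: Cohort composition of the published test set this generator emulates.
DEFAULT_COMPOSITION = {"unifocal_frac": 74 / 97, "newly_frac": 16 / 97}

#: Whole-tumor Dice targets per diagnosis status: newly diagnosed cases
#: segment better than postoperative recurrences.
DEFAULT_QUALITY_PROFILE = {"newly_diagnosed": 0.81, "recurrent": 0.70}

#: Per-case Gaussian jitter (SD) on the Dice target, and clip range.
DICE_JITTER_SD = 0.05
DICE_TARGET_RANGE = (0.45, 0.98)


def make_cohort(
    n_cases: int,
    composition: Mapping[str, float] = DEFAULT_COMPOSITION,
    quality_profile: Mapping[str, float] = DEFAULT_QUALITY_PROFILE,
    seed: int = 0,
    grid_shape: Tuple[int, int, int] = (44, 44, 44),
) -> List[CaseRecord]:
    """Reproducible synthetic cohort with planted subgroup effects.

    Each case gets a reference phantom (one focus if unifocal, 2-3 small
    foci if multifocal; recurrent cases may carry a resection cavity) and
    a candidate eroded to a per-status Dice target with per-case jitter.
    Multifocal candidates additionally lose their smallest focus,
    emulating missed satellite lesions, which plants the
    unifocal-better-than-multifocal effect on top of the status effect.
    """
    uf = float(composition["unifocal_frac"])
    nf = float(composition["newly_frac"])
    if not (0 <= uf <= 1 and 0 <= nf <= 1):
        raise ValueError("composition fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_uni = int(round(n_cases * uf))
    n_newly = int(round(n_cases * nf))
    focality = np.array(
        ["unifocal"] * n_uni + ["multifocal"] * (n_cases - n_uni)
    )
    status = np.array(["recurrent"] * n_cases, dtype=object)
    status[rng.choice(n_cases, size=n_newly, replace=False)] = "newly_diagnosed"

    cases: List[CaseRecord] = []
    for i in range(n_cases):
        child = int(rng.integers(2**31 - 2))
        case_rng = np.random.default_rng(child)
        multifocal = focality[i] == "multifocal"
        if multifocal:
            pspec = PhantomSpec(
                grid_shape=grid_shape,
                n_foci=int(case_rng.integers(2, 4)),
                radii=((1.6, 2.2), (2.8, 3.6), (4.2, 5.6)),
                cavity=False,
                seed=child,
            )
        else:
            pspec = PhantomSpec(
                grid_shape=grid_shape,
                n_foci=1,
                radii=((2.8, 3.6), (4.8, 6.2), (7.5, 9.5)),
                cavity=bool(
                    status[i] == "recurrent" and case_rng.random() < 0.3
                ),
                seed=child,
            )
        reference = make_reference_case(pspec)
        base = float(quality_profile[status[i]])
        if base >= 1.0:
            # degenerate perfect profile: candidate is the reference itself
            target = 1.0
        else:
            target = float(
                np.clip(
                    base + case_rng.normal(0, DICE_JITTER_SD),
                    *DICE_TARGET_RANGE,
                )
            )
        candidate = degrade(
            reference,
            DegradationSpec("erode", wt_dice=target, seed=child + 1),
        )
        if multifocal and target < 1.0:
            try:
                candidate = degrade(
                    candidate, DegradationSpec("drop_focus", seed=child + 2)
                )
            except TargetUnattainableError:
                pass  # erosion may already have consumed the smallest focus
        cases.append(
            CaseRecord(
                case_id=f"case_{i:03d}",
                reference=reference,
                candidate=candidate,
                status=str(status[i]),
                focality=str(focality[i]),
            )
        )
    return cases


def write_cohort(cases: Sequence[CaseRecord], out_dir) -> Path:
    """Write a cohort as NIfTI pairs plus a manifest CSV; returns the
    manifest path. The manifest schema matches real-cohort input, so the
    pipeline is substrate-blind."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        ref_name = f"{case.case_id}_ref.nii.gz"
        cand_name = f"{case.case_id}_cand.nii.gz"
        save_mask(case.reference, out_dir / ref_name)
        save_mask(case.candidate, out_dir / cand_name)
        rows.append(
            {
                "case_id": case.case_id,
                "reference_path": ref_name,
                "candidate_path": cand_name,
                "status": case.status,
                "focality": case.focality,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def simulate_rater_pair(
    scores: Sequence[int], seed: int = 0, disagree_prob: float = 0.25
) -> np.ndarray:
    """An n x 2 ordinal rating matrix: rater 1 is the given scores, rater
    2 re-rates each case and moves one point up or down with probability
    ``disagree_prob`` (clipped to the 1-5 scale)."""
    rng = np.random.default_rng(seed)
    r1 = np.asarray(scores, dtype=int)
    steps = rng.choice(
        [-1, 0, 1],
        size=r1.size,
        p=[disagree_prob / 2, 1 - disagree_prob, disagree_prob / 2],
    )
    r2 = np.clip(r1 + steps, 1, 5)
    return np.column_stack([r1, r2])
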