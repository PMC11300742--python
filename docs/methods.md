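# Methods

## Mask model

A case is a pair of co-registered 3D integer label volumes (NIfTI) on a
common grid: a manual reference and a candidate segmentation. Labels are
mutually exclusive — 1 enhancing tumor, 2 abnormal-ADC region, 3
FLAIR-T2 hyperintensity, 0 background — so the stored volume is a
partition of the annotated region; a voxel carries the innermost
compartment it belongs to. Per-sequence compartments are the single
labels; the whole tumor (WT) is the union {1, 2, 3}, following the
BraTS convention of WT as the superset compartment. The package never
resamples or registers: pairs must already share shape, spacing and
orientation (checked to a relative tolerance of 1e-3), which keeps the
evaluation deterministic and independent of any particular
preprocessing tool. Voxel indexing is 0-based; physical coordinates
exist only through the NIfTI affine.

## Overlap metrics

For a compartment with reference set R and candidate set C (voxel
counts; volumes in mm³ are counts times voxel volume, and since both
masks share spacing, Dice is identical in voxel and mm³ units):

* Dice `2|R∩C| / (|R|+|C|)`. Both-empty pairs are defined as Dice 1.0
  (perfect agreement on absence; configurable), one-empty as 0.0.
* missing fraction `|R\C| / |R|`; 0 for an empty reference.
* false-inclusion fraction `|C\R| / |R|`. Normalizing by the reference
  (not the candidate) makes the penalty trigger scale with lesion size:
  the same 2 cm³ of falsely included brain matters more next to a small
  recurrence than next to a large untreated tumor. An empty reference
  with a non-empty candidate returns infinity ("pure false inclusion"),
  which always trips the penalty threshold.

## The two-step 5-point score

The original scale is a radiologist's visual protocol; this package
replaces each visual estimate with a computed quantity so the scale
becomes deterministic and auditable:

* **Step 1 (general consistency).** The gestalt judgment "generally
  consistent with the lesion's morphology across all sequences" becomes
  WT Dice ≥ `consistency_dice_threshold` (default 0.7, the conventional
  cut for good segmentation performance; the gate is inclusive at the
  boundary). The driving compartment is configurable (`WT` union by
  default, `FLAIR_HYPER` restricts to the outer label only, since a
  cohort could reasonably report whole-tumor agreement on the FLAIR
  envelope alone).
* **Step 2 (sequence-by-sequence review).** With
  `M = max(m_ET, m_ADC, m_FLAIR)`: consistent branch 5 / 4 / 3 for
  `M ≤ 0.05` / `M < 0.25` / else; inconsistent branch 3 / 2 / 1 for
  `M < 0.25` / `0.25 ≤ M ≤ 0.5` / `M > 0.5`. "Complete consistency"
  for a 5 tolerates `M ≤ 0.05` rather than exact voxel equality, which
  a visual criterion could never resolve. Boundaries follow the scale's
  wording literally: "less than a quarter" strict, "a quarter to a
  half" inclusive both ends, "more than half" strict. The consistent
  branch can never fall below 3 before the penalty and the inconsistent
  branch never above 3.
* **Penalty.** One point off (floored at the scale minimum of 1 — the
  protocol is silent about penalizing a score of 1, and a floor keeps
  the scale closed) when the WT false-inclusion fraction exceeds
  `penalty_inclusion_threshold` (default 0.10), the automated proxy for
  "erroneously including normal anatomy or artifacts".

All thresholds live in `ScoringConfig`, are validated
(`0 < tol < 1/4 < 1/2 < 1`) and are serialized with every pipeline run.

## Cohort statistics

* Score summaries: mean, SD with denominator n−1 (this is what
  reproduces the published 0.789/0.710 from the 97-case marginal
  counts; the n denominator gives 0.785/0.706 and is therefore wrong
  for that cohort), and fraction scoring ≥ 3.
* Chi-square: Pearson, no continuity correction, all-zero rows/columns
  dropped; degenerate tables raise. This variant reproduces every
  printed p value of the published cohort (0.107, 0.357, 0.367, 0.015,
  0.315) exactly at printed precision.
* Mann–Whitney U: two-sided; exact enumeration of the U distribution
  when the product of group sizes is ≤ 400 and the pooled sample is
  untied, otherwise the normal approximation with tie-corrected
  variance and continuity correction. For untied groups of sizes 5–10
  the approximation tracks exact enumeration within 0.01 on one-sided
  tail probabilities and within 0.01 on two-sided p throughout the
  decision-relevant region (p ≤ 0.2); its worst-case two-sided error
  anywhere is 0.017, at mid-range p near 0.4 where it cannot affect a
  conclusion — and at those sizes the implementation takes the exact
  path anyway.
* ICC(3,1): single-rater, two-way mixed-effects, consistency type,
  `(MS_rows − MS_error) / (MS_rows + (k−1)·MS_error)` via pingouin's
  ANOVA decomposition, with perfect-agreement matrices (zero error mean
  square) short-circuited to 1.0 and zero between-case variance raised
  as undefined. Single-rater rather than average-measures because one
  rater scores the full cohort; the second rater exists only for the
  reliability substudy.
* No multiple-testing correction; each comparison is reported at
  two-sided α = 0.05, matching the analysis this mirrors.
* Quartiles are reported as P25–P75 with linear interpolation
  (numpy default).

## Synthetic phantoms

The real MRI cohort is private, so the pipeline is exercised on
phantoms that reproduce the geometry the score depends on, not the MR
intensities:

* **Reference.** Per focus, three nested ellipsoids (enhancing core ⊂
  ADC-abnormal ⊂ FLAIR envelope) with mildly anisotropic, volume-
  preserving axis ratios (0.8–1.25), labelled as a partition from the
  outside in. Multifocal cases place 2–3 well-separated smaller foci;
  recurrent cases may carry a resection-cavity morphology (the
  enhancing core hollowed to a rim, the regime hardest for real
  models). Ellipsoids are a choice of convenience — nothing in the
  evaluation depends on the exact shape, only on nested compartments
  and focus counts.
* **Degradation.** Candidates are produced by boundary erosion or
  dilation steered by the Euclidean distance transform: a tiny
  deterministic jitter (≤ 1e-4 voxel) breaks distance ties so any voxel
  count is achievable, and the voxel count for a Dice target d follows
  in closed form (for an eroded subset, missing fraction
  m = (2−2d)/(2−d)). Rigid translation and focus dropping cover
  misregistration-like and missed-satellite errors. Achieved overlap is
  verified against the target within a declared tolerance (default
  0.02) or an error is raised.
* **Cohort.** Defaults emulate the published test set: 97 cases, 74
  unifocal / 23 multifocal, 16 newly diagnosed / 81 recurrent; WT Dice
  targets 0.81 (newly) vs 0.70 (recurrent) with per-case Gaussian
  jitter (SD 0.05, clipped to [0.45, 0.98]); multifocal candidates
  additionally lose their smallest focus. A profile target of exactly
  1.0 bypasses jitter and returns the reference itself. All randomness
  flows from one seed per cohort through per-case child seeds; no
  global random state. The default grid is 44³ voxels at 1 mm — small
  enough that a 97-case cohort generates and evaluates in seconds,
  large enough that discretization error on achieved Dice stays well
  inside the 0.02 tolerance.
* **Simulated second rater.** For the reliability substudy, rater 2
  re-rates each case and moves one point up or down with probability
  0.25, clipped to the 1–5 scale.

What passing on phantoms does and does not show: it validates the
metric, scoring and statistical machinery exactly, and the subgroup
analysis' ability to recover planted effects of realistic size at the
published n. It does not validate anything about MR intensity
distributions, annotation variability, registration error, or how a
real model fails; the published cohort's absolute Dice medians
(e.g. 0.729 whole-tumor) and inter-rater ICCs (0.759/0.770) depend on
the private images and are out of scope.

## Known limitations

* Erosion-based degradation removes the outermost shell first, so
  missing volume concentrates in the FLAIR compartment; synthetic score
  distributions are therefore coarser (clustered at 3 and 1) than the
  published cohort's, whose errors spread across sequences. The planted
  Dice effects are unaffected.
* The label partition assumes annotators enforced mutual exclusivity;
  overlapping per-sequence ROIs would need a stacked-channel import
  (interpreting channel index as label) before evaluation.
* The inconsistent branch is capped at 3 before the penalty; whether a
  human rater could award 4 after re-inspection is left out, following
  the protocol's flowchart.
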