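# segqa — quality assessment of multi-sequence glioma segmentations

`segqa` evaluates how well a candidate (e.g. deep-learning) glioma
segmentation matches a manual reference on co-registered multi-sequence
MRI, for radiologists and imaging researchers who need a segmentation
quality readout that goes beyond a single Dice number.

Masks use a 3-label scheme stored as one integer volume per case:
label 1 = enhancing tumor (contrast-enhanced T1), label 2 = abnormal-ADC
region (tumor plus high-ADC edema), label 3 = FLAIR-T2 hyperintensity,
label 0 = background; the whole tumor (WT) is the union {1, 2, 3}.

Three layers build on each other:

1. **Overlap metrics** per compartment `X`:
   `DSC = 2|R_X ∩ C_X| / (|R_X| + |C_X|)`, the missing fraction
   `m_X = |R_X \ C_X| / |R_X|`, and the false-inclusion fraction
   `f_X = |C_X \ R_X| / |R_X|`, where `R` is the reference and `C` the
   candidate.
2. **A two-step 5-point semi-quantitative score** (5 = Excellent …
   1 = Poor) that algorithmizes a radiologist's visual rating: step 1
   gates on general morphological consistency (WT Dice ≥ 0.7); step 2
   scores the worst per-sequence missing fraction
   `M = max(m_ET, m_ADC, m_FLAIR)` — consistent: 5 if `M ≤ 0.05`, 4 if
   `M < 1/4`, else 3; inconsistent: 3 if `M < 1/4`, 2 if
   `1/4 ≤ M ≤ 1/2`, 1 if `M > 1/2` — with a 1-point penalty when
   `f_WT > 0.10`.
3. **Cohort statistics**: score summaries (mean, SD, fraction ≥ 3),
   cross-tabulations with Pearson chi-square, Mann–Whitney U subgroup
   comparisons of Dice (newly diagnosed vs recurrent, unifocal vs
   multifocal), and the inter-rater consistency ICC(3,1).

Because clinical MRI cohorts of this kind are not redistributable, the
package ships a synthetic phantom generator (nested ellipsoidal
compartments, multifocality, resection-cavity morphology) with
controlled degradations that hit prescribed Dice or missing-volume
targets, plus the printed score tables of a published 97-case glioma
cohort as fixed numeric inputs.

## Worked example

```sh
$ segqa reproduce-tables --out-dir results/published_tables
DL mean 3.567 +/- 0.789, 93.8% >= 3; manual mean 3.639 +/- 0.710, 97.9% >= 3; chi-square p 0.107
```

The deep-learning segmentations of the published cohort average
3.567 ± 0.789 on the 5-point scale with 93.8% rated Good or better,
statistically indistinguishable from the manual segmentations
(3.639 ± 0.710, 97.9% ≥ 3; Pearson chi-square p = 0.107).

The same pipeline runs end to end on synthetic phantoms:

```sh
$ python analysis/01_simulate_cohort.py --seed 1
wrote 97 cases to scratch/cohort
focality: {'unifocal': 74, 'multifocal': 23}
status:   {'recurrent': 81, 'newly_diagnosed': 16}
$ python analysis/02_evaluate_cohort.py
97 cases (0 skipped); median WT Dice 0.715 (P25-P75 0.661-0.755)
WT Dice by status: newly_diagnosed: 0.811 (0.779-0.846, n=16), recurrent: 0.704 (0.638-0.730, n=81); Mann-Whitney p = 5.99e-08 (significant)
WT Dice by focality: unifocal: 0.718 (0.679-0.754, n=74), multifocal: 0.605 (0.482-0.763, n=23); Mann-Whitney p = 2.83e-02 (significant)
```

The generator plants better segmentation quality for newly diagnosed
than recurrent disease (Dice targets 0.81 vs 0.70) and drops a satellite
focus in multifocal cases; the Mann–Whitney tests recover both effects
at n = 97. `analysis/03_published_tables.py` and
`analysis/04_interrater_icc.py` cover the printed-table statistics and
the simulated two-rater consistency ICC.

The `segqa` CLI exposes the same steps as subcommands: `simulate`,
`evaluate`, `report`, `reproduce-tables`.

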