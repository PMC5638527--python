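# ppct

Local **p**eri**p**apillary **c**horoidal **t**hickness morphometry and
analysis for circumpapillary OCT circle scans.

The choroid around the optic disc thins in myopia and glaucoma, but a
single averaged peripapillary choroidal thickness (ppCT) hides focal
change. This package quantifies ppCT *locally* — in eight 45° sectors
(T, ST, S, SN, N, IN, I, IT) anchored at the fovea–disc axis of the 3.4 mm
circle scan — together with two measures of how the posterior pole is
configured:

* **Optic disc tilt**, as the amplitude *a* of the least-squares sinusoid
  *y = a·sin(b·x − c)* fitted to the marked RPE trajectory of the unwrapped
  circular B-scan (a circular section of a tilted plane is one sinusoid
  period, so amplitude ∝ tan(tilt));
* **Papillo-macular position (PMP) angle**, the signed angle between the
  horizontal and the disc-center→fovea line (positive = fovea inferior).

On top of the per-eye measurements it runs the cohort-level battery:
Steel–Dwass all-pairs comparison of the eight sectors, per-sector Spearman
correlations and standardized multiple-regression coefficients against
axial length, PMP and tilt, the temporal ppCT ratio (temporal / mean of the
other seven sectors), Mann–Whitney comparisons by parapapillary-atrophy
status, and sex-stratified grids with Fisher-z comparison of correlations.
The nonparametric statistics are implemented from their definitions (see
`docs/methods.md`), with library implementations used as independent
cross-checks in the tests. A seedable synthetic-data generator produces
cohort tables and boundary traces with programmed effect structure, so the
whole chain is testable end to end without clinical data.

Intended users: researchers working with circumpapillary OCT morphometry
who need reproducible sector-level thickness analysis, and anyone needing a
reference implementation of the Steel–Dwass test or the sine-amplitude
disc-tilt metric.

## Worked example

```python
from ppct import (CohortConfig, TraceConfig, generate_cohort, generate_trace,
                  build_sector_map, measure_ppct, measure_tilt, temporal_ratio,
                  apply_eligibility, run_study)
from ppct.synthetic_data import landmarks_from_pmp

cohort = generate_cohort(CohortConfig(n_eyes=114, seed=1))
eye = cohort.iloc[0]

# forward-model one eye's scan, then measure it back
trace, marked = generate_trace(eye, TraceConfig(), seed=100003)
sectors = build_sector_map(landmarks_from_pmp(eye.pmp_deg))
thickness = measure_ppct(trace, sectors, window_deg=5.0)
fit = measure_tilt(marked)
print(f"T sector {thickness['T']:.1f} um (programmed {eye.ppct_t:.1f}), "
      f"tilt {fit.a:.1f} px (programmed {eye.tilt_px:.1f}), "
      f"ratio {temporal_ratio(thickness):.3f}")

# cohort-level analysis
eligible, _ = apply_eligibility(cohort)
report = run_study(eligible)
print(report.sector_summary.round(1).head(3))
r = report.association_grid.set_index(["sector", "predictor"])
print(f"Spearman r (T vs axial length): {r.loc[('T','axial_length'),'spearman_r']:.2f}")
```

Output:

```
T sector 85.3 um (programmed 85.1), tilt 64.9 px (programmed 65.5), ratio 0.642
  sector   mean    sd
0      T  165.1  65.0
1     ST  181.7  59.0
2      S  189.4  54.5
Spearman r (T vs axial length): -0.46
```

The measured sector value and tilt invert the forward model to within a
micrometre and less than a pixel; the cohort shows the programmed
pattern — thinner choroid in longer eyes everywhere, with tilt mattering
only temporally.

The same chain is scriptable from the shell (`ppct simulate`,
`ppct measure`, `ppct analyze`) and is walked through narratively by the
numbered drivers in `analysis/` (simulate → measure → analyze → replicate
across seeds), which write their tables under `results/`.

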