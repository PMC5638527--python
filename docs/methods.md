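# Methods

This note documents the models, conventions, numerical choices and
limitations behind `ppct`. The package quantifies three per-eye measures on
circumpapillary OCT circle scans — local peripapillary choroidal thickness
(ppCT), optic disc tilt, and papillo-macular position (PMP) angle — and runs
the cohort-level statistical analysis relating them.

## Geometry of the circle scan

The scan is a 3.4 mm-diameter circle centered on the optic disc, sampled at
1024 A-scans and unwrapped into a linear B-scan. Sector anchoring follows
the fovea–disc axis: the temporal (T) site is the intersection of the line
from the disc center to the fovea with the scan circle; the remaining seven
sites (ST, S, SN, N, IN, I, IT) follow at 45° intervals, superior side
first (TSNIT unwrapping).

Conventions, chosen once and used everywhere:

* **Image frame.** Fundus-photograph screen coordinates, y increasing
  inferiorly, units µm.
* **PMP angle.** Signed angle between the horizontal through the disc
  center and the disc→fovea line, positive when the fovea is inferior;
  open range (−90°, 90°). A fovea vertically aligned with the disc is
  rejected as degenerate. PMP is kept signed in all analyses (observed
  cohort ranges straddle zero).
* **Scan angular frame.** 0° at the temporal horizontal axis, increasing
  toward superior; laterality-aware, so left-eye sector names keep their
  anatomical meaning and a mirrored left eye produces the same sector map
  as its right-eye counterpart. The T anchor sits at −PMP in this frame.

## Optic disc tilt (sine-amplitude metric)

A circular section through a locally planar, tilted RPE is an ellipse;
unwrapped, it is one period of a sinusoid. Tilt is therefore measured as
the amplitude `a` of the least-squares fit

    y = a · sin(b·x − c)

to manually marked RPE points after recentering (x shifted so the scan
midline is 0; y shifted by its mean — mean-centering rather than
midline-of-extremes, a choice that is exact for symmetric sampling of a
full period). Numerical choices:

* `b` is fitted but bounded to [0.5, 2] × 2π/scan-width: a tilted plane
  produces exactly one period per circle, and an unbounded frequency lets
  noise lock onto harmonics.
* Initialization: `a₀ = (max y − min y)/2`, `b₀ = 2π/scan-width`, phase
  seeded from the first Fourier component and multi-started at four
  quadrant offsets; the best-cost solution is kept. Deterministic.
* Amplitude is reported non-negative (a sign flip is absorbed as a π phase
  shift); a flat trace returns `a = 0` with `converged = True`; optimizer
  failure is flagged rather than raised.
* Units: axial **pixels**, the native unit of the marking procedure. The
  forward model `amplitude = r·tan(tilt)/axial_scale` (scan radius r =
  1700 µm, default axial scale 2.6 µm/px) converts a geometric tilt angle
  to the expected amplitude and is used by the generator and in recovery
  checks. The number of marked points per eye (default 64) and the axial
  pixel pitch are configuration parameters; both defaults are assumptions,
  not device constants.

## Sector thickness and the temporal ratio

Per A-scan, choroidal thickness is `(z_csi − z_rpe) · axial_scale` — the
axial distance from the outer RPE boundary to the sclerochoroidal
interface. Axial distance approximates the perpendicular distance and
coincides with it where the boundaries run parallel to the circle; defining
surface normals from a 1-D trace is deliberately avoided. A sector value is
the **median** over A-scans within ±`window_deg` of the sector center
(robust to marking noise); `window_deg = 0` (default) reads the single
nearest A-scan, emulating point-wise manual grading. Both behaviours are
exposed because graded datasets differ in this respect.

The temporal ppCT ratio is the T-sector value divided by the mean of the
other seven sectors — a per-eye asymmetry index that is < 1 when the
temporal choroid is relatively thinned.

## Statistical battery

All procedures are implemented from their definitions (library routines are
used only as independent cross-checks in the tests):

* **Spearman correlation**: Pearson correlation of mid-ranks; two-sided p
  from the t approximation on n−2 df (an exact-enumeration path would only
  matter below n ≈ 10 and the pipeline operates at n ≈ 100).
* **Standardized multiple regression**: OLS on z-scored outcome and
  predictors (axial length, PMP, tilt entered simultaneously); betas are
  standardized coefficients, p from two-sided t on n−p−1 df; rank-deficient
  designs raise a collinearity error.
* **Mann-Whitney**: two-sided p from the normal approximation with
  tie-corrected variance and 0.5 continuity correction; an exact
  enumeration method (tie-safe, all C(m+n, m) assignments) is provided for
  small samples.
* **Steel-Dwass all-pairs comparison**: for each pair of groups, the
  rank-sum z on that pair's pooled mid-ranks (same tie and continuity
  treatment as Mann-Whitney, so the k = 2 case reduces exactly to it);
  adjusted p refers √2·|z| to the studentized range of k groups with
  infinite degrees of freedom. That tail probability is evaluated by direct
  trapezoidal quadrature of `k∫φ(z)[Φ(z)−Φ(z−q)]^{k−1}dz` on a fine grid
  (absolute error < 1e−6, vectorized in q). Simulated family-wise type-I
  error under three equal normal groups is ≈ 0.045 at α = 0.05.
* **Fisher z comparison** of two independent correlations, for the
  between-sex contrast.

Two fidelity choices are worth flagging: the sector comparison treats the
eight sector columns as independent groups although they are within-eye
repeated measures, and the 8 × 3 association grid is read at two-sided
p < 0.05 with no multiple-testing correction. Both mirror the analysis
design this pipeline reproduces; a mixed-effects or corrected variant is
out of scope.

The pipeline's eligibility filter retains right eyes of adults aged 20–40
with BCVA ≤ 0.1 logMAR, IOP ≤ 21 mmHg (bounds inclusive) and no exclusion
flag, logging every triggered rule per excluded eye. Left eyes can be
mirrored into the right-eye frame instead of excluded; sector names are
anatomical, so mirroring is a relabelling.

## Synthetic data generator

The generator defines the study conditions for every test; it emulates a
young, predominantly myopic cohort of 114 right eyes:

* axial length: truncated normal, 25.46 ± 1.43 mm on [22.38, 30.42];
* PMP: normal, 5.43 ± 3.47°; age: truncated normal 25.8 ± 3.9 y on [20, 40];
* refractive error: linear in axial length (−2 D/mm) plus noise, centered
  at −4.79 ± 3.31 D;
* disc tilt: 53.08 ± 23.93 px, weakly positively coupled to axial length
  (correlation 0.05 by default — longer eyes are slightly more tilted;
  the coupling strength is a free parameter);
* sector ppCT: per-sector baseline (T 166.87 … N 190.62 µm, the emulated
  population means) plus centered linear effects of axial length
  (negative, all sectors), PMP (positive, all sectors) and tilt (negative,
  **T and IT only**), plus residual noise. Predictors are centered at their
  population means so cohort sector means equal the baselines.
* parapapillary atrophy: Bernoulli with log-odds increasing in axial
  length, baseline prevalence 0.69.

Effect coefficients are not hand-set: `calibrated_effects` derives them
analytically from target marginal correlations (axial length −0.28 to
−0.42 across sectors, PMP +0.26 to +0.36, tilt −0.32 in T and IT) given
the predictor SDs, the tilt–axial-length coupling, and the requirement that
each sector's total SD equal its configured value. The tilt targets sit at
the detectable end of the plausible range because the pattern the cohort is
built to exhibit — tilt significant in exactly T and IT at n = 114 — is a
threshold property: detection probability at α = 0.05 is monotone in effect
size, while six null sectors each carry a 5% false-positive rate. Even so
the exact pattern appears in only ~80% of replicate cohorts; that ceiling
is a property of testing eight sectors at a fixed α, not of the
implementation, and the replication tests are set accordingly (majority of
20 seeds).

Residual noise has a shared per-eye component (85% of residual variance by
default): choroidal thickness is strongly spatially correlated within an
eye, and the shared term reproduces that while also making the sector-wise
sampling errors realistically dependent. The generator's joint structure is
linear-Gaussian throughout — an assumption, since only marginal summaries
and pairwise associations of the emulated population are known.

Traces follow the forward geometric model: `z_rpe(i) = offset + tilt ·
sin(2πi/n − c) + noise` with a random per-eye phase; the sclerochoroidal
interface lies below the RPE by the eye's angular thickness profile
(periodic cubic spline through the 8 sector anchors) plus independent
interface noise (1.5 px default), so the measured thickness is not a
trivial constant difference. Marked RPE points sample the noisy trace
uniformly around the circle (uniformity keeps the sampled sinusoid
mean-zero, so recentering introduces no offset bias) with additional
2 px marking noise. Default boundary noise is 2 px ≈ 5 µm, a realistic
manual-grading jitter. What the generator does **not** emulate: speckle,
vessel shadowing, segmentation failures, scan decentration, axial-length-
dependent transverse magnification, and any non-linear or interaction
effects; passing tests therefore demonstrate correctness of the chain on
data satisfying the model's assumptions, not robustness to real-device
artefacts.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each property is informative: 114-eye
cohorts (the emulated study scale) for the pipeline and pattern-replication
checks across 20 seeds; 500 replicates for noisy sine-fit recovery; 2000
simulations for the Steel-Dwass type-I calibration; 10⁴ shuffles for the
permutation reference; full enumeration at 4+4 for the exact Mann-Whitney
oracle.

## Known limitations

* Exact reproduction of a graded clinical dataset's printed statistics
  requires that dataset; the reproduction test here runs the pipeline on a
  synthetic stand-in table and verifies its summary and ratio statistics to
  two decimals against independent computation.
* Thickness is axial, not boundary-normal; the difference grows where the
  interfaces are steeply inclined to the A-scan direction.
* The sine model assumes a locally planar RPE; strongly curved or
  staphylomatous posterior poles violate it (such eyes are excluded by the
  eligibility rules the pipeline applies).
* The tilt metric is in device pixels; comparisons across devices need the
  axial-scale conversion.
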