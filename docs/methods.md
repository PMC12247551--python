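# Methods

This note documents the models implemented in `brainstates`, the synthetic
cohort that exercises them, and the numerical and design choices a
maintainer would want to know about.

## Scientific setting

Cerebral small vessel disease leaves a radiological footprint of white
matter hyperintensities (WMH), and has been linked to a *dedifferentiation*
of large-scale functional brain dynamics: people with a higher WMH burden
spend less of their resting-state scan in the two dominant brain states
related to the default mode network (DMN), and less time in those states
accompanies slower executive performance (Trail Making Test part B,
TMT-B).  The package re-implements that analysis chain as a reusable,
tested pipeline:

1. **Brain states** are estimated by co-activation-pattern (CAP) analysis:
   every participant's parcel-level BOLD volumes are pooled into one
   `n_parcels × Σᵢ Tᵢ` feature matrix and the volumes are clustered with
   k-means (k = 5) under correlation distance `d(x, y) = 1 − r(x, y)`.
2. **Fractional occupancy** `FO_{s,i}` is the share of participant *i*'s
   retained volumes assigned to state *s*; `fo_high` is the arithmetic mean
   of the FOs of the two states with the highest cohort-mean occupancy.
3. **WMH burden** comes from binary lesion masks: 26-connected components
   below 30 voxels are discarded, surviving lesion voxels are split into
   periventricular (distance to the ventricular system ≤ 10 mm) and deep
   (> 10 mm) compartments, and volumes are reported in mL.
4. **Hypothesis models.**  The primary model is a fixed-dispersion beta
   regression, `logit E[fo_high] = β₀ + β_w ln WMH⁺ + β_z 1{WMH=0} +
   β_a·age + β_f·female`, reported as an odds ratio per interquartile ratio
   (Q3/Q1) of the non-zero WMH distribution.  The secondary model is a
   Gamma GLM with log link, `ln E[TMT-B] = γ₀ + γ_fo·fo_high + …`, reported
   as a multiplier per 5 percentage points of occupancy.  Binomial GLMs
   with logit link cover bounded cognitive scores.
5. **Robustness and design.**  A multiverse grid crosses 9 confound
   regression variants × 9 parcellations × 3 WMH compartments (243
   scenarios; 81 when only total volume is analysed), flagging nominal
   significance without any multiplicity correction.  A bootstrap power
   analysis resamples a reference cohort at a ladder of sample sizes and
   records how often the primary null is rejected.

## The beta regression

The response density is

    f(y; μ, φ) = Γ(φ) / (Γ(μφ) Γ((1−μ)φ)) · y^{μφ−1} (1−y)^{(1−μ)φ−1},

with `logit μᵢ = xᵢᵀβ` and a single precision φ shared across
observations.  Estimation maximizes the log-likelihood over `(β, ln φ)`
(the log keeps φ positive) with the analytic score, an L-BFGS-B pass and a
Newton polish using a numerically differentiated observed information; the
polish routinely drives the gradient below 1e-10, which is what makes the
1e-6 agreement with independent optimizers attainable.  Standard errors
are Wald, from the inverse observed information; confidence intervals are
two-sided at α = 0.05, matching the reporting convention of the Gamma and
binomial fits (which delegate to IRLS with Pearson dispersion).  Starting
values come from a logit-scale least-squares fit and a moment estimate of
φ.

Outcomes exactly at 0 or 1 are a hard error: the likelihood is undefined
there, and silently nudging data would change the estimand.  An explicit
`shrink_boundary` option applies the usual `(y(n−1) + ½)/n` compression
when the caller asks for it.

WMH volumes enter as `ln` of the non-zero volume; exact zeros keep the
value 0 and are flagged by a binary indicator.  The indicator is included
only when zeros are present — with none it is a constant column and is
dropped, which leaves every other estimate untouched (tested).

Effect sizes are monotone transforms of link-scale coefficients —
`exp(β·ln(Q3/Q1))` for the WMH odds ratio, `exp(β·k/100)` for a k-percentage
-point occupancy multiplier, `exp(β·10)` for age per decade — and never
alter p-values.  Occupancy is modelled on the proportion scale; the choice
is invariant under the reporting transform.

## Correlation-distance k-means

For vectors standardized to zero mean and unit norm,
`1 − r(x, y) = ‖x̃ − ỹ‖²/2`.  All pooled volumes are standardized once and
Lloyd iterations run in that geometry; centroids are re-standardized after
every mean update so they remain correlation prototypes (this
re-standardization is adopted as the canonical behaviour here; clustering
packages differ on it and it is rarely documented).  Defaults: 20 restarts
with k distinct volumes sampled uniformly per restart, 300 iterations
maximum, inertia tolerance 1e-6 — the method itself does not prescribe
these, so they are package defaults, stated as such.  Ties in assignment go
to the lowest state index; an emptied cluster is re-seeded from the point
farthest from its current centroid.  Volumes that are flat across parcels
have no defined correlation and are rejected at input validation.

On tiny inputs (when the number of distinct k-subsets of points is small)
every distinct initial centroid subset is tried deterministically instead
of random sampling; in testing this always reached the exhaustive-
enumeration optimum on ≤ 8-point instances, whereas purely random restarts
occasionally stalled in a local minimum.

States are ranked by cohort-**mean** FO (medians are also reported); ties
prefer the lower state index.  `fo_high` is the arithmetic mean of the top
two per-participant FOs — an option to use the sum exists but is
non-default, and the mean is what the intercepts of the occupancy models
(≈ 0.24 on the response scale) refer to.

## WMH quantification conventions

* 26-connectivity for components (face, edge or corner contact).
* The size filter precedes the distance partition.
* The partition is voxel-wise, so one lesion may straddle both classes.
* Distances are voxel-center to nearest ventricle voxel center via an
  exact Euclidean distance transform honouring anisotropic spacing; a
  voxel exactly at the cutoff counts as periventricular (the boundary case
  is otherwise unassigned in the usual "<10 mm / >10 mm" phrasing).
* Conservation (`periventricular + deep = total`) is asserted to 1e-9 mL.

## The synthetic cohort generator

The generator (`brainstates.synth`) produces cohorts with the statistical
structure the analysis assumes, with known ground truth.  Defaults encode
the study conditions of a population cohort of 1651 middle-aged to elderly
participants:

| quantity | default | rationale |
|---|---|---|
| age | median 66, IQR 59–72 (piecewise-linear quantile function) | cohort marginals; only median/IQR targeted |
| sex | 57% male | cohort proportion |
| education | integer, median 13, IQR 12–16 | cohort marginals |
| WMH volume | zero-inflated log-normal; median 1.05 mL, Q3/Q1 = 5.06, P(0) = 9/1651 | reported quartiles; log-normal family assumed from the log transform used in analysis, checked by KS test on logs |
| state targets | mean FO (0.248, 0.240, 0.184, 0.168, 0.160) | two high DMN-related states ≈ 24–25%, three low states; entries must sum to 1 |
| occupancy link | OR 0.95 per interquartile ratio of WMH | smallest effect of interest in the study design |
| precision φ = 80 | realized `fo_high` IQR ≈ 20.8–28.0% once label-count noise at T ≈ 112 volumes is added | calibrated once against the cohort's FO dispersion and fixed |
| TMT-B | Gamma, shape 6, median 83 s; multiplier 0.98 per 5 pp FO | cohort median/IQR; reported effect size |
| retained volumes | uniform 100–125 per participant | scan length after volume censoring |
| nuisance effects | age OR 1.04/decade, female OR 1.12 on occupancy; age 1.18/decade, education 0.97/yr, sex 0.99 on TMT-B | adjusted estimates of the cohort analysis |
| TMT missingness | 9.8% | observed missing-data rate; exercises the complete-case rule |

Per participant the generator draws the mean high-state occupancy
`mᵢ ~ Beta(μᵢφ, (1−μᵢ)φ)` with `logit μᵢ` affine in centered ln WMH and
covariates, then assigns each retained volume independently: the two high
states get probability `mᵢ` each and the remaining mass is split over the
low states in proportion to their targets.  BOLD volumes are the planted
state centroid (±activation on one of seven canonical networks; the two
high states activate and suppress the default network) plus i.i.d.
Gaussian noise.  Binary covariates enter the generative linear predictors
centered, so marginal means stay on target.

What the generator deliberately does **not** emulate: temporal
autocorrelation or Markovian dwell times (the analysis uses occupancy
only, which is order-invariant; a transition-matrix hook is reserved),
spatial noise correlation, scanner drift or motion artefacts, and residual
confound structure after de-noising.  Passing tests therefore demonstrate
the correctness and calibration of the estimation chain under the assumed
generative structure, not robustness to real-data artefacts — the
multiverse variants (noise scaling, volume censoring, a spatially loaded
shared component standing in for residual global signal) probe only the
named, parameterized departures.  A uniform global shift would be
invisible under correlation distance, which is why the shared component
carries a random spatial loading.

## Calibration and problem sizes

Problem sizes in the test suite and `scripts/acceptance.py` are the
package's own choices:

* **CI coverage**: 100 replicates at n = 1500 with generator defaults;
  both hypothesis models must cover their generative effects in ≥ 90.
  These replicates take occupancies directly from the generator's label
  sequences; the clustering stage reproduces those labels with > 99%
  agreement at default noise and is validated end-to-end in a separate
  single full-scale run (n = 1651) plus planted-recovery tests, so the
  replicated coverage study isolates the inferential stage.
* **Type-I error**: 2000 null simulations at n = 400; rejection rate must
  lie within 0.05 ± 0.01.
* **Bootstrap power null calibration**: resamples inherit the reference
  cohort's empirical association, so rejection ≈ α under a null generator
  only when the reference cohort is much larger than the resample size;
  the calibration draws n = 300 resamples from a null cohort of n = 20000.
  Against a finite null cohort the curve correctly reports power against
  that cohort's sampling noise — that is a property of the bootstrap, not
  a defect.
* **Multiverse**: the full 9 × 9 × 3 grid is executed on a compact cohort
  (40 participants, 30 volumes) — scenario bookkeeping and robustness
  counting do not require full-scale data.

## Known limitations

* The beta regression is fixed-dispersion only; variable-dispersion or
  mixed-effects extensions are out of scope.
* Wald intervals throughout; profile-likelihood intervals are not
  implemented.
* Missing covariates are handled by complete-case analysis only.
* WMH segmentation itself (and all MRI preprocessing) is upstream of this
  package: inputs are binary masks and de-confounded parcel time series.
* The per-participant label-sequence generator is i.i.d. given occupancy;
  dwell-time statistics simulated from it are not meaningful.
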