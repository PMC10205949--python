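# Methods

This note documents the models, estimators, parameters and numerical
choices behind `extravakit`, and what the synthetic-data tests do and do
not establish about real recordings.

## Signal model and metric estimators

A monitored administration yields two H\*(10) dose-rate series at
nominally 1 Hz: the injection arm shows a sharp peak as the ~10 s bolus
passes the proximal sensor, then relaxes to a plateau; the contralateral
arm rises smoothly as tracer disperses systemically.  The analysis
window is cut from one minute before to nine minutes after the
injection-arm peak; at least 120 s of post-peak data are required, and
windows shorter than the nominal nine minutes are flagged truncated.

**Smoothing.**  Curves are denoised by discrete Gaussian-kernel
convolution (kernel truncated at ±4σ and renormalised; boundary mode
`reflect`, alternatively `nearest`).  The default σ = 3 s suppresses
sample-to-sample detector noise by a factor √Σw² ≈ 0.31 while leaving
the minute-scale plateau structure intact.  σ = 0 disables smoothing.

**Peak.**  DR<sup>in</sup><sub>max</sub> is the maximum *raw* sample
(ties broken at the first occurrence).  The bolus peak is only seconds
wide, so any smoothing attenuates it; the raw maximum is also what a
dose-rate meter displays.  Under multiplicative noise the raw maximum
of a sharp (cusp-like) peak is dominated by the single true-peak
sample, so it is close to unbiased; this ceases to hold for broad,
flat-topped transits.

**Plateau.**  Stability is declared when, for 60 consecutive seconds,
the smoothed arm-difference signal ΔR changes by at most 15 µSv/h
between consecutive samples.  The onset t\* is the *start* of the first
qualifying window, and the search begins at the injection peak: the
raw rule alone can fire at the smoothed-peak crest, where the slope
momentarily vanishes, which would fold part of the peak into the
plateau mean.  In single-detector mode (no contralateral curve) the
same rule is applied to the smoothed injection curve itself; the
ΔR-family metrics are then unavailable and the classification is
flagged as resting on Δp<sup>in</sup><sub>NOR</sub> alone.

The 15 µSv/h tolerance is an absolute device-level constant.  This has
a consistency consequence: at plateau level P with relative noise ε the
smoothed consecutive differences scatter with SD ≈ 0.23·0.31·εP, so for
ε = 10% the rule is reliably satisfiable only for plateaus up to a few
hundred µSv/h.  The method is therefore calibrated for detectors worn
*near*, not on, the injection site.

**Assembly.**  DR<sup>in</sup><sub>mean</sub> averages the smoothed
injection curve from onset to window end (the published definition
fixes no end point; using the whole remaining window minimises
variance).  ΔR is evaluated exactly 360 s after onset; if the record
ends earlier the last sample is used and the result flagged.  t\* is
reported relative to the peak.  The identities
Δp = DR<sub>max</sub> − DR<sub>mean</sub>,
Δp<sub>NOR</sub> = Δp/DR<sub>max</sub> and
ΔR<sub>NOR</sub> = ΔR(6′)/DR<sub>max</sub> hold exactly.

## Classification

Thresholds come from least-squares fits of
`outcome = 1/(1+exp(−k(metric−a)))` to 0/1 outcomes (1 =
extravasation), matching the curve-fitting practice the thresholds were
originally derived with, rather than logistic regression by maximum
likelihood.  The fit uses multi-start Levenberg–Marquardt (slope seeds
±{1,4}/SD, location seeded at the class-mean midpoint); with a 0.5
decision limit the fitted `a` is the threshold.  On well-separated
cohorts the least-squares optimum drives k large and places `a` near
the maximum-margin midpoint of the class gap — the fitted `a` is then
init-robust but its exact value depends on the realised gap, which is
why threshold-recovery checks use the median over hundreds of seeded
cohorts.  A value exactly at `a` does not flag extravasation.

The three-class rule is: extravasation if Δp<sub>NOR</sub> < a(Δp) *or*
ΔR(6′) > a(ΔR) (OR favours sensitivity; disagreements are recorded);
otherwise abnormal if either metric leaves the normal band.  The
normal/abnormal boundary is not part of the fitted-threshold analysis;
it defaults to the normal-class mean ± 2 SD (Δp<sub>NOR</sub> < 0.79 or
ΔR > 46 µSv/h) and is configurable.

The cohort-size planner for a one-sided AUC superiority test uses the
Hanley–McNeil exponential-approximation variance at both hypotheses,
with positives entering as prevalence·n; the reference design (AUC 0.80
vs 0.90, α = 0.05, power 0.90, prevalence 0.06) gives n ≈ 840–1000
patients depending on the variance-formula variant.

## Dosimetry and SUV correction

Residual activity: `A_RS = mean concentration × volume ×
2^(t_up/T_½)`, with t_up the uptake time (default 60 min) and T_½ the
¹⁸F *physical* half-life, 109.771 min — a deliberately conservative
choice, as no patient-specific clearance curve exists.  Segmentation is
a global relative threshold (10%/40% of the maximum voxel) without
connected-component filtering; manual VOI choice is emulated by
cropping the grid first.  Dose factors are tabulated inputs
(unit-density-sphere model, mGy/MBq); the sphere mass equals the
segmented volume at water density, and factors are interpolated
log-log, since sphere S-values are near power-law in mass
(extrapolation outside the table is refused unless requested).  Self-
dose is `A_RS[MBq] × factor / 1000` Gy.

SUV correction: subtracting the residual activity from the SUV
denominator gives `coefficient = 1/(1 − A_RS/A_in) = 1 + SUV_%CR/100`,
exactly 1 at zero residual and strictly increasing in the residual
fraction.  This algebra reproduces the four published case
coefficients {1.063, 1.004, 1.003, 1.021} from the published residual
percentages to the printed precision.  The coefficient-vs-metric trend
is summarised by `coefficient = 1 + exp(−a(metric−b))`, fitted by
multi-start nonlinear least squares; R², RMSE and NRMSE (RMSE divided
by the population SD of the observed coefficients) are reported.  The
published anchor point (the cumulative non-extravasation point at
coefficient 1) has an unrecoverable abscissa; we default it to the
non-extravasation class mean of the metric, so R² is reproducible
(≥ 0.95 on the four-point fit) but the published RMSE values are not.

## Synthetic data

The generator emits closed-form noiseless curves plus multiplicative
Gaussian noise (CV 10% by default, per sample, clipped at zero), with
a full `GroundTruth` record from which the noiseless curves can be
rebuilt exactly.

* Injection arm: quartic ramp over a rise time drawn uniformly from
  8–12 s (the bolus-push duration), an exponential washout with
  τ = 2 s from the cusp-like peak, then a flat plateau; the abnormal
  class adds a slow plateau decay (τ = 1500 s).
* Contralateral arm: saturating exponential rise (τ = 45 s) after a 5-s
  transit delay.
* Per-class draws: Δp<sub>NOR</sub> targets N(0.91, 0.06) /
  N(0.77, 0.23) / N(0.44, 0.05) (clipped to [0.05, 0.97]); ΔR at six
  minutes targets N(24, 11) / N(150, 22) / N(390, 26) µSv/h; the
  contralateral plateau is the injection plateau minus the ΔR draw,
  floored at 20 µSv/h (the peak is raised if needed, preserving both
  targets).
* Peak amplitudes: lognormal, median 850 µSv/h, log-SD 0.12.  No
  clinical peak amplitudes are published; the scale is set where the
  absolute 15 µSv/h stability rule remains attainable at extravasation
  plateau levels under 10% noise (see above), i.e. inside the method's
  own operating envelope.
* Cusp sharpness matters: the quartic ramp and 2-s washout make
  neighbours of the true peak 1.5–3 noise-SD lower, which keeps the
  raw-maximum estimator of DR<sub>max</sub> near-unbiased at 10% noise.
* Cohorts derive per-session seeds from the master seed via
  `SeedSequence.spawn`, so any subset regenerates identically.
* Phantoms: the depot is a uniform sphere (radius 2.5·σ_spot) blurred
  with a 0.5·σ_spot Gaussian — a flat-topped, PSF-blurred pool whose
  40% isocontour recovers ≳ 75% of the activity, consistent with
  threshold segmentation being meaningful clinically; a pure Gaussian
  profile (for which the 40% contour captures only ~39%) is available
  as an option.  Grids are normalised so the integrated activity
  matches the request exactly.

**What the synthetic tests show** — that the estimators recover the
generator's ground truth without material bias under the published
class statistics and noise level, and that the decision thresholds
refitted on such cohorts reproduce the published values within their
stated uncertainties.  **What they do not show** — robustness to
patient motion beyond stationary multiplicative noise, to detector
repositioning, to non-exponential venous-retention kinetics, or to
class statistics different from the published cohort (n = 69, only 4
extravasations).

## Numerical choices and degenerate inputs

* Curves must have ≥ 2 samples, strictly increasing times, non-negative
  values; non-uniform sampling is rejected by the smoother and plateau
  detector (resampling first interpolates both arms linearly onto an
  integer-second grid spanning their overlap, which must be ≥ 120 s).
* Raw dual-detector sessions are expected to overlap ≥ 600 s; this is
  checked at pipeline entry rather than in the container type, so
  windowed or deliberately short fixtures remain representable.
* Logistic and correction-curve fits clip exponents at ±500, use
  multi-start over sign and scale, and report non-convergence and
  degenerate inputs (single-class outcomes, all-equal coefficients) as
  errors rather than returning garbage.
* Reports are JSON with sorted keys and shortest round-tripping float
  reprs: repeated runs are byte-identical and parse-back is lossless;
  session CSVs round-trip bit-exactly (floats re-parsed with
  correctly-rounded parsing).
* All problem sizes used in tests and in the acceptance script (500
  threshold-refit replicates, 200-session recovery cohorts) were chosen
  to put the Monte-Carlo error well below the tolerances being checked
  while keeping a full run in minutes on one core.

## Known limitations

* The plateau rule's absolute tolerance couples the method to detector
  placement and amplitude scale (see above); a relative tolerance would
  decouple it but would no longer reproduce the published procedure.
* Dose factors assume a spherical, uniformly filled, unit-density
  depot; real infiltrates are neither spherical nor uniform, and no
  voxel-level dose calculation is attempted.
* Physical decay only: any biological clearance makes the reported
  A_RS and self-dose upper bounds.
* The normal/abnormal band and the correction-curve anchor abscissa are
  package choices (documented defaults), not published quantities.
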