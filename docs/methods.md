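# Methods

## Measurement model

A recording session follows a five-phase protocol of nominally one minute
each: resting baseline; thigh-cuff inflation to 60 mmHg (≈10 s ramp) and
hold; rapid deflation and recovery; inflation to 100 mmHg and hold;
deflation and recovery.  Sub-arterial cuff pressure blocks venous return
while arterial inflow continues, so blood pools distally and total
hemoglobin (HbT) in the instrumented foot angiosomes rises toward a
plateau.  Each patch carries four laser diodes (670, 780, 808, 850 nm) and
two photodiodes at 1.6 cm ("near") and 2.5 cm ("far"); the shared
acquisition bus fixes the frame rate by patch count
(1 → 10.24, 2 → 5.12, 3 → 3.41, 4 → 2.56 frames/s).

Reconstruction uses the modified Beer–Lambert law (MBLL).  With
baseline-referenced optical density
`dOD(λ,t) = −log10(V(λ,t) / V̄₀(λ))` (V̄₀ the mean voltage over the
central 40 s of the baseline phase), the concentration changes solve, per
frame, the overdetermined linear system

    dOD(λ) = [ε_HbO2(λ)·ΔHbO2 + ε_Hb(λ)·ΔHb] · d · DPF(λ)

by least squares over the available wavelengths.  Extinction coefficients
come from a standard published compilation of hemoglobin spectra; the
differential pathlength factor defaults to 6.0 at all wavelengths and the
far detector (d = 2.5 cm) is used by default, both configurable.  MBLL
with a wavelength-independent DPF recovers *changes* relative to baseline,
not absolute concentrations; that is sufficient here because the plateau
time depends only on curve shape.  A full photon-transport reconstruction
is out of scope by design.

## Plateau-time extraction

For one inflation trial (window: inflation onset through the end of the
post-deflation minute) the plateau time (PT) is the interval between the
two points where the HbT curve crosses 90% of its maximum.  Implementation
details, each configurable:

- **Threshold reference.** The 90% level is referenced to the
  pre-inflation resting level (median over the 5 s before onset; the first
  in-window sample if no earlier data exist):
  `thr = y₀ + 0.9·(HbTmax − y₀)`.  This makes PT invariant under positive
  affine rescaling of the curve and robust to the curve already rising at
  the first in-window frame.
- **Crossing times** are located by linear interpolation between the
  bracketing frames (the sampling grid gives no sub-frame information
  otherwise).
- **Smoothing.** A centered moving average, default 5 frames, is applied
  before extraction (1 disables it).  The plateau level `HbTmax` is read
  from a more heavily smoothed copy (≈4 s window) whenever smoothing is
  active: the sample maximum of a noisy series is biased upward, and that
  bias shifts the threshold; the plateau is flat enough that the heavier
  window is harmless.  Crossings always come from the lightly smoothed
  curve.
- **Right-censoring.** If the curve never falls below the threshold before
  the window ends, the down-crossing clamps to the window end and a
  censored flag is set, preserving the qualitative distinction between a
  sustained plateau and a curve still rising at deflation.
- **Degenerate input.** A flat or non-rising curve yields an explicitly
  undefined feature with a diagnostic, never a silent zero.
- A trial counts as *saturated* when the curve stays within 10% of its
  maximum for at least 5 s contiguously.

Patch PT is the mean of the two trial PTs (one defined trial is used with
a warning; none propagates as missing).  Per patient and time point, the
general (Gen) feature is the mean over all patches and the localized (Loc)
feature resolves against the arterial tree of the foot
(anterior tibial → dorsalis pedis; posterior tibial → medial and lateral
plantar): the patch on the ulcer's angiosome, else the mean of patches
below the affected artery, else the patch directly above, else missing.
Classification uses time-point differences, later minus earlier: PostPre,
FU1Pre and FU1Post, with FU1Post = FU1Pre − PostPre by construction.

## Statistics

- **Redundancy screen:** pairwise-complete Spearman correlations; pairs
  with R > 0.75 are flagged (strictly greater; perfectly anticorrelated
  pairs are not flagged).
- **Group comparison:** Welch's unequal-variance t-test, signed as
  negative-outcome mean minus positive-outcome mean over the Welch
  standard error, degrees of freedom by Welch–Satterthwaite.  Two-sided
  p-values are Bonferroni-adjusted with multiplier m = 3 by default (the
  three independent Gen difference features).
- **ROC:** AUC is the Mann–Whitney probability with ties counted one
  half.  Candidate cutoffs sit at midpoints between adjacent distinct
  scores, flanked by ±∞.  The operating point maximizes the Youden index
  J = Se + Sp − 1; ties break by distance to the ideal (0, 1) corner of
  ROC space, then by the larger cutoff.  For the PT-difference feature the
  decision direction is: predict a negative outcome when the feature falls
  below the cutoff.
- **Reported percentages** round half-up to the nearest integer (8/9 →
  89%); undefined rates (empty denominator) stay undefined.
- **Sample size:** per group `n = ⌈2·(z₁₋α/₂ + z₁₋β)² / Δ²⌉` with the
  effect Δ in units of the common SD; the total is 2n.  With α = 0.05,
  β = 0.04 and a one-SD effect this gives 56 patients.  The underlying
  precision statement admits more than one reading; this closed form is
  the package's declared interpretation.
- **Modality cutoffs** (FU1): optical, PT difference < −1.3 s ⇒ predicted
  non-healing; ABI ratio < 0.9 ⇒ non-healing (standard PAD abnormality
  direction); A-DUS PSV ratio > 2.4 ⇒ non-healing (stenosis direction).
  All three use strict inequality on the abnormal side, and each direction
  is isolated in a `CutoffRule` so it can be flipped in configuration.
  Modality metrics are computed on each modality's available subset, with
  subset sizes reported alongside.

## Synthetic cohorts

The generator plants the classification signal where the analysis looks
for it: per patient the FU1−Post Gen PT difference is drawn from the
outcome group's normal distribution (defaults: positive 6.7 ± 9.3 s,
negative −7.1 ± 4.3 s; 9 positive and 5 negative patients).  Group PT
*levels* are not published, so defaults are declared: Pre 20 ± 6 s
(positive) / 15 ± 5 s (negative), Post 42 ± 6 s / 47 ± 6 s — negatives get
the larger immediate post-intervention improvement — and FU1 = Post +
drawn difference.  A feasibility loop keeps Post and FU1 inside the 3–75 s
band where the curve family keeps both 90% crossings on steep flanks; it
resamples only the Post level, never the drawn difference, so the group
signal is never truncated.  Per-patch offsets (SD 4 s) are constant across
time points and therefore cancel exactly in difference features; patch
counts are uniform over 1–4 (ulcer angiosome instrumented first), with the
frame rate following the patch-count law.

**Curve family.**  Per trial, relative to baseline: flat until pooling
onset (a delay after cuff inflation covering the ramp and venous
capacitance), then a saturating-exponential rise with a short time
constant (2 s), a convex (cubic) plateau decline from the peak to 90% of
peak at the target down-crossing, and a washout that starts at the
decline's end slope and accelerates with a 4 s Gaussian time scale.  The
two 90% crossings are placed analytically/by 1-D root finding so the
noiseless realized PT equals the target to within interpolation error;
the onset delay (rather than a stretched rise constant) keeps both
crossings on steep flanks, which is what makes the extracted PT robust to
detector noise, and the slope-continuous washout avoids a kink that would
bias smoothed crossing estimates.  Non-saturated trials (flag off) rise
slowly from onset with the configured time constant and no plateau; their
realized PT is emergent and short.  ΔHbO₂ carries a fixed 55% share of the
HbT change, so the component sum reproduces HbT exactly.

**Forward model and noise.**  Voltages follow the Beer–Lambert
attenuation with multiplicative Gaussian noise, default 1% relative SD,
independent per channel and frame.  All randomness derives from the
cohort seed; recordings are rendered lazily from seeds derived per
patient, time point and patch, so identical seeds give bit-identical
cohorts regardless of evaluation order.

**Modality panels.**  ABI and A-DUS ratios are drawn with only a weak
outcome association (both modalities performed poorly in the clinic) and
with availability matching the study (ABI: 5/14 pre, 10/14 FU1; A-DUS:
9/14 pre, 11/14 FU1).  Missingness is explicit absence, never a sentinel.

**What the simulator does not emulate.**  Real optical transport (the
forward model is the same MBLL the reconstruction inverts, so round-trip
tests validate the inversion, not tissue physics), motion artifacts,
drift, detector saturation, and inter-trial physiological variation
beyond the modeled noise.  Every default cohort realizes its drawn
difference with *saturated* curves: a curve that fails to saturate has an
emergent PT that cannot equal a prescribed target, so the exactness
contract takes precedence; non-saturated behavior is exercised by the
curve-level API and its tests instead.  Passing tests therefore show that
the analysis chain is correct and recovers planted signals — not that the
signal exists in any particular clinical population.

## Numerical choices and problem sizes

Noiseless end-to-end round trips recover concentrations to ≤ 1e−9 µM and
realized Gen PT differences match drawn ones to well under one frame
interval; with 1% noise the difference error is ≈ 0.0 ± 0.1 s.  Monte-Carlo
checks in the test suite and the acceptance script use 300–500 cohorts with
single-patch patients (the Gen difference is patch-count invariant by
construction, and one patch at 10.24 fps is the cheapest rendering), and
4000 cohorts for the law-of-large-numbers check on drawn differences.
Root finding uses Brent's method with 1e−10 tolerances; least squares uses
the Moore–Penrose pseudoinverse of the 4×2 pathlength matrix.

## Known limitations

- MBLL with a flat DPF is a deliberate simplification; absolute
  quantitation, scattering and SO₂ estimation are out of scope.
- How the original instrument combined the near/far detectors is unknown;
  the far detector is used alone by default.
- Whether clinical PT extraction interpolated between frames, smoothed, or
  censored non-saturating trials is unknown; all three behaviors are
  explicit options here with declared defaults.
- The duplex-ultrasound column of the bundled truth table assigns every
  available patient to the stenosis side of the 2.4 cutoff, so its NPV is
  undefined on this cohort; the package reports it as undefined rather
  than zero.
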