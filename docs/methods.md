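# Methods

This note documents the models, conventions, numerical choices, and the
synthetic-data conditions behind `petkin`. It records design decisions and
their rationale; every empirical number it mentions is computed by the test
suite or `scripts/acceptance.py`, not asserted by hand.

## Conventions

Time zero is the injection time; all times are stored in seconds internally
and reported in minutes in user-facing tables. Activity concentrations are
Bq/mL. A frame value is the average concentration over the frame, plotted at
the frame midpoint — the standard dynamic-PET convention. Decay correction
is referenced to injection time (the SUV convention); the reference is a
parameter of `decay_correct` for other choices. The ⁶⁸Ga half-life defaults
to 67.71 min (the physical value) and is overridable per curve. The default
acquisition is 28 frames over 60 min: 10×30 s, 5×60 s, 5×120 s, 8×300 s.

Rate constants are per minute (K1 in mL·min⁻¹·mL⁻¹). Output tables print
units explicitly because the macro-parameter Ki (mL·min⁻¹·mL⁻¹) is easy to
mislabel.

## Arterial input function

The automatic sampler records counts per second through external tubing:
background-shifted, decay-uncorrected, and dispersed. Corrections are
applied in that order:

1. constant pre-injection background subtraction (clipped at zero);
2. dispersion removal. The kernel is modelled as monoexponential,
   (1/τ)e^(−t/τ) with τ = 5 s by default — the standard external-detector
   model; no kernel measurement is available, so τ is a configuration
   constant. The inverse is c(t) = g(t) + τ·dg/dt with dg/dt from central
   differences, clipped at zero; a warning fires if more than 20% of samples
   clip (τ too large for the data). A forward-convolution/round-trip test
   bounds the residual error at < 2% of peak away from the bolus onset
   (the onset itself is discretization-limited).
3. decay correction to injection time and calibration to Bq/mL.

Sampler pauses during manual draws shorter than 30 s are bridged by linear
interpolation; longer gaps are left to the merge stage.

The 10-min sampler curve is extended to 60 min through the manual
whole-blood samples with **log-linear** (mono-exponential) segments,
anchored at the sampler endpoint. Linear interpolation would bias the AUC
upward on a convex clearance curve. Manual samples inside the sampler
window serve only as a scale-consistency check (warning beyond a 15% ratio
deviation); no rescaling is applied in either direction.

Plasma conversion multiplies by the mean plasma-to-blood ratio of the
manual samples when at least three usable draws exist, otherwise by the
cohort default 1.62. The ratio is tied to hematocrit by R_P/B = 1/(1−HCT)
(tracer confined to plasma, no metabolites); the parent fraction in plasma
is fixed at 1.0 and exposed as a constant for generality.

## Image-derived input function

The IDIF is the per-frame **median** within the pooled vessel mask (two
straight iliac-like segments, 8 and 9 mm; the median is robust to edge
voxels), corrected with the two-coefficient contamination model

    measured(t) = RC(d)·true(t) + S(d)·background(t)

inverted as corrected = (measured − S·background)/RC. The background
regressor is the median in a peri-vascular shell 2–6 mm outside the vessel
(the near rim is blur-contaminated; the exact shell bounds are a design
choice, as no anatomical definition is imposed). RC(d) and S(d) are
calibrated per diameter from single-vessel phantoms with known truth by
least squares across frames, using the *same* shell measurement as the
correction applies — making calibration and inversion self-consistent — and
RC is forced non-decreasing in diameter by pool-adjacent-violators. The
calibration table ships as YAML/JSON with linear interpolation between
listed diameters; querying outside the calibrated range is an error rather
than an extrapolation.

The IDIF time base is the frame midpoints; no sub-frame bolus peak recovery
is attempted (the first frames are 30 s). The consequence — peak
underestimation — is surfaced by the AUCr check rather than hidden. For
kinetic fitting the midpoint-sampled IDIF is extended to the scan end by
log-linear extrapolation of its last segment.

Tissue VOIs: the 40%-isocontour is grown from a seed point, with the
reference maximum taken over the grown region by fixed-point iteration —
growing from a seed rather than thresholding on the global maximum keeps
nearby hot structures (bladder) out of the VOI. Spherical VOIs include
voxels whose centres lie within r = (3V/4π)^⅓. Masks must share the image
grid exactly; there is no implicit resampling.

## Kinetic modelling

The forward model is solved by exact exponential-basis convolution: the
impulse response of each configuration is a sum of (at most two)
exponentials with closed-form amplitudes and eigenvalues; the convolution
with a piecewise-linear input is evaluated exactly per 1-s grid segment as
a first-order IIR recursion, then averaged over each frame. Against an
independent stiff ODE integrator the solution agrees to better than 10⁻⁵
of curve maximum at every frame — the 0.1% acceptance bound is met with
orders of magnitude to spare. Degenerate 2T4k eigenvalues (repeated roots)
are separated by a 10⁻¹⁰ nudge.

V_B mixing uses **whole blood** (not plasma) in the intravascular term —
the physically meaningful choice, documented because the source protocol
only states that V_B was fitted.

Fitting is weighted nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) with bounds K1, k ∈ [0, 5], V_B ∈ [0, 0.5], and
multi-start: one geometric-mid-bounds start plus nine log-uniform draws
(fixed seed), lowest RSS wins. Two-tissue objectives are multimodal;
noiseless self-generated lesion data are recovered to ≪1% and 100
default-noise replicates keep the median |Ki bias| under 5% (micro-
parameters k2, k3 are less robust, and a fit is flagged unidentifiable when
the Gauss–Newton relative standard error of k2 or k3 exceeds 100%). Weights
are uniform by default; a Δt·e^(−λt) frame-count scheme is available.
No input/tissue time delay is fitted by default. Motion-corrupted late
frames are excluded via an explicit per-region frame mask, not automatic
detection.

Model selection uses plain AIC (AICc is available but off by default),
ties broken toward fewer parameters. Ki is K1·k3/(k2+k3) for the two-tissue
models (0/0 guarded), K1 for 1T1k, and reported as 0 with a cleared flag
for the fully reversible 1T2k. Patlak uses plasma as input, frames with
midpoints ≥ t* = 15 min, x computed by trapezoid on the 1-s plasma grid in
minutes, ordinary least squares for slope and intercept.

## Statistics

Spearman (mid-ranks; exact permutation p for n ≤ 9, t-approximation
otherwise), ICC(3,1) two-way mixed single-measure *consistency* (additive
rater shifts do not count against agreement), Friedman with tie correction
(exact enumeration over (k!)ⁿ for n ≤ 5), and Wilcoxon signed-rank (zeros
dropped, mid-ranks; exact 2ⁿ enumeration for n ≤ 12, normal approximation
with continuity correction and tie-adjusted variance beyond). Each exact
variant is verified against an independent brute-force enumeration; the
asymptotic variants are cross-checked against scipy and pingouin. All tests
are two-sided at the 5% level with no multiplicity correction, matching the
validation design. Lesion-level analyses first select the most avid lesion
(highest 45–60 min SUV) per subject to avoid intra-subject dependency; ties
break deterministically by region label.

## Synthetic data: what it emulates, and what it does not

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Bolus**: Feng-type tri-exponential plasma curve, t₀ = 10 s,
  amplitudes (A1, A2, A3) = (40 000 Bq·mL⁻¹·s⁻¹, 10 000, 5 000 Bq/mL) and
  rates (0.12, 0.01, 0.00012) s⁻¹ — arterial peak ≈ 120 kBq/mL and a
  60-min plasma tail ≈ 1.5 kBq/mL, scaled to a ≈190 MBq injection in a
  75 kg subject. Whole blood = plasma·(1−HCT) with HCT = 0.38.
* **Blood measurements**: sampler = whole blood convolved with the τ = 5 s
  kernel, decay-uncorrected, calibration 10 (Bq/mL)/cps, background 20 cps,
  1-s samples over 0–600 s; manual draws at 3, 7, 15, 25, 40, 59.5 min.
* **Tissue**: lesion/prostate/muscle rate constants drawn log-uniformly
  within tissue-class interquartile ranges (lesion K1 0.099–0.229,
  k2 0.213–0.484, k3 0.057–0.125; analogous prostate and muscle ranges),
  simulated with the irreversible two-tissue model, V_B = 0.
* **Noise**: per-frame Gaussian with sd = α·√(value/(Δt·e^(−λt))), α = 50 —
  the count-limited frame-variance approximation; ≈3.5% CV on late lesion
  frames. α = 0 reproduces noiseless curves exactly.
* **Cohort**: 14 subjects (10 with one lesion, 4 with two — 18 lesions),
  per-subject AIF amplitude scaled by a 10% lognormal factor. Serum PSA is
  linked to the hottest lesion's Ki by log PSA = a + log Ki + N(0, 0.35)
  with a anchored so the median PSA is ≈8.6 ng/mL — the SUV/Ki-vs-PSA
  correlations are therefore positive *by construction*, with magnitude set
  by the noise term; other covariates (Gleason, PI-RADS, ADC, lesion size)
  are drawn independently.
* **Phantom**: two straight z-axis cylinders (8, 9 mm) anti-aliased into a
  2 mm grid (48×48×24), filled with the frame-averaged whole-blood curve in
  a muscle-like background slab, blurred with a 4 mm FWHM isotropic
  Gaussian PSF.

Every generator is a pure function of (truth, seed) — regeneration is
bit-identical.

What passing tests on these data do **not** show: robustness to real
anatomy (curved vessels, bladder filling, heterogeneous background), motion,
scatter/attenuation residuals, reconstruction artefacts, sub-frame bolus
dynamics, or mis-specified kinetics (the tissue truth *is* the fitted model
family). The cohort-level statistics show that the chain preserves known
relationships, not that those relationships hold clinically. In particular,
the corrected-IDIF AUCr ≈ 1.00 on the phantom reflects a self-consistent
inversion under matched geometry; real-data AUCr (≈0.84 with residual
partial-volume and motion effects) cannot be reproduced by construction.

## Problem sizes

Default analysis sizes are chosen so the whole suite runs comfortably on a
single CPU: 100 replicates for noise-bias and model-recovery studies, 20
random parameter draws for the ODE-oracle comparison, a 20-region cohort
for the Patlak-vs-compartment rank check, and the 14-subject cohort for the
validation tables. The Patlak-vs-compartment rank agreement is evaluated on
noiseless curves: it is an estimator-agreement property, and at default
noise it would instead count rank flips between regions whose true Ki
differ by less than the noise floor (the noisy value is still reported by
the acceptance script, unasserted).

## Known limitations

* The dispersion inverse amplifies high-frequency noise (derivative term);
  no regularization beyond clipping is applied. For noisy sampler data a
  smoothing step before correction would be needed.
* PVC calibration assumes straight cylinders and a spatially invariant,
  known PSF; RC/S tables are only as good as the phantom's match to the
  vessel geometry.
* The identifiability flag is based on the local Gauss–Newton covariance;
  it under-reports problems when the optimum sits on a bound.
* Patlak t* is fixed, not estimated from linearity diagnostics.
* `run_study` fits the full candidate set only on the arterial-plasma arm;
  IDIF arms fit the irreversible two-tissue model (the validation
  quantity), a deliberate compute trade-off.
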