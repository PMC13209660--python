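# Methods

This note documents the models, defaults and numerical choices behind
`nirsleep`, and what the synthetic-data experiments do and do not
demonstrate about real infant recordings.

## Synthetic forward model

A recording is built as `I(t) = I0 · exp(−ΔOD(t))` per channel and
wavelength, where ΔOD combines:

* **Evoked response.** Per trial, a double-gamma HRF (peak 7 s, undershoot
  16 s, ratio 1/6; the infant HRF is not firmly established, so all timing
  constants are configurable) is convolved with the 8-s stimulus boxcar and
  normalized to unit peak, so a planted amplitude *A* (µM HbO) equals the
  peak concentration change of an isolated trial. The amplitude is looked
  up per condition and per sleep stage at trial onset; awake periods evoke
  nothing. For the HaND run, familiarization epochs Fam2 and Fam3 are
  scaled by `decay^1` and `decay^2`. HbR is a delayed (1 s), negatively
  scaled (−0.35) copy of HbO. Concentrations map to OD through the modified
  Beer–Lambert law with tabulated extinction coefficients (1/(mM·cm):
  780 nm — HbO 0.736, HbR 1.102; 850 nm — HbO 1.058, HbR 0.691), 2 cm
  separation and DPFs 5.22 (780 nm) / 4.23 (850 nm).
* **Physiology.** A cardiac sinusoid (2.5 Hz ± subject jitter, clipped to
  the 1.5–3.5 Hz quality band) shared across wavelengths with per-channel
  phase — this is what gives well-coupled channels their high SCI/PSP — plus
  respiration (0.8 Hz), slow sinusoidal drift (0.002–0.015 Hz, 0.004 OD)
  and white noise (0.002 OD). Noise lives in OD space so intensity stays
  positive by construction.
* **Motion artifacts.** Poisson-count events with stage-dependent rates
  (defaults 0.15/min in QS, 0.6/min in AS, mirroring the direction of the
  reported data-quality gap), each hitting a random majority of channels as
  either a ~0.5 s spike or a 5–15 s baseline step of 0.6–1.5 OD.

Sleep timelines are epoch-level Markov chains over {QS, AS, awake} in 15-s
steps. Coding sheets emulate a human coder: each behavioral criterion
applicable to the epoch's true stage is marked observed with probability
`mean_observability`, and the epoch score is the summed weight of observed
criteria.

**Calibration.** Default planted amplitudes are simulation settings chosen
once so that the full pipeline reproduces the order of magnitude of the
study regime: HaND peak amplitudes 1.4 µM (AS) / 0.35 µM (QS) with AS decay
0.25 yield window-mean Fam1 responses near 0.6 / 0.15 µM and a habituation
contrast difference of d ≈ 1.5–1.8 at n = 16/15; social amplitudes 1.3 µM
(N) / 0.7 µM (V) give window-mean non-vocal selectivity near 0.3 µM.
Between-subject variability is multiplicative (SD 0.45). These are not
empirical claims about infants; they are the operating point at which the
pipeline's power characteristics are exercised.

## What the generator does not emulate

Real optode arrays have channel-specific coupling, superficial (scalp)
hemodynamics, serially correlated colored noise, heart-rate variability and
spatially structured responses; the generator uses idealized versions
(uniform coupling, sinusoidal physiology, spatially uniform or binary
channel gains). Passing tests therefore demonstrate that the *pipeline*
recovers what was planted under controlled violations — not that the
pipeline is optimal for any particular real dataset.

## Preprocessing choices

* **Channel quality.** SCI is the cross-wavelength Pearson correlation of
  the cardiac-band-filtered signals; PSP is the peak of the normalized
  cross power spectrum. Both are computed in 10-s windows: SCI takes the
  per-channel median, and PSP averages per-window normalized complex
  cross-spectra (each bounded by Cauchy–Schwarz) so that phase-incoherent
  broadband noise cancels while the phase-locked cardiac peak accumulates.
  Windowing keeps isolated motion artifacts from condemning otherwise
  well-coupled channels. The printed PSP threshold is treated as 0.1 on
  this normalized, unitless quantity; thresholds: SCI 0.7, PSP 0.1, dataset
  dropped when more than 40% of the 18 channels fail either.
* **OD convention.** ΔOD = −ln(I / mean(I)) per channel and wavelength; the
  mean-referenced constant cancels in baseline-referenced block averages.
* **Motion detection.** Within 1-s sliding windows a channel is flagged
  when the OD excursion (max − min, either wavelength) exceeds 15× the
  whole-record channel SD or 0.5 OD; flags dilate 1 s each side. Trials are
  invalid when strictly more than 50% of channels are flagged at any sample
  of the trial's peristimulus window.
* **Motion correction.** Flagged segments are fitted with a smoothing
  spline (csaps-style p = 0.99, mapped to `make_smoothing_spline`'s
  roughness weight λ = (1−p)/p scaled by segment length), the fit is
  subtracted and the residual re-anchored on a linear ramp between the
  signal levels flanking the segment (0.5-s anchor means), which converts
  abrupt steps into slow ramps. A discrete wavelet pass (db2) then zeroes
  detail coefficients outside 0.8×IQR fences per level; decomposition depth
  is limited so detail bands stay above ~0.6 Hz — motion transients are
  broadband and still reachable, while the evoked response lives in the
  approximation and is untouched. Segments under 4 samples pass through and
  are logged.
* **Filtering.** Zero-phase 5th-order Butterworth low-pass at 0.6 Hz
  (`sosfiltfilt`); no high-pass beyond linear detrending.
* **Block averaging and detrending.** One linear trend is removed from the
  whole concentration record per channel before segmenting ("global" mode).
  Per-segment alternatives ("baseline", "full") exist but are not the
  default: with 18–20 s onset spacing a per-segment fit regresses out part
  of the response, and extrapolating a baseline-only fit amplifies the
  decaying previous-trial response into a ~2.6× peak inflation on planted
  noiseless data. Segments are then referenced to the mean of −4..0 s and
  averaged per condition; conditions with fewer than three valid trials are
  dropped, and a missing required condition (N and V; Fam1, Fam3, novel)
  excludes the subject.
* **Response overlap.** With the paradigms' own inter-stimulus intervals,
  successive responses overlap, so baseline-referenced block averages are
  attenuated relative to the planted single-trial amplitude (~0.5× for
  window means). This is a property of the block design shared by all
  subjects and groups; the exact forward/inverse round-trip identity (2%
  recovery) is therefore verified on schedules with 60-s onset spacing,
  where it is well defined.
* **Analysis window.** Windowed mean responses default to 8–16 s
  post-onset (configurable); the study-specific windows derived from
  cluster statistics in prior full-cohort work are not published, so this
  default covers the convolved response peak.
* **% clean data** is the share of channel×time samples not flagged by
  motion detection, per recording.

## Sleep staging

The shipped criterion weight table is a synthetic stand-in (the published
table is unavailable): per stage, one 35% REM-status criterion, one 35%
respiration-regularity criterion, one 20% movement criterion and a shared
10% startle criterion, satisfying the stated constraint that
stage-exclusive behaviors outweigh shared ones; it is fully overridable via
YAML. Codability uses all epochs (awake epochs are scored against the QS
set, since the score measures what is visible on video) and the exclusion
rule is strict: mean score exactly 65% is retained. ICC is fixed to the
two-way random-effects, absolute-agreement, single-measure variant ICC(2,1),
computed from the ANOVA mean squares and cross-checked against pingouin in
tests.

## Trial allocation

Stage labels come from coding sheets only. A trial overlapping a stage
transition is `mixed` and never retained. Interpretations where the rules
underdetermine behavior: the six-trial social window means six consecutive
positions of the 16-trial sequence (earliest qualifying window wins);
motion-invalid trials occupy positions without counting; a window may not
straddle awake or mixed trials; and the HaND novelty run must be a
contiguous run of valid same-stage trials crossing the Fam3|novel boundary
with no invalid trial inside. All decisions are verified against an
independent brute-force enumeration on random cohorts.

## Statistics

Data-quality comparisons use Welch t (recomputing the published group
summaries with Welch reproduces the printed statistics); ROI comparisons
default to pooled variance (printed integer dfs imply n1+n2−2); both are
configurable. Group comparisons are computed AS − QS. Quartiles use linear
interpolation between order statistics — this fixes the 1.5×IQR fences and
is part of the contract. Permutation tests enumerate all C(n, n1) label
assignments (or 2^n sign patterns) when they fit within the 5000-permutation
budget, else use a seeded Monte-Carlo sample with the observed labeling
included; the default null statistic is the difference of means. Bootstrap
CIs are stratified percentile intervals over 5000 resamples; degenerate
(zero-pooled-SD) resamples are redrawn and logged. Significance is adjusted
p < 0.05 after Benjamini–Hochberg step-up correction (statsmodels); the
stage-2 contrast family is the set of channels significant against
baseline, configurable to the full 18-channel family. Normality and
variance screening (Shapiro–Wilk, Levene) is computed and logged but never
gates the parametric tests.

Two operating characteristics worth knowing:

* **Trim-then-test size.** Applying the 1.5×IQR exclusion per group before
  the t test inflates the empirical type-I rate above the nominal 5% (to
  roughly 8% at n = 15/16 on normal data) because trimming shortens the
  tails and shrinks the pooled SD. This is a property of the
  outlier-exclusion procedure itself, which the package implements as
  specified; single 200-replicate measurements of the null rejection rate
  scatter around that value.
* **Bootstrap coverage.** The percentile CI for Cohen's d undercovers
  slightly (measured 93.6% for a nominal 95% interval at n = 50/50, d = 1),
  a known small-sample property of the percentile method applied to a
  biased, skewed estimator.

## Degenerate inputs and tie-breaks

Zero-variance channels get SCI = PSP = 0 and are flagged; equal constant
groups make the t statistic undefined and raise; constant vectors pass the
IQR filter unchanged; exactly 50% of channels in motion does not reject a
trial (strictly-greater rule); 7/18 bad channels retains a dataset and 8/18
drops it; a codability mean of exactly 65% is retained.

## Problem sizes

Default experiment sizes used by the test suite and acceptance script —
cohorts of 10–31 subjects, 200-replicate power runs, 500-replicate
coverage and allocation-equivalence runs, 1000-replicate FDR nulls — were
chosen to put Monte-Carlo error well inside each check's tolerance while
keeping a full run in the low minutes on one core.

## Known limitations

The spline/wavelet motion correction is a faithful but simplified variant
of the established tooling (whole-record SD threshold, fixed db2 basis,
level-limited thresholding); the CLI covers simulate/code-sleep/analyze
with preprocessing, allocation and reporting folded into `analyze`; SNIRF
support is a minimal continuous-wave writer/reader (intensity, probe
wavelengths, stimulus groups) rather than a full implementation of the
specification; and no EEG, photon-transport or cortical-anatomy modeling is
attempted.
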