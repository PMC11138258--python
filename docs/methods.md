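# Methods

This note documents the models, defaults and design choices behind
`eegretest`, in the spirit of a statistical package's methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Reliability model and estimator

Measurements follow the two-way simple random-effects model
`y_ij = mu + r_i + c_j + e_ij`, subjects `r_i ~ N(0, sigma2_r)` crossed
with visits `c_j ~ N(0, sigma2_c)`, residual `e_ij ~ N(0, sigma2_e)`.
The target quantity is absolute-agreement single-measure reliability
`ICC(A,1) = sigma2_r / (sigma2_r + sigma2_c + sigma2_e)`: a systematic
visit shift counts against reliability, which is the right convention
for test-retest stability of a biomarker.

Estimation is by the moment formula on the two-way ANOVA mean squares
(`anova_mean_squares` enforces the decomposition identity
`(n−1)BMS + (k−1)RMS + (n−1)(k−1)EMS = SS_total`):

```
ICC(A,1) = (BMS − EMS) / (BMS + (k−1)·EMS + (k/n)·(RMS − EMS))
```

This is algebraically identical to plugging the unbiased variance
component estimates `s2_r = (BMS−EMS)/k`, `s2_c = (RMS−EMS)/n`,
`s2_e = EMS` into the agreement ratio — the property the test suite
exploits as an independent oracle, alongside a cross-check against
pingouin's ICC2 row. Negative estimates are reported as computed (they
classify as "poor"); truncation at zero would bias simulation summaries.

A second formula variant, `formula="as-printed"`, replaces `(k−1)·EMS`
with `(k+1)·EMS`. It exists only for auditing against sources that print
that denominator; it does not follow from the two-way ANOVA expectations
and is never the default.

Confidence intervals are the McGraw–Wong F-based approximation with a
Satterthwaite denominator df. Coverage at the default 95% level is
verified by simulation (n = 30, k = 2, true ICC 0.85, 500 datasets) to
lie in the low-to-mid 90s, as expected for this approximation.

Classification bands: poor < 0.5 ≤ moderate < 0.75 ≤ good < 0.9 ≤
excellent ≤ 1, left-closed at each threshold.

### Pairing design

Sessions carry interval labels from the closed vocabulary {baseline,
same_day, 2wk, 4wk, 6wk}, assigned by study design, never inferred from
timestamps. The pair for interval L is (baseline visit, L visit);
subjects missing either side are dropped listwise, and the per-interval
n is reported next to each estimate.

## Study-design power

The design calculation uses the one-way reliability F-test: with
`C(rho) = 1 + k·rho/(1−rho)`, the statistic `MSB/MSW` scaled by
`1/C(rho)` is central `F(n−1, n(k−1))`, giving the exact power
expression implemented in `icc_test_power`. The test is one-sided
(`H1: rho > rho0`) at alpha = 0.05 by default — the conventional
reliability-design test — with a `two_sided` flag that spends alpha/2.
`detectable_icc` inverts the power in rho1 by Brent root-finding to
1e-6; `required_n` searches the integer n exactly, with the
Walter–Eliasziw–Donner log-F closed form (`required_n_approx`) kept for
comparison (it agrees within ±2 subjects over the tested grid). A
Monte-Carlo of the same F statistic (`simulate_rejection_rate`) serves
as the simulation oracle in tests and in the acceptance script.

For the reference design (n = 30, k = 2, rho0 = 0.50, alpha = 0.05) the
detectable ICC at 80% power is 0.7671, i.e. 0.77 at two decimals. Note
that the power at the *rounded* value 0.77 is 0.810; the root-finding
round-trip (power at the unrounded root equals 0.800000) is the
well-posed statement of the calculation.

## Synthetic data generator

The generator defines the study conditions for all end-to-end checks.
Per subject-session and channel the signal is the sum of:

* a 1/f^chi Gaussian background (chi per subject, N(1.5, 0.1) truncated
  to [0.5, 3]; amplitude flattened below 1 Hz; total SD 10 uV),
* five band-limited noise components with SDs `exp(log-amplitude)`;
  band log-amplitude means log(8, 5, 6, 3, 1.5) uV for delta..gamma give
  a plausible low-frequency-dominant resting spectrum,
* a narrowband (±0.25 Hz) oscillation at the subject's alpha peak
  frequency (subject-level N(10, 1) Hz truncated to [8, 12.5]), with
  amplitude 6 uV scaled by the realised alpha log-amplitude so the peak
  covaries with its band.

Band-limited components are made by masking the FFT of white noise and
inverting — exact band control without filter ringing.

Reliability is injected at the latent log-amplitude level: per band,
subject/session/residual normal effects with variances
`(sigma2_subject, sigma2_session, sigma2_error)`;
`variance_components_for_icc(target, total, session_share)` maps a
target ICC to components. Defaults: total log-amplitude variance 0.04
(power varying by roughly ±50% across subjects), session share 0.3 of
the non-subject variance, and per-band target ICCs
delta 0.810, theta 0.875, alpha 0.959, beta 0.840, gamma 0.814 — the
same-day reliability regime this package is organised around. The alpha
peak frequency is a subject constant by default (IPF true ICC ≈ 1);
`alpha_peak_jitter_sd` adds session wander when lower IPF reliability is
wanted.

Because variance components act on log-amplitudes while the extracted
feature is *relative* power (a nonlinear function of all bands plus the
background), the true ICC of the extracted feature differs somewhat from
the latent target. Tests therefore check exact recovery at the latent
level and tolerance-banded recovery end-to-end.

Artifacts are deliberately schematic: a fixed-amplitude 60 Hz sinusoid,
flat or 20x-noise bad channels (deterministically the first channels),
and Gaussian-envelope blink-like transients on frontal channels. They
exercise the rejection/interpolation/bandstop machinery but do not
mimic real ocular or EMG morphology; passing tests demonstrate that the
pipeline removes *these* contaminants, not that it would clean any real
recording.

Randomness is counter-based: subject i draws from stream `[1, seed, i]`,
session (i, j) from `[3, seed, i, j]` (signal synthesis from
`[2, seed, i, j]`), so enlarging a design never perturbs existing
subjects, and every stage is reproducible from one master seed.

Default acquisition geometry is 128 channels at 1000 Hz for 300 s.
Tests and the packaged fast fixture use 8 channels at 250 Hz for 60 s
with 6 subjects x 2 sessions — sizes chosen so the full suite runs in
well under a minute of simulation time while every code path (montage
exclusion aside) is exercised; the 128-channel montage paths are covered
by the interpolation and montage tests directly.

## Preprocessing

* **Filtering.** One symmetric windowed-sinc FIR kernel combines the
  2 Hz highpass, 80 Hz lowpass and 55–65 Hz bandstop plus its harmonic
  images (115–125, 175–185, … up to the Nyquist frequency of the
  original sampling rate — redundant above the lowpass but retained for
  fidelity to the stated chain). Transition widths: 25% of each corner
  for highpass/lowpass, 2.5 Hz at bandstop edges; kernel length scales
  as ~6.6/(0.5 Hz) cycles so the Hamming window's ~50 dB floor is
  reached everywhere. The kernel is applied once with reflection
  edge-padding and the constant group delay trimmed — a zero-phase
  response verified by lag-0 cross-correlation. Measured contract:
  ≤ 1 dB ripple in 4–50 Hz, ≥ 40 dB attenuation at ≤ 1 Hz, at 60 Hz and
  at ≥ 90 Hz.
* **Epoching.** Contiguous non-overlapping 2 s epochs; trailing partial
  epochs discarded.
* **Bad channels.** Flat channels, and channels whose log variance is
  more than 5 robust z-units (median/MAD) from the montage median, are
  flagged, capped worst-first at floor(5% of channels). The cap mirrors
  the analysis rule that a recording needing more interpolation than
  that should be treated as suspect rather than repaired.
* **Interpolation.** Perrin-style spherical splines: kernel
  `g(cos) = (1/4pi) * sum_{l=1..7} (2l+1)/(l(l+1))^4 * P_l(cos)`
  (order m = 4, 7 Legendre terms, 1e-5 ridge on the spline system).
  The bad←good mapping is a single time-independent matrix. Exact on
  constant fields; within 5% on low-order spherical-harmonic fields at
  128 channels; cross-checked against MNE's interpolation matrix at
  matched truncation.
* **Epoch rejection.** Deterministic surrogate for manual artifact
  screening: an epoch is dropped when any analysis channel exceeds
  150 uV half peak-to-peak, or its log total variance exceeds the
  across-epoch median by 4 robust z-units. Order: detect bad channels →
  interpolate → reject epochs, so rejection statistics see repaired
  channels. These thresholds are surrogates chosen for reproducibility,
  not a validated clone of expert screening (no ICA is performed).

## Spectral features

Welch PSD: 2 s Hann (periodic) windows, 50% overlap, window power
normalisation, one-sided density scaling, 0.5 Hz grid. Segments slide
within contiguous runs of *kept* epochs only — no segment spans a
rejection gap; on gap-free data the implementation matches
`scipy.signal.welch` to 1e-10 relative.

Relative power divides each 2–80 Hz bin by the channel's total 2–80 Hz
power; out-of-range bins join neither numerator nor denominator. Band
assignment is closed on both edges with the 30 Hz boundary bin going to
beta (lower band wins); the printed inter-band gaps (3.5→4, 12.5→13)
make all other 0.5 Hz-grid bins unambiguous. The 55–65 Hz stopband bins
stay in the total-power denominator (their post-filter power is ~0) but
are excluded from the gamma band average. IPF takes the global argmax of
log10 relative power in 5–14 Hz, first-lowest on ties; peakless monotone
spectra return the window edge and are logged as a quality flag. All six
features are montage-averaged (unweighted) over non-excluded,
non-undefined channels; flat channels are flagged undefined and skipped
with a warning.

Computing IPF per channel and then averaging (rather than on the
averaged spectrum) matches the convention of averaging *feature values*
across electrodes; on spectra with a single dominant subject-level peak
the two conventions coincide on the 0.5 Hz grid.

## Montage

The packaged 128-channel montage is a synthetic idealisation: a
Fibonacci-spiral layout on the spherical cap z ≥ −0.45 standing in for a
high-density geodesic net, with the 20 lowest (face/neck ring) positions
flagged excluded, leaving the 108-channel analysis subset. No public
label list exists for the concrete net's exclusion set, so the fixture
reproduces the selection rule (drop the outermost below-equator ring)
rather than specific labels. `fibonacci_montage(n, n_excluded)`
generates reduced layouts for tests.

## EDF I/O

Recordings travel as plain 16-bit EDF (one-second records, uniform rate,
microvolt units, symmetric per-channel physical ranges padded 1%).
Writer and reader invert the same affine map, so round-trips are exact
to half a quantisation step; MNE's independent EDF reader is the
round-trip oracle in tests. EDF+ annotations, BDF and proprietary raw
formats are out of scope.

## Numerical and degenerate-input choices

* Zero-variance measurement matrices: mean squares all zero, flagged
  degenerate; ICC undefined (NaN), CI (−1, 1).
* Negative residual SS from floating cancellation is clamped at 0.
* Feature tables are written at %.17g and parsed with round-trip float
  precision, so write→read→write is bit-identical.
* CLI exit codes: 0 success, 2 usage, 3 validation/configuration,
  4 data quality (e.g. all epochs rejected).

## Known limitations

* No ICA or ocular regression; the deterministic rejection thresholds
  are a reproducibility-first surrogate for expert screening.
* The generator's channels are exchangeable (no spatial covariance or
  forward model), so interpolation quality on synthetic data understates
  the benefit real spatial correlation would provide.
* Extracted-feature true ICCs are only approximately the latent targets
  (see above); recovery tests are therefore tolerance-banded.
* The McGraw–Wong interval is approximate; its small-sample coverage is
  verified only at the simulated design points.
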