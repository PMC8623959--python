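# Methods

## The estimation problem

A pedicle screw seated in bone behaves as a lightly damped mechanical
resonator. A nanosecond laser pulse delivers a broadband impulse; the
screw then rings at its natural frequencies, which rise with the stiffness
of the screw-bone interface and hence with the peak insertion torque τ.
The classical diagnostic regresses the single dominant spectral peak on
ln τ. For polyaxial screws the movable head perturbs the spectrum in a
non-repeatable way, so the package instead regresses τ on a large set of
band-wise spectral statistics, with L1-based variable ranking in front of a
kernel regression.

## Preprocessing

A record of duration T sampled at rate fs contains T·f_pulse impulse
responses with onsets at the (laser-triggered) segment boundaries. The
segments are averaged — uncorrelated noise shrinks by 1/√(number of
pulses) — and the first 2 ms after the pulse are discarded, because the
impact transient carries broadband energy that masks the low-order modes.
The amplitude spectrum of the remainder is computed with a rectangular
window (no taper, no zero padding, no detrending): the responses are
transient and fully decayed within a segment, so leakage control would
cost resolution for no benefit.

Spectrum convention: one-sided **amplitude** (not power), with the DFT
magnitude scaled by 1/N at DC and Nyquist and 2/N elsewhere, so a unit
sinusoid shows a unit peak. With this scaling the mean square of the
signal equals `a₀² + Σ aₖ²/2 + a_nyq²` (tested). Frequency resolution is
fs/N ≈ 10.2 Hz after the purge. The choice is isolated in `Spectrum`; the
shape statistics are scale-equivariant, and z-scoring removes overall
scale before any model sees the features.

## Band features

Bands are half-open `[low, high)` so adjacent bands partition the axis;
the whole-range band deliberately overlaps the sub-bands, mirroring the
published band schemes. Per band: peak frequency (ties broken toward the
lower frequency, deterministically), peak intensity, intensity-weighted
centroid frequency, centroid intensity (linear interpolation of the
spectrum at the centroid frequency; nearest-bin available as an option),
average intensity, dispersion (population variance, 1/n), and
bias-adjusted excess kurtosis and skewness (sample sd, n−1). A flat band
(s = 0) or one with fewer than 4 bins has no shape information; kurtosis
and skewness are emitted as 0 with a warning rather than NaN so downstream
matrices stay complete.

The skewness formula is implemented in its standard bias-adjusted form,
the natural companion of the adjusted kurtosis used here; a variant that
normalizes by s⁴ inside the cube is dimensionally inconsistent and is not
used.

## Bootstrap-Lasso ranking

All explanatory columns and the objective are z-scored (constant columns
dropped with a warning). For each λ on a 20-point log grid spanning
1e−3…1 — a range that brackets the strengths typically chosen on
normalized data — the same 2000 bootstrap resamples (drawn once, shared
across λ, which makes results at different strengths paired and the
procedure invariant to row permutations for a fixed index sequence) are
fitted by coordinate-descent Lasso (tolerance 1e−6, iteration cap 5000;
capped fits are logged and still counted). Each fit is centered within its
resample, equivalent to an intercept. The chosen λ maximizes the best
in-resample R² subject to a selection-footprint cap of 40 variables
(mean selected per trial by default; a distinct-variables mode is a config
switch). Variables are ranked by selection count, ties broken by column
order.

## SVR and validation

The regression is an ε-insensitive SVR with an RBF kernel on the top-k
(default 30) ranked variables, z-scored with statistics from the training
rows only. Hyperparameters are searched exhaustively on power-of-two
grids (ε: 2⁻²⁰…2⁹, C: 2⁻¹⁰…2¹⁰, γ: 2⁻¹⁵…2⁹, exponent step 1 by default),
scored by mean R² over a seeded shuffled 3-fold split of the training
rows; ties go to the first triple in grid order. The best triple is refit
on all training rows. Predictions store the normalization and kernel
expansion explicitly, so a model persisted to its JSON archive reproduces
in-memory predictions exactly. Queries outside the training feature range
are predicted but flagged: kernel regressions revert toward the training
mean under extrapolation, and accuracy degrades sharply.

Validation folds follow the torque-stratified rule: the minimum- and
maximum-torque measurements are pinned to fold 1 (which always trains),
and the remaining measurements, sorted by torque, are dealt out in
consecutive triplets, one per fold. Metrics: R² (1 − SS_res/SS_tot),
Pearson r, MSE (reported on the raw Nm² scale and variance-normalized,
since either convention appears in practice), and the fraction of
predictions with |pred − true| ≤ 0.2·true. Leave-one-out validation and
the log-fit baseline `f = a·ln τ + b` (least squares; invertible to a
torque predictor) complete the evaluation surface.

## The synthetic vibration generator

Each pulse starts a sum of exponentially damped sinusoids,
`s(t) = Σ Aₘ e^{−dₘt} sin(2π fₘ t)`, plus white noise (sd 0.05 of the
dominant amplitude). Defaults emulate a titanium polyaxial screw in
polyurethane test bone over 0.06–3 Nm:

| parameter | default | rationale |
|---|---|---|
| sampling rate, duration, pulse rate | 100 kHz, 2 s, 10 Hz | the acquisition design (20 responses/record) |
| dominant mode | f₁ = 6900 + 1300·ln τ Hz | keeps the dominant peak in the observed ~3–9 kHz range, ≈6.9 kHz near 1 Nm |
| tilt shifts | horizontal −800 Hz, vertical +800 Hz, skew midway, jitter sd 250 Hz | reproduces the reported same-torque scatter of roughly ±1000 Hz |
| tilt-amplitude coupling | ×exp(4·10⁻⁴·shift) on mode 1 | measured intensity varies with measurement direction; resonant frequency does not |
| body modes | 600+400√τ, 9800+500·ln τ, 11500+1800√τ, 15500+3000√τ, 23000+400·ln τ Hz | one resonance per analysis band; log-law modes mirror the dominant peak's phenomenology, √τ modes follow f ∝ √k for modes governed by the interface spring |
| tilt coupling of body modes | 0, 0.1, 0, 0, 0.1 | body resonances of the screw shaft are essentially immune to head orientation |
| damping | 100…350 s⁻¹, scaled by τ^0.15 | decay times of a few ms; stiffer fixation dissipates the impulse faster, so intensities carry torque information |
| per-pulse jitter | sd 10 Hz on mode 1 | small head wobble between pulses of one placement |

Torques in a simulated campaign are log-uniform with both interval
endpoints always present (so stratified folds can keep the extremes in
training); head placements are drawn uniformly over the four tilt types
unless a policy is given. All randomness flows from explicit seeds; there
is no hidden global state.

**What the generator does and does not emulate.** It reproduces the
qualitative phenomenology the analysis relies on — the logarithmic
dominant-peak law, the direction-dependent tilt shifts and their
non-repeatability, multi-peak spectra with band-separated resonances, and
intensity/damping variation with fixation — with analytic ground truth
for every mode frequency. It does **not** model laser-metal interaction
physics, finite-element mode shapes, mode splitting or coupling,
bone-density-specific effects, or colored measurement noise; mode count
and damping of real screws are unpublished, so those defaults are
placeholders, not measured values. Passing tests therefore demonstrate
that the pipeline recovers torque when its statistical assumptions hold,
not that it would reach the same accuracy on laboratory records.

Two generator design points deserve emphasis, since the open design space
was large. First, the √τ frequency laws: with log-law modes only, every
spectral feature is linear in ln τ, and a ±20 % torque criterion demands
resolution the feature space cannot deliver below ~0.2 Nm; interface-
spring modes with f ∝ √τ are physically standard and spread the
low-torque regime out. Second, the tilt-amplitude coupling: if tilt only
shifted frequencies, a tilt would be exactly collinear with a torque
change within the dominant-mode bands and no estimator could separate
them; the direction-dependent pickup intensity makes tilt identifiable,
which is precisely what the multivariate scheme exploits to beat the
single-peak baseline.

A consequence of the tilt-immune body modes is that the bootstrap-Lasso
ranks the clean body-mode bands above the tilt-scrambled dominant band:
dominant-band features are still selected in well over half the resamples
and sit inside the top ten, but not in the top three. On laboratory data,
where no band is noise-free, the dominant band ranks first.

## Problem sizes and numerical choices

The shipped experiments use the study-scale design throughout: 57
measurements (31 for the monoaxial leave-one-out demonstration), 2000
bootstrap resamples over a 20-point λ grid, and the full 30×21×25
power-of-two SVR grid with 3-fold tuning; the complete synthetic
experiment runs in about two minutes on one CPU. Unit tests use reduced
grids where hyperparameter search is incidental to the property under
test. Seeded determinism is asserted at every level (record, dataset,
selection, model, full demo). Known limitations: the ±20 %-band fraction
of the held-out fold is estimated from 18 points and varies by a few
counts between seeds; extrapolated queries are flagged, not refused; and
the in-resample R² reported by the Lasso stage is an optimistic
quantity retained for comparability, with an out-of-bag variant off by
default.
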