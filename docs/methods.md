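# Methods

This note documents the models, conventions and design choices behind
`sftag`, in the order data flow through the package.

## Steerable pyramid

The decomposition is built in the frequency domain as a Parseval tight
frame. Radial windows are raised cosines in log frequency,
`h_s(r) = cos((π/2)·log2(r/ω_s))` on `ω_s/2 ≤ r ≤ 2ω_s`, with octave
centres `ω_s = π/2^s` (radians/sample), i.e. band centres at
`2^-(s+1)` cycles/pixel; the highpass and lowpass residuals complete the
partition so that the squared transfer functions of all channels sum to
one exactly. Angular windows are `A_k(θ) ∝ |cos(θ − θ_k)|^(K−1)` with
`θ_k = kπ/K`; for `K` orientations the normaliser
`K·C(2K−2, K−1)/4^(K−1)` makes `Σ_k A_k² = 1` an identity. Consequences:

* decompose→reconstruct is exact to machine precision (measured
  ~3·10⁻¹⁶ relative), and energy is conserved exactly;
* filtering is periodic (FFT) — boundary effects appear only as
  wrap-around for non-periodic content, which the tests avoid by
  measuring on interior crops;
* orientation channels overlap: a grating aligned with channel k holds
  ~60% of bandpass energy there, ~20% in each neighbor. This overlap is
  what makes cardinal channels pick up an attenuated copy of the oblique
  modulation (measured ~0.7–0.8 of the oblique modulation depth on 1/f
  clips) — the expected behavior of a sinusoidal orientation taper; a
  sharper taper would reduce it at the cost of ringing.

Scales and orientations default to 5 and 8 but are constructor
parameters. All channels stay at full resolution; memory is
`(5·8+2)·H·W` doubles per frame, which is the price of exact algebra and
is irrelevant at the frame sizes used here.

## Viewing geometry

Cycles/degree map to cycles/pixel through pixels-per-degree. The default
(≈47.8 px/deg) is derived from a 27-inch 16:9 display at 2560×1440
viewed from 64 cm and can be overridden everywhere. With it, the five
band centres sit at ≈12.0, 6.0, 3.0, 1.5 and 0.75 cyc/deg, so the
3.2 cyc/deg threshold assigns scales {1, 2} to the *higher* set and
{3, 4, 5} to the *lower* set. A band centred exactly on the threshold
goes to the lower set (the higher range is strictly `>`). The highpass
residual is modulated with the higher set (weighted by the mean oblique
weight `mean_k |sin 2θ_k| ≈ 0.60`, since it has no orientation split);
the lowpass residual carries mean luminance and is never modulated.

## Tagging

Flicker `A(t) = (1 + sin(2πft + φ))/2` is sampled at frame timestamps;
the start phase defaults to 0 and is stored in clip metadata. The gain
applied to a channel is `g = 1 + F` with `F = (2A−1)|sin 2θ|`: the only
affine map that up- and down-regulates obliques symmetrically around
unity while fixing cardinals. Because the whole per-frame operation is
linear in the coefficients, it is applied as a single frequency-domain
transfer `Σ_k g_k |B_k|²` rather than an explicit
decompose/scale/reconstruct loop (identical result, one FFT pair per
frame). The modulated value channel is clipped to [0, 1] (clipped-pixel
fraction logged per frame, typically <1%) and recombined with the
original hue and saturation. Hue/saturation are bit-exact except at
pixels whose value clips to 0 or 1, where chroma is undefined.

## Tag verification

Per frame, channel power is averaged over the six oblique orientations
(k ∉ {0, K/2}) within each SF set; the series is linearly detrended
(natural video content drifts) and Fourier transformed. A set passes
when the maximum-SNR bin lies within one bin of the assigned frequency
with linear SNR ≥ 3 (repository convention; configurable). SNR uses the
same 4-neighbors-per-side rule as the EEG spectra. Minimum clip length
is 2 s, the shortest window separating 7 from 9 Hz.

## EEG analysis

Preprocessing: bad-channel interpolation (inverse-distance-squared
weights on standard 10-20 positions), zero-phase Butterworth band-pass
1–100 Hz (order 4, forward-backward), zero-phase notch at the line
frequency (default 60 Hz, Q = 30), average reference, then an optional
pluggable artifact hook (e.g. an ICA backend); measured transfer:
< −20 dB at 60 Hz (in practice < −100 dB), 7 Hz preserved within 5%.

Epochs are 7 s from 0.5 s after video onset. "Baseline correction" is
the full-epoch mean: the epoching scheme has no pre-stimulus interval,
and the linear detrend removes the mean as a side effect. Epochs with
any |sample| > 150 µV on the 16 occipitoparietal channels are flagged
rejected; truncated final presentations are flagged, not fatal.

Spectra are FFT amplitudes of the per-condition ERP (average over kept
epochs), resolution 1/7 Hz, so 7 and 9 Hz fall exactly on bins 49
and 63. "Power" in the SNR is squared amplitude; the neighborhood is the
4 strictly adjacent bins per side (0.57 Hz, no exclusion gap). A zero
neighborhood with nonzero target power returns a flagged +inf sentinel
instead of raising, so batch runs survive pathological channels; a fully
flat zero spectrum returns SNR 1.

Electrode selection is per participant and per flicker frequency: the
two candidates with the highest linear SNR at that frequency, averaged
over the two counterbalanced conditions (ties break by a fixed candidate
order). Each SF set's SNR is then the mean over its two
condition×frequency cells of the mean linear SNR across the selected
electrodes — combination happens on the linear scale, before any dB
conversion, and the convention is recorded in the marker output. The
marker is `ln(SNR_lower/SNR_higher)`, algebraically
`(dB_lower − dB_higher)·ln(10)/10`; the natural (not base-10) log is the
convention that reproduces the bundled reference table, which the tests
verify for all 31 rows. Harmonics (14/18 Hz) appear in the spectra but
never enter the marker.

## Synthetic data

*Videos* are Gaussian fields with amplitude spectrum ∝ 1/f^α (α default
1, i.e. scale-invariant power per octave) evolving with AR(1) temporal
coherence ρ = 0.9 (natural footage is strongly frame-to-frame
correlated), mean luminance 0.5, contrast (field SD) 0.15, optional
deterministic gratings, rendered as achromatic RGB. Note that at exactly
α = 1 the per-octave band energies are flat by construction; a monotone
power decrease with spatial frequency appears for α > 1.

*EEG* is built per presentation: sinusoids at the condition's two tag
frequencies (second harmonics at gain 0.3), phase-locked to presentation
onset with one random phase per participant per SF set, projected
through Gaussian spatial topographies on standard 10-20 electrode
positions (width 0.05 m; higher-SF centre Oz for both groups, lower-SF
centre Oz for controls and POz for the AMD-like group, emulating the
anterior shift), plus 1/f Gaussian noise (default 15 µV RMS) drawn
independently per presentation and channel, and optional supra-threshold
half-sine spikes for rejection testing. Group SSVEP strengths are
parameterized in dB SNR — AMD-like: higher 5.99 ± 2.21, lower
13.20 ± 2.26; control-like: higher 11.70 ± 4.76, lower 11.00 ± 3.17 —
and converted to µV amplitudes through a seeded numerical calibration of
the expected noise power in the analysis pipeline's neighbor bins.
Fixed µV amplitudes can be supplied instead (used by the noiseless
tests). The default simulation montage is an 18-channel posterior-
weighted cap (the 16 marker channels plus Cz and Fz); the full 68-label
cap is available. Synthesis is single precision — the background-noise
model does not warrant more — while all analysis accumulates in double.

Known idealizations: no eye-movement or muscle artifacts beyond the
spike process, no alpha rhythm or evoked transients, linear behavioral
links, and noise that is exactly 1/f^γ. Passing tests therefore
demonstrate correctness of the analysis chain and sensible behavior at
study-magnitude effect sizes, not performance on real recordings.

*Cohorts* draw per-participant dB values from the group distributions
and generate behavioral scores as
`score = intercept + β·log_ratio_true + noise` with β defaulting to 0.54
(logMAR) and −0.41 (logCS).

A known small positive bias (~0.1–0.2 in the log ratio, 1–3 dB in SNR)
arises from max-SNR electrode selection on finite noisy spectra; it
affects both SF sets nearly equally and does not affect group contrasts.

## Statistics

The JZS two-sample Bayes factor uses the Rouder formulation: Cauchy(0, r)
prior on effect size (default r = √2/2), integrated by adaptive
quadrature over the inverse-gamma mixing density; it matches an
independent implementation (pingouin) to ~10⁻¹² and a brute-force
Riemann oracle to 4+ significant figures. Run on the bundled reference
table it returns BF₁₀ = 940.5 for the AMD-vs-control marker contrast.

`UoILasso` is a scikit-learn estimator implementing Union of
Intersections: 30 selection bootstraps over a shared 48-point log-spaced
λ path, keeping features selected in ≥ `stability_selection` (default
0.5) of bootstraps per λ; then 30 estimation bootstraps fitting OLS on
each candidate support, scored on out-of-bag samples. The per-bootstrap
support score is BIC on the OOB error: with the permissive 0.5 stability
threshold, raw OOB MSE over-selects (exact-support recovery ~5% on
3-of-16 problems at SNR 5, n = 60) whereas BIC reaches >90%; plain MSE
remains available via `estimation_score`. Final coefficients are the
feature-wise median across bootstraps; unselected features are exactly
zero. Features are z-scored internally and coefficients returned on the
original scale.

Cross-validated R² pools out-of-fold predictions (5 folds, seeded
shuffle) with a normal-approximation CI using the classical variance
formula `4R²(1−R²)²(n−p−1)²/((n²−1)(n+3))`. Classification uses
stratified 5-fold CV repeated 20 times with within-fold z-scoring;
sensitivity takes AMD as the positive class, and metrics pool confusion
counts. The (10, 2) MLP is trained as five fixed-seed restarts with
majority vote, dropping restarts that fail on their own training data —
networks this small on n ≈ 31 are initialization-sensitive.

## Duration optimization

For duration T the scan resamples, with replacement and per participant,
`N/2` epochs per condition (`N = T/7.5`) and recomputes the full marker
(including electrode selection) from just those epochs, 30 permutations
by default; summaries are means and percentile CIs over permutations.
Sampling happens after artifact rejection. The gap-versus-duration curve
is fit with `a(1 − e^{−s(T−i)})` by multi-start nonlinear least squares
(s₀ ∈ {10⁻³, 10⁻², 10⁻¹} s⁻¹, a₀ from the data, i₀ = 0, s bounded
positive, i bounded below min T); `t99 = i + ln(100)/s`. On synthetic
cohorts the per-trial SNR is high enough that the gap is near-stable
from short durations, so the package reports endpoint gaps and CI
shrinkage there rather than an (unidentified) t99.

## Problem sizes in the test suite

Stochastic end-to-end checks run at sizes chosen to keep the suite
focused: tag-embedding verification uses 3 s, 30 fps, 128×128 clips over
20 seeds (the 2 s minimum plus margin; 7 and 9 Hz fall on exact bins);
cohort-level group separation uses the full 15-vs-16 design at 1000 Hz
with the 18-channel simulation montage over 50 seeds; UoI recovery uses
40 seeded runs. The acceptance script uses the same machinery at
slightly smaller ensemble counts, all derived from its `--seed`.
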