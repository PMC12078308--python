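# sftag — video spatial-frequency tagging and the log(SSVEP ratio) neuromarker

`sftag` implements a video-based, fixation-free test of visual function
aimed at conditions such as age-related macular degeneration (AMD), where
central vision loss selectively degrades sensitivity to fine spatial
detail. The package covers both halves of the protocol:

**Stimulus side.** Full-color natural videos are decomposed frame by
frame with an invertible steerable wavelet pyramid (5 octave-spaced
spatial-frequency bands × 8 orientations on the HSV value channel).
Contrast in the bands above and below a threshold of 3.2 cyc/deg is
modulated sinusoidally at two different temporal frequencies (7 and
9 Hz), using the oblique-orientation power filter

    F = (2A − 1) · |sin 2θ|,   g = 1 + F,

where `A ∈ [0, 1]` is the instantaneous flicker amplitude and `θ` the
orientation of a pyramid channel, so cardinal orientations stay
untouched. Each clip is rendered under both counterbalanced assignments
(condition 1: high SF→7 Hz, low SF→9 Hz; condition 2 swapped), and a
verification module re-decomposes the output to confirm the embedded
tags.

**Analysis side.** EEG recorded while a participant watches the tagged
series is turned into steady-state visual evoked potential (SSVEP)
estimates: 7 s epochs starting 0.5 s after each video onset, linear
detrend, 150 µV artifact rejection on 16 occipitoparietal channels,
per-condition ERP averaging, FFT, and spectral signal-to-noise

    SNR(f) = P(f) / mean(P over the 4 neighboring bins per side),
    SNR(dB) = 10·log10(SNR),

with the neighborhood spanning 0.57 Hz per side at the 1/7 Hz
resolution. Per flicker frequency the two strongest occipitoparietal
electrodes are selected, and the neuromarker is the natural log of the
ratio of linear SNRs,

    log(SSVEP ratio) = ln(SNR_lowSF / SNR_highSF),

which is near zero or negative in healthy controls and positive when
high-SF responses collapse. Around the marker the package provides a
synthetic-data layer (1/f videos; multichannel EEG with phase-locked
SSVEP components, topographic gains, 1/f noise and artifact spikes),
JZS Bayes-factor t-tests, Union-of-Intersections Lasso regression with
cross-validated R², AMD/control classification (L1 logistic, KNN-5,
MLP(10,2)), and a duration-optimization model
`Δlog(ratio)(T) = a(1 − e^{−s(T−i)})` with its 99%-of-asymptote time
`t99 = i + ln(100)/s`.

## Worked example

Simulate an AMD-like participant (weak high-SF response, low-SF response
shifted anteriorly toward POz) and run the full analysis chain:

```python
from sftag import (SyntheticEEGSpec, make_eeg, amd_group_params,
                   recording_marker)

rec = make_eeg(SyntheticEEGSpec(seed=7), amd_group_params())
m = recording_marker(rec)
print(m.electrodes)   # {7.0: ('POz', 'Pz'), 9.0: ('P1', 'PO3')}
print(m.snr_db)       # {'higher': 0.40, 'lower': 13.97}
print(m.log_ratio)    # 3.13
```

The positive marker (+3.13) reflects the AMD-like profile: the low-SF
SSVEP (14 dB) dominates the high-SF one (0.4 dB), and the selected
electrodes sit anterior to Oz. A healthy-control simulation
(`control_group_params()`) gives a marker near or below zero.

The bundled reference cohort (15 AMD, 16 controls) reproduces the
published group statistics from first principles:

```python
from sftag import load_reference_cohort, jzs_bf_ttest

tab = load_reference_cohort()
amd = tab[tab.group == "AMD"].log_ratio      # mean 1.67
ctl = tab[tab.group == "control"].log_ratio  # mean -0.14
t, bf = jzs_bf_ttest(amd, ctl)
print(round(t, 2), round(bf, 1))             # 5.13 940.5
```

A command-line layer mirrors the library:
`sftag make-schedule`, `sftag tag-embed`, `sftag tag-verify`,
`sftag ssvep-analyze`, `sftag simulate`, `sftag fit-convergence`
(see `sftag --help`).

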