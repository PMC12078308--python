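"""SSVEP chain: preprocessing, epoching, spectra, SNR, electrode selection, marker."""

import math

import numpy as np
import pandas as pd
import pytest

from sftag.datasets import load_reference_cohort
from sftag.eeg import (
    OCCIPITOPARIETAL,
    EEGRecording,
    PreprocessConfig,
    SpectrumResult,
    epoch,
    evoked_spectrum,
    log_ratio_from_db,
    marker,
    neighbor_bandwidth_hz,
    neighbor_snr,
    preprocess,
    select_peak_electrodes,
    snr,
)

SF = 1000.0
CH3 = ("Oz", "O1", "O2")


def _events(n, spacing_s=7.5, sfreq=SF, start=0):
    onsets = (start + np.arange(n) * spacing_s * sfreq).astype(int)
    conds = np.tile([1, 2], math.ceil(n / 2))[:n]
    return pd.DataFrame({"onset_sample": onsets, "video_id": 1, "condition": conds})


def _recording(data, events, ch_names=CH3):
    return EEGRecording(data=data, sfreq=SF, ch_names=ch_names, events=events)


def _sinusoid_recording(freq, n_events=4, amp=1.0, phase_locked=True, seed=0,
                        ch_names=CH3):
    """Per-presentation sinusoid segments, optionally phase-locked to onset."""
    rng = np.random.default_rng(seed)
    n_pres = int(7.5 * SF)
    n = n_events * n_pres + int(SF)
    data = np.zeros((len(ch_names), n))
    t = np.arange(n_pres) / SF
    for j in range(n_events):
        ph = 0.0 if phase_locked else rng.uniform(0, 2 * np.pi)
        data[:, j * n_pres : (j + 1) * n_pres] = amp * np.sin(2 * np.pi * freq * t + ph)
    ev = _events(n_events)
    ev["condition"] = 1
    return _recording(data, ev, ch_names)


class TestPreprocess:
    def test_dc_offset_removed(self):
        data = np.outer([5.0, -3.0, 11.0], np.ones(int(20 * SF)))
        rec = _recording(data, _events(2))
        out = preprocess(rec, PreprocessConfig(average_reference=False))
        assert np.abs(out.data).max() < 1e-6

    def test_line_noise_attenuated_20db(self):
        t = np.arange(int(30 * SF)) / SF
        rec = _recording(np.vstack([np.sin(2 * np.pi * 60 * t)] * 3), _events(2))
        out = preprocess(rec, PreprocessConfig(average_reference=False))
        mid = slice(int(5 * SF), int(25 * SF))
        gain = np.sqrt(np.mean(out.data[0, mid] ** 2) / 0.5)
        assert 20 * np.log10(gain) < -20

    def test_passband_preserves_7hz(self):
        t = np.arange(int(30 * SF)) / SF
        rec = _recording(np.vstack([np.sin(2 * np.pi * 7 * t)] * 3), _events(2))
        out = preprocess(rec, PreprocessConfig(average_reference=False))
        mid = slice(int(5 * SF), int(25 * SF))
        gain = np.sqrt(np.mean(out.data[0, mid] ** 2) / 0.5)
        assert abs(gain - 1.0) < 0.05

    def test_bad_channel_interpolated_from_neighbors(self):
        rng = np.random.default_rng(0)
        n = int(10 * SF)
        common = rng.standard_normal(n)
        data = np.vstack([common, common, 100 * rng.standard_normal(n)])
        rec = _recording(data, _events(1))
        out = preprocess(rec, PreprocessConfig(average_reference=False,
                                               bad_channels=("O2",)))
        # interpolated O2 now tracks its neighbors instead of its own garbage
        corr = np.corrcoef(out.data[2], out.data[0])[0, 1]
        assert corr > 0.99

    def test_all_marker_channels_bad_is_fatal(self):
        rec = _recording(np.zeros((3, int(10 * SF))), _events(1))
        with pytest.raises(ValueError, match="unrecoverable"):
            preprocess(rec, PreprocessConfig(bad_channels=CH3))

    def test_artifact_hook_runs_last(self):
        rec = _recording(np.ones((3, int(10 * SF))), _events(1))
        called = {}

        def hook(data, sfreq, ch_names):
            called["yes"] = True
            return data * 0

        out = preprocess(rec, PreprocessConfig(artifact_hook=hook))
        assert called and np.all(out.data == 0)


class TestEpoch:
    def test_epoch_window_arithmetic(self):
        rec = _sinusoid_recording(7.0, n_events=3)
        eps = epoch(rec)
        assert eps.epochs.shape == (3, 3, 7000)  # 7 s at 1000 Hz

    def test_epoch_starts_half_second_after_onset(self):
        # a step at onset+0.5 s should be the first sample of the epoch
        n = int(10 * SF)
        data = np.zeros((3, n))
        data[:, int(0.5 * SF) + 100] = 5.0  # marker spike inside epoch
        rec = _recording(data, _events(1))
        eps = epoch(rec, reject_uv=1e9)
        assert np.abs(eps.epochs[0, 0]).argmax() == 100

    def test_spike_beyond_150uv_rejected(self):
        rec = _sinusoid_recording(7.0, n_events=4, amp=1.0)
        rec.data[0, int(2 * SF)] = 200.0  # 200 uV spike at Oz in epoch 0
        eps = epoch(rec)
        assert eps.rejected[0]
        assert "150" in eps.reject_reason[0]
        assert not eps.rejected[1:].any()

    def test_quiet_recording_no_rejections(self):
        rec = _sinusoid_recording(7.0, n_events=4)
        eps = epoch(rec)
        assert not eps.rejected.any()

    def test_rejection_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        rec = _sinusoid_recording(7.0, n_events=8)
        rec.data[:] += 60 * rng.standard_normal(rec.data.shape)
        kept = [
            (~epoch(rec, reject_uv=thr).rejected).sum()
            for thr in (300, 250, 200, 150, 100, 50)
        ]
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_truncated_final_epoch_flagged_not_fatal(self):
        rec = _sinusoid_recording(7.0, n_events=2)
        ev = rec.events.copy()
        ev.loc[len(ev)] = {"onset_sample": rec.n_samples - 1000, "video_id": 9,
                           "condition": 2}
        rec2 = _recording(rec.data, ev)
        eps = epoch(rec2)
        assert eps.rejected[-1] and eps.reject_reason[-1] == "truncated"
        assert not eps.rejected[:-1].any()


class TestSpectrumAndSnr:
    def test_phase_locked_sinusoid_peaks_at_bin_49(self):
        rec = _sinusoid_recording(7.0, n_events=4, amp=2.0)
        spec = evoked_spectrum(epoch(rec), 1)
        assert spec.df == pytest.approx(1 / 7)
        peak = int(np.argmax(spec.amplitude[0]))
        assert peak == 49  # 7 Hz / (1/7 Hz)
        assert spec.amplitude[0, peak] == pytest.approx(2.0, rel=1e-3)

    def test_phase_random_erp_shrinks_as_sqrt_n(self):
        amp_locked = []
        amp_random = []
        for n_ev in (4, 16):
            for locked, store in ((True, amp_locked), (False, amp_random)):
                rec = _sinusoid_recording(7.0, n_events=n_ev, amp=1.0,
                                          phase_locked=locked, seed=n_ev)
                spec = evoked_spectrum(epoch(rec), 1)
                store.append(spec.amplitude[0, 49])
        assert amp_locked[0] == pytest.approx(amp_locked[1], rel=1e-6)
        # random-phase: amplitude of the mean drops roughly as 1/sqrt(N)
        assert amp_random[1] < amp_random[0]

    def test_zero_signal_flat_spectrum(self):
        rec = _recording(np.zeros((3, int(20 * SF))), _events(2))
        spec = evoked_spectrum(epoch(rec), 1)
        assert np.abs(spec.amplitude).max() == 0.0

    def test_empty_condition_raises(self):
        rec = _sinusoid_recording(7.0, n_events=2)
        with pytest.raises(ValueError, match="condition"):
            evoked_spectrum(epoch(rec), 2)

    def test_flat_spectrum_snr_is_unity(self):
        power = np.ones(100)
        lin, flag = neighbor_snr(power, 50)
        assert lin == 1.0 and not flag

    def test_neighbor_bandwidth_is_057_hz(self):
        assert neighbor_bandwidth_hz() == pytest.approx(0.5714285714, abs=1e-9)

    def test_delta_spectrum_inf_sentinel(self):
        power = np.zeros(100)
        power[50] = 4.0
        lin, flag = neighbor_snr(power, 50)
        assert lin == math.inf and flag

    def test_edge_bin_raises(self):
        with pytest.raises(ValueError, match="neighbors"):
            neighbor_snr(np.ones(100), 2)

    def test_snr_off_grid_frequency_raises(self):
        rec = _sinusoid_recording(7.0, n_events=2)
        spec = evoked_spectrum(epoch(rec), 1)
        with pytest.raises(ValueError, match="grid"):
            snr(spec, 7.05)


def _topo_spectra(peaks_by_freq, ch_names=OCCIPITOPARIETAL, noise=1e-4, seed=0):
    """Build a pair of condition spectra with SSVEPs injected at given
    channels: peaks_by_freq = {freq: {channel: linear_amplitude}}."""
    rng = np.random.default_rng(seed)
    n = 7000
    freqs = np.fft.rfftfreq(n, d=1 / SF)
    out = {}
    for cond in (1, 2):
        amp = noise * (1 + rng.random((len(ch_names), len(freqs))))
        for f, chans in peaks_by_freq.items():
            i = int(round(f * 7))
            for ch, a in chans.items():
                amp[ch_names.index(ch), i] = a
        out[cond] = SpectrumResult(freqs=freqs, amplitude=amp, sfreq=SF,
                                   ch_names=tuple(ch_names), condition=cond,
                                   n_epochs=24)
    return out


class TestElectrodeSelectionAndMarker:
    def test_injected_topography_selects_those_channels(self):
        spectra = _topo_spectra({7.0: {"Oz": 1.0, "O1": 0.7}})
        assert set(select_peak_electrodes(spectra, 7.0)) == {"Oz", "O1"}

    def test_tie_break_follows_candidate_order(self):
        spectra = _topo_spectra({}, noise=0.0)
        for c in spectra.values():
            c.amplitude[:] = 1.0  # identical channels
        assert select_peak_electrodes(spectra, 7.0) == ("Iz", "I1")

    def test_too_few_candidates_raises(self):
        spectra = _topo_spectra({7.0: {"Oz": 1.0}})
        with pytest.raises(ValueError, match="candidate"):
            select_peak_electrodes(spectra, 7.0, candidates=("Oz",))

    def test_marker_prefers_per_frequency_electrodes(self):
        # low-SF response anterior (POz), high-SF posterior (Oz): the marker
        # must pick each frequency's own electrodes
        spectra = _topo_spectra(
            {7.0: {"Oz": 1.0, "O1": 0.8}, 9.0: {"POz": 1.5, "PO3": 1.2}}
        )
        m = marker(spectra)
        assert set(m.electrodes[7.0]) == {"Oz", "O1"}
        assert set(m.electrodes[9.0]) == {"POz", "PO3"}

    def test_equal_snrs_give_zero_log_ratio(self):
        spectra = _topo_spectra(
            {7.0: {"Oz": 1.0, "O1": 1.0}, 9.0: {"Oz": 1.0, "O1": 1.0}}
        )
        m = marker(spectra)
        assert m.log_ratio == pytest.approx(0.0, abs=0.2)

    def test_db_identity_algebra(self):
        spectra = _topo_spectra(
            {7.0: {"Oz": 2.0, "O1": 1.5}, 9.0: {"POz": 0.5, "PO3": 0.4}}
        )
        m = marker(spectra)
        assert m.log_ratio == pytest.approx(
            log_ratio_from_db(m.snr_db["lower"], m.snr_db["higher"]), abs=1e-12
        )

    def test_marker_scale_invariance(self):
        rec = _make_two_condition_recording(seed=3)
        m1 = _marker_of(rec)
        rec_scaled = EEGRecording(rec.data * 17.0, rec.sfreq, rec.ch_names, rec.events)
        m2 = _marker_of(rec_scaled)
        assert m2.log_ratio == pytest.approx(m1.log_ratio, abs=1e-6)
        for sf_set in ("higher", "lower"):
            assert m2.snr_linear[sf_set] == pytest.approx(m1.snr_linear[sf_set], rel=1e-6)

    def test_counterbalancing_swap_leaves_marker_invariant(self):
        """Relabelling condition 1 <-> 2 while also swapping the two tag
        frequencies describes the same physical stimuli, so the per-SF
        marker must not change."""
        from sftag.tagging import TagSpec

        rec = _make_two_condition_recording(seed=4)
        m1 = _marker_of(rec)
        ev = rec.events.copy()
        ev["condition"] = 3 - ev["condition"]
        rec_swapped = EEGRecording(rec.data, rec.sfreq, rec.ch_names, ev)
        swapped_spec = TagSpec(freq_a_hz=9.0, freq_b_hz=7.0)
        m2 = _marker_of(rec_swapped, tag_spec=swapped_spec)
        assert m2.log_ratio == pytest.approx(m1.log_ratio, abs=1e-9)


def _make_two_condition_recording(seed=0, ch_names=OCCIPITOPARIETAL):
    """8 presentations alternating conditions, distinct 7/9 Hz amplitudes."""
    rng = np.random.default_rng(seed)
    n_pres = int(7.5 * SF)
    n_ev = 8
    data = 0.5 * rng.standard_normal((len(ch_names), n_ev * n_pres + int(SF)))
    t = np.arange(n_pres) / SF
    gains = 0.5 + rng.random(len(ch_names))
    ev = _events(n_ev)
    for j, cond in enumerate(ev.condition):
        f_high, f_low = (7.0, 9.0) if cond == 1 else (9.0, 7.0)
        seg = 0.8 * np.sin(2 * np.pi * f_high * t) + 2.0 * np.sin(2 * np.pi * f_low * t)
        data[:, j * n_pres : (j + 1) * n_pres] += gains[:, None] * seg[None, :]
    return _recording(data, ev, ch_names)


def _marker_of(rec, tag_spec=None):
    eps = epoch(rec)
    spectra = {c: evoked_spectrum(eps, c) for c in (1, 2)}
    return marker(spectra, tag_spec)


class TestReferenceCohortAlgebra:
    """The published per-participant table must be internally consistent with
    the natural-log ratio definition."""

    def test_c1_and_amd25_rows(self):
        assert log_ratio_from_db(7.86, 22.08) == pytest.approx(-3.27, abs=0.005)
        assert log_ratio_from_db(13.36, 0.45) == pytest.approx(2.97, abs=0.005)

    def test_all_31_rows_reproduce_printed_ratio(self):
        # The dB columns are themselves printed to 2 dp, so the recomputed
        # ratio can differ from the printed one by up to half an ulp of the
        # ratio plus the propagated half-ulps of the two dB inputs:
        # 0.005 + 2 * 0.005 * ln(10)/10 ~ 0.0073.
        tab = load_reference_cohort()
        assert len(tab) == 31
        recomputed = [
            log_ratio_from_db(r.ssvep_lower_db, r.ssvep_higher_db)
            for r in tab.itertuples()
        ]
        np.testing.assert_allclose(recomputed, tab.log_ratio, atol=0.0074)
        # and the overwhelming majority agree at the naive half-ulp already
        close = np.abs(np.asarray(recomputed) - tab.log_ratio) <= 0.005
        assert close.sum() >= 29
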