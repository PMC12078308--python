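"""Synthetic videos, EEG and cohorts for exercising the full pipeline.

Nothing here depends on recorded data: videos are 1/f-spectrum noise
fields (optionally with deterministic gratings) evolving with AR(1)
temporal coherence, and EEG is built from phase-locked sinusoids at the
tag frequencies with Gaussian spatial topographies on an idealized 10-20
layout, on top of 1/f^gamma background noise that is phase-random across
presentations.

Group-level SSVEP strengths are parameterized directly in dB SNR (the
scale on which groups are described); the generator converts a target dB
to a sinusoid amplitude in uV through a seeded numerical calibration of
the expected noise floor in the analysis pipeline's neighbor bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .eeg import EEGRecording, log_ratio_from_db
from .geometry import BandGeometry
from .montage import REDUCED_CHANNELS, channel_positions
from .tagging import Condition, StimulusSchedule, TagSpec, VideoClip, build_schedule

__all__ = [
    "SyntheticVideoSpec",
    "SyntheticEEGSpec",
    "SyntheticCohortSpec",
    "GroupParams",
    "CohortData",
    "make_video",
    "make_eeg",
    "make_cohort",
    "control_group_params",
    "amd_group_params",
]


# ---------------------------------------------------------------------------
# Video


@dataclass(frozen=True)
class SyntheticVideoSpec:
    size: tuple[int, int] = (128, 128)
    fps: float = 30.0
    duration_s: float = 3.0
    spectral_exponent: float = 1.0  # amplitude ~ 1/f^alpha
    temporal_coherence: float = 0.9  # AR(1) rho between successive frames
    contrast: float = 0.15  # std of the luminance field
    mean_luminance: float = 0.5
    gratings: tuple = ()  # of (cpd, orientation_rad, contrast)
    pixels_per_degree: float | None = None
    seed: int = 0


def _spatial_noise_field(rng: np.random.Generator, size, alpha: float) -> np.ndarray:
    """One 1/f^alpha-amplitude Gaussian field, unit variance, zero mean."""
    h, w = size
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    r = np.hypot(fy, fx)
    shape = np.zeros_like(r)
    shape[r > 0] = r[r > 0] ** (-alpha)
    spec = (rng.standard_normal((h, fx.shape[1])) + 1j * rng.standard_normal((h, fx.shape[1]))) * shape
    x = np.fft.irfft2(spec, s=size)
    x -= x.mean()
    return x / x.std()


def make_video(spec: SyntheticVideoSpec) -> VideoClip:
    """Natural-statistics clip: AR(1)-evolving 1/f noise plus optional gratings.

    Frames are grayscale (equal RGB), value-range clipped to [0, 1];
    identical seeds give bit-identical clips.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration_s * spec.fps))
    h, w = spec.size
    ppd = spec.pixels_per_degree
    geom = BandGeometry() if ppd is None else BandGeometry(pixels_per_degree=ppd)

    rho = spec.temporal_coherence
    field_t = _spatial_noise_field(rng, spec.size, spec.spectral_exponent)
    static = np.zeros(spec.size)
    if spec.gratings:
        yy, xx = np.mgrid[0:h, 0:w]
        for cpd, theta, contrast in spec.gratings:
            cpp = geom.cpd_to_cpp(cpd)
            static += contrast * np.sin(
                2.0 * np.pi * cpp * (xx * np.cos(theta) + yy * np.sin(theta))
            )

    frames = np.empty((n_frames, h, w, 3))
    for i in range(n_frames):
        if i > 0:
            fresh = _spatial_noise_field(rng, spec.size, spec.spectral_exponent)
            field_t = rho * field_t + math.sqrt(1.0 - rho**2) * fresh
        v = spec.mean_luminance + spec.contrast * field_t + static
        frames[i] = np.clip(v, 0.0, 1.0)[..., None]
    return VideoClip(frames=frames, fps=spec.fps, geometry=geom, meta={"seed": spec.seed})


# ---------------------------------------------------------------------------
# EEG


@dataclass(frozen=True)
class GroupParams:
    """SSVEP strength and topography of one participant group.

    ``mean_db``/``sd_db`` describe the across-participant distribution of
    SSVEP SNR (dB) per spatial-frequency set; ``topo_center`` is the
    electrode where that set's response peaks, with a Gaussian falloff of
    width ``topo_sigma`` (meters of inter-electrode distance).
    """

    mean_db: dict
    sd_db: dict
    topo_center: dict
    topo_sigma: float = 0.05
    #: optional fixed sinusoid amplitudes in uV per SF set; when given they
    #: bypass the dB-to-amplitude calibration (useful for noiseless tests).
    amp_uv: dict | None = None


def control_group_params() -> GroupParams:
    """Age-matched healthy controls: strong high-SF and low-SF responses at Oz."""
    return GroupParams(
        mean_db={"higher": 11.70, "lower": 11.00},
        sd_db={"higher": 4.76, "lower": 3.17},
        topo_center={"higher": "Oz", "lower": "Oz"},
    )


def amd_group_params() -> GroupParams:
    """AMD-like group: weakened high-SF response, boosted low-SF response
    shifted anteriorly toward POz."""
    return GroupParams(
        mean_db={"higher": 5.99, "lower": 13.20},
        sd_db={"higher": 2.21, "lower": 2.26},
        topo_center={"higher": "Oz", "lower": "POz"},
    )


@dataclass(frozen=True)
class SyntheticEEGSpec:
    ch_names: tuple = REDUCED_CHANNELS
    sfreq: float = 1000.0
    schedule: StimulusSchedule | None = None  # defaults to the 48-presentation run
    tag_spec: TagSpec = field(default_factory=TagSpec)
    noise_exponent: float = 1.0  # power ~ 1/f^gamma
    noise_rms_uv: float = 15.0
    harmonic_gain: float = 0.3
    spike_rate: float = 0.0  # per-presentation probability of an artifact spike
    spike_amp_uv: float = 300.0
    seed: int = 0


def _schedule_or_default(spec: SyntheticEEGSpec) -> StimulusSchedule:
    return spec.schedule if spec.schedule is not None else build_schedule(seed=spec.seed)


def _noise_epoch(rng, n_rows, n_samp, sfreq, gamma, rms):
    """Independent 1/f^gamma Gaussian noise rows, target RMS in uV.

    Generated in single precision (the background noise model does not
    warrant 15 significant digits) for speed.
    """
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / sfreq)
    shape = np.zeros(len(freqs), dtype=np.float32)
    shape[freqs > 0] = freqs[freqs > 0] ** (-gamma / 2.0)
    z = rng.standard_normal((2, n_rows, len(freqs)), dtype=np.float32)
    spec = (z[0] + 1j * z[1]) * shape
    x = np.fft.irfft(spec, n=n_samp, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    ms = np.mean(x**2, axis=-1, keepdims=True)
    scale = np.where(ms > 0, rms / np.sqrt(np.maximum(ms, 1e-30)), 0.0)
    return x * scale


_CALIBRATION_CACHE: dict = {}


def _expected_neighbor_power(spec: SyntheticEEGSpec, freq_hz: float,
                             epoch_len_s: float = 7.0, n_neighbors: int = 4) -> float:
    """Expected single-epoch neighbor-bin power of the background noise.

    Measured by a short fixed-seed Monte-Carlo run through the same
    windowing/detrending/FFT conventions the analysis uses; cached per
    noise configuration.  Used to convert a target SNR (dB) into an
    injected sinusoid amplitude.
    """
    import scipy.signal

    key = (spec.sfreq, spec.noise_exponent, spec.noise_rms_uv, freq_hz, epoch_len_s)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    rng = np.random.default_rng(123456789)  # calibration seed, independent of data seeds
    n = int(round(epoch_len_s * spec.sfreq))
    m = 48
    x = _noise_epoch(rng, m, n, spec.sfreq, spec.noise_exponent, spec.noise_rms_uv)
    x = scipy.signal.detrend(x, axis=1)
    amp = np.abs(np.fft.rfft(x, axis=1)) * 2.0 / n
    power = amp**2
    i = int(round(freq_hz * epoch_len_s))
    neigh = np.r_[power[:, i - n_neighbors : i].ravel(), power[:, i + 1 : i + 1 + n_neighbors].ravel()]
    val = float(neigh.mean())
    _CALIBRATION_CACHE[key] = val
    return val


def _amplitude_for_db(spec: SyntheticEEGSpec, target_db: float, freq_hz: float,
                      n_avg: int) -> float:
    """Sinusoid amplitude (uV) whose pipeline SNR is expected to hit target_db."""
    noise_floor = _expected_neighbor_power(spec, freq_hz) / n_avg
    target_lin = 10.0 ** (target_db / 10.0)
    return math.sqrt(target_lin * noise_floor)


def make_eeg(
    spec: SyntheticEEGSpec,
    group: GroupParams | str,
    return_truth: bool = False,
):
    """Simulate one participant's recording for the full stimulus schedule.

    Per presentation, sinusoids at the condition's two tag frequencies
    (plus second harmonics at ``harmonic_gain``) are added with channel
    gains from the group's per-SF Gaussian topographies; the sinusoid
    phase is locked to presentation onset, while background noise is
    drawn fresh per presentation.  Optional supra-threshold spikes test
    the artifact-rejection path.
    """
    if isinstance(group, str):
        group = {"control": control_group_params(), "amd": amd_group_params()}[group.lower()]
    rng = np.random.default_rng(spec.seed)
    schedule = _schedule_or_default(spec)
    sf = spec.sfreq
    n_pres = int(round(schedule.clip_duration_s * sf))
    n_total = n_pres * len(schedule) + int(sf)  # 1 s tail margin
    n_ch = len(spec.ch_names)
    pos = channel_positions(spec.ch_names)

    # Per-participant SSVEP strength (dB) and phase per SF set.
    n_avg = len(schedule) // 2  # epochs averaged per condition
    truth: dict = {"db": {}, "amp_uv": {}, "phase": {}, "topo_gain": {}, "spike_presentations": []}
    topo = {}
    for sf_set in ("higher", "lower"):
        db = rng.normal(group.mean_db[sf_set], group.sd_db[sf_set])
        center = np.asarray(pos[group.topo_center[sf_set]])
        gains = np.array(
            [math.exp(-np.sum((np.asarray(pos[c]) - center) ** 2) / (2 * group.topo_sigma**2))
             for c in spec.ch_names]
        )
        truth["db"][sf_set] = db
        truth["phase"][sf_set] = rng.uniform(0, 2 * np.pi)
        truth["topo_gain"][sf_set] = gains
        topo[sf_set] = gains

    # Per-condition signal template: the two SF sinusoids (plus harmonics),
    # phase-locked to presentation onset, projected through the topographies.
    t_local = np.arange(n_pres) / sf
    templates = {}
    for cond in (Condition.COND1, Condition.COND2):
        tag = replace(spec.tag_spec, condition=cond)
        tpl = np.zeros((n_ch, n_pres))
        for sf_set in ("higher", "lower"):
            f = tag.frequency_for(sf_set)
            if group.amp_uv is not None:
                amp = group.amp_uv[sf_set]
            else:
                amp = _amplitude_for_db(spec, truth["db"][sf_set], f, n_avg)
            truth["amp_uv"][(sf_set, f)] = amp
            phase = truth["phase"][sf_set]
            wave = amp * np.sin(2 * np.pi * f * t_local + phase)
            wave += spec.harmonic_gain * amp * np.sin(2 * np.pi * 2 * f * t_local + phase)
            tpl += topo[sf_set][:, None] * wave[None, :]
        templates[int(cond)] = tpl

    noise = _noise_epoch(
        rng, len(schedule) * n_ch, n_pres, sf, spec.noise_exponent, spec.noise_rms_uv
    ).reshape(len(schedule), n_ch, n_pres)

    data = np.zeros((n_ch, n_total), dtype=np.float32)
    onsets = []
    for j, (video_id, cond, _) in enumerate(schedule.entries):
        start = j * n_pres
        onsets.append((start, video_id, int(cond)))
        seg = data[:, start : start + n_pres]
        seg += noise[j]
        seg += templates[int(cond)]
        if spec.spike_rate > 0 and rng.random() < spec.spike_rate:
            truth["spike_presentations"].append(j)
            # 50 ms half-sine spike at Oz, inside the analysis epoch window
            i0 = int(1.0 * sf) + int(rng.integers(0, int(5.0 * sf)))
            width = int(0.05 * sf)
            pulse = spec.spike_amp_uv * np.sin(np.linspace(0, np.pi, width))
            ch = spec.ch_names.index("Oz") if "Oz" in spec.ch_names else 0
            seg[ch, i0 : i0 + width] += pulse

    events = pd.DataFrame(
        {
            "onset_sample": [o[0] for o in onsets],
            "video_id": [o[1] for o in onsets],
            "condition": [o[2] for o in onsets],
        }
    )
    truth["log_ratio"] = log_ratio_from_db(truth["db"]["lower"], truth["db"]["higher"])
    rec = EEGRecording(data=data, sfreq=sf, ch_names=spec.ch_names, events=events)
    return (rec, truth) if return_truth else rec


# ---------------------------------------------------------------------------
# Cohort


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_amd: int = 15
    n_control: int = 16
    amd_params: GroupParams = field(default_factory=amd_group_params)
    control_params: GroupParams = field(default_factory=control_group_params)
    eeg: SyntheticEEGSpec = field(default_factory=SyntheticEEGSpec)
    # Behavioral link: score = intercept + beta * log_ratio_true + N(0, noise_sd)
    beta_logmar: float = 0.54
    intercept_logmar: float = 0.03
    noise_logmar: float = 0.10
    beta_logcs: float = -0.41
    intercept_logcs: float = 1.74
    noise_logcs: float = 0.15
    include_recordings: bool = True
    seed: int = 0


@dataclass
class CohortData:
    scores: pd.DataFrame  # id, group, logmar, logcs, true_log_ratio, true dB columns
    recordings: dict  # id -> EEGRecording (empty if not generated)
    truths: dict  # id -> generator ground truth


def make_cohort(spec: SyntheticCohortSpec) -> CohortData:
    """Simulate a two-group cohort with linked behavioral scores.

    Per participant: an EEG recording (optional, for pipeline runs) and
    behavioral scores generated from the participant's true log ratio
    through the stated linear links.  ``n >= 2`` per group required.
    """
    if min(spec.n_amd, spec.n_control) < 2:
        raise ValueError("need at least 2 participants per group")
    rng = np.random.default_rng(spec.seed)
    rows = []
    recordings: dict = {}
    truths: dict = {}
    roster = [("amd", i, spec.amd_params) for i in range(spec.n_amd)] + [
        ("control", i, spec.control_params) for i in range(spec.n_control)
    ]
    for group_name, i, params in roster:
        pid = f"{group_name.upper()}{i + 1}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        eeg_spec = replace(spec.eeg, seed=sub_seed)
        if spec.include_recordings:
            rec, truth = make_eeg(eeg_spec, params, return_truth=True)
            recordings[pid] = rec
        else:
            # Draw the same per-participant dB values the generator would use.
            sub_rng = np.random.default_rng(sub_seed)
            truth = {"db": {}}
            for sf_set in ("higher", "lower"):
                truth["db"][sf_set] = sub_rng.normal(
                    params.mean_db[sf_set], params.sd_db[sf_set]
                )
            truth["log_ratio"] = log_ratio_from_db(
                truth["db"]["lower"], truth["db"]["higher"]
            )
        truths[pid] = truth
        lr = truth["log_ratio"]
        rows.append(
            {
                "id": pid,
                "group": group_name.upper() if group_name == "amd" else "control",
                "logmar": spec.intercept_logmar + spec.beta_logmar * lr
                + rng.normal(0, spec.noise_logmar),
                "logcs": spec.intercept_logcs + spec.beta_logcs * lr
                + rng.normal(0, spec.noise_logcs),
                "true_log_ratio": lr,
                "true_db_higher": truth["db"]["higher"],
                "true_db_lower": truth["db"]["lower"],
            }
        )
    return CohortData(scores=pd.DataFrame(rows), recordings=recordings, truths=truths)
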