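"""Embedding temporal frequency tags into the spatial-frequency content of video.

Each RGB frame is converted to HSV; the value (luminance) channel is run
through the steerable pyramid; every oriented channel in the *higher*
spatial-frequency scale set is scaled by a gain driven by one sinusoidal
flicker signal, every channel in the *lower* set by the other; the frame
is reconstructed and recombined with its untouched hue and saturation.

The per-channel power filter is ``F = (2A - 1) * |sin(2 theta)|`` where
``A in [0, 1]`` is the instantaneous flicker amplitude and ``theta`` the
channel orientation: oblique orientations are modulated up and down
around unity while cardinal orientations (theta = 0, pi/2) are left
untouched.  The filter is mapped to a multiplicative coefficient gain
``g = 1 + F`` (so ``g in [0, 2]`` and ``g = 1`` means "no change").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from math import pi, sin

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv

from .geometry import BandGeometry
from .pyramid import get_pyramid, map_threshold_to_scales

__all__ = [
    "Condition",
    "TagSpec",
    "StimulusSchedule",
    "VideoClip",
    "VideoTagger",
    "flicker_amplitude",
    "orientation_filter",
    "channel_gain",
    "tag_frame",
    "tag_video",
    "build_schedule",
]

# Mean of |sin(2 theta_k)| over the 8 orientation channels; used to drive
# the (isotropic) highpass residual together with the higher-SF set.
def _mean_oblique_weight(n_orientations: int) -> float:
    return float(np.mean(np.abs(np.sin(2 * np.arange(n_orientations) * pi / n_orientations))))


class Condition(enum.IntEnum):
    """Counterbalanced tag-frequency-to-SF-band assignments."""

    COND1 = 1  # higher SF -> freq_a (7 Hz), lower SF -> freq_b (9 Hz)
    COND2 = 2  # higher SF -> freq_b (9 Hz), lower SF -> freq_a (7 Hz)


@dataclass(frozen=True)
class TagSpec:
    """What to tag, at which frequencies, under which condition."""

    threshold_cpd: float = 3.2
    freq_a_hz: float = 7.0
    freq_b_hz: float = 9.0
    condition: Condition = Condition.COND1
    start_phase_rad: float = 0.0

    def __post_init__(self):
        if self.freq_a_hz == self.freq_b_hz:
            raise ValueError("the two tag frequencies must differ")

    def frequency_for(self, sf_set: str) -> float:
        """Tag frequency (Hz) assigned to 'higher' or 'lower' SF under this condition."""
        if sf_set not in ("higher", "lower"):
            raise ValueError("sf_set must be 'higher' or 'lower'")
        if Condition(self.condition) is Condition.COND1:
            return self.freq_a_hz if sf_set == "higher" else self.freq_b_hz
        return self.freq_b_hz if sf_set == "higher" else self.freq_a_hz


@dataclass
class VideoClip:
    """Ordered RGB frames plus frame rate and viewing geometry."""

    frames: np.ndarray  # (n_frames, height, width, 3), values in [0, 1]
    fps: float
    geometry: BandGeometry = field(default_factory=BandGeometry)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (n_frames, h, w, 3)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class StimulusSchedule:
    """Randomized presentation order of (video, condition) pairs."""

    entries: tuple  # of (video_id, Condition, presentation_index)
    n_videos: int
    n_conditions: int
    n_repeats: int
    seed: int
    clip_duration_s: float = 7.5

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total_duration_s(self) -> float:
        return len(self.entries) * self.clip_duration_s

    def onsets_s(self) -> np.ndarray:
        return np.arange(len(self.entries)) * self.clip_duration_s

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "presentation_index": [e[2] for e in self.entries],
                "video_id": [e[0] for e in self.entries],
                "condition": [int(e[1]) for e in self.entries],
                "onset_s": self.onsets_s(),
            }
        )


def flicker_amplitude(t, freq_hz: float, phase_rad: float = 0.0):
    """Sinusoidal flicker amplitude ``A(t) = (1 + sin(2 pi f t + phase)) / 2``.

    Oscillates in [0, 1]; at A = 0.5 the tag leaves the frame unchanged.
    """
    return 0.5 * (1.0 + np.sin(2.0 * pi * freq_hz * np.asarray(t, dtype=float) + phase_rad))


def orientation_filter(A: float, theta: float) -> float:
    """Power filter ``F = (2A - 1) |sin 2 theta|``; zero at cardinal angles."""
    A = float(A)
    if not 0.0 <= A <= 1.0:
        raise ValueError(f"flicker amplitude must be in [0, 1], got {A}")
    return (2.0 * A - 1.0) * abs(sin(2.0 * theta))


def channel_gain(F: float) -> float:
    """Map the power filter to a multiplicative coefficient gain ``g = 1 + F``."""
    return 1.0 + float(F)


class VideoTagger:
    """Caches the pyramid, SF partition and per-channel weights for one geometry."""

    def __init__(
        self,
        frame_shape: tuple[int, int],
        spec: TagSpec,
        geometry: BandGeometry | None = None,
        n_orientations: int = 8,
    ):
        self.spec = spec
        self.geometry = geometry or BandGeometry()
        self.pyramid = get_pyramid(frame_shape, self.geometry.n_scales, n_orientations)
        self.higher_scales, self.lower_scales = map_threshold_to_scales(
            self.geometry, spec.threshold_cpd
        )
        self.theta = np.arange(n_orientations) * pi / n_orientations
        self._oblique_w = np.abs(np.sin(2.0 * self.theta))
        self._hp_w = _mean_oblique_weight(n_orientations)

    def gains_at(self, t: float) -> tuple[dict, float]:
        """Per-channel gains and the highpass-residual gain at time t (s)."""
        a_high = flicker_amplitude(t, self.spec.frequency_for("higher"), self.spec.start_phase_rad)
        a_low = flicker_amplitude(t, self.spec.frequency_for("lower"), self.spec.start_phase_rad)
        gains: dict[tuple[int, int], float] = {}
        for s in self.higher_scales:
            for k, w in enumerate(self._oblique_w):
                gains[(s, k)] = 1.0 + (2.0 * a_high - 1.0) * w
        for s in self.lower_scales:
            for k, w in enumerate(self._oblique_w):
                gains[(s, k)] = 1.0 + (2.0 * a_low - 1.0) * w
        hp_gain = 1.0 + (2.0 * a_high - 1.0) * self._hp_w
        return gains, hp_gain

    def tag_frame(self, frame_rgb: np.ndarray, t: float) -> tuple[np.ndarray, float]:
        """Tag one frame at clip time ``t``; returns (frame, clipped_fraction)."""
        frame_rgb = np.asarray(frame_rgb, dtype=float)
        hsv = rgb_to_hsv(frame_rgb)
        v = hsv[..., 2]
        gains, hp_gain = self.gains_at(t)
        v_mod, _ = self.pyramid.band_gains_applied(v, gains, highpass_gain=hp_gain)
        clipped = float(np.mean((v_mod < 0.0) | (v_mod > 1.0)))
        hsv_out = hsv.copy()
        hsv_out[..., 2] = np.clip(v_mod, 0.0, 1.0)
        return hsv_to_rgb(hsv_out), clipped

    def tag_video(self, clip: VideoClip) -> VideoClip:
        nyq = clip.fps / 2.0
        fmax = max(self.spec.freq_a_hz, self.spec.freq_b_hz)
        if fmax >= nyq:
            raise ValueError(
                f"tag frequency {fmax} Hz is not below the temporal Nyquist "
                f"frequency {nyq} Hz of a {clip.fps} fps clip"
            )
        out = np.empty_like(clip.frames)
        clipped = np.empty(clip.n_frames)
        for i, t in enumerate(clip.times()):
            out[i], clipped[i] = self.tag_frame(clip.frames[i], t)
        meta = dict(clip.meta)
        meta.update(
            condition=int(self.spec.condition),
            threshold_cpd=self.spec.threshold_cpd,
            freqs_hz=(self.spec.freq_a_hz, self.spec.freq_b_hz),
            start_phase_rad=self.spec.start_phase_rad,
            clipped_fraction_per_frame=clipped,
        )
        return VideoClip(frames=out, fps=clip.fps, geometry=clip.geometry, meta=meta)


def tag_frame(
    frame_rgb: np.ndarray,
    t: float,
    spec: TagSpec,
    geom: BandGeometry | None = None,
) -> np.ndarray:
    """Tag a single RGB frame at time ``t`` seconds (convenience wrapper)."""
    tagger = VideoTagger(np.asarray(frame_rgb).shape[:2], spec, geom)
    frame, _ = tagger.tag_frame(frame_rgb, t)
    return frame


def tag_video(clip: VideoClip, spec: TagSpec) -> VideoClip:
    """Tag every frame of a clip with flicker evaluated at its timestamp."""
    return VideoTagger(clip.frame_shape, spec, clip.geometry).tag_video(clip)


def build_schedule(
    n_videos: int = 6,
    n_conditions: int = 2,
    n_repeats: int = 4,
    seed: int = 0,
    clip_duration_s: float = 7.5,
) -> StimulusSchedule:
    """Seeded random permutation of the full (video x condition x repeat) factorial.

    Defaults give the 6 videos x 2 conditions x 4 repeats = 48 presentations
    of a 6-minute run at 7.5 s per clip.
    """
    if min(n_videos, n_conditions, n_repeats) < 1:
        raise ValueError("all counts must be >= 1")
    cells = [
        (v, Condition(c + 1) if n_conditions == 2 else c + 1)
        for v in range(1, n_videos + 1)
        for c in range(n_conditions)
        for _ in range(n_repeats)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    entries = tuple(
        (cells[j][0], cells[j][1], i) for i, j in enumerate(order)
    )
    return StimulusSchedule(
        entries=entries,
        n_videos=n_videos,
        n_conditions=n_conditions,
        n_repeats=n_repeats,
        seed=seed,
        clip_duration_s=clip_duration_s,
    )
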