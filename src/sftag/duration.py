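"""Marker stability versus experiment duration, and the convergence model.

For a target duration ``T`` the scan draws, per participant and per
permutation, ``N/2`` epochs with replacement from each tagging condition
(``N = T / 7.5`` presentations), recomputes the marker from just those
epochs, and summarizes the group means and the AMD-control gap with
percentile (Monte-Carlo) confidence intervals.

The gap-versus-duration curve is then fit with the inverse exponential

    y(T) = a * (1 - exp(-s * (T - i)))

whose asymptote ``a``, scaling factor ``s`` and x-intercept ``i`` give
the duration needed to reach 99% of asymptote, ``t99 = i + ln(100)/s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .eeg import EpochSet, SSVEPMarker, evoked_spectrum, marker
from .tagging import Condition, TagSpec

__all__ = [
    "DurationScanResult",
    "ExpFitResult",
    "duration_scan",
    "fit_inverse_exponential",
    "marker_from_epoch_sample",
]

DEFAULT_DURATIONS_S = (15.0, 60.0, 120.0, 180.0, 240.0, 300.0, 360.0)
CLIP_DURATION_S = 7.5


@dataclass
class DurationScanResult:
    durations_s: tuple
    n_permutations: int
    #: per duration: array (n_permutations,) of group-mean markers per permutation
    group_means: dict  # {group: {T: array}}
    gap: dict  # {T: array} AMD - control per permutation
    summary: dict  # {T: {'gap_mean', 'gap_ci', 'amd_mean', 'control_mean', ...}}
    seed: int


@dataclass
class ExpFitResult:
    a: float  # asymptote
    s: float  # scaling factor (1/s units of the x axis)
    i: float  # x-axis intercept
    r2: float
    t99: float  # duration reaching 99% of the asymptote

    def predict(self, T):
        return self.a * (1.0 - np.exp(-self.s * (np.asarray(T, dtype=float) - self.i)))


def marker_from_epoch_sample(
    epochs: EpochSet, indices_by_condition: dict, tag_spec: TagSpec | None = None
) -> SSVEPMarker:
    """Marker recomputed from an explicit per-condition epoch sample."""
    idx = np.concatenate([np.asarray(v, dtype=int) for v in indices_by_condition.values()])
    sub = epochs.subset(idx)
    spectra = {int(c): evoked_spectrum(sub, int(c)) for c in indices_by_condition}
    return marker(spectra, tag_spec)


def duration_scan(
    epochs_by_participant: dict,
    groups: dict,
    durations_s=DEFAULT_DURATIONS_S,
    n_perm: int = 30,
    seed: int = 0,
    tag_spec: TagSpec | None = None,
    clip_duration_s: float = CLIP_DURATION_S,
) -> DurationScanResult:
    """Bootstrap the marker over subsampled presentations at each duration.

    ``epochs_by_participant`` maps participant id -> EpochSet (artifact
    rejection already applied; rejected epochs are never sampled);
    ``groups`` maps participant id -> 'AMD' | 'control'.  Sampling is
    with replacement, independently per participant, permutation and
    condition; the full scan is reproducible bit-for-bit given ``seed``.
    """
    durations_s = tuple(float(T) for T in durations_s)
    for T in durations_s:
        n_trials = T / clip_duration_s
        if n_trials < 2 or abs(n_trials - round(n_trials)) > 1e-9:
            raise ValueError(
                f"duration {T} s must be a multiple of {clip_duration_s} s covering "
                "at least one trial per condition"
            )
    rng = np.random.default_rng(seed)
    conds = (int(Condition.COND1), int(Condition.COND2))
    kept = {
        pid: {c: ep.kept(c) for c in conds} for pid, ep in epochs_by_participant.items()
    }
    for pid, by_c in kept.items():
        for c, k in by_c.items():
            if len(k) == 0:
                raise ValueError(f"participant {pid} has no usable epochs in condition {c}")

    group_means: dict = {"AMD": {}, "control": {}}
    gap: dict = {}
    summary: dict = {}
    pids = list(epochs_by_participant)
    for T in durations_s:
        n_half = int(round(T / clip_duration_s)) // 2
        per_perm = {g: np.empty(n_perm) for g in group_means}
        for p in range(n_perm):
            markers = {g: [] for g in group_means}
            for pid in pids:
                sample = {
                    c: rng.choice(kept[pid][c], size=n_half, replace=True) for c in conds
                }
                m = marker_from_epoch_sample(epochs_by_participant[pid], sample, tag_spec)
                markers[groups[pid]].append(m.log_ratio)
            for g in group_means:
                per_perm[g][p] = float(np.mean(markers[g])) if markers[g] else np.nan
        for g in group_means:
            group_means[g][T] = per_perm[g]
        gap[T] = per_perm["AMD"] - per_perm["control"]
        summary[T] = {
            "amd_mean": float(np.nanmean(per_perm["AMD"])),
            "control_mean": float(np.nanmean(per_perm["control"])),
            "gap_mean": float(np.nanmean(gap[T])),
            "gap_ci": tuple(np.nanpercentile(gap[T], [2.5, 97.5]).tolist()),
            "amd_ci": tuple(np.nanpercentile(per_perm["AMD"], [2.5, 97.5]).tolist()),
            "control_ci": tuple(np.nanpercentile(per_perm["control"], [2.5, 97.5]).tolist()),
        }
    return DurationScanResult(
        durations_s=durations_s,
        n_permutations=n_perm,
        group_means=group_means,
        gap=gap,
        summary=summary,
        seed=seed,
    )


def _inv_exp(T, a, s, i):
    return a * (1.0 - np.exp(-s * (T - i)))


def fit_inverse_exponential(T, y) -> ExpFitResult:
    """Nonlinear least squares of ``y = a (1 - exp(-s (T - i)))``.

    The objective is nonconvex, so several starting values of ``s`` are
    tried and the best sum of squares kept.  ``t99`` solves
    ``y(t99) = 0.99 a``, i.e. ``t99 = i + ln(100)/s``.
    """
    T = np.asarray(T, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(T) < 4:
        raise ValueError("need at least 4 points to fit the three-parameter model")
    if np.allclose(y, y[0]):
        raise ValueError("response is constant; model unidentifiable")
    best = None
    a0 = y[np.argmax(np.abs(y))]
    for s0 in (1e-3, 1e-2, 1e-1):
        try:
            popt, _ = scipy.optimize.curve_fit(
                _inv_exp,
                T,
                y,
                p0=(a0, s0, 0.0),
                maxfev=20000,
                bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.min(T)]),
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - _inv_exp(T, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError(
            "inverse-exponential fit failed to converge from all starting points; "
            f"data range y=[{y.min():.3g}, {y.max():.3g}]"
        )
    sse, (a, s, i) = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst
    t99 = i + math.log(100.0) / s
    return ExpFitResult(a=float(a), s=float(s), i=float(i), r2=float(r2), t99=float(t99))
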