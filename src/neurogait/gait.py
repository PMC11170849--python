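"""Knee-angle trace processing: averaging, movement onset, gait events.

Onset detection uses a two-stage rule: find the first time the smoothed
trace exceeds the pre-cue baseline by a threshold and stays above it for a
persistence interval, then backtrack to the last sample at or below the
baseline plus a small fraction of the threshold.  The backtracking step
recovers the true start of a smooth movement, which the raw threshold
crossing alone would place tens of milliseconds late.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import KneeAngleTraces


@dataclass
class KneeAngleTrace:
    """One (possibly trial-averaged) knee-angle trace.

    ``times`` are seconds relative to the MP cue; ``angle`` in degrees.
    """

    times: np.ndarray
    angle: np.ndarray
    fs: float
    me_cue_s: float      # ME cue time on this axis (relative to MP cue)
    n_trials: int = 1
    side: str = "all"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.times.shape != self.angle.shape:
            raise ValueError("times and angle must have equal length")
        if not np.all(np.isfinite(self.angle)):
            raise ValueError("angle must be finite")


@dataclass
class GaitEvents:
    """Movement onset and peak descriptors for one trace.

    ``onset_s`` and ``reaction_time_s`` are seconds after the ME cue (they
    coincide when the onset follows the cue; an anticipatory onset is
    negative).  ``peak_time_s`` is the onset-to-peak delay.
    """

    onset_s: float
    reaction_time_s: float
    peak_time_s: float
    peak_angle_deg: float


class NoMovementError(ValueError):
    """Raised when the threshold is never reached (no movement detected)."""


def average_trace(traces: KneeAngleTraces, trials: np.ndarray | None = None,
                  side: str = "all") -> KneeAngleTrace:
    """Pointwise mean of cue-aligned knee traces, on the MP-cue time axis.

    All per-trial traces share the generator's common cue-aligned span, so
    truncation to a common support is the identity here; traces of unequal
    length would indicate misaligned time axes and raise.
    """
    angles = traces.angles if trials is None else traces.angles[np.asarray(trials)]
    if angles.size == 0:
        raise ValueError("no trials selected")
    t = traces.times() - traces.mp_cue_s
    return KneeAngleTrace(t, angles.mean(axis=0), traces.fs,
                          me_cue_s=traces.me_cue_s - traces.mp_cue_s,
                          n_trials=angles.shape[0], side=side)


def _smooth(x: np.ndarray, fs: float, width_s: float) -> np.ndarray:
    w = max(int(round(width_s * fs)), 1)
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def detect_onset(trace: KneeAngleTrace, threshold_deg: float = 5.0,
                 baseline: tuple[float, float] | None = None,
                 persist_s: float = 0.1, smooth_s: float = 0.05,
                 backtrack_frac: float = 0.1) -> float:
    """Movement onset in seconds after the ME cue.

    The trace is moving-average smoothed, a baseline mean is taken over
    ``baseline`` (default: the second before the ME cue), and the onset is
    the backtracked start of the first excursion that exceeds
    ``baseline + threshold_deg`` for at least ``persist_s``.  The onset may
    be negative (movement anticipating the cue).  Raises
    :class:`NoMovementError` when the threshold is never sustained.
    """
    if baseline is None:
        baseline = (trace.me_cue_s - 1.0, trace.me_cue_s)
    if baseline[1] > trace.me_cue_s + 1e-9:
        raise ValueError("baseline window must precede the ME cue")
    x = _smooth(trace.angle, trace.fs, smooth_s)
    bmask = (trace.times >= baseline[0]) & (trace.times < baseline[1])
    if not np.any(bmask):
        raise ValueError("baseline window outside the trace")
    base = x[bmask].mean()

    above = x > base + threshold_deg
    persist = max(int(round(persist_s * trace.fs)), 1)
    # first index from which `above` holds for `persist` consecutive samples
    run = np.convolve(above.astype(int), np.ones(persist, dtype=int), mode="valid")
    starts = np.flatnonzero(run == persist)
    if len(starts) == 0:
        raise NoMovementError(
            f"threshold of {threshold_deg} deg above baseline never sustained")
    k = starts[0]
    # backtrack to the last sample at/below baseline + a fraction of threshold
    floor = base + backtrack_frac * threshold_deg
    below = np.flatnonzero(x[:k + 1] <= floor)
    onset_idx = int(below[-1]) if len(below) else int(k)
    return float(trace.times[onset_idx] - trace.me_cue_s)


def gait_events(trace: KneeAngleTrace, onset_s: float,
                baseline: tuple[float, float] | None = None) -> GaitEvents:
    """Peak latency and amplitude relative to a detected onset.

    ``peak_time_s`` is argmax(angle) − onset (ties broken toward the
    earlier peak); ``peak_angle_deg`` is the maximum minus the pre-cue
    baseline mean.
    """
    if baseline is None:
        baseline = (trace.me_cue_s - 1.0, trace.me_cue_s)
    t_on = trace.me_cue_s + onset_s
    if t_on > trace.times[-1]:
        raise ValueError("onset lies after the end of the trace")
    bmask = (trace.times >= baseline[0]) & (trace.times < baseline[1])
    base = trace.angle[bmask].mean()
    after = trace.times >= t_on
    idx = np.flatnonzero(after)
    k = idx[int(np.argmax(trace.angle[idx]))]
    return GaitEvents(
        onset_s=float(onset_s),
        reaction_time_s=float(onset_s),
        peak_time_s=float(trace.times[k] - t_on),
        peak_angle_deg=float(trace.angle[k] - base),
    )


def trial_knee_peaks(traces: KneeAngleTraces,
                     baseline_s: float = 1.0) -> np.ndarray:
    """Per-trial peak knee-angle change (deg) during the ME phase.

    The maximum of each smoothed trial trace after the ME cue minus that
    trial's pre-cue baseline mean — the per-trial motor-performance
    quantity regressed against preparatory connectivity.
    """
    t = traces.times()
    me = traces.me_cue_s
    bmask = (t >= me - baseline_s) & (t < me)
    amask = t >= me
    out = np.empty(traces.angles.shape[0])
    for i, tr in enumerate(traces.angles):
        x = _smooth(tr, traces.fs, 0.05)
        out[i] = x[amask].max() - x[bmask].mean()
    return out
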