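"""Pairwise Pearson functional connectivity, static and time-varying.

Connectivity between two channels x and y over a window of N_t samples is
the sample Pearson correlation

    r_xy = sum_i (x_i - x̄)(y_i - ȳ) /
           sqrt(sum_i (x_i - x̄)^2) / sqrt(sum_i (y_i - ȳ)^2),

aggregated over all channel pairs into a symmetric N_c x N_c matrix with a
unit diagonal.  Static connectivity uses each full 3-s phase window
(N_t = 1500 at 500 Hz); time-varying connectivity slides a 200-ms window
with 90% overlap along the 6-s MP+ME segment (N_t = 100, step 20 ms),
yielding 291 windows without padding.

The parietal–frontocentral connectivity (PFCC) time courses are the
windowed correlations of the P3–FC4 and P3–C4 pairs on alpha-band filtered
signals, with two landmark times: the first window after the MP cue at
which the trial-averaged curve turns negative, and the peak time within
the ME phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .filtering import ALPHA_BAND, FIRBandpass
from .montage import MOTOR_CHANNELS_9
from .session import EpochedSession

#: Default frequency bands (Hz) for the motor-area connectivity grid.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

PHASES = ("mp", "me")


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length signals.

    Raises if either signal is constant (the correlation is undefined
    there) instead of silently returning 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.dot(xd, xd))
    sy = np.sqrt(np.dot(yd, yd))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant signal")
    return float(np.dot(xd, yd) / (sx * sy))


def window_count(n_samples: int, win_samples: int, step_samples: int) -> int:
    """Number of sliding windows without padding: floor((n-w)/step) + 1."""
    if step_samples < 1:
        raise ValueError("step_samples must be >= 1")
    if win_samples > n_samples:
        raise ValueError(
            f"window of {win_samples} samples does not fit in {n_samples}")
    return (n_samples - win_samples) // step_samples + 1


def _corr_matrix(X: np.ndarray) -> np.ndarray:
    """Correlation matrix of (n_channels, n_samples); errors on constants."""
    Xd = X - X.mean(axis=-1, keepdims=True)
    sd = np.sqrt(np.einsum("ct,ct->c", Xd, Xd))
    if np.any(sd == 0):
        raise ValueError("constant channel: correlation undefined")
    C = (Xd @ Xd.T) / np.outer(sd, sd)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def _windowed_corr(X: np.ndarray, win: int, step: int) -> np.ndarray:
    """All sliding-window correlation matrices of (n_channels, n_samples).

    Returns (n_windows, n_channels, n_channels).
    """
    n = X.shape[-1]
    n_win = window_count(n, win, step)
    starts = np.arange(n_win) * step
    idx = starts[:, None] + np.arange(win)[None, :]
    W = X[:, idx]                                 # (ch, n_win, win)
    W = W - W.mean(axis=-1, keepdims=True)
    cov = np.einsum("cwt,dwt->wcd", W, W)
    var = np.einsum("cwt,cwt->wc", W, W)
    if np.any(var == 0):
        raise ValueError("constant channel within a window: correlation undefined")
    sd = np.sqrt(var)
    C = cov / (sd[:, :, None] * sd[:, None, :])
    C = np.clip((C + np.swapaxes(C, 1, 2)) / 2.0, -1.0, 1.0)
    ii = np.arange(X.shape[0])
    C[:, ii, ii] = 1.0
    return C


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Symmetric channels x channels Pearson matrix with unit diagonal."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    window: tuple[float, float]  # (start_s, end_s) relative to trial start

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        nc = len(self.channel_names)
        if v.shape != (nc, nc):
            raise ValueError("matrix shape does not match channel count")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("connectivity matrix must have a unit diagonal")
        if v.min() < -1 - 1e-8 or v.max() > 1 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v
        self.channel_names = tuple(self.channel_names)


@dataclass
class TVConnectivitySeries:
    """Ordered sliding-window connectivity matrices for one trial.

    ``values`` is (n_windows, n_channels, n_channels); ``window_centers_s``
    are window-center times relative to the MP cue.
    """

    values: np.ndarray
    channel_names: tuple[str, ...]
    window_centers_s: np.ndarray
    window_len_s: float
    overlap_frac: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_centers_s = np.asarray(self.window_centers_s, dtype=float)
        if len(self.window_centers_s) != len(self.values):
            raise ValueError("one center per matrix required")
        if np.any(np.diff(self.window_centers_s) <= 0):
            raise ValueError("window centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, k: int) -> ConnectivityMatrix:
        c = self.window_centers_s[k]
        h = self.window_len_s / 2.0
        return ConnectivityMatrix(self.values[k], self.channel_names, (c - h, c + h))


@dataclass
class PFCCTimecourse:
    """Windowed parietal–frontocentral correlation for one channel pair."""

    connection: str
    window_centers_s: np.ndarray        # relative to the MP cue
    per_trial_r: np.ndarray             # (n_trials, n_windows)
    mean_r: np.ndarray
    sd_r: np.ndarray
    negative_crossing_s: float | None   # after MP cue; None if never negative
    me_peak_s: float | None             # after ME cue
    me_peak_r: float | None
    mp_s: float = 3.0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def static_connectivity(session: EpochedSession, phase: str) -> list[ConnectivityMatrix]:
    """One full-phase connectivity matrix per trial (``phase``: 'mp'|'me').

    The session is assumed already bandpass filtered to the connectivity
    band; each matrix is computed on the complete 3-s phase window.
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    start = session.mp_cue_s if phase == "mp" else session.me_cue_s
    dur = session.mp_s if phase == "mp" else session.me_s
    seg = session.segment(start, start + dur)
    return [ConnectivityMatrix(_corr_matrix(trial), session.channel_names,
                               (start, start + dur))
            for trial in seg]


def tv_connectivity(trial: np.ndarray, fs: float,
                    channel_names: tuple[str, ...],
                    window_s: float = 0.2, overlap: float = 0.9) -> TVConnectivitySeries:
    """Sliding-window connectivity of one trial segment (channels x samples).

    The segment is expected to start at the MP cue; window centers are
    reported relative to its first sample.  Any segment length is handled
    through the no-padding window count (a 6-s, 500-Hz segment yields 291
    windows of 100 samples at a 10-sample step).
    """
    trial = np.asarray(trial, dtype=float)
    win = int(round(window_s * fs))
    step = max(int(round(win * (1.0 - overlap))), 1)
    C = _windowed_corr(trial, win, step)
    centers = (np.arange(len(C)) * step + win / 2.0) / fs
    return TVConnectivitySeries(C, tuple(channel_names), centers, window_s, overlap)


def session_tv_connectivity(session: EpochedSession, window_s: float = 0.2,
                            overlap: float = 0.9) -> list[TVConnectivitySeries]:
    """TV connectivity of the 6-s MP+ME segment for every trial."""
    seg, _ = session.mp_me_segment()
    return [tv_connectivity(trial, session.fs, session.channel_names,
                            window_s, overlap) for trial in seg]


def _refine_peak(centers: np.ndarray, curve: np.ndarray, k: int,
                 half: int = 12) -> float:
    """Parabola-refined peak time around sample index ``k``."""
    lo, hi = max(k - half, 0), min(k + half + 1, len(curve))
    if hi - lo < 3:
        return float(centers[k])
    a, b, _ = np.polyfit(centers[lo:hi], curve[lo:hi], 2)
    if a >= 0:  # not concave; keep the raw argmax
        return float(centers[k])
    vertex = -b / (2 * a)
    if centers[lo] <= vertex <= centers[hi - 1]:
        return float(vertex)
    return float(centers[k])


def pfcc_timecourse(session: EpochedSession, connection: str,
                    alpha_band: tuple[float, float] = ALPHA_BAND,
                    window_s: float = 0.2, overlap: float = 0.9,
                    fisher: bool = False,
                    trials: np.ndarray | None = None) -> PFCCTimecourse:
    """Alpha-band windowed correlation time course for ``'P3-FC4'``/``'P3-C4'``.

    The raw session is alpha-band filtered here; ``trials`` optionally
    restricts to a boolean trial mask.  The trial-averaged curve (plain
    mean by default, Fisher-z mean if ``fisher``) carries two landmarks:
    the first window center after the MP cue at which it is negative, and
    the (parabola-refined) peak time within the ME phase, reported relative
    to the ME cue.
    """
    try:
        ch_a, ch_b = connection.split("-")
        ia, ib = session.channel_index(ch_a), session.channel_index(ch_b)
    except (ValueError, KeyError):
        raise ValueError(f"unknown connection id {connection!r}") from None

    bp = FIRBandpass(alpha_band[0], alpha_band[1], session.fs).fit()
    pair = bp.transform(session.eeg[:, [ia, ib], :])
    i0 = int(round(session.mp_cue_s * session.fs))
    i1 = int(round((session.me_cue_s + session.me_s) * session.fs))
    pair = pair[:, :, i0:i1]
    if trials is not None:
        pair = pair[np.asarray(trials)]

    win = int(round(window_s * session.fs))
    step = max(int(round(win * (1.0 - overlap))), 1)
    n_win = window_count(pair.shape[-1], win, step)
    per_trial = np.empty((pair.shape[0], n_win))
    for i, trial in enumerate(pair):
        per_trial[i] = _windowed_corr(trial, win, step)[:, 0, 1]
    centers = (np.arange(n_win) * step + win / 2.0) / session.fs

    if fisher:
        mean = np.tanh(np.arctanh(np.clip(per_trial, -1 + 1e-12, 1 - 1e-12)).mean(axis=0))
    else:
        mean = per_trial.mean(axis=0)
    sd = per_trial.std(axis=0, ddof=1) if len(per_trial) > 1 else np.zeros(n_win)

    neg = np.flatnonzero(mean < 0)
    crossing = float(centers[neg[0]]) if len(neg) else None

    me_mask = centers >= session.mp_s
    if np.any(me_mask):
        offset = np.flatnonzero(me_mask)[0]
        k = offset + int(np.argmax(mean[me_mask]))
        peak_t = _refine_peak(centers, mean, k) - session.mp_s
        peak_r = float(mean[k])
    else:
        peak_t = peak_r = None

    return PFCCTimecourse(connection, centers, per_trial, mean, sd,
                          crossing, peak_t, peak_r, mp_s=session.mp_s)


def phase_window_mask(centers_s: np.ndarray, window_s: float, phase: str,
                      mp_s: float = 3.0, me_s: float = 3.0,
                      onset_s: float | None = None) -> np.ndarray:
    """Windows lying fully inside a phase of the 6-s MP+ME segment.

    Phases: ``'mp'`` = [0, mp_s); ``'premovement'`` = [mp_s, mp_s+onset);
    ``'me'`` = [mp_s+onset, mp_s+me_s) (onset defaults to 0 for 'me' and is
    required for 'premovement').  Centers are relative to the MP cue.
    """
    c = np.asarray(centers_s, dtype=float)
    h = window_s / 2.0
    if phase == "mp":
        return (c - h >= 0) & (c + h <= mp_s)
    if phase == "premovement":
        if onset_s is None:
            raise ValueError("premovement mask requires the movement onset")
        return (c - h >= mp_s) & (c + h <= mp_s + onset_s)
    if phase == "me":
        start = mp_s + (onset_s or 0.0)
        return (c - h >= start) & (c + h <= mp_s + me_s)
    raise ValueError(f"unknown phase {phase!r}")


def trial_phase_means(tc: PFCCTimecourse, phase: str, me_s: float = 3.0,
                      onset_s: float | None = None,
                      window_s: float = 0.2) -> np.ndarray:
    """Per-trial mean windowed r over the windows fully inside ``phase``."""
    mask = phase_window_mask(tc.window_centers_s, window_s, phase,
                             tc.mp_s, me_s, onset_s)
    if not np.any(mask):
        raise ValueError(f"no windows fully inside phase {phase!r}")
    return tc.per_trial_r[:, mask].mean(axis=1)


def band_connectivity_grid(session: EpochedSession,
                           channels: tuple[str, ...] = MOTOR_CHANNELS_9,
                           bands: dict[str, tuple[float, float]] | None = None,
                           trials: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Per-band, per-trial connectivity among a channel subset.

    For each band the raw session is bandpass filtered and one correlation
    matrix per trial is computed over the 6-s MP+ME segment, returned as
    ``{band: (n_trials, n_ch, n_ch)}`` ready for paired condition testing.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    idx = [session.channel_index(ch) for ch in channels]
    i0 = int(round(session.mp_cue_s * session.fs))
    i1 = int(round((session.me_cue_s + session.me_s) * session.fs))
    sub = session.eeg[:, idx, i0:i1]
    if trials is not None:
        sub = sub[np.asarray(trials)]
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands.items():
        if not 0 <= lo < hi < session.fs / 2:
            raise ValueError(f"band {name} {lo}-{hi} Hz outside (0, fs/2)")
        filt = FIRBandpass(lo, hi, session.fs).fit().transform(sub)
        out[name] = np.stack([_corr_matrix(trial) for trial in filt])
    return out


class SlidingWindowConnectivity(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: trials -> sliding-window correlation stacks.

    ``transform`` maps ``(n_trials, n_channels, n_samples)`` to
    ``(n_trials, n_windows, n_channels, n_channels)``.
    """

    def __init__(self, window_s: float = 0.2, overlap: float = 0.9, fs: float = 500.0):
        self.window_s = window_s
        self.overlap = overlap
        self.fs = fs

    def fit(self, X, y=None):
        X = np.asarray(X)
        win = int(round(self.window_s * self.fs))
        step = max(int(round(win * (1.0 - self.overlap))), 1)
        self.win_samples_ = win
        self.step_samples_ = step
        self.n_windows_ = window_count(X.shape[-1], win, step)
        self.window_centers_s_ = (np.arange(self.n_windows_) * step + win / 2.0) / self.fs
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "n_windows_"):
            self.fit(X)
        return np.stack([_windowed_corr(trial, self.win_samples_, self.step_samples_)
                         for trial in X])
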