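"""Time synchronization of the four feature streams and the group statistics.

The four streams — trial-averaged MRCP, parietal–frontocentral
connectivity (PFCC) time courses, the time-varying classification accuracy
curve, and the averaged knee-angle trace — are resampled onto the shared
sliding-window time axis (window centers relative to the MP cue), with the
landmark times computed by the owning modules carried alongside:
PFCC negative-crossing, movement onset, MRCP trough, PFCC execution peak.

Condition comparisons (hemiplegic vs nonhemiplegic foot) use the Wilcoxon
signed-rank test on paired window-wise values, with the percent increment
of the hemiplegic mean over the nonhemiplegic mean; trial-wise preparatory
PFCC is regressed against the trial's peak knee-angle change with ordinary
least squares, reporting the RMSE normalized by the observed knee range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classification import AccuracyCurve
from .connectivity import PFCCTimecourse
from .gait import KneeAngleTrace
from .mrcp import MRCPWaveform


@dataclass
class SynchronizedFeatures:
    """All feature streams on the common window-center axis (s after MP cue)."""

    times_s: np.ndarray
    mrcp_uv: np.ndarray
    pfcc: dict[str, np.ndarray]
    accuracy: np.ndarray
    knee_deg: np.ndarray
    landmarks: dict[str, float | None] = field(default_factory=dict)


def synchronize(mrcp_wave: MRCPWaveform | None,
                pfcc: dict[str, PFCCTimecourse] | None,
                accuracy: AccuracyCurve | None,
                knee: KneeAngleTrace | None,
                movement_onset_s: float | None = None) -> SynchronizedFeatures:
    """Resample every stream to the sliding-window centers.

    A missing stream raises an error naming it.  EEG-derived curves are
    already on window centers; the MRCP (sample-rate) and knee traces are
    linearly interpolated.  Landmarks are pure copies of the times computed
    upstream — synchronization never re-estimates them.  Landmark times in
    the table are uniformly relative to the MP cue; ``None`` marks a
    landmark that was not found (e.g. a flat curve with no crossing).
    """
    for name, stream in (("mrcp", mrcp_wave), ("pfcc", pfcc),
                         ("accuracy", accuracy), ("knee", knee)):
        if stream is None:
            raise ValueError(f"missing feature stream: {name}")

    t = np.asarray(accuracy.window_centers_s, dtype=float)
    mp_s = next(iter(pfcc.values())).mp_s

    # MRCP axis is relative to the ME cue; shift to the MP-cue axis
    mrcp_t = mrcp_wave.times + mp_s
    mrcp_rs = np.interp(t, mrcp_t, mrcp_wave.amplitude)
    knee_rs = np.interp(t, knee.times, knee.angle)
    pfcc_rs = {}
    for conn, tc in pfcc.items():
        pfcc_rs[conn] = np.interp(t, tc.window_centers_s, tc.mean_r)

    first = next(iter(pfcc.values()))
    landmarks: dict[str, float | None] = {
        "pfcc_negative_crossing_s": first.negative_crossing_s,
        "mrcp_trough_s": mrcp_wave.trough_time_s + mp_s,
        "pfcc_me_peak_s": (first.me_peak_s + mp_s
                           if first.me_peak_s is not None else None),
        "movement_onset_s": (movement_onset_s + mp_s
                             if movement_onset_s is not None else None),
        "accuracy_peak_s": float(t[int(np.argmax(accuracy.accuracy))]),
    }
    return SynchronizedFeatures(t, mrcp_rs, pfcc_rs, np.asarray(accuracy.accuracy),
                                knee_rs, landmarks)


def percent_increment(hemi: np.ndarray, nonhemi: np.ndarray) -> float:
    """100 x (mean(hemi) − mean(nonhemi)) / |mean(nonhemi)|.

    The nonhemiplegic condition is the comparison baseline.  Swapping the
    conditions is antisymmetric only up to this denominator convention.
    """
    m_h = float(np.mean(hemi))
    m_n = float(np.mean(nonhemi))
    if m_n == 0:
        raise ValueError("nonhemiplegic mean is zero; increment undefined")
    return 100.0 * (m_h - m_n) / abs(m_n)


def paired_connectivity_test(hemi: np.ndarray, nonhemi: np.ndarray
                             ) -> tuple[float, float, float]:
    """Wilcoxon signed-rank test on paired connectivity values.

    ``hemi`` and ``nonhemi`` are paired samples (same windows or same
    subjects) of the target connection.  Returns (statistic, p, percent
    increment).  When every paired difference is zero the test is
    degenerate: p is reported as 1 with a warning rather than failing.
    """
    hemi = np.asarray(hemi, dtype=float)
    nonhemi = np.asarray(nonhemi, dtype=float)
    if hemi.shape != nonhemi.shape:
        raise ValueError("paired samples must have equal length")
    inc = percent_increment(hemi, nonhemi)
    diff = hemi - nonhemi
    if np.all(diff == 0):
        warnings.warn("all paired differences are zero; signed-rank test "
                      "degenerate, reporting p = 1")
        return 0.0, 1.0, inc
    stat, p = stats.wilcoxon(hemi, nonhemi)
    return float(stat), float(p), inc


def grid_signed_rank(hemi_grids: np.ndarray, nonhemi_grids: np.ndarray,
                     alpha: float = 0.01, fdr: bool = False
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Cross-subject signed-rank test per grid cell.

    Inputs are ``(n_subjects, n_ch, n_ch)`` per-subject mean connectivity
    matrices per condition.  Returns ``(p_values, significant_mask)`` with
    the diagonal marked non-significant.  ``fdr`` applies a
    Benjamini–Hochberg correction over the strict upper triangle (off by
    default; the mask otherwise uses the raw threshold).
    """
    h = np.asarray(hemi_grids, dtype=float)
    n = np.asarray(nonhemi_grids, dtype=float)
    if h.shape != n.shape or h.ndim != 3:
        raise ValueError("expected paired (n_subjects, n_ch, n_ch) stacks")
    nc = h.shape[1]
    p = np.ones((nc, nc))
    for i in range(nc):
        for j in range(i + 1, nc):
            diff = h[:, i, j] - n[:, i, j]
            if np.all(diff == 0):
                pij = 1.0
            else:
                _, pij = stats.wilcoxon(h[:, i, j], n[:, i, j])
            p[i, j] = p[j, i] = pij
    if fdr:
        iu = np.triu_indices(nc, k=1)
        flat = p[iu]
        order = np.argsort(flat)
        m = len(flat)
        thresh = alpha * (np.arange(1, m + 1)) / m
        passed = flat[order] <= thresh
        k = np.max(np.flatnonzero(passed)) + 1 if np.any(passed) else 0
        mask_flat = np.zeros(m, dtype=bool)
        mask_flat[order[:k]] = True
        mask = np.zeros((nc, nc), dtype=bool)
        mask[iu] = mask_flat
        mask |= mask.T
    else:
        mask = p < alpha
        np.fill_diagonal(mask, False)
    return p, mask


@dataclass
class RegressionResult:
    """OLS line between preparatory connectivity and knee performance."""

    slope: float
    intercept: float
    nrmse: float
    connection: str
    phase: str
    n: int


def regress_pfcc_knee(pfcc_means: np.ndarray, knee_peaks: np.ndarray,
                      connection: str = "P3-FC4", phase: str = "mp"
                      ) -> RegressionResult:
    """Ordinary least squares of knee peak angle on per-trial PFCC mean.

    NRMSE is the residual RMSE divided by the observed knee range
    (max − min), making it invariant to affine rescaling of the angle
    units.  A constant predictor raises.
    """
    x = np.asarray(pfcc_means, dtype=float)
    y = np.asarray(knee_peaks, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D samples required")
    if len(x) < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression undefined")
    res = stats.linregress(x, y)
    pred = res.intercept + res.slope * x
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    rng = float(np.ptp(y))
    nrmse = rmse / rng if rng > 0 else 0.0
    return RegressionResult(float(res.slope), float(res.intercept), nrmse,
                            connection, phase, len(x))
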