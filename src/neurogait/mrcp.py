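"""Movement-related cortical potential (MRCP) at the central Cz electrode.

The MRCP is the slow (0.1–5 Hz) potential time-locked to voluntary
movement: a negative deflection that deepens toward movement and rebounds
afterwards.  Trials are filtered, baseline-corrected against the final
second of fixation, epoched from the MP cue to the end of the ME phase
(−3 s to +3 s around the ME cue) and averaged pointwise; the trough is the
global minimum within a search window of the ME phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .filtering import MRCP_BAND, FIRBandpass
from .session import EpochedSession


@dataclass
class MRCPWaveform:
    """Trial-averaged slow potential with its trough descriptor.

    ``times`` are seconds relative to the ME cue (uniform at 1/fs);
    amplitudes are microvolts.
    """

    times: np.ndarray
    amplitude: np.ndarray
    n_trials: int
    channel: str
    trough_time_s: float
    trough_amplitude_uv: float
    fs: float


def find_trough(times: np.ndarray, amplitude: np.ndarray,
                search: tuple[float, float] = (0.0, 3.0)) -> tuple[float, float]:
    """Global minimum of a waveform within ``search`` (s, relative axis).

    Ties are broken toward the earlier time (``argmin`` returns the first
    minimum).  Raises on an empty search window.
    """
    mask = (times >= search[0]) & (times <= search[1])
    if not np.any(mask):
        raise ValueError(f"search window {search} outside waveform support")
    idx = np.flatnonzero(mask)
    k = idx[int(np.argmin(amplitude[idx]))]
    return float(times[k]), float(amplitude[k])


def average_mrcp(session: EpochedSession, foot: str = "all",
                 channel: str = "Cz",
                 band: tuple[float, float] = MRCP_BAND,
                 baseline_s: float = 1.0,
                 search: tuple[float, float] = (0.0, 3.0)) -> MRCPWaveform:
    """Trial-averaged MRCP for a foot/side selector.

    Each selected trial is bandpass filtered, baseline-corrected by
    subtracting its mean over the final ``baseline_s`` seconds of fixation,
    and the epoch spanning the MP cue to the end of the ME phase is
    averaged pointwise across trials.
    """
    mask = session.trial_mask(foot)
    if not np.any(mask):
        raise ValueError(f"no trials match selector {foot!r}")
    ich = session.channel_index(channel)

    bp = FIRBandpass(band[0], band[1], session.fs).fit()
    x = bp.transform(session.eeg[mask, ich, :])

    b0 = int(round((session.mp_cue_s - baseline_s) * session.fs))
    b1 = int(round(session.mp_cue_s * session.fs))
    x = x - x[:, b0:b1].mean(axis=1, keepdims=True)

    i0 = int(round(session.mp_cue_s * session.fs))
    i1 = int(round((session.me_cue_s + session.me_s) * session.fs))
    epoch = x[:, i0:i1]
    avg = epoch.mean(axis=0)
    times = np.arange(epoch.shape[1]) / session.fs - session.mp_s  # 0 = ME cue

    t_tr, a_tr = find_trough(times, avg, search)
    return MRCPWaveform(times, avg, int(mask.sum()), channel, t_tr, a_tr,
                        session.fs)


def compare_troughs(hemiplegic: list[MRCPWaveform],
                    nonhemiplegic: list[MRCPWaveform]) -> tuple[float, float]:
    """Mean trough-amplitude difference (hemi − nonhemi, µV) and t-test p.

    Expects one waveform per subject per condition; a two-sample t-test is
    applied to the per-subject trough amplitudes.  Identical groups give a
    difference of 0 and p = 1.
    """
    if len(hemiplegic) < 2 or len(nonhemiplegic) < 2:
        raise ValueError("need at least 2 subjects per condition")
    a = np.array([w.trough_amplitude_uv for w in hemiplegic])
    b = np.array([w.trough_amplitude_uv for w in nonhemiplegic])
    diff = float(a.mean() - b.mean())
    if np.allclose(a, b) and np.ptp(a) == 0 and np.ptp(b) == 0:
        return diff, 1.0
    t, p = stats.ttest_ind(a, b)
    if np.isnan(p):  # zero variance in both groups but equal means
        p = 1.0
    return diff, float(p)
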