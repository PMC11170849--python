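"""End-to-end per-session analysis: all four feature streams plus landmarks."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classification import (AccuracyCurve, PhaseAccuracySummary,
                             phase_accuracy_summary, session_tv_features,
                             tv_accuracy_curve)
from .connectivity import PFCCTimecourse, pfcc_timecourse, trial_phase_means
from .filtering import ALPHA_BAND, CONN_BAND, MRCP_BAND
from .gait import GaitEvents, KneeAngleTrace, average_trace, detect_onset, gait_events, trial_knee_peaks
from .mrcp import MRCPWaveform, average_mrcp
from .session import EpochedSession, KneeAngleTraces
from .simulate import PFCC_CONNECTIONS
from .sync import RegressionResult, SynchronizedFeatures, regress_pfcc_knee, synchronize

log = logging.getLogger("neurogait")


@dataclass
class SessionAnalysis:
    """Everything the pipeline extracts from one session."""

    mrcp: MRCPWaveform
    pfcc: dict[str, PFCCTimecourse]
    accuracy: AccuracyCurve
    knee: KneeAngleTrace
    onset_s: float
    gait: GaitEvents
    phases: PhaseAccuracySummary
    synchronized: SynchronizedFeatures
    regressions: dict[str, RegressionResult]


def analyze_session(session: EpochedSession, knees: KneeAngleTraces,
                    seed: int = 0, folds: int = 10) -> SessionAnalysis:
    """Run the full pipeline on one session.

    Extracts the Cz slow potential, the two PFCC time courses, the
    291-window accuracy curve, the averaged knee trace with its gait
    events, the phase-wise accuracies, the synchronized feature table and
    the preparatory-connectivity regressions against knee performance.
    """
    log.info("analysis bands: mrcp=%s Hz, connectivity=%s Hz, alpha=%s Hz",
             MRCP_BAND, CONN_BAND, ALPHA_BAND)
    log.info("tv windows: 200 ms, 90%% overlap; cv: %d folds, seed=%d",
             folds, seed)
    wave = average_mrcp(session)
    pfcc = {c: pfcc_timecourse(session, c) for c in PFCC_CONNECTIONS}

    feats, centers = session_tv_features(session)
    curve = tv_accuracy_curve(feats, session.labels, centers, folds, seed)

    knee = average_trace(knees)
    onset = detect_onset(knee)
    events = gait_events(knee, onset)
    phases = phase_accuracy_summary(session, onset, curve, folds, seed)
    synced = synchronize(wave, pfcc, curve, knee, onset)

    peaks = trial_knee_peaks(knees)
    regressions = {}
    for conn, tc in pfcc.items():
        x = trial_phase_means(tc, "mp")
        regressions[conn] = regress_pfcc_knee(x, peaks, conn, "mp")
    return SessionAnalysis(wave, pfcc, curve, knee, onset, events, phases,
                           synced, regressions)


def landmark_summary(analysis: SessionAnalysis) -> dict[str, float | None]:
    """The headline latencies of one session, on the cue-relative scales.

    Times after the MP cue for the PFCC negative crossing; after the ME
    cue for the movement onset, the MRCP trough and the PFCC peak; and the
    onset-to-peak knee delay.
    """
    first = analysis.pfcc[PFCC_CONNECTIONS[0]]
    return {
        "pfcc_negative_crossing_s": first.negative_crossing_s,
        "reaction_time_s": analysis.gait.reaction_time_s,
        "mrcp_trough_s": analysis.mrcp.trough_time_s,
        "pfcc_me_peak_s": first.me_peak_s,
        "knee_peak_delay_s": analysis.gait.peak_time_s,
    }
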