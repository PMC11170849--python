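"""Session readers/writers and the per-run report bundle.

Sessions are written as MNE FIF epochs (the field's standard epoched
container) plus columnar CSV tables for trial metadata and knee traces;
the generator's ground truth goes to a separate JSON file that the
analysis pipeline never reads.  EDF recordings can be imported through
``mne.io.read_raw_edf`` and epoched into an :class:`EpochedSession` by the
caller.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .session import EpochedSession, GroundTruth, KneeAngleTraces


def write_session(session: EpochedSession, knees: KneeAngleTraces,
                  truth: GroundTruth | None, outdir: str | Path) -> Path:
    """Write one session to ``outdir`` (FIF epochs + CSV tables + truth JSON)."""
    import mne

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    info = mne.create_info(list(session.channel_names), session.fs, "eeg")
    event_id = {"left": 1, "right": 2}
    events = np.column_stack([
        np.arange(session.n_trials) * session.n_samples,
        np.zeros(session.n_trials, dtype=int),
        [event_id[l] for l in session.labels],
    ])
    epochs = mne.EpochsArray(session.eeg * 1e-6, info, events=events,
                             event_id=event_id, tmin=0.0, verbose="error")
    epochs.save(outdir / "session-epo.fif", overwrite=True, verbose="error")

    meta = pd.DataFrame({
        "trial": np.arange(session.n_trials),
        "label": session.labels,
        "mp_cue_s": session.mp_cue_s,
        "me_cue_s": session.me_cue_s,
        "onset_s": truth.onset_s if truth is not None else np.nan,
    })
    meta.to_csv(outdir / "trials.csv", index=False)

    t = knees.times()
    knee_rows = pd.DataFrame({
        "trial": np.repeat(np.arange(knees.angles.shape[0]), knees.angles.shape[1]),
        "time_s": np.tile(t, knees.angles.shape[0]),
        "angle_deg": knees.angles.ravel(),
    })
    knee_rows.to_csv(outdir / "knee.csv", index=False)

    params = {
        "fs": session.fs,
        "fixation_s": session.fixation_s,
        "mp_s": session.mp_s,
        "me_s": session.me_s,
        "hemiplegic_side": session.hemiplegic_side,
    }
    (outdir / "session.json").write_text(json.dumps(params, indent=2))
    if truth is not None:
        (outdir / "ground_truth.json").write_text(
            json.dumps(truth.to_dict(), indent=2))
    return outdir


def read_session(indir: str | Path) -> tuple[EpochedSession, KneeAngleTraces]:
    """Read a session written by :func:`write_session`."""
    import mne

    indir = Path(indir)
    params = json.loads((indir / "session.json").read_text())
    epochs = mne.read_epochs(indir / "session-epo.fif", preload=True,
                             verbose="error")
    meta = pd.read_csv(indir / "trials.csv")
    labels = meta["label"].to_numpy()
    session = EpochedSession(epochs.get_data(copy=True) * 1e6,
                             tuple(epochs.ch_names), params["fs"], labels,
                             params["fixation_s"], params["mp_s"],
                             params["me_s"], params["hemiplegic_side"])
    knee = pd.read_csv(indir / "knee.csv")
    n_trials = int(knee["trial"].max()) + 1
    angles = knee["angle_deg"].to_numpy().reshape(n_trials, -1)
    knees = KneeAngleTraces(angles, params["fs"], labels,
                            me_cue_s=params["fixation_s"] + params["mp_s"],
                            mp_cue_s=params["fixation_s"])
    return session, knees


def write_report(analysis, outdir: str | Path) -> Path:
    """Write the per-run report bundle: landmark, curve and summary tables."""
    from .pipeline import landmark_summary

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    lm = landmark_summary(analysis)
    pd.DataFrame([lm]).to_csv(outdir / "landmarks.csv", index=False)

    s = analysis.synchronized
    table = pd.DataFrame({"time_s": s.times_s, "mrcp_uv": s.mrcp_uv,
                          "accuracy": s.accuracy, "knee_deg": s.knee_deg})
    for conn, curve in s.pfcc.items():
        table[f"pfcc_{conn}"] = curve
    table.to_csv(outdir / "synchronized.csv", index=False)

    for conn, tc in analysis.pfcc.items():
        pd.DataFrame({"window_center_s": tc.window_centers_s,
                      "mean_r": tc.mean_r, "sd_r": tc.sd_r}).to_csv(
            outdir / f"pfcc_{conn}.csv", index=False)

    pd.DataFrame({"window_center_s": analysis.accuracy.window_centers_s,
                  "accuracy": analysis.accuracy.accuracy,
                  "sd_across_folds": analysis.accuracy.sd_across_folds}).to_csv(
        outdir / "accuracy_curve.csv", index=False)

    summary = {
        "mp_accuracy": analysis.phases.mp_accuracy,
        "premovement_accuracy": analysis.phases.premovement_accuracy,
        "me_accuracy": analysis.phases.me_accuracy,
        "premovement_peak_vs_onset_s": analysis.phases.premovement_peak_vs_onset_s,
        "movement_onset_s": analysis.onset_s,
        "knee_peak_deg": analysis.gait.peak_angle_deg,
        "mrcp_trough_uv": analysis.mrcp.trough_amplitude_uv,
        "regressions": {c: {"slope": r.slope, "intercept": r.intercept,
                            "nrmse": r.nrmse, "n": r.n}
                        for c, r in analysis.regressions.items()},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return outdir
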