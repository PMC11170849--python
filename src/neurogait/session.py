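"""In-memory containers for one recording session.

A session holds cue-aligned 10-s trials (4 s fixation, 3 s motor
preparation, 3 s motor execution) of multichannel EEG together with the
per-trial foot labels, the side affected by the stroke, and the knee-angle
traces recorded by the leg-mounted inertial sensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

#: Valid trial selectors for label/side resolution.
SELECTORS = ("left", "right", "hemiplegic", "nonhemiplegic", "all")


@dataclass
class EpochedSession:
    """Cue-aligned EEG trials for one subject.

    Attributes
    ----------
    eeg : ndarray, shape (n_trials, n_channels, n_samples)
        EEG in microvolts; trials start at fixation onset.
    channel_names : tuple of str
        10/20 labels, one per EEG row.
    fs : float
        Sampling frequency (Hz).
    labels : ndarray of str
        ``'left'`` / ``'right'`` foot cue per trial.
    fixation_s, mp_s, me_s : float
        Durations of the fixation, motor-preparation and motor-execution
        phases (s).  The MP cue appears at ``fixation_s`` and the ME cue at
        ``fixation_s + mp_s`` relative to trial start.
    hemiplegic_side : str
        ``'left'`` or ``'right'``; which foot is the stroke-affected one.
    """

    eeg: np.ndarray
    channel_names: tuple[str, ...]
    fs: float
    labels: np.ndarray
    fixation_s: float = 4.0
    mp_s: float = 3.0
    me_s: float = 3.0
    hemiplegic_side: str = "left"

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.labels = np.asarray(self.labels)
        self.channel_names = tuple(self.channel_names)
        if self.eeg.ndim != 3:
            raise ValueError("eeg must be (n_trials, n_channels, n_samples)")
        if self.eeg.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length does not match eeg axis 1")
        if self.eeg.shape[0] != len(self.labels):
            raise ValueError("labels length does not match trial count")
        if self.hemiplegic_side not in ("left", "right"):
            raise ValueError("hemiplegic_side must be 'left' or 'right'")

    # -- timeline ---------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[1]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[2]

    @property
    def mp_cue_s(self) -> float:
        """MP cue time relative to trial start (s)."""
        return self.fixation_s

    @property
    def me_cue_s(self) -> float:
        """ME cue time relative to trial start (s)."""
        return self.fixation_s + self.mp_s

    def times(self) -> np.ndarray:
        """Time axis relative to trial start (s)."""
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel label {name!r}") from None

    def segment(self, start_s: float, stop_s: float) -> np.ndarray:
        """EEG slice ``[start_s, stop_s)`` relative to trial start."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(stop_s * self.fs))
        if not 0 <= i0 < i1 <= self.n_samples:
            raise ValueError(f"segment [{start_s}, {stop_s}) s outside trial")
        return self.eeg[:, :, i0:i1]

    def mp_me_segment(self) -> tuple[np.ndarray, np.ndarray]:
        """The 6-s MP+ME segment and its time axis relative to the MP cue."""
        seg = self.segment(self.mp_cue_s, self.me_cue_s + self.me_s)
        t = np.arange(seg.shape[2]) / self.fs
        return seg, t

    # -- trial selection --------------------------------------------------
    def trial_mask(self, selector: str) -> np.ndarray:
        """Boolean mask over trials for a foot/side selector.

        ``'hemiplegic'`` resolves to trials whose cued foot equals
        ``hemiplegic_side``; ``'nonhemiplegic'`` to the other foot.
        """
        if selector not in SELECTORS:
            raise ValueError(f"selector must be one of {SELECTORS}")
        if selector == "all":
            return np.ones(self.n_trials, dtype=bool)
        if selector == "hemiplegic":
            return self.labels == self.hemiplegic_side
        if selector == "nonhemiplegic":
            return self.labels != self.hemiplegic_side
        return self.labels == selector


@dataclass
class KneeAngleTraces:
    """Per-trial knee-angle traces on the session's trial time axis.

    ``angles`` is ``(n_trials, n_samples)`` in degrees, time-aligned with
    the EEG trials (t = 0 at fixation onset).
    """

    angles: np.ndarray
    fs: float
    labels: np.ndarray
    me_cue_s: float
    mp_cue_s: float = 4.0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.angles.ndim != 2:
            raise ValueError("angles must be (n_trials, n_samples)")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("knee angles must be finite")

    def times(self) -> np.ndarray:
        return np.arange(self.angles.shape[1]) / self.fs


@dataclass
class GroundTruth:
    """What the generator injected — for parameter-recovery tests only.

    The analysis pipeline never reads this; it exists so tests can compare
    recovered landmarks against the injected ones.  All times are seconds
    after the ME cue unless noted.
    """

    labels: np.ndarray
    onset_s: np.ndarray
    trough_time_s: np.ndarray
    trough_amp_uv: np.ndarray
    knee_peak_deg: np.ndarray
    pfcc_trial_offset: np.ndarray
    pfcc_r_by_phase: dict
    pfcc_mp_negative_onset_s: float
    pfcc_me_peak_s: float
    discrim_window: tuple[float, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "onset_s": self.onset_s.tolist(),
            "trough_time_s": self.trough_time_s.tolist(),
            "trough_amp_uv": self.trough_amp_uv.tolist(),
            "knee_peak_deg": self.knee_peak_deg.tolist(),
            "pfcc_trial_offset": self.pfcc_trial_offset.tolist(),
            "pfcc_r_by_phase": self.pfcc_r_by_phase,
            "pfcc_mp_negative_onset_s": self.pfcc_mp_negative_onset_s,
            "pfcc_me_peak_s": self.pfcc_me_peak_s,
            "discrim_window": list(self.discrim_window),
            "seed": self.seed,
        }
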