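"""Zero-phase FIR bandpass filtering.

Two analysis bands are used downstream: a 0.1–5 Hz band for the slow
movement-related cortical potential and an 8–50 Hz band for functional
connectivity; the 8–13 Hz alpha band serves the parietal–frontocentral
connectivity time courses.  Filters are linear-phase windowed-sinc designs
applied forward–backward so that event latencies (troughs, peaks, onsets)
are not shifted by filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

#: Band presets (Hz): slow cortical potential, connectivity, alpha.
MRCP_BAND: tuple[float, float] = (0.1, 5.0)
CONN_BAND: tuple[float, float] = (8.0, 50.0)
ALPHA_BAND: tuple[float, float] = (8.0, 13.0)

#: Cap on the number of taps so the filter stays usable on 10-s trials
#: (zero-phase application requires signals longer than 3x the tap count).
MAX_NUMTAPS = 1501


def default_numtaps(low_hz: float, fs: float, cap: int = MAX_NUMTAPS) -> int:
    """Odd tap count ~3.3 cycles of the low edge, capped for short trials.

    The cap deliberately relaxes the transition at a 0.1 Hz low edge: a
    full-resolution 0.1 Hz filter would be longer than a 10-s trial.
    """
    n = int(round(3.3 * fs / low_hz))
    n = min(n, cap)
    return n if n % 2 == 1 else n + 1


@dataclass(frozen=True)
class BandpassSpec:
    """Windowed-sinc bandpass description.

    Parameters
    ----------
    low_hz, high_hz : float
        Band edges in Hz, ``0 <= low_hz < high_hz < fs/2``.
    fs : float
        Sampling frequency in Hz.
    numtaps : int, optional
        Odd FIR length; defaults to :func:`default_numtaps`.
    window : str
        Window function passed to :func:`scipy.signal.firwin`.
    """

    low_hz: float
    high_hz: float
    fs: float
    numtaps: int | None = None
    window: str = "hamming"

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(
                f"band edges must satisfy 0 <= low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )
        if self.high_hz >= self.fs / 2:
            raise ValueError(
                f"high edge {self.high_hz} Hz violates Nyquist for fs={self.fs}"
            )
        if self.numtaps is None:
            object.__setattr__(
                self, "numtaps", default_numtaps(max(self.low_hz, 1e-6), self.fs)
            )
        if self.numtaps % 2 == 0:
            raise ValueError("numtaps must be odd for a symmetric linear-phase FIR")


def design_fir(spec: BandpassSpec) -> np.ndarray:
    """Linear-phase FIR bandpass coefficients for ``spec``."""
    return signal.firwin(
        spec.numtaps,
        [spec.low_hz, spec.high_hz],
        pass_zero=False,
        window=spec.window,
        fs=spec.fs,
    )


def frequency_response(coeffs: np.ndarray, fs: float, freqs_hz: np.ndarray) -> np.ndarray:
    """Magnitude response of ``coeffs`` at ``freqs_hz`` (single pass)."""
    _, h = signal.freqz(coeffs, worN=2 * np.pi * np.asarray(freqs_hz) / fs)
    return np.abs(h)


def apply_zero_phase(coeffs: np.ndarray, x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Forward–backward (zero net group delay) FIR filtering.

    The signal is reflect-padded by one filter length internally, so the
    output has the same length as the input and in-band components are not
    time-shifted.  Raises ``ValueError`` for signals shorter than 3x the
    filter length rather than silently truncating the padding.
    """
    x = np.asarray(x, dtype=float)
    ntaps = len(coeffs)
    n = x.shape[axis]
    if n <= 3 * ntaps:
        raise ValueError(
            f"signal length {n} too short for zero-phase filtering with "
            f"{ntaps} taps (needs > {3 * ntaps} samples)"
        )
    return signal.filtfilt(coeffs, [1.0], x, axis=axis, padtype="even", padlen=ntaps)


class FIRBandpass(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: zero-phase FIR bandpass along the last axis.

    ``fit`` designs the coefficients (stateless with respect to the data);
    ``transform`` filters arrays of shape ``(..., n_samples)``.

    Examples
    --------
    >>> bp = FIRBandpass(8, 50, fs=500).fit()
    >>> y = bp.transform(x)          # x: (n_trials, n_channels, n_samples)
    """

    def __init__(self, low_hz: float, high_hz: float, fs: float,
                 numtaps: int | None = None, window: str = "hamming"):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.fs = fs
        self.numtaps = numtaps
        self.window = window

    def fit(self, X=None, y=None):
        self.spec_ = BandpassSpec(self.low_hz, self.high_hz, self.fs,
                                  self.numtaps, self.window)
        self.coeffs_ = design_fir(self.spec_)
        return self

    def transform(self, X):
        if not hasattr(self, "coeffs_"):
            self.fit()
        return apply_zero_phase(self.coeffs_, X, axis=-1)
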