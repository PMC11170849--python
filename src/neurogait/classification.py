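"""Left-vs-right foot decoding from vectorized connectivity.

Connectivity matrices are vectorized (strict upper triangle) and fed to a
linear maximum-margin classifier (linear SVM) with per-feature centering
fit on the training folds only (correlation features already share the
bounded [-1, 1] scale; see :func:`_make_classifier` for why variance
scaling is optional).  Accuracy is estimated by seeded stratified tenfold
cross-validation; for time-varying connectivity the same fold assignment
is reused across all windows so the accuracy curve's variation reflects
the features, not fold resampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .connectivity import ConnectivityMatrix, session_tv_connectivity, static_connectivity
from .filtering import CONN_BAND, FIRBandpass
from .session import EpochedSession


@dataclass
class AccuracyCurve:
    """Per-window cross-validated accuracy on a shared time axis.

    ``window_centers_s`` are relative to the MP cue; each accuracy is the
    mean over the (seeded) folds, with the across-fold standard deviation
    alongside.
    """

    window_centers_s: np.ndarray
    accuracy: np.ndarray
    sd_across_folds: np.ndarray
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        self.window_centers_s = np.asarray(self.window_centers_s, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if len(self.accuracy) != len(self.window_centers_s):
            raise ValueError("one accuracy per window required")
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracies must lie in [0, 1]")


def vectorize(matrix) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major.

    Accepts a :class:`ConnectivityMatrix`, a single (N_c, N_c) array or a
    batch (..., N_c, N_c); a 32-channel matrix yields 496 features.  The
    inverse is :func:`unvectorize`.
    """
    v = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    nc = v.shape[-1]
    if v.shape[-2] != nc:
        raise ValueError("expected a square matrix on the last two axes")
    if not np.allclose(v, np.swapaxes(v, -1, -2), atol=1e-6):
        raise ValueError("matrix is asymmetric beyond tolerance")
    iu = np.triu_indices(nc, k=1)
    return v[..., iu[0], iu[1]]


def unvectorize(vec: np.ndarray, n_channels: int) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix from its upper triangle."""
    vec = np.asarray(vec)
    iu = np.triu_indices(n_channels, k=1)
    if vec.shape[-1] != len(iu[0]):
        raise ValueError("vector length does not match n_channels")
    m = np.zeros(vec.shape[:-1] + (n_channels, n_channels))
    m[..., iu[0], iu[1]] = vec
    m = m + np.swapaxes(m, -1, -2)
    ii = np.arange(n_channels)
    m[..., ii, ii] = 1.0
    return m


def _make_classifier(C: float = 1.0, standardize: str = "center"):
    """Linear max-margin classifier with leakage-free feature scaling.

    ``standardize``: ``'center'`` (default) removes the training-fold mean
    per feature; ``'zscore'`` additionally divides by the training-fold
    standard deviation; ``None`` feeds raw features.  Correlation features
    share the bounded [-1, 1] scale, and dividing by per-feature standard
    deviations amplifies low-variance pairs (and the noise they carry) at
    the expense of strongly class-separated ones, so variance scaling is
    off by default and exposed for unbounded feature sets.
    """
    if standardize == "center":
        return make_pipeline(StandardScaler(with_std=False), LinearSVC(C=C, random_state=0))
    if standardize == "zscore":
        return make_pipeline(StandardScaler(), LinearSVC(C=C, random_state=0))
    if standardize is None:
        return make_pipeline(LinearSVC(C=C, random_state=0))
    raise ValueError("standardize must be 'center', 'zscore' or None")


def _fold_indices(labels: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def cv_accuracy(features: np.ndarray, labels: np.ndarray, folds: int = 10,
                seed: int = 0, C: float = 1.0,
                standardize: str = "center",
                return_folds: bool = False):
    """Mean held-out accuracy of the linear classifier over seeded folds.

    Stratified fold assignment guarantees both classes appear in every
    training fold; per-fold accuracies are returned when requested, and
    their mean equals the reported accuracy.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("expected exactly two classes")
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} trials per class for {folds}-fold CV")
    accs = []
    for tr, te in _fold_indices(y, folds, seed):
        clf = _make_classifier(C, standardize)
        clf.fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    accs = np.asarray(accs)
    return (float(accs.mean()), accs) if return_folds else float(accs.mean())


def tv_accuracy_curve(tv_features: np.ndarray, labels: np.ndarray,
                      window_centers_s: np.ndarray, folds: int = 10,
                      seed: int = 0, C: float = 1.0,
                      standardize: str = "center") -> AccuracyCurve:
    """Cross-validated accuracy per sliding window.

    ``tv_features`` is (n_trials, n_windows, n_features) — one vectorized
    connectivity matrix per trial and window, with identical window counts
    across trials.  The seeded fold assignment is computed once from the
    labels and reused for every window.
    """
    X = np.asarray(tv_features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 3:
        raise ValueError("tv_features must be (n_trials, n_windows, n_features)")
    if X.shape[1] != len(window_centers_s):
        raise ValueError("inconsistent window counts")
    splits = _fold_indices(y, folds, seed)
    acc = np.empty(X.shape[1])
    sd = np.empty(X.shape[1])
    for w in range(X.shape[1]):
        fold_accs = []
        for tr, te in splits:
            clf = _make_classifier(C, standardize)
            clf.fit(X[tr, w], y[tr])
            fold_accs.append(float(np.mean(clf.predict(X[te, w]) == y[te])))
        acc[w] = np.mean(fold_accs)
        sd[w] = np.std(fold_accs, ddof=1)
    return AccuracyCurve(np.asarray(window_centers_s, dtype=float), acc, sd,
                         folds, seed)


def session_tv_features(session: EpochedSession,
                        band: tuple[float, float] = CONN_BAND,
                        window_s: float = 0.2, overlap: float = 0.9):
    """Vectorized TV connectivity features of the 6-s MP+ME segment.

    Filters the session to the connectivity band, computes sliding-window
    matrices for every trial and vectorizes them.  Returns
    ``(features (n_trials, n_windows, n_pairs), window_centers_s)``.
    """
    bp = FIRBandpass(band[0], band[1], session.fs).fit()
    filtered = EpochedSession(bp.transform(session.eeg), session.channel_names,
                              session.fs, session.labels, session.fixation_s,
                              session.mp_s, session.me_s, session.hemiplegic_side)
    series = session_tv_connectivity(filtered, window_s, overlap)
    feats = np.stack([vectorize(s.values) for s in series])
    return feats, series[0].window_centers_s


def session_static_features(session: EpochedSession, phase: str,
                            band: tuple[float, float] = CONN_BAND) -> np.ndarray:
    """Vectorized full-phase connectivity features, (n_trials, n_pairs)."""
    bp = FIRBandpass(band[0], band[1], session.fs).fit()
    filtered = EpochedSession(bp.transform(session.eeg), session.channel_names,
                              session.fs, session.labels, session.fixation_s,
                              session.mp_s, session.me_s, session.hemiplegic_side)
    mats = static_connectivity(filtered, phase)
    return np.stack([vectorize(m) for m in mats])


@dataclass
class PhaseAccuracySummary:
    """Static MP/ME accuracies plus the premovement peak of the TV curve."""

    mp_accuracy: float
    premovement_accuracy: float
    me_accuracy: float
    premovement_peak_s: float        # window center relative to the MP cue
    premovement_peak_vs_onset_s: float  # center − movement onset (<= 0)
    movement_onset_s: float          # after the ME cue


def phase_accuracy_summary(session: EpochedSession, movement_onset_s: float,
                           curve: AccuracyCurve | None = None,
                           folds: int = 10, seed: int = 0) -> PhaseAccuracySummary:
    """MP, premovement and ME accuracies for one session.

    The premovement accuracy is the maximum of the TV accuracy curve among
    windows whose center precedes the movement onset (``movement_onset_s``
    is seconds after the ME cue, typically from the averaged knee trace).
    """
    if movement_onset_s is None:
        raise ValueError("movement onset required to define the premovement phase")
    acc_mp = cv_accuracy(session_static_features(session, "mp"),
                         session.labels, folds, seed)
    acc_me = cv_accuracy(session_static_features(session, "me"),
                         session.labels, folds, seed)
    if curve is None:
        feats, centers = session_tv_features(session)
        curve = tv_accuracy_curve(feats, session.labels, centers, folds, seed)
    onset_vs_mp = session.mp_s + movement_onset_s
    pre = np.flatnonzero(curve.window_centers_s < onset_vs_mp)
    if len(pre) == 0:
        raise ValueError("no window centers precede the movement onset")
    k = pre[int(np.argmax(curve.accuracy[pre]))]
    return PhaseAccuracySummary(
        mp_accuracy=acc_mp,
        premovement_accuracy=float(curve.accuracy[k]),
        me_accuracy=acc_me,
        premovement_peak_s=float(curve.window_centers_s[k]),
        premovement_peak_vs_onset_s=float(curve.window_centers_s[k] - onset_vs_mp),
        movement_onset_s=float(movement_onset_s),
    )


def time_series_baseline(session: EpochedSession, window: tuple[float, float],
                         band: tuple[float, float] = CONN_BAND,
                         folds: int = 10, seed: int = 0) -> float:
    """CV accuracy of raw (band-filtered) time-series features in a window.

    ``window`` is (start_s, end_s) relative to the MP cue; all channels'
    samples in the window are flattened per trial, mirroring the protocol
    used for the connectivity features.
    """
    bp = FIRBandpass(band[0], band[1], session.fs).fit()
    filtered = bp.transform(session.eeg)
    i0 = int(round((session.mp_cue_s + window[0]) * session.fs))
    i1 = int(round((session.mp_cue_s + window[1]) * session.fs))
    if not 0 <= i0 < i1 <= session.n_samples:
        raise ValueError(f"window {window} outside the trial")
    feats = filtered[:, :, i0:i1].reshape(session.n_trials, -1)
    return cv_accuracy(feats, session.labels, folds, seed)
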