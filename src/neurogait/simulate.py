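"""Synthetic EEG + IMU session generator with known ground truth.

Every downstream stage of the pipeline (slow-potential averaging,
sliding-window connectivity, bipedal classification, gait event detection,
synchronization statistics) is validated by parameter recovery against
sessions produced here.  The generator emulates the cued bipedal paradigm:
10-s trials (4 s fixation, 3 s motor preparation, 3 s motor execution),
50 left-foot and 50 right-foot trials, 32-channel 10/20 EEG at 500 Hz, and
a knee-angle trace per trial.

Injected structure
------------------
* A Cz-focal slow negative potential (trough + rebound) time-locked to the
  per-trial movement onset, spreading to neighboring electrodes with an
  exponential scalp-distance decay.
* Alpha-band sources on P3, FC4 and C4 whose mixing phase is steered so the
  windowed Pearson correlation of the P3–FC4 and P3–C4 pairs follows a
  target profile per phase: a positive-to-negative step during motor
  preparation (the dysconnection), and a raised-cosine peak during motor
  execution.  The construction uses the source's Hilbert quadrature, so the
  *sample* correlation over even a 200-ms window tracks the target rather
  than only its long-run expectation.
* A class-discriminative cross-channel component confined to a short
  premovement window: broadband 8–50 Hz activity mixed with opposite signs
  into two channels for left vs right trials, leaving each channel's
  marginal distribution identical between classes (only the correlation
  pattern carries class information).
* A smooth unimodal knee-angle bump starting at the reaction time after the
  ME cue and peaking a configurable delay later; the per-trial peak angle
  is (optionally) negatively coupled to the trial's preparatory
  parietal–frontocentral correlation level.
* 1/f-shaped Gaussian background noise, independent across channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .filtering import (ALPHA_BAND, CONN_BAND, MRCP_BAND, BandpassSpec,
                        apply_zero_phase, design_fir)
from .montage import CHANNELS_32, distances_from
from .session import EpochedSession, GroundTruth, KneeAngleTraces

PFCC_CONNECTIONS = ("P3-FC4", "P3-C4")


def _default_pfcc_targets() -> dict:
    # Phase-wise target Pearson r per connection: preparatory dysconnection
    # (negative), a weakly positive premovement level, and an execution peak.
    per = {"mp": -0.2, "premovement": 0.15, "me": 0.55}
    return {c: dict(per) for c in PFCC_CONNECTIONS}


@dataclass
class SimulationConfig:
    """Generator settings; defaults reproduce the cued bipedal paradigm.

    Times are seconds, amplitudes microvolts, angles degrees.
    """

    n_trials_per_class: int = 50
    fs: float = 500.0
    channel_names: tuple[str, ...] = CHANNELS_32
    fixation_s: float = 4.0
    mp_s: float = 3.0
    me_s: float = 3.0
    hemiplegic_side: str = "left"

    # slow movement-related potential (relative to the ME cue)
    mrcp_trough_latency_s: float = 1.21
    mrcp_trough_amplitude: float = -5.0       # negative = desynchronization
    mrcp_spatial_focus: str = "Cz"
    mrcp_spread_m: float = 0.04               # e-folding scalp distance
    mrcp_amplitude_jitter: float = 0.1        # fractional trial-to-trial sd
    mrcp_hemi_extra_uv: float = -0.25         # deeper trough, hemiplegic foot

    # gait
    reaction_time_s: float = 0.97             # ME cue -> movement onset
    onset_jitter_sd_s: float = 0.05
    knee_peak_delay_s: float = 0.70           # onset -> peak angle
    knee_peak_deg: float = 40.0
    knee_decay_s: float = 0.70                # peak -> return toward zero
    knee_noise_deg: float = 0.5
    knee_peak_sd_deg: float = 2.0
    knee_pfcc_slope_deg: float = -15.0        # deg per unit preparatory r

    # alpha-band connectivity control
    alpha_band: tuple[float, float] = ALPHA_BAND
    alpha_amp_uv: float = 10.0                # RMS of the injected sources
    pfcc_r_by_phase: dict = field(default_factory=_default_pfcc_targets)
    pfcc_profile: str = "event"               # 'event' or 'flat'
    pfcc_mp_negative_onset_s: float = 2.32    # after MP cue ('event' mode)
    pfcc_me_peak_s: float = 1.60              # after ME cue ('event' mode)
    pfcc_me_peak_halfwidth_s: float = 0.5
    pfcc_mp_baseline: float | None = None     # default: +|r_mp| (symmetric step)
    pfcc_trial_sd: float = 0.1                # per-trial r offset sd
    pfcc_hemi_r_offset: float = 0.05          # added for hemiplegic trials

    # class-discriminative premovement connectivity
    discrim_window: tuple[float, float] = (-0.2, 0.2)  # (start, length) vs onset
    discrim_strength: float = 1.0             # amplitude relative to noise_sd
    discrim_channels: tuple[str, str] = ("C3", "C4")

    noise_sd: float = 10.0                    # broadband RMS per channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        names = tuple(self.channel_names)
        if len(set(names)) != len(names):
            raise ValueError("channel_names must be unique")
        for required in ("P3", "FC4", "C4", "Cz"):
            if required not in names:
                raise ValueError(f"channel_names must include {required!r}")
        self.channel_names = names
        for conn, phases in self.pfcc_r_by_phase.items():
            if conn not in PFCC_CONNECTIONS:
                raise ValueError(f"unknown connection {conn!r}")
            for ph, r in phases.items():
                if not -1.0 <= r <= 1.0:
                    raise ValueError(f"target r {r} for {conn}/{ph} outside [-1, 1]")
        if self.pfcc_profile not in ("event", "flat"):
            raise ValueError("pfcc_profile must be 'event' or 'flat'")
        if self.mrcp_spatial_focus not in names:
            raise ValueError("mrcp_spatial_focus must be a montage channel")
        for ch in self.discrim_channels:
            if ch not in names:
                raise ValueError(f"discrim channel {ch!r} not in montage")

    @property
    def trial_s(self) -> float:
        return self.fixation_s + self.mp_s + self.me_s

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_s * self.fs))


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def make_correlated_pair(n: int, r_target: float, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Two zero-mean Gaussian signals with population correlation ``r_target``.

    Mixing construction: ``y = r*x + sqrt(1-r^2)*z`` with independent
    standard-normal ``x`` and ``z`` (the Cholesky factor of the 2x2
    correlation matrix).
    """
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not -1.0 <= r_target <= 1.0:
        raise ValueError(f"|r_target| must be <= 1, got {r_target}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    y = r_target * x + np.sqrt(1.0 - r_target**2) * z
    return x, y


def mrcp_template(fs: float, trough_amplitude: float,
                  pre_s: float = 2.0, post_s: float = 2.5) -> tuple[np.ndarray, np.ndarray]:
    """Smooth negative-then-rebound waveform with its minimum exactly at t=0.

    Returns ``(t, amplitude)``: a negative Gaussian trough followed by a
    positive rebound, scaled so the minimum equals ``trough_amplitude``
    (a negative value in microvolts).
    """
    sigma_trough, sigma_reb, t_reb, reb_frac = 0.30, 0.40, 0.90, 0.45

    def shape(t):
        return (-np.exp(-t**2 / (2 * sigma_trough**2))
                + reb_frac * np.exp(-(t - t_reb)**2 / (2 * sigma_reb**2)))

    # the rebound pulls the raw minimum slightly off zero; re-center it
    fine = np.arange(-0.5, 0.5, 1e-4)
    t_min = fine[np.argmin(shape(fine))]
    t = np.arange(-pre_s, post_s, 1.0 / fs)
    w = shape(t + t_min)
    w = w / abs(w.min()) * abs(trough_amplitude)
    return t, -w if trough_amplitude > 0 else w


def _one_over_f_noise(rng: np.random.Generator, shape: tuple, fs: float,
                      sd: float) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum (flat below 1 Hz)."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    gain = 1.0 / np.sqrt(np.maximum(f, 1.0))
    spec *= gain
    x = np.fft.irfft(spec, n=n, axis=-1)
    x *= sd / x.std(axis=-1, keepdims=True)
    return x


def _narrowband_source(rng: np.random.Generator, n_trials: int, n: int,
                       fs: float, band: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance narrowband Gaussian source and its Hilbert quadrature."""
    spec = BandpassSpec(band[0], band[1], fs)
    coeffs = design_fir(spec)
    s = apply_zero_phase(coeffs, rng.standard_normal((n_trials, n)))
    analytic = hilbert(s, axis=-1)
    s0 = np.real(analytic)
    sq = np.imag(analytic)
    s0 = s0 / s0.std(axis=-1, keepdims=True)
    sq = sq / sq.std(axis=-1, keepdims=True)
    return s0, sq


def _pfcc_profile(cfg: SimulationConfig, t: np.ndarray, onset_s: float,
                  targets: dict) -> np.ndarray:
    """Target correlation rho(t) over the trial grid for one connection.

    ``onset_s`` is the trial's movement onset after the ME cue.  In
    ``'event'`` mode the preparation phase steps from a symmetric positive
    baseline to the (negative) MP target at the nominal crossing time, and
    the execution phase carries a raised-cosine bump peaking at the nominal
    peak time; in ``'flat'`` mode each phase sits at its target value.
    """
    t_mp, t_me = cfg.fixation_s, cfg.fixation_s + cfg.mp_s
    r_mp, r_pre, r_me = targets["mp"], targets["premovement"], targets["me"]
    rho = np.full_like(t, r_mp)
    if cfg.pfcc_profile == "flat":
        rho[t >= t_me] = r_pre
        rho[t >= t_me + onset_s] = r_me
        return rho
    baseline = cfg.pfcc_mp_baseline if cfg.pfcc_mp_baseline is not None else abs(r_mp)
    rho[t < t_mp + cfg.pfcc_mp_negative_onset_s] = baseline
    rho[t >= t_me] = r_pre
    t_pk = t_me + cfg.pfcc_me_peak_s
    w = cfg.pfcc_me_peak_halfwidth_s
    in_bump = (t >= t_me) & (np.abs(t - t_pk) <= w)
    rho[in_bump] = r_pre + (r_me - r_pre) * np.cos(np.pi * (t[in_bump] - t_pk) / (2 * w))**2
    return rho


def _alpha_band_noise_var(cfg: SimulationConfig, noise: np.ndarray,
                          idx: list[int]) -> float:
    """Mean variance of the background noise within the alpha band."""
    if cfg.noise_sd == 0:
        return 0.0
    coeffs = design_fir(BandpassSpec(cfg.alpha_band[0], cfg.alpha_band[1], cfg.fs))
    filt = apply_zero_phase(coeffs, noise[:, idx, :])
    return float(filt.var(axis=-1).mean())


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def generate_session(cfg: SimulationConfig) -> tuple[EpochedSession, KneeAngleTraces, GroundTruth]:
    """Generate one session: EEG trials, knee traces and the ground truth.

    Deterministic in ``cfg.seed`` (same config + seed gives bit-identical
    arrays).  Trial order is a seeded shuffle of the balanced label set.
    """
    rng = np.random.default_rng(cfg.seed)
    n_trials = 2 * cfg.n_trials_per_class
    n = cfg.n_samples
    fs = cfg.fs
    t = np.arange(n) / fs
    t_me = cfg.fixation_s + cfg.mp_s

    labels = np.array(["left"] * cfg.n_trials_per_class
                      + ["right"] * cfg.n_trials_per_class)
    rng.shuffle(labels)
    hemi_mask = labels == cfg.hemiplegic_side

    # --- background noise ------------------------------------------------
    eeg = _one_over_f_noise(rng, (n_trials, len(cfg.channel_names), n), fs,
                            cfg.noise_sd)

    # --- per-trial latent variables --------------------------------------
    onset_s = cfg.reaction_time_s + cfg.onset_jitter_sd_s * rng.standard_normal(n_trials)
    onset_s = np.clip(onset_s, 0.0, cfg.me_s - cfg.knee_peak_delay_s - 0.05)
    trough_time_s = cfg.mrcp_trough_latency_s + (onset_s - cfg.reaction_time_s)
    trough_amp = cfg.mrcp_trough_amplitude * (
        1.0 + cfg.mrcp_amplitude_jitter * rng.standard_normal(n_trials))
    trough_amp = np.where(hemi_mask, trough_amp + cfg.mrcp_hemi_extra_uv, trough_amp)
    pfcc_offset = cfg.pfcc_trial_sd * rng.standard_normal(n_trials)

    # --- slow movement-related potential ---------------------------------
    ch_names = cfg.channel_names
    d = distances_from(cfg.mrcp_spatial_focus, ch_names)
    spread = np.exp(-d / cfg.mrcp_spread_m)
    # Unit-depth template, re-centered so its trough is at t=0 *after* the
    # 0.1-5 Hz analysis filter: the relaxed low edge feasible on 10-s
    # trials reshapes the asymmetric trough/rebound pair, and the injected
    # latency is defined on the filtered waveform the pipeline measures.
    tmpl_t, tmpl = mrcp_template(fs, -1.0)
    mrcp_coeffs = design_fir(BandpassSpec(MRCP_BAND[0], MRCP_BAND[1], fs))
    pad = np.zeros(max(n, 3 * len(mrcp_coeffs) + 1))
    mid = (len(pad) - len(tmpl)) // 2
    pad[mid:mid + len(tmpl)] = tmpl
    shift = int(np.argmin(apply_zero_phase(mrcp_coeffs, pad))) - (
        mid + int(np.argmin(tmpl)))
    tmpl_t = tmpl_t - shift / fs  # inject so the *filtered* trough lands at 0
    for i in range(n_trials):
        i0 = int(round((t_me + trough_time_s[i]) * fs)) + int(round(tmpl_t[0] * fs))
        j0, j1 = max(i0, 0), min(i0 + len(tmpl), n)
        seg = tmpl[j0 - i0:j1 - i0] * abs(trough_amp[i])
        eeg[i, :, j0:j1] += spread[:, None] * seg[None, :]

    # --- alpha-band connectivity control ---------------------------------
    i_p3 = ch_names.index("P3")
    i_fc4 = ch_names.index("FC4")
    i_c4 = ch_names.index("C4")
    n_alpha_var = _alpha_band_noise_var(cfg, eeg, [i_p3, i_fc4, i_c4])
    amp = cfg.alpha_amp_uv
    # attenuation by in-band background noise; pre-compensate the mixing
    comp = 1.0 + n_alpha_var / amp**2 if amp > 0 else 1.0
    s0, sq = _narrowband_source(rng, n_trials, n, fs, cfg.alpha_band)

    if amp > 0:
        eeg[:, i_p3, :] += amp * s0
        for conn, i_ch in (("P3-FC4", i_fc4), ("P3-C4", i_c4)):
            targets = cfg.pfcc_r_by_phase[conn]
            mix = np.empty((n_trials, n))
            for i in range(n_trials):
                rho = _pfcc_profile(cfg, t, onset_s[i], targets)
                rho = rho + pfcc_offset[i]
                if hemi_mask[i]:
                    rho = rho + cfg.pfcc_hemi_r_offset
                cos_delta = np.clip(rho * comp, -1.0, 1.0)
                sin_delta = np.sqrt(1.0 - cos_delta**2)
                mix[i] = cos_delta * s0[i] + sin_delta * sq[i]
            eeg[:, i_ch, :] += amp * mix

    # --- class-discriminative premovement component ----------------------
    if cfg.discrim_strength > 0:
        conn_coeffs = design_fir(BandpassSpec(CONN_BAND[0], CONN_BAND[1], fs))
        g = apply_zero_phase(conn_coeffs, rng.standard_normal((n_trials, n)))
        g = g / g.std(axis=-1, keepdims=True)
        w_amp = cfg.discrim_strength * (cfg.noise_sd if cfg.noise_sd > 0 else 1.0)
        i_a = ch_names.index(cfg.discrim_channels[0])
        i_b = ch_names.index(cfg.discrim_channels[1])
        start, length = cfg.discrim_window
        for i in range(n_trials):
            w0 = t_me + onset_s[i] + start
            k0 = int(round(w0 * fs))
            k1 = int(round((w0 + length) * fs))
            k0, k1 = max(k0, 0), min(k1, n)
            if k1 <= k0:
                continue
            taper = np.hanning(k1 - k0)
            sgn = 1.0 if labels[i] == "left" else -1.0
            burst = w_amp * taper * g[i, k0:k1]
            # class flips the *sign of the shared component on one channel
            # only*: the cross-covariance is +w^2 for left and -w^2 for
            # right trials while each channel's marginal is unchanged
            eeg[i, i_a, k0:k1] += burst
            eeg[i, i_b, k0:k1] += sgn * burst

    # --- knee-angle traces ------------------------------------------------
    knee_peak = (cfg.knee_peak_deg
                 + cfg.knee_pfcc_slope_deg * pfcc_offset
                 + cfg.knee_peak_sd_deg * rng.standard_normal(n_trials))
    knee_peak = np.clip(knee_peak, 5.0, None)
    angles = np.zeros((n_trials, n))
    for i in range(n_trials):
        t_on = t_me + onset_s[i]
        rise = (t >= t_on) & (t < t_on + cfg.knee_peak_delay_s)
        angles[i, rise] = knee_peak[i] * np.sin(
            np.pi * (t[rise] - t_on) / (2 * cfg.knee_peak_delay_s))
        t_pk = t_on + cfg.knee_peak_delay_s
        fall = (t >= t_pk) & (t < t_pk + cfg.knee_decay_s)
        angles[i, fall] = knee_peak[i] * np.cos(
            np.pi * (t[fall] - t_pk) / (2 * cfg.knee_decay_s))
    if cfg.knee_noise_deg > 0:
        angles += cfg.knee_noise_deg * rng.standard_normal(angles.shape)

    session = EpochedSession(eeg, ch_names, fs, labels,
                             cfg.fixation_s, cfg.mp_s, cfg.me_s,
                             cfg.hemiplegic_side)
    knees = KneeAngleTraces(angles, fs, labels, me_cue_s=t_me,
                            mp_cue_s=cfg.fixation_s)
    truth = GroundTruth(labels=labels.copy(), onset_s=onset_s,
                        trough_time_s=trough_time_s, trough_amp_uv=trough_amp,
                        knee_peak_deg=knee_peak, pfcc_trial_offset=pfcc_offset,
                        pfcc_r_by_phase={c: dict(v) for c, v in cfg.pfcc_r_by_phase.items()},
                        pfcc_mp_negative_onset_s=cfg.pfcc_mp_negative_onset_s,
                        pfcc_me_peak_s=cfg.pfcc_me_peak_s,
                        discrim_window=cfg.discrim_window, seed=cfg.seed)
    return session, knees, truth


def low_noise_config(**overrides) -> SimulationConfig:
    """Validation conditions for landmark recovery.

    Low background noise, minimal trial-to-trial jitter, and no
    condition/trial offsets on the PFCC targets, so that every injected
    latency (trough, crossing, peak, reaction time, knee-peak delay) is
    recoverable at window/sample resolution.
    """
    params = dict(noise_sd=0.5, onset_jitter_sd_s=0.01, knee_noise_deg=0.1,
                  mrcp_amplitude_jitter=0.02, pfcc_hemi_r_offset=0.0,
                  pfcc_trial_sd=0.0)
    params.update(overrides)
    return SimulationConfig(**params)


def reduced_montage_config(**overrides) -> SimulationConfig:
    """A small-montage, fewer-trials config for Monte-Carlo studies.

    Uses the nine motor-related channels (which include all channels the
    generator needs) and 20 trials per class; everything else defaults.
    """
    from .montage import MOTOR_CHANNELS_9

    params = dict(n_trials_per_class=20, channel_names=MOTOR_CHANNELS_9)
    params.update(overrides)
    return SimulationConfig(**params)
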