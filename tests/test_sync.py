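"""Feature synchronization, paired condition tests, regression."""

import numpy as np
import pytest
from scipy import stats

from neurogait import (AccuracyCurve, average_mrcp, average_trace, detect_onset,
                       generate_session, paired_connectivity_test, percent_increment,
                       pfcc_timecourse, reduced_montage_config, regress_pfcc_knee,
                       synchronize, trial_knee_peaks, trial_phase_means)
from neurogait.sync import grid_signed_rank


@pytest.fixture(scope="module")
def synced(low_noise_session):
    session, knees, truth = low_noise_session
    pfcc = {c: pfcc_timecourse(session, c) for c in ("P3-FC4", "P3-C4")}
    wave = average_mrcp(session)
    knee = average_trace(knees)
    onset = detect_onset(knee)
    centers = pfcc["P3-FC4"].window_centers_s
    # alignment-only stand-in for the (expensive) decoding curve
    curve = AccuracyCurve(centers, np.full(len(centers), 0.5),
                          np.zeros(len(centers)), 10, 0)
    return synchronize(wave, pfcc, curve, knee, onset), truth


class TestSynchronize:
    def test_landmark_ordering_matches_injected_timeline(self, synced):
        """Dysconnection onset < movement onset < trough < connectivity peak."""
        lm = synced[0].landmarks
        assert (lm["pfcc_negative_crossing_s"]
                < lm["movement_onset_s"]
                < lm["mrcp_trough_s"]
                < lm["pfcc_me_peak_s"])

    def test_streams_share_the_window_axis(self, synced):
        s = synced[0]
        n = len(s.times_s)
        assert len(s.mrcp_uv) == len(s.accuracy) == len(s.knee_deg) == n
        assert all(len(v) == n for v in s.pfcc.values())

    def test_missing_stream_is_named(self, synced):
        with pytest.raises(ValueError, match="knee"):
            synchronize(object(), {"x": object()}, object(), None)

    def test_linear_ramp_resamples_exactly(self, low_noise_session):
        session, knees, _ = low_noise_session
        pfcc = {c: pfcc_timecourse(session, c) for c in ("P3-FC4",)}
        wave = average_mrcp(session)
        knee = average_trace(knees)
        knee.angle[:] = 2.0 * knee.times + 1.0   # a pure line
        centers = pfcc["P3-FC4"].window_centers_s
        curve = AccuracyCurve(centers, np.full(len(centers), 0.5),
                              np.zeros(len(centers)), 10, 0)
        out = synchronize(wave, pfcc, curve, knee, 1.0)
        assert np.allclose(out.knee_deg, 2.0 * centers + 1.0, atol=1e-9)


class TestPairedTest:
    def test_identical_conditions_degenerate(self):
        x = np.linspace(0.1, 0.5, 50)
        with pytest.warns(UserWarning, match="degenerate"):
            stat, p, inc = paired_connectivity_test(x, x)
        assert p == 1.0 and inc == 0.0

    def test_proportional_increase_has_exact_increment(self):
        x = np.linspace(0.1, 0.5, 291)
        _, _, inc = paired_connectivity_test(x * 1.0345, x)
        assert inc == pytest.approx(3.45, abs=1e-9)

    def test_increment_antisymmetry_up_to_denominator(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.2, 0.6, 40)
        b = a + 0.1
        assert percent_increment(b, a) * np.mean(a) == pytest.approx(
            -percent_increment(a, b) * np.mean(b), rel=1e-9)

    def test_injected_offset_detected_at_291_windows(self, small_session):
        session, _, _ = small_session
        # small_session has the default +0.05 hemiplegic offset injected
        h = pfcc_timecourse(session, "P3-C4",
                            trials=session.trial_mask("hemiplegic")).mean_r
        n = pfcc_timecourse(session, "P3-C4",
                            trials=session.trial_mask("nonhemiplegic")).mean_r
        assert len(h) == 291
        _, p, inc = paired_connectivity_test(h, n)
        assert p < 0.01
        assert inc > 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            paired_connectivity_test(np.ones(5), np.ones(6))


class TestGridTest:
    def test_grid_shapes_and_symmetry(self):
        rng = np.random.default_rng(1)
        h = rng.uniform(-1, 1, (10, 4, 4))
        n = h + 0.0
        n[:, 0, 1] = h[:, 0, 1] - 0.3  # one consistently different cell
        n[:, 1, 0] = n[:, 0, 1]
        p, mask = grid_signed_rank(h, n, alpha=0.01)
        assert p.shape == mask.shape == (4, 4)
        assert np.allclose(p, p.T)
        assert mask[0, 1] and mask[1, 0]
        assert not mask.diagonal().any()

    def test_fdr_option_is_not_more_liberal(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(-1, 1, (12, 5, 5))
        n = rng.uniform(-1, 1, (12, 5, 5))
        _, raw = grid_signed_rank(h, n, alpha=0.05)
        _, fdr = grid_signed_rank(h, n, alpha=0.05, fdr=True)
        assert fdr.sum() <= raw.sum()


class TestRegression:
    def test_exact_line_has_zero_nrmse_and_exact_slope(self):
        x = np.linspace(-0.3, 0.3, 20)
        res = regress_pfcc_knee(x, 30.0 - 12.0 * x)
        assert res.slope == pytest.approx(-12.0, abs=1e-9)
        assert res.nrmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regress_pfcc_knee(np.ones(10), np.arange(10.0))

    def test_nrmse_invariant_to_affine_unit_change(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50) * 0.1
        y = 40 - 15 * x + rng.standard_normal(50)
        r1 = regress_pfcc_knee(x, y)
        r2 = regress_pfcc_knee(x, y * 180 / np.pi + 7.0)
        assert r1.nrmse == pytest.approx(r2.nrmse, rel=1e-9)

    def test_slope_ci_covers_injected_coupling_with_latent_predictor(self):
        """OLS on the generator's latent preparatory level recovers b."""
        cfg = reduced_montage_config(seed=61)
        _, knees, truth = generate_session(cfg)
        peaks = trial_knee_peaks(knees)
        res = stats.linregress(truth.pfcc_trial_offset, peaks)
        ci = 1.96 * res.stderr
        assert res.slope - ci < -15.0 < res.slope + ci

    def test_measured_pfcc_regression_recovers_negative_sign(self, small_session):
        session, knees, _ = small_session
        x = trial_phase_means(pfcc_timecourse(session, "P3-FC4"), "mp")
        res = regress_pfcc_knee(x, trial_knee_peaks(knees))
        assert res.slope < 0

    def test_pure_noise_slope_ci_covers_zero_95pct(self):
        rng = np.random.default_rng(4)
        cover = 0
        for _ in range(200):
            x = rng.standard_normal(50)
            y = rng.standard_normal(50)
            res = stats.linregress(x, y)
            if abs(res.slope) < 1.96 * res.stderr:
                cover += 1
        assert cover / 200 == pytest.approx(0.95, abs=0.05)
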