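"""Pearson connectivity: scalar, static matrices, sliding windows, PFCC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from neurogait import generate_session, reduced_montage_config
from neurogait.connectivity import (ConnectivityMatrix, SlidingWindowConnectivity,
                                    band_connectivity_grid, pearson_r,
                                    pfcc_timecourse, static_connectivity,
                                    tv_connectivity, window_count)
from .conftest import make_noise_session


def pearson_two_pass(x, y):
    """Independent oracle: literal two-pass evaluation of the formula."""
    xb = sum(x) / len(x)
    yb = sum(y) / len(y)
    num = sum((xi - xb) * (yi - yb) for xi, yi in zip(x, y))
    dx = sum((xi - xb) ** 2 for xi in x) ** 0.5
    dy = sum((yi - yb) ** 2 for yi in y) ** 0.5
    return num / (dx * dy)


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(0).standard_normal(100)
        assert pearson_r(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_gives_minus_one(self):
        x = np.random.default_rng(1).standard_normal(100)
        assert pearson_r(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_worked_example(self):
        # by hand: num=6.5, sx=sqrt(5), sy=sqrt(8.75) -> r=0.982707...
        x, y = [1, 2, 3, 4], [1, 2, 3, 5]
        expected = pearson_two_pass(x, y)
        assert expected == pytest.approx(0.9827076298, abs=1e-9)
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_signal_raises(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r(np.ones(10), np.arange(10.0))

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="3 samples"):
            pearson_r([1.0, 2.0], [2.0, 1.0])

    @settings(deadline=None, max_examples=100)
    @given(arrays(np.float64, st.integers(3, 60),
                  elements=st.floats(-100, 100, allow_nan=False)),
           st.integers(0, 2**16))
    def test_matches_two_pass_oracle(self, x, seed):
        y = np.random.default_rng(seed).standard_normal(len(x))
        if np.ptp(x) < 1e-6:  # (near-)constant input is a domain error
            return
        assert pearson_r(x, y) == pytest.approx(pearson_two_pass(x, y), abs=1e-12)


class TestWindowCount:
    @pytest.mark.parametrize("n,win,step,expected", [
        (3000, 100, 10, 291),   # 6 s at 500 Hz, 200 ms windows, 90% overlap
        (100, 100, 10, 1),
        (1000, 100, 50, 19),    # start indices 0, 50, ..., 900
    ])
    def test_counts(self, n, win, step, expected):
        assert window_count(n, win, step) == expected

    def test_count_matches_enumeration(self):
        for n, win, step in [(777, 50, 7), (512, 128, 13), (100, 99, 1)]:
            starts = [s for s in range(n) if s + win <= n and s % step == 0]
            assert window_count(n, win, step) == len(starts)

    def test_window_larger_than_signal_raises(self):
        with pytest.raises(ValueError, match="fit"):
            window_count(50, 100, 10)


class TestStaticConnectivity:
    def test_full_montage_shape_and_window_length(self, low_noise_session):
        session, _, _ = low_noise_session
        mats = static_connectivity(session, "me")
        assert len(mats) == session.n_trials
        assert mats[0].values.shape == (32, 32)
        # the 3-s phase at 500 Hz contains exactly 1500 samples
        assert session.segment(7.0, 10.0).shape[-1] == 1500

    def test_duplicated_channels_fully_correlated(self):
        session = make_noise_session(n_trials=4, n_channels=4, seed=3)
        session.eeg[:, 1, :] = session.eeg[:, 0, :]
        m = static_connectivity(session, "mp")[0]
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_independent_noise_off_diagonals_are_small(self):
        # null sd of r at N_t=1500 is ~1/sqrt(1500)=0.026; 0.08 is ~3 sigma
        session = make_noise_session(n_trials=10, n_channels=8, seed=4)
        mats = static_connectivity(session, "me")
        iu = np.triu_indices(8, k=1)
        offdiag = np.concatenate([m.values[iu] for m in mats])
        assert np.mean(np.abs(offdiag) > 0.08) < 0.02

    def test_unknown_phase_rejected(self, small_session):
        with pytest.raises(ValueError, match="phase"):
            static_connectivity(small_session[0], "fixation")


class TestTVConnectivity:
    def test_six_second_trial_yields_291_windows(self):
        rng = np.random.default_rng(5)
        series = tv_connectivity(rng.standard_normal((4, 3000)), 500.0,
                                 ("a", "b", "c", "d"))
        assert len(series) == 291
        assert series.values.shape == (291, 4, 4)
        assert np.all(np.diff(series.window_centers_s) > 0)

    def test_matrices_are_valid_correlations(self):
        rng = np.random.default_rng(6)
        series = tv_connectivity(rng.standard_normal((5, 1000)), 500.0,
                                 tuple("abcde"))
        v = series.values
        assert np.allclose(v, np.swapaxes(v, 1, 2))
        assert np.allclose(v[:, np.arange(5), np.arange(5)], 1.0)
        assert v.min() >= -1 and v.max() <= 1
        eigs = np.linalg.eigvalsh(v)
        assert eigs.min() >= -1e-8  # PSD up to floating error

    def test_single_full_window_reproduces_static(self):
        session = make_noise_session(n_trials=2, n_channels=5, seed=7)
        static = static_connectivity(session, "me")[0]
        seg = session.segment(7.0, 10.0)[0]
        series = tv_connectivity(seg, 500.0, session.channel_names,
                                 window_s=3.0, overlap=0.0)
        assert len(series) == 1
        assert np.allclose(series.values[0], static.values, atol=1e-12)

    def test_stationary_window_scatter_matches_sampling_noise(self):
        # r estimates from N_t=100 white-noise samples scatter ~1/sqrt(97)
        session = make_noise_session(n_trials=1, n_channels=2, seed=8,
                                     labels=np.array(["left"]))
        series = tv_connectivity(session.eeg[0], 500.0, ("a", "b"))
        r = series.values[:, 0, 1]
        expected = 1 / np.sqrt(97)
        assert 0.5 * expected < r.std() < 2 * expected

    def test_transformer_stacks_trials(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((3, 4, 1000))
        swc = SlidingWindowConnectivity(fs=500.0).fit(X)
        out = swc.transform(X)
        assert out.shape == (3, swc.n_windows_, 4, 4)
        assert swc.n_windows_ == window_count(1000, 100, 10)


class TestConnectivityMatrixInvariants:
    def test_asymmetric_values_rejected(self):
        v = np.eye(3)
        v[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            ConnectivityMatrix(v, ("a", "b", "c"), (0, 1))

    def test_non_unit_diagonal_rejected(self):
        v = np.eye(3) * 0.9
        with pytest.raises(ValueError, match="diagonal"):
            ConnectivityMatrix(v, ("a", "b", "c"), (0, 1))


class TestPFCC:
    def test_flat_positive_profile_has_no_crossing(self):
        flat = {c: {"mp": 0.4, "premovement": 0.4, "me": 0.4}
                for c in ("P3-FC4", "P3-C4")}
        cfg = reduced_montage_config(seed=51, pfcc_profile="flat",
                                     pfcc_r_by_phase=flat,
                                     pfcc_hemi_r_offset=0.0, pfcc_trial_sd=0.0)
        session, _, _ = generate_session(cfg)
        tc = pfcc_timecourse(session, "P3-FC4")
        assert tc.negative_crossing_s is None
        assert tc.mean_r.std() < 0.1  # flat curve

    def test_unknown_connection_rejected(self, small_session):
        with pytest.raises(ValueError, match="connection"):
            pfcc_timecourse(small_session[0], "P3-XX")

    def test_per_trial_curves_have_shared_length(self, small_session):
        tc = pfcc_timecourse(small_session[0], "P3-C4")
        assert tc.per_trial_r.shape == (40, len(tc.window_centers_s))
        assert np.all(np.abs(tc.per_trial_r) <= 1)


class TestBandGrid:
    def test_alpha_grid_shape(self, small_session):
        session, _, _ = small_session
        grids = band_connectivity_grid(session, bands={"alpha": (8.0, 13.0)})
        assert grids["alpha"].shape == (session.n_trials, 9, 9)

    def test_identical_conditions_have_zero_paired_difference(self, small_session):
        session, _, _ = small_session
        g = band_connectivity_grid(session, bands={"alpha": (8.0, 13.0)})["alpha"]
        assert np.allclose(g - g, 0.0)

    def test_injected_alpha_difference_localizes_to_alpha_pfcc_cell(self):
        cfg = reduced_montage_config(seed=52, pfcc_hemi_r_offset=0.25,
                                     pfcc_trial_sd=0.0)
        session, _, _ = generate_session(cfg)
        bands = {"theta": (4.0, 7.0), "alpha": (8.0, 13.0)}
        hemi = band_connectivity_grid(session, bands=bands,
                                      trials=session.trial_mask("hemiplegic"))
        non = band_connectivity_grid(session, bands=bands,
                                     trials=session.trial_mask("nonhemiplegic"))
        names = ("FC3", "FCz", "FC4", "C3", "Cz", "C4", "P3", "Pz", "P4")
        i_p3, i_c4 = names.index("P3"), names.index("C4")
        d_alpha = hemi["alpha"].mean(0) - non["alpha"].mean(0)
        d_theta = hemi["theta"].mean(0) - non["theta"].mean(0)
        assert d_alpha[i_p3, i_c4] > 0.1
        assert abs(d_theta[i_p3, i_c4]) < d_alpha[i_p3, i_c4] / 2

    def test_unknown_channel_rejected(self, small_session):
        with pytest.raises(KeyError):
            band_connectivity_grid(small_session[0], channels=("P3", "XX"))
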