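"""Closed-form phenomenological predictions versus simulation oracles, and
the exact two-learner decomposition."""

import numpy as np
import pytest

import sinadapt as sa
from sinadapt.analytic import (
    asymptote,
    periodic_response,
    timescales,
    two_learner_view,
)
from sinadapt.state_model import GenerativeParams, simulate


class TestAsymptote:
    def test_zero_drift_pins_baseline_at_zero(self):
        assert asymptote(K=0.1, A=0.99, m=0.0, D=-0.05) == 0.0

    def test_m_over_k_at_unit_retention(self):
        assert asymptote(K=0.02, A=1.0, m=-0.004) == pytest.approx(-0.2)

    def test_m_over_k_plus_d_with_double_error_sampling(self):
        val = asymptote(K=0.15, A=1.0, m=-0.004, D=-0.13)
        assert val == pytest.approx(-0.2)
        # fixed point of a long zero-stimulus run
        x, _ = simulate(
            None, GenerativeParams(K=0.15, A=1.0, m=-0.004, D=-0.13, G=1.0), np.zeros(10_000)
        )
        assert x[-1] == pytest.approx(val, abs=1e-10)

    def test_marginally_stable_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            asymptote(K=0.02, A=1.02, m=-0.004)


class TestTimescales:
    def test_single_error_mode_is_a_minus_k(self):
        base = timescales(K=0.02, A=1.0, D=0.0)
        assert base.modes == (pytest.approx(0.98),)
        assert base.dominant_lambda == pytest.approx(-np.log(0.98))
        assert base.dominant_lambda == pytest.approx(0.0202, abs=2e-4)

    def test_unit_root_gives_zero_decay(self):
        assert timescales(K=0.0, A=1.0, D=0.0).dominant_lambda == pytest.approx(0.0)

    def test_double_error_modes_match_companion_eigenvalues(self):
        base = timescales(K=0.15, A=1.0, D=-0.13)
        eig = np.linalg.eigvals(np.array([[0.85, 0.13], [1.0, 0.0]]))
        np.testing.assert_allclose(sorted(base.modes), sorted(eig.real), atol=1e-12)
        assert base.modes[0] == pytest.approx(0.98234, abs=1e-5)
        assert base.modes[1] == pytest.approx(-0.13234, abs=1e-5)
        assert base.dominant_lambda == pytest.approx(0.0178, abs=1e-4)
        assert not base.oscillatory

    def test_complex_modes_are_flagged_oscillatory(self):
        base = timescales(K=0.1, A=1.0, D=0.5)
        assert base.oscillatory

    def test_negative_d_slows_the_dominant_decay(self):
        # same A - K: a negative D pushes the dominant root toward 1, so the
        # baseline decays with smaller lambda (a longer integration window)
        lam_single = timescales(K=0.15, A=0.99, D=0.0).dominant_lambda
        lam_double = timescales(K=0.15, A=0.99, D=-0.13).dominant_lambda
        assert lam_double < lam_single


class TestPeriodicResponse:
    def test_single_error_limit_has_no_extra_lag(self):
        per = periodic_response(K=0.05, A=0.99, D=0.0, omega=0.1)
        assert per.varphi == 0.0
        assert per.Q == pytest.approx(0.05)
        assert per.a == pytest.approx(0.05 / per.R)

    def test_slow_stimulus_is_fully_tracked(self):
        per = periodic_response(K=0.02, A=1.0, D=0.0, omega=1e-6)
        assert per.a == pytest.approx(1.0, abs=1e-3)

    def test_matches_simulation_regression(self):
        K, A, D = 0.02, 1.0, 0.0
        w = 2 * np.pi * 6 / 384
        n = np.arange(1, 8001)
        x, _ = simulate(None, GenerativeParams(K=K, A=A), np.sin(w * n))
        X = np.column_stack([np.sin(w * n), np.cos(w * n), np.ones(n.size)])
        beta, *_ = np.linalg.lstsq(X[4000:], x[4000:], rcond=None)
        per = periodic_response(K, A, D, w)
        assert np.hypot(beta[0], beta[1]) == pytest.approx(per.a, abs=1e-6)
        assert np.arctan2(-beta[1], beta[0]) == pytest.approx(per.total_lag, abs=1e-6)

    def test_lag_reported_in_trials(self):
        per = periodic_response(K=0.05, A=1.0, D=-0.02, omega=0.1)
        assert per.total_lag_trials == pytest.approx(per.total_lag / 0.1)

    def test_omega_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            periodic_response(K=0.05, omega=0.0)


class TestTwoLearnerView:
    def test_rates_are_sum_and_difference(self, single_block_trials):
        x, _ = simulate(None, GenerativeParams(K=0.15, D=-0.13), single_block_trials)
        view = two_learner_view(0.15, -0.13, single_block_trials, x)
        assert view.kappa == pytest.approx(0.02)
        assert view.eta == pytest.approx(0.28)

    def test_constant_stimulus_has_no_difference_channel(self):
        s = np.full(50, 0.7)
        x, _ = simulate(None, GenerativeParams(K=0.1, D=-0.05, G=0.0), s)
        view = two_learner_view(0.1, -0.05, s, x)
        np.testing.assert_allclose(view.S_minus[1:], 0.0, atol=1e-14)
        np.testing.assert_allclose(view.S_plus[1:], 0.7, atol=1e-14)

    def test_reconstruction_identities_exact(self, single_block_trials):
        x, _ = simulate(None, GenerativeParams(K=0.15, A=0.99, D=-0.13, G=0.2), single_block_trials)
        view = two_learner_view(0.15, -0.13, single_block_trials, x)
        np.testing.assert_allclose(view.X_plus + view.X_minus, x, atol=1e-15, rtol=0)
        s = single_block_trials["s"].to_numpy()
        np.testing.assert_allclose(view.S_plus + view.S_minus, s, atol=1e-15, rtol=0)
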