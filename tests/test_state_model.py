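"""State-equation family: enumeration, forward simulation, and its
equivalence with the explicit convolution solution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sinadapt as sa
from sinadapt.state_model import (
    GenerativeParams,
    enumerate_model_specs,
    get_model_spec,
    initial_gain_estimate,
    is_stable,
    self_consistent_initial_gain,
    simulate,
)


class TestModelFamily:
    def test_sixteen_unique_models_four_per_group(self):
        specs = enumerate_model_specs()
        assert len(specs) == 16
        assert len({s.name for s in specs}) == 16
        by_group = {}
        for s in specs:
            by_group.setdefault(s.group, []).append(s.name)
        assert {g: len(v) for g, v in by_group.items()} == {"I": 4, "II": 4, "III": 4, "IV": 4}

    def test_group_membership_matches_m_and_d_presence(self):
        by_group = {}
        for s in enumerate_model_specs():
            by_group.setdefault(s.group, set()).add(s.name)
        assert by_group["II"] == {"Km", "KmG", "KAm", "KAmG"}
        assert by_group["IV"] == {"KmD", "KAmD", "KmDG", "KAmDG"}

    def test_fixed_parameters_enforced(self):
        spec = get_model_spec("K")
        p = GenerativeParams(K=0.02, A=0.5, m=0.3, D=0.1).constrained(spec)
        assert (p.A, p.m, p.D) == (1.0, 0.0, 0.0)

    def test_enumeration_is_deterministic(self):
        assert [s.name for s in enumerate_model_specs()] == [
            s.name for s in enumerate_model_specs()
        ]


class TestInitialGainEstimate:
    def test_constant_series(self):
        assert initial_gain_estimate(np.full(10, 0.1)) == pytest.approx(0.1)

    def test_window_excludes_later_values(self):
        g = np.array([0.0, 0.5, -0.5, 0.2, -0.2, 9.0, 9.0])
        assert initial_gain_estimate(g) == pytest.approx(0.0)

    def test_degenerate_window(self):
        assert initial_gain_estimate(np.array([0.3, 5.0]), window=1) == pytest.approx(0.3)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            initial_gain_estimate(np.array([]))


class TestSimulate:
    def test_geometric_contraction_without_stimulus(self):
        x, unstable = simulate(None, GenerativeParams(K=0.02, A=1.0, G=1.0), np.zeros(200))
        np.testing.assert_allclose(x, 0.98 ** np.arange(200), rtol=1e-12)
        assert not unstable

    def test_drift_fixed_point_m_over_k(self):
        x, _ = simulate(None, GenerativeParams(K=0.02, A=1.0, m=-0.004), np.zeros(2000))
        assert x[-1] == pytest.approx(-0.2, abs=1e-8)

    def test_steady_state_matches_analytic_sinusoid(self):
        K, A, D = 0.05, 1.0, 0.0
        w = 2 * np.pi * 6 / 384
        n = np.arange(1, 4001)
        x, _ = simulate(None, GenerativeParams(K=K, A=A), np.sin(w * n))
        per = sa.periodic_response(K, A, D, w)
        expected = per.a * np.sin(w * n - per.total_lag)
        assert np.max(np.abs(x[2000:] - expected[2000:])) < 1e-6

    def test_matches_convolution_solution_when_d_is_zero(self):
        # iteration oracle: x(n) = (A-K)^(n-1) G + sum_j (A-K)^(n-1-j) (K s(j) + m)
        rng = np.random.default_rng(7)
        s = rng.uniform(-1, 1, 200)
        for K, A, m, G in [(0.02, 1.0, 0.0, 0.5), (0.1, 0.97, -0.004, -0.3)]:
            x, _ = simulate(None, GenerativeParams(K=K, A=A, m=m, G=G), s)
            b = A - K
            expected = np.empty(200)
            for n in range(1, 201):
                acc = b ** (n - 1) * G
                for j in range(1, n):
                    acc += b ** (n - 1 - j) * (K * s[j - 1] + m)
                expected[n - 1] = acc
            np.testing.assert_allclose(x, expected, atol=1e-12)

    def test_linearity_in_the_stimulus(self):
        rng = np.random.default_rng(3)
        s1, s2 = rng.uniform(-1, 1, (2, 300))
        p = GenerativeParams(K=0.15, A=0.99, D=-0.1)
        x1, _ = simulate(None, p, s1)
        x2, _ = simulate(None, p, s2)
        x12, _ = simulate(None, p, 2.0 * s1 - 0.5 * s2)
        np.testing.assert_allclose(x12, 2.0 * x1 - 0.5 * x2, atol=1e-10)

    def test_divergence_is_flagged_not_raised(self):
        x, unstable = simulate(None, GenerativeParams(K=-0.5, A=1.4, G=1.0), np.zeros(500))
        assert unstable
        assert np.all(np.isfinite(x))

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate(None, GenerativeParams(K=np.nan), np.zeros(10))

    @settings(derandomize=True, max_examples=100)
    @given(
        K=st.floats(0.0, 0.5),
        A=st.floats(0.8, 1.1),
        D=st.floats(-0.4, 0.2),
    )
    def test_stability_flag_matches_companion_matrix_oracle(self, K, A, D):
        roots = np.linalg.eigvals(np.array([[A - K, -D], [1.0, 0.0]]))
        oracle = bool(np.all(np.abs(roots) < 1.0))
        assert is_stable(K, A, D) == oracle
        if abs(max(np.abs(roots)) - 1.0) > 0.02:  # away from the marginal case
            x, unstable = simulate(
                None, GenerativeParams(K=K, A=A, D=D, G=1.0), np.sin(0.1 * np.arange(3000))
            )
            assert unstable == (not oracle)

    def test_self_consistent_initial_gain_is_a_fixed_point(self):
        p = GenerativeParams(K=0.02, A=0.99, m=-0.004)
        s = sa.build_session(sa.single_block_design(6))["s"].to_numpy()
        G = self_consistent_initial_gain(p, s)
        x, _ = simulate(None, GenerativeParams(K=p.K, A=p.A, m=p.m, G=G), s)
        assert x[:5].mean() == pytest.approx(G, abs=1e-12)
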