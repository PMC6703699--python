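"""Phenomenological curve fitting, posterior behavior and decibel evidence."""

import numpy as np
import pytest

import sinadapt as sa
from sinadapt.phenom_fit import (
    PhenomenologicalModel,
    PhenomParams,
    PhenomPriors,
    evidence_db,
    evidence_report,
    phenom_predict,
    weighted_population_estimate,
)
from sinadapt.state_model import GenerativeParams, simulate

TRUTH = PhenomParams(a=0.3, nu=6.0, phi=0.8, B=0.25, lam=0.01, B0=-0.2)


class TestPhenomPredict:
    def test_zero_amplitude_is_pure_drift(self, single_block_trials):
        p = PhenomParams(a=0.0, nu=6.0, B=0.3, lam=0.02, B0=-0.1)
        n = np.arange(1, len(single_block_trials) + 1)
        np.testing.assert_allclose(
            phenom_predict(p, single_block_trials), 0.3 * np.exp(-0.02 * n) - 0.1
        )

    def test_pure_sinusoid_is_silent_before_adaptation_onset(self, single_block_trials):
        p = PhenomParams(a=0.5, nu=6.0, phi=0.3)
        pred = phenom_predict(p, single_block_trials)
        np.testing.assert_allclose(pred[:75], 0.0)
        w = 2 * np.pi * 6 / 384
        j = np.arange(1, 385)
        np.testing.assert_allclose(pred[75:], 0.5 * np.sin(w * j - 0.3))

    def test_analytic_parameters_reproduce_state_simulation(self):
        # cross-module consistency: closed-form solution -> phenom curve
        K, A, m, D = 0.02, 0.997, -0.0002, 0.0
        f, N = 6, 384
        w = 2 * np.pi * f / N
        design = sa.SessionDesign((N * 10,), ("adaptation",), (f * 10,))
        trials = sa.build_session(design)
        x, _ = simulate(None, GenerativeParams(K=K, A=A, m=m), trials)
        per = sa.periodic_response(K, A, D, w)
        p = PhenomParams(
            a=per.a, nu=float(f * 10), phi=per.total_lag, B=0.0, lam=0.0,
            B0=sa.asymptote(K, A, m, D),
        )
        pred = phenom_predict(p, trials)
        rms = np.sqrt(np.mean((x[2000:] - pred[2000:]) ** 2))
        assert rms < 1e-3


class TestFit:
    def test_noise_free_recovery_is_exact(self, single_block_trials):
        y = phenom_predict(TRUTH, single_block_trials)
        est = PhenomenologicalModel().fit(single_block_trials, y)
        for name in ("a", "nu", "phi", "B", "lam", "B0"):
            assert getattr(est.params_, name) == pytest.approx(
                getattr(TRUTH, name), rel=1e-6
            ), name

    def test_white_noise_supports_the_noise_only_model(self, single_block_trials):
        rng = np.random.default_rng(11)
        y = -0.1 + rng.normal(0.0, 0.1, len(single_block_trials))
        est = PhenomenologicalModel().fit(single_block_trials, y)
        mean, var = est.posterior_.moments["a"]
        assert abs(mean) < 3 * np.sqrt(var) + 0.02
        rep = evidence_report(y, single_block_trials)
        assert rep.db_full_vs_noise < 0
        assert rep.db_drift_vs_noise < 0

    def test_frequency_recovered_for_every_freq_session_block(self):
        truth = GenerativeParams(K=0.02, A=0.99, m=-0.004)
        obs = sa.generate_observer(sa.freq_design(), "KAm", truth, 0.1, seed=5)
        for _, blk in obs[obs["block_type"] == "adaptation"].groupby("block"):
            f = blk["frequency_cpb"].iloc[0]
            pre = obs[(obs["block"] == blk["block"].iloc[0] - 1)]
            seg = np.concatenate([pre.index, blk.index])
            trials_seg = obs.loc[seg].reset_index(drop=True)
            trials_seg["trial"] = np.arange(1, len(trials_seg) + 1)
            est = PhenomenologicalModel().fit(trials_seg, trials_seg["g"])
            assert est.params_.nu == pytest.approx(f, abs=0.25)

    def test_posterior_concentrates_with_trial_count(self):
        rng = np.random.default_rng(2)
        sds = {}
        for n_adapt in (150, 1500):
            design = sa.SessionDesign(
                (50, n_adapt), ("non-adaptation", "adaptation"), (max(1, n_adapt // 64),)
            )
            trials = sa.build_session(design)
            p = PhenomParams(a=0.3, nu=float(max(1, n_adapt // 64)), phi=0.5,
                             B=0.2, lam=0.02, B0=-0.15)
            y = phenom_predict(p, trials) + rng.normal(0, 0.05, len(trials))
            est = PhenomenologicalModel().fit(trials, y)
            sds[n_adapt] = est.posterior_.sd("a")
        assert sds[1500] < sds[150]

    def test_too_few_trials_rejected(self):
        trials = sa.build_session(sa.SessionDesign((4,), ("adaptation",), (1,)))
        with pytest.raises(ValueError, match="fewer trials"):
            PhenomenologicalModel().fit(trials, np.zeros(4))

    def test_misaligned_series_rejected(self, single_block_trials):
        with pytest.raises(ValueError, match="misaligned"):
            PhenomenologicalModel().fit(single_block_trials, np.zeros(10))


@pytest.fixture(scope="module")
def noisy_series(single_block_trials):
    rng = np.random.default_rng(8)
    return phenom_predict(TRUTH, single_block_trials) + rng.normal(
        0, 0.1, len(single_block_trials)
    )


class TestEvidence:

    def test_identical_models_have_zero_evidence(self, noisy_series, single_block_trials):
        assert evidence_db(noisy_series, single_block_trials, "full", "full") == 0.0

    def test_antisymmetry(self, noisy_series, single_block_trials):
        ab = evidence_db(noisy_series, single_block_trials, "full", "drift")
        ba = evidence_db(noisy_series, single_block_trials, "drift", "full")
        assert ab == pytest.approx(-ba, abs=1e-9)

    def test_nested_chain_additivity(self, noisy_series, single_block_trials):
        rep = evidence_report(noisy_series, single_block_trials)
        direct = evidence_db(noisy_series, single_block_trials, "full", "noise")
        assert rep.db_full_vs_drift + rep.db_drift_vs_noise == pytest.approx(
            direct, abs=1e-9
        )

    def test_clear_periodic_signal_beats_drift_by_more_than_3_db(
        self, noisy_series, single_block_trials
    ):
        assert evidence_db(noisy_series, single_block_trials, "full", "drift") > 3.0

    def test_scale_invariance_of_the_marginalized_posterior(
        self, noisy_series, single_block_trials
    ):
        db1 = evidence_db(noisy_series, single_block_trials, "full", "drift")
        c = 7.0
        priors = PhenomPriors(
            amp_range=(-2 * c, 2 * c), B_range=(-2 * c, 2 * c), B0_range=(-2 * c, 2 * c)
        )
        db2 = evidence_db(c * noisy_series, single_block_trials, "full", "drift",
                          priors=priors)
        assert db2 == pytest.approx(db1, abs=1e-6)

    def test_non_nested_model_name_rejected(self, noisy_series, single_block_trials):
        with pytest.raises(ValueError):
            evidence_db(noisy_series, single_block_trials, "full", "cubic")


class TestPopulationPooling:
    def test_equal_uncertainty_reduces_to_mean(self):
        assert weighted_population_estimate([1.0, 3.0], [1.0, 1.0]) == pytest.approx(2.0)

    def test_uncertain_participant_is_downweighted(self):
        assert weighted_population_estimate([0.0, 10.0], [1.0, 1e6]) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_single_participant(self):
        assert weighted_population_estimate([0.4], [0.2]) == pytest.approx(0.4)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            weighted_population_estimate([1.0, 2.0], [0.0, 1.0])
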