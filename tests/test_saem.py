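"""Estimation-engine behaviour: recovery, reproducibility, uncertainty."""

import math

import numpy as np
import pytest

from trajmix import (
    ModelSpec,
    ParameterLink,
    SAEMSettings,
    SimScenario,
    empirical_bayes,
    fit,
    marginal_loglik,
    simulate_dataset,
    smm_scenario,
    wald_pvalues,
)
from trajmix.errors import InitializationError


def noise_free_pmm(n=50, seed=21):
    truth = ParameterLink(
        alpha=[-1.21, -0.03, -0.32, -3.0],
        random_mask=(True,) * 4,
        B=np.diag([1e-8] * 4),
        sigma=1e-4,
    )
    return simulate_dataset(SimScenario(model_id=2, n_subjects=n, truth=truth, seed=seed))


class TestFit:
    def test_noise_free_limit_recovers_fixed_effects(self):
        """With vanishing random effects and noise the estimator must
        collapse to nonlinear least squares on the population curve."""
        sim = noise_free_pmm()
        res = fit(sim.data, ModelSpec(model_id=2),
                  SAEMSettings(n_burn_iters=300, n_sa_iters=100, n_chains=1,
                               seed=3, compute_se=False, compute_loglik=False))
        assert np.allclose(res.estimates.alpha, [-1.21, -0.03, -0.32, -3.0],
                           atol=1e-2)

    def test_seeded_fit_is_bit_reproducible(self, pmm_sim, fast_settings):
        r1 = fit(pmm_sim.data, ModelSpec(model_id=2), fast_settings)
        r2 = fit(pmm_sim.data, ModelSpec(model_id=2), fast_settings)
        assert np.array_equal(r1.trace, r2.trace)

    def test_covariance_sparsity_mask_is_exact(self, pmm_sim, fast_settings):
        res = fit(pmm_sim.data, ModelSpec(model_id=2), fast_settings)
        B = res.estimates.B
        for i, j in ((0, 1), (0, 2), (0, 3), (1, 3), (2, 3)):
            assert B[i, j] == 0.0 == B[j, i]
        assert B[1, 2] == B[2, 1]

    def test_smm_random_effects_limited_to_levels(self, smm_sim, fast_settings):
        res = fit(smm_sim.data, ModelSpec(model_id=1), fast_settings)
        B = res.estimates.B
        assert np.all(B[2:, :] == 0) and np.all(B[:, 2:] == 0)
        assert res.estimates.sigma > 0

    def test_non_finite_initials_raise(self, pmm_sim):
        spec = ModelSpec(model_id=1, start=[np.inf, 0.4, 2.0, 1.0])
        with pytest.raises(Exception):
            fit(pmm_sim.data, spec, SAEMSettings(n_burn_iters=5, n_sa_iters=5))


class TestWaldPvalues:
    def test_zero_estimate_gives_p_one(self):
        assert wald_pvalues({"a": 0.0}, {"a": 1.0})["a"] == pytest.approx(1.0)

    def test_critical_z(self):
        p = wald_pvalues({"a": 1.959964}, {"a": 1.0})["a"]
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_huge_se_no_information(self):
        p = wald_pvalues({"a": 1.0}, {"a": 1e6})["a"]
        assert p > 0.999

    def test_missing_se_gives_missing_p(self):
        assert wald_pvalues({"a": 1.0}, {"a": None})["a"] is None


class TestMarginalLoglik:
    def test_zero_variance_equals_residual_loglik(self):
        sim = noise_free_pmm(n=6, seed=5)
        truth = ParameterLink(
            alpha=[-1.21, -0.03, -0.32, -3.0],
            random_mask=(True,) * 4,
            B=np.zeros((4, 4)),
            sigma=0.5,
        )
        ll, se = marginal_loglik(sim.data, ModelSpec(model_id=2), truth,
                                 n_is_samples=10, seed=0)
        from trajmix.models import MODELS
        t = sim.data.time
        f = MODELS[2].evaluate(t, np.tile(truth.alpha, (t.size, 1)))
        resid = sim.data.outcome - f
        expect = (-0.5 * t.size * math.log(2 * math.pi * 0.25)
                  - float(resid @ resid) / (2 * 0.25))
        assert ll == pytest.approx(expect, rel=1e-12)
        assert se == 0.0

    def test_doubling_samples_is_consistent(self):
        sim = simulate_dataset(smm_scenario(n_subjects=25, seed=3))
        spec = ModelSpec(model_id=1)
        truth = sim.scenario.truth
        ll1, se1 = marginal_loglik(sim.data, spec, truth, n_is_samples=200, seed=1)
        ll2, se2 = marginal_loglik(sim.data, spec, truth, n_is_samples=400, seed=2)
        assert abs(ll2 - ll1) < 2 * (se1 + se2)

    def test_reproducible_for_fixed_seed(self):
        sim = simulate_dataset(smm_scenario(n_subjects=10, seed=3))
        spec = ModelSpec(model_id=1)
        a = marginal_loglik(sim.data, spec, sim.scenario.truth, 100, seed=9)
        b = marginal_loglik(sim.data, spec, sim.scenario.truth, 100, seed=9)
        assert a == b


class TestEmpiricalBayes:
    def test_near_noise_free_subjects_recover_their_effects(self):
        B = np.zeros((4, 4))
        B[0, 0], B[1, 1] = 1.46**2, 0.51**2
        truth = ParameterLink(
            alpha=[-1.03, 0.37, 4.0, 1.69],
            random_mask=(True, True, False, False),
            B=B,
            sigma=1e-3,
        )
        sim = simulate_dataset(SimScenario(model_id=1, n_subjects=25, truth=truth, seed=6))
        eta, psi = empirical_bayes(sim.data, ModelSpec(model_id=1), truth,
                                   n_burn=150, n_keep=300, seed=2)
        err = np.abs(eta.to_numpy()[:, :2] - sim.eta[:, :2])
        assert err.max() < 1e-2

    def test_population_mean_of_estimates_centres_at_zero(self, pmm_sim):
        eta, _ = empirical_bayes(pmm_sim.data, ModelSpec(model_id=2),
                                 pmm_sim.scenario.truth, n_burn=50, n_keep=100,
                                 seed=4)
        m = eta.to_numpy().mean(axis=0)
        sds = np.sqrt(np.diag(pmm_sim.scenario.truth.B))
        assert np.all(np.abs(m) < 3.5 * sds / np.sqrt(pmm_sim.data.n_subjects) + 1e-6)
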