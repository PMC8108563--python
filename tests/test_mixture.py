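import numpy as np
import pytest
from scipy import integrate

import locmem as lm
from locmem.circular import circ_sd_to_kappa
from locmem.mixture import (
    FitError,
    McmcConfig,
    MixtureParams,
    compare_models,
    dic,
    fit_bayes,
    fit_mle,
    negative_log_likelihood,
    sample_mixture_errors,
)

FAST_MCMC = McmcConfig(n_chains=3, n_draws=4000, burn_in=1000, thin=4)


def brute_force_nll(errors, offsets, params, model_id):
    """Independent oracle: per-trial density summed with plain scipy calls."""
    from scipy.special import iv

    total = 0.0
    for i, e in enumerate(errors):
        vm = lambda x, mu: np.exp(params.kappa * np.cos(np.radians(x - mu))) / (
            360.0 * iv(0, params.kappa))
        dens = params.p_target * vm(e, 0.0)
        if model_id >= 2:
            dens += params.p_guess / 360.0
        if model_id == 3:
            dens += params.p_swap * np.mean([vm(e, o) for o in offsets[i]])
        total -= np.log(dens)
    return total


class TestLikelihood:
    def test_degenerate_mixture_is_uniform(self):
        params = MixtureParams(kappa=1e-12, p_guess=0.5)
        nll = negative_log_likelihood([0.0] * 10, None, params, 2)
        assert nll == pytest.approx(10 * np.log(360.0), rel=1e-9)

    def test_model_nesting(self, model2_errors_20k):
        e = model2_errors_20k[:500]
        kappa = circ_sd_to_kappa(20.0)
        nll1 = negative_log_likelihood(e, None, MixtureParams(kappa=kappa), 1)
        nll2 = negative_log_likelihood(
            e, None, MixtureParams(kappa=kappa, p_guess=0.0), 2)
        assert nll1 == pytest.approx(nll2, rel=1e-12)

    @pytest.mark.parametrize("model_id", [1, 2, 3])
    def test_matches_brute_force_evaluator(self, model_id):
        errors = np.array([-40.0, -5.0, 0.0, 3.0, 120.0])
        offsets = np.array(
            [[70.0, -80.0], [65.0, 130.0], [-90.0, 63.0], [100.0, -70.0],
             [118.0, -120.0]])
        params = {
            1: MixtureParams(kappa=8.0),
            2: MixtureParams(kappa=8.0, p_guess=0.3),
            3: MixtureParams(kappa=8.0, p_guess=0.3, p_swap=0.2),
        }[model_id]
        ours = negative_log_likelihood(errors, offsets, params, model_id)
        assert ours == pytest.approx(
            brute_force_nll(errors, offsets, params, model_id), abs=1e-8)

    def test_mixture_density_normalizes(self):
        params = MixtureParams(kappa=8.0, p_guess=0.3, p_swap=0.2)
        offsets = np.array([[70.0, -90.0]])

        def dens(theta):
            return np.exp(-negative_log_likelihood(
                [theta], offsets, params, 3))

        total, _ = integrate.quad(dens, -180, 180, limit=300)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_model3_without_offsets_rejected(self):
        with pytest.raises(ValueError, match="offsets"):
            negative_log_likelihood(
                [0.0], None, MixtureParams(kappa=5.0, p_swap=0.1), 3)

    def test_weight_constraint_rejected(self):
        with pytest.raises(ValueError):
            MixtureParams(kappa=5.0, p_guess=0.7, p_swap=0.5)


class TestMle:
    def test_recovers_generating_parameters(self, model2_errors_20k, e3e3_params):
        fit = fit_mle(model2_errors_20k, model_id=2, rng=0)
        assert fit.params.p_guess == pytest.approx(e3e3_params.p_guess, abs=0.02)
        assert fit.circ_sd_deg == pytest.approx(e3e3_params.circ_sd_deg, abs=0.5)

    def test_pure_target_data_has_no_guessing(self, rng):
        errors = np.degrees(rng.vonmises(0, circ_sd_to_kappa(10.0), 200))
        fit = fit_mle(errors, model_id=2, rng=1)
        assert fit.params.p_guess <= 0.01

    def test_all_zero_errors(self):
        fit = fit_mle(np.zeros(30), model_id=2, rng=1)
        assert fit.params.p_guess <= 0.01

    def test_mle_beats_generating_parameters(self, model2_errors_20k, e3e3_params):
        fit = fit_mle(model2_errors_20k, model_id=2, rng=0)
        nll_gen = negative_log_likelihood(
            model2_errors_20k, None, e3e3_params, 2)
        assert fit.nll <= nll_gen

    def test_nested_fits_weakly_improve(self, rng):
        offsets = rng.uniform(-180, 180, size=(2000, 2))
        params = MixtureParams(kappa=circ_sd_to_kappa(18.0), p_guess=0.2,
                               p_swap=0.15)
        errors = sample_mixture_errors(params, 2000, rng, offsets)
        nlls = [fit_mle(errors, offsets, model_id=m, rng=2, n_starts=8).nll
                for m in (1, 2, 3)]
        assert nlls[0] >= nlls[1] - 1e-6 >= nlls[2] - 2e-6

    def test_too_few_trials_rejected(self):
        with pytest.raises(FitError):
            fit_mle(np.zeros(5), model_id=2)

    def test_ci_contains_point_estimate(self, model2_errors_20k):
        fit = fit_mle(model2_errors_20k, model_id=2, rng=0)
        lo, hi = fit.ci["p_guess"]
        assert lo <= fit.params.p_guess <= hi
        lo, hi = fit.ci["circ_sd_deg"]
        assert lo <= fit.circ_sd_deg <= hi


class TestBayes:
    def test_posterior_mean_matches_mle(self, model2_errors_20k):
        sub = model2_errors_20k[:4000]
        mle = fit_mle(sub, model_id=2, rng=0)
        bay = fit_bayes(sub, model_id=2, config=FAST_MCMC, seed=0)
        assert bay.params.p_guess == pytest.approx(mle.params.p_guess, abs=0.02)
        assert bay.circ_sd_deg == pytest.approx(mle.circ_sd_deg, abs=1.0)
        assert bay.converged
        assert all(r < 1.05 for r in bay.rhat.values())

    def test_all_zero_errors_concentrate_near_zero_guessing(self):
        bay = fit_bayes(np.zeros(30), model_id=2, config=FAST_MCMC, seed=1)
        assert bay.params.p_guess < 0.15
        assert bay.ci["p_guess"][0] < 0.05

    def test_ci_contains_posterior_mean(self, model2_errors_20k):
        bay = fit_bayes(model2_errors_20k[:2000], model_id=2,
                        config=FAST_MCMC, seed=2)
        for name in ("p_guess", "kappa"):
            lo, hi = bay.ci[name]
            val = getattr(bay.params, name)
            assert lo <= val <= hi

    def test_determinism_under_seed(self, model2_errors_20k):
        a = fit_bayes(model2_errors_20k[:1000], model_id=2, config=FAST_MCMC,
                      seed=7)
        b = fit_bayes(model2_errors_20k[:1000], model_id=2, config=FAST_MCMC,
                      seed=7)
        assert a.params.p_guess == b.params.p_guess
        assert a.dic == b.dic


class TestDic:
    def test_effective_parameters_positive(self, model2_errors_20k):
        bay = fit_bayes(model2_errors_20k[:2000], model_id=2,
                        config=FAST_MCMC, seed=3)
        assert bay.p_dic > 0

    def test_dic_function_matches_fit_value(self, model2_errors_20k):
        e = model2_errors_20k[:2000]
        bay = fit_bayes(e, model_id=2, config=FAST_MCMC, seed=3)
        assert dic(bay, e) == pytest.approx(bay.dic, rel=1e-9)

    def test_missing_draws_rejected(self, model2_errors_20k):
        mle = fit_mle(model2_errors_20k[:500], model_id=2, rng=0)
        with pytest.raises(ValueError):
            dic(mle)


class TestModelComparison:
    def test_winner_on_model2_data(self, model2_errors_20k, rng):
        e = model2_errors_20k[:5000]
        offsets = rng.uniform(-180, 180, size=(5000, 2))
        comp = compare_models(e, offsets, config=FAST_MCMC, seed=4)
        assert comp.winner == 2
        assert comp.dic[2] < comp.dic[1]

    def test_winner_invariant_to_sign_flip(self, model2_errors_20k, rng):
        e = model2_errors_20k[:3000]
        offsets = rng.uniform(-180, 180, size=(3000, 2))
        comp_a = compare_models(e, offsets, config=FAST_MCMC, seed=5)
        comp_b = compare_models(-e, -offsets, config=FAST_MCMC, seed=5)
        assert comp_a.winner == comp_b.winner

    def test_partial_table_when_offsets_missing(self, model2_errors_20k):
        comp = compare_models(model2_errors_20k[:1000], None,
                              config=FAST_MCMC, seed=6)
        assert 3 in comp.failures
        assert comp.winner in (1, 2)
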