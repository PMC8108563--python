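import numpy as np
import pandas as pd
import pytest

import locmem as lm
from locmem.circular import circ_sd_to_kappa, vm_density
from locmem.metrics import (
    CutoffError,
    MetricError,
    auxiliary_metrics,
    delay_slope,
    derive_guess_cutoff,
    expected_retrieval_success,
    mean_abs_error,
    nn_distance,
    precision_sd,
    retrieval_success,
    subject_metrics_table,
)
from locmem.mixture import MixtureParams


def grid_scan_cutoff(p_guess, kappa, step=0.01):
    """Oracle: brute-force scan for the uniform/target crossover."""
    grid = np.arange(0.0, 180.0 + step, step)
    target = (1 - p_guess) * vm_density(grid, 0.0, kappa)
    uniform = p_guess / 360.0
    idx = np.argmax(uniform >= target)
    return grid[idx]


class TestCutoff:
    def test_k_sd_rule_arithmetic(self):
        params = MixtureParams(kappa=circ_sd_to_kappa(18.0), p_guess=0.3)
        cut = derive_guess_cutoff(params, rule="k_sd", k=3.5)
        assert cut.cutoff_deg == pytest.approx(63.0, abs=1e-9)
        assert cut.rule == "k_sd"

    def test_responsibility_near_total_guessing(self):
        params = MixtureParams(kappa=circ_sd_to_kappa(18.0), p_guess=0.999)
        cut = derive_guess_cutoff(params, rule="responsibility")
        assert cut.cutoff_deg < 2.0

    def test_responsibility_matches_grid_scan(self):
        kappa = circ_sd_to_kappa(18.35)
        cut = derive_guess_cutoff(
            MixtureParams(kappa=kappa, p_guess=0.30), rule="responsibility")
        assert cut.cutoff_deg == pytest.approx(
            grid_scan_cutoff(0.30, kappa), abs=0.02)

    def test_no_guessing_raises_with_guidance(self):
        with pytest.raises(CutoffError, match="k_sd"):
            derive_guess_cutoff(MixtureParams(kappa=5.0, p_guess=0.0))


class TestRetrievalAndPrecision:
    def test_perfect_errors(self):
        assert retrieval_success(np.zeros(20), 63.0) == 1.0

    def test_uniform_mass_at_cutoff(self, rng):
        errors = rng.uniform(-180, 180, 10_000)
        assert retrieval_success(errors, 63.0) == pytest.approx(
            126 / 360, abs=0.01)

    def test_identical_retained_errors_have_zero_spread(self):
        assert precision_sd(np.full(10, 5.0), 63.0) == 0.0

    def test_uniform_window_closed_form(self, rng):
        errors = rng.uniform(-63, 63, 200_000)
        assert precision_sd(errors, 63.0) == pytest.approx(
            63 / np.sqrt(3), abs=0.2)

    def test_precision_monotone_in_generating_sd(self, rng):
        out = []
        for sd in (10.0, 15.0, 20.0, 25.0, 30.0):
            e = np.degrees(rng.vonmises(0, circ_sd_to_kappa(sd), 20_000))
            out.append(precision_sd(e, 63.0))
        assert np.all(np.diff(out) > 0)

    def test_wide_cutoff_recovers_plain_sd(self, rng):
        e = rng.normal(0, 20, 500).clip(-179, 179)
        assert retrieval_success(e, 180.0) == 1.0
        assert precision_sd(e, 180.0) == pytest.approx(np.std(e, ddof=1))

    def test_too_few_trials_flagged(self):
        with pytest.raises(MetricError):
            retrieval_success([], 63.0)
        with pytest.raises(MetricError):
            precision_sd(np.array([0.0, 100.0]), 63.0)

    def test_analytic_consistency_with_simulation(self, e3e3_params,
                                                  model2_errors_20k):
        simulated = retrieval_success(model2_errors_20k, 63.0)
        analytic = expected_retrieval_success(e3e3_params, 63.0)
        assert simulated == pytest.approx(analytic, abs=0.01)


class TestAuxiliary:
    def _trials(self, response, target, d1, d2, ident=None):
        n = len(response)
        return pd.DataFrame(
            {
                "response_angle_deg": response,
                "target_angle_deg": target,
                "distractor1_angle_deg": d1,
                "distractor2_angle_deg": d2,
                "error_deg": lm.signed_error(np.asarray(response),
                                             np.asarray(target)),
                "identification_correct": ident if ident is not None
                else [True] * n,
            }
        )

    def test_on_target_responses(self):
        t = self._trials([10.0, -50.0], [10.0, -50.0], [100, 40], [-100, 150])
        mae, nn, ident = auxiliary_metrics(t)
        assert mae == 0.0 and nn == 0.0 and ident == 1.0

    def test_swap_geometry(self):
        # responses exactly on a distractor: nn 0, error >= separation
        t = self._trials([100.0, 150.0], [10.0, -50.0], [100, 40], [-100, 150])
        mae, nn, ident = auxiliary_metrics(t)
        assert nn == 0.0
        assert mae >= 62.04

    def test_more_swapping_shrinks_nn_distance_among_errors(self, rng):
        # among error trials (|error| > cutoff) swaps sit on a distractor,
        # guesses do not, so more swapping pulls the mean NN distance down
        cfg = lm.TaskConfig(n_blocks=34, displays_per_block=10)  # ~1k trials
        sched = lm.generate_task_structure(cfg, rng)
        nns = []
        for p_swap in (0.0, 0.2, 0.4):
            sub = lm.SubjectParams(p_guess=0.3, p_swap=p_swap, circ_sd_deg=15.0)
            trials = lm.simulate_responses(sched, sub, rng)
            _, nn, _ = auxiliary_metrics(trials, cutoff_deg=63.0,
                                         errors_only=True)
            nns.append(nn)
        assert nns[0] > nns[1] > nns[2]

    def test_rotation_invariance(self, rng):
        resp = rng.uniform(-180, 180, 50)
        targ = rng.uniform(-180, 180, 50)
        d1 = rng.uniform(-180, 180, 50)
        d2 = rng.uniform(-180, 180, 50)
        shift = 73.0
        a = auxiliary_metrics(self._trials(resp, targ, d1, d2))
        b = auxiliary_metrics(
            self._trials(*(lm.wrap_angle(x + shift) for x in (resp, targ, d1, d2))))
        assert a[0] == pytest.approx(b[0], abs=1e-9)
        assert a[1] == pytest.approx(b[1], abs=1e-9)

    def test_zero_trials_flagged(self):
        t = self._trials([0.0], [0.0], [90.0], [-90.0], ident=[False])
        with pytest.raises(MetricError):
            auxiliary_metrics(t)


class TestDelaySlope:
    def test_monotone_forgetting_gives_plus_one(self):
        delays = np.arange(10)
        errors = np.linspace(1, 40, 10)
        assert delay_slope(errors, delays) == pytest.approx(1.0)

    def test_reversing_delay_flips_sign(self, rng):
        delays = np.arange(20)
        errors = rng.uniform(0, 90, 20)
        fwd = delay_slope(errors, delays)
        rev = delay_slope(errors, delays[::-1])
        assert rev == pytest.approx(-fwd)

    def test_null_slope_distribution_centred_on_zero(self, rng):
        slopes = []
        for _ in range(100):
            errors = rng.uniform(0, 90, 75)
            slopes.append(delay_slope(errors, np.tile(np.arange(15), 5)))
        assert abs(np.mean(slopes)) < 0.04

    def test_degenerate_inputs_flagged(self):
        with pytest.raises(MetricError):
            delay_slope(np.arange(10.0), np.zeros(10))
        with pytest.raises(MetricError):
            delay_slope(np.zeros(10), np.arange(10))


class TestSubjectTable:
    def test_table_covers_all_subjects(self, small_cohort):
        subjects, trials = small_cohort
        table = subject_metrics_table(trials, 63.0, subjects)
        assert len(table) == len(subjects)
        assert {"retrieval_success", "precision_sd_deg", "age", "sex"} <= set(
            table.columns)
        assert (table["n_trials_used"] <= 75).all()

    def test_reference_cohort_reproduces_group_means(self, default_cohort):
        # subject-level means should land near the generating group profile
        subjects, trials = default_cohort
        table = subject_metrics_table(trials, 63.0, subjects)
        by_group = table.groupby("group")
        means = by_group["retrieval_success"].mean()
        assert means["e3e3"] == pytest.approx(0.80, abs=0.06)
        assert by_group["identification_accuracy"].mean()["e3e3"] == \
            pytest.approx(0.83, abs=0.05)
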