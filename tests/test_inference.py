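import numpy as np
import pandas as pd
import pytest

import locmem as lm
from locmem.inference import (
    correlation_with_bf,
    glm_effect,
    permutation_parameter_test,
    power_simulation,
)


def _errors_by_subject(subjects, trials):
    eligible = trials[trials["identification_correct"].astype(bool)]
    return [
        eligible.loc[eligible["subject_id"] == s, "error_deg"].to_numpy()
        for s in subjects["subject_id"]
    ]


class TestPermutation:
    def test_identical_pooled_data_gives_null_z(self, rng):
        # both groups literally share the same error sample
        errors = np.degrees(rng.vonmises(0, 10, 100))
        by_subj = [errors.copy() for _ in range(12)]
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = permutation_parameter_test(by_subj, labels, "p_guess",
                                         n_perm=100, rng=1)
        assert res.observed_diff == pytest.approx(0.0, abs=1e-6)
        assert abs(res.z) <= 0.1
        assert res.p > 0.9

    def test_group_sizes_preserved(self, small_cohort):
        subjects, trials = small_cohort
        by_subj = _errors_by_subject(subjects, trials)
        res = permutation_parameter_test(
            by_subj, subjects["group"].to_numpy(),
            parameter=("p_guess", "circ_sd_deg"), n_perm=100, rng=0,
            group_order=("e3e3", "e3e4"))
        for p, comp in res.items():
            assert comp.group_order == ("e3e3", "e3e4")
            assert comp.n_permutations == 100
            assert 0 < comp.p <= 1

    def test_detects_large_guessing_difference(self, rng):
        kappa = 10.0
        group_a = [np.degrees(rng.vonmises(0, kappa, 75)) for _ in range(10)]
        group_b = [rng.uniform(-180, 180, 75) for _ in range(10)]
        res = permutation_parameter_test(
            group_a + group_b, np.array(["a"] * 10 + ["b"] * 10),
            "p_guess", n_perm=200, rng=2, group_order=("a", "b"))
        assert res.observed_diff < -0.5
        assert res.p < 0.05

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_parameter_test([np.zeros(10)] * 4,
                                       np.array(["a", "a", "b", "b"]),
                                       n_perm=10)


class TestGlm:
    def _table(self, rng, n=46, effect=0.0):
        group = np.array(["g1"] * 26 + ["g2"] * (n - 26))
        age = rng.normal(64, 6, n)
        sex = rng.choice(["F", "M"], n)
        y = rng.normal(0.8, 0.1, n) + effect * (group == "g2")
        return pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(n)], "group": group,
             "age": age, "sex": sex, "dv": y})

    def test_f2_identity_from_r2_change(self):
        # R2_cov = 0.2, R2_full = 0.4  ->  f2 = 0.2/0.6
        assert (0.4 - 0.2) / (1 - 0.4) == pytest.approx(1 / 3)

    def test_matches_textbook_two_model_anova(self, rng):
        table = self._table(rng, effect=0.08)
        rep = glm_effect(table, "dv")
        # oracle: explicit OLS via lstsq and the classical F formula
        y = table["dv"].to_numpy()
        sex = (table["sex"] == "M").astype(float).to_numpy()
        g = (table["group"] == "g2").astype(float).to_numpy()
        age = table["age"].to_numpy()
        X0 = np.column_stack([np.ones(len(y)), age - age.mean(), sex])
        X1 = np.column_stack([X0, g])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        rss0, rss1 = rss(X0), rss(X1)
        F = (rss0 - rss1) / 1 / (rss1 / (len(y) - X1.shape[1]))
        assert rep.F == pytest.approx(F, abs=1e-10)
        tss = float(((y - y.mean()) ** 2).sum())
        r2_0, r2_1 = 1 - rss0 / tss, 1 - rss1 / tss
        assert rep.f2 == pytest.approx((r2_1 - r2_0) / (1 - r2_1), abs=1e-10)

    def test_bf_reciprocal_identity(self, rng):
        for method in ("bic", "jzs"):
            rep = glm_effect(self._table(rng), "dv", bf_method=method)
            assert rep.bf10 * rep.bf01 == pytest.approx(1.0, rel=1e-12)
            assert rep.bf10 > 0

    def test_constant_factor_rejected(self, rng):
        table = self._table(rng)
        table["group"] = "g1"
        with pytest.raises(ValueError, match="2 levels"):
            glm_effect(table, "dv")

    def test_collinear_covariate_rejected(self, rng):
        table = self._table(rng)
        table["dup"] = (table["group"] == "g2").astype(float)
        with pytest.raises(ValueError, match="rank-deficient"):
            glm_effect(table, "dv", covariates=("age", "sex", "dup"))

    def test_jzs_detects_strong_effect(self, rng):
        rep = glm_effect(self._table(rng, effect=0.3), "dv", bf_method="jzs")
        assert rep.bf10 > 3


class TestCorrelation:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=20)
        rep = correlation_with_bf(x, x)
        assert rep.r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = correlation_with_bf(x, y)
        b = correlation_with_bf(3.0 * x - 7.0, 0.5 * y + 2.0)
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.bf10 == pytest.approx(b.bf10, rel=1e-9)

    def test_bf_matches_independent_jzs_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y = rng.normal(size=33), rng.normal(size=33)
        rep = correlation_with_bf(x, y)
        expected = float(pingouin.bayesfactor_pearson(rep.r, rep.n,
                                                      method="wetzels"))
        assert rep.bf10 == pytest.approx(expected, rel=1e-3)

    def test_null_correlations_stay_small(self, rng):
        # mirrors reporting r over many independent samples of n=33
        rs = [correlation_with_bf(rng.normal(size=33),
                                  rng.normal(size=33)).r for _ in range(200)]
        assert abs(np.mean(rs)) < 0.05
        assert np.mean(np.abs(np.array(rs)) >= 0.25) < 0.5

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_with_bf(np.ones(10), rng.normal(size=10))


class TestPowerSimulation:
    def test_effect_monotonicity_without_permutation(self, rng):
        import dataclasses

        spec = lm.null_cohort_spec(5)
        g1 = dataclasses.replace(spec.groups[0], n=13)
        g2 = dataclasses.replace(spec.groups[1], n=10)
        spec = dataclasses.replace(spec, groups=(g1, g2))
        table = power_simulation(
            spec, [{}, {"p_guess": 0.35}], n_sims=50, rng=rng,
            run_permutation=False)
        null_row = table.iloc[0]
        big_row = table.iloc[1]
        assert big_row["glm_reject_rate"] >= null_row["glm_reject_rate"]
        assert null_row["glm_reject_rate"] <= 0.2
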