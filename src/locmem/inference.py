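"""Group-level statistics: permutation tests on group mixture parameters,
GLMs with covariates (F, Cohen's f-squared, Bayes factors) and Pearson
correlations with Bayesian evidence.

The permutation test operates on group-level Model-2 fits: errors are pooled
within each group, the model refitted, and the observed parameter difference
compared against the distribution obtained by randomly reassigning whole
subjects (never single trials, which would break within-subject dependence)
to pseudo-groups of the original sizes.

The GLM compares a covariates-only linear model against the full model with
the group factor added; the F statistic, Cohen's
``f2 = (R2_full - R2_cov) / (1 - R2_full)`` and a Bayes factor for the nested
comparison are reported.  The default BF uses the BIC approximation
``BF01 = exp((BIC_full - BIC_cov) / 2)``; a JZS-style numerical-integration
option is available.  Two-sided tests throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, stats

from .mixture import FitError, fit_mle, _pack
from . import metrics as _metrics
from . import taskgen as _taskgen

__all__ = [
    "GroupComparison",
    "EffectReport",
    "CorrelationReport",
    "permutation_parameter_test",
    "glm_effect",
    "correlation_with_bf",
    "power_simulation",
]

PERM_PARAMETERS = ("p_guess", "circ_sd_deg")


@dataclass(frozen=True)
class GroupComparison:
    """Permutation-test result for one group-level model parameter."""

    parameter: str
    group_order: tuple
    observed_diff: float
    z: float
    p: float
    n_permutations: int
    n_redrawn: int
    seed: object = None

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "group_order": list(self.group_order),
            "observed_diff": self.observed_diff,
            "z": self.z,
            "p": self.p,
            "n_permutations": self.n_permutations,
            "n_redrawn": self.n_redrawn,
        }


@dataclass(frozen=True)
class EffectReport:
    """Nested-GLM comparison: covariates-only versus covariates + factor."""

    dv: str
    factor: str
    covariates: tuple
    F: float
    df1: int
    df2: int
    p: float
    f2: float
    bf10: float
    bf01: float
    bf_method: str
    n: int

    def to_dict(self) -> dict:
        return {
            "dv": self.dv,
            "factor": self.factor,
            "covariates": list(self.covariates),
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "f2": self.f2,
            "bf10": self.bf10,
            "bf01": self.bf01,
            "bf_method": self.bf_method,
            "n": self.n,
        }


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation with a Jeffreys-prior Bayes factor."""

    r: float
    p: float
    bf10: float
    n: int
    prior: str = "JZS (Wetzels-style numerical integration over g)"

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "bf10": self.bf10, "n": self.n,
                "prior": self.prior}


# ---------------------------------------------------------------------------
# permutation test on group-level mixture parameters
# ---------------------------------------------------------------------------

def _group_param_fit(cos_concat, params_of_interest, x0, rng):
    """Fit Model 2 from precomputed error cosines; return requested params."""
    from .mixture import _Objective, _unpack, MODELS  # noqa: F401

    obj = _Objective.__new__(_Objective)
    obj.n = cos_concat.size
    obj.cos_err = cos_concat
    obj.cos_off = None
    # one warm start at the pooled solution plus one random restart
    from scipy import optimize

    from .mixture import MLE_KAPPA_BOUNDS, _random_start

    bounds = [(-16.0, 16.0), (np.log(MLE_KAPPA_BOUNDS[0]), np.log(MLE_KAPPA_BOUNDS[1]))]

    def fun(x):
        pg, ps, k = _unpack(x, 2)
        return obj.nll(pg, ps, k, 2)

    best = None
    for s in (x0, _random_start(rng, 2)):
        res = optimize.minimize(fun, s, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("permutation refit failed")
    pg, _, kappa = _unpack(best.x, 2)
    out = {}
    if "p_guess" in params_of_interest:
        out["p_guess"] = pg
    if "circ_sd_deg" in params_of_interest:
        from .circular import kappa_to_circ_sd

        out["circ_sd_deg"] = kappa_to_circ_sd(kappa)
    return out


def permutation_parameter_test(
    errors_by_subject,
    group_labels,
    parameter="p_guess",
    n_perm: int = 1000,
    rng=None,
    group_order=None,
    max_failure_frac: float = 0.05,
):
    """Permutation test on group-level Model-2 parameters.

    Parameters
    ----------
    errors_by_subject:
        Sequence of 1-D arrays, one per subject, of wrapped signed errors
        (identification-correct trials).
    group_labels:
        Group label per subject (exactly two groups).
    parameter:
        ``"p_guess"``, ``"circ_sd_deg"``, or a sequence of both; both share
        one set of permutation refits.
    group_order:
        Pair fixing the sign convention of the difference (first minus
        second); defaults to the sorted label order.

    The observed difference is standardized against the permutation
    distribution, ``z = (d_obs - mean d_perm) / sd d_perm``, and the
    two-sided p-value uses the add-one estimator
    ``p = (1 + #{|z_perm| >= |z_obs|}) / (n_perm + 1)``.  A permutation whose
    refit fails is redrawn; more than ``max_failure_frac`` failures aborts.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    single = isinstance(parameter, str)
    params = (parameter,) if single else tuple(parameter)
    for p in params:
        if p not in PERM_PARAMETERS:
            raise ValueError(f"unknown parameter {p!r}; choose from {PERM_PARAMETERS}")

    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist())) if group_order is None else list(group_order)
    if len(groups) != 2 or set(labels.tolist()) != set(groups):
        raise ValueError("exactly two groups required")
    subj_cos = [np.cos(np.radians(np.asarray(e, dtype=float)))
                for e in errors_by_subject]
    if len(subj_cos) != labels.size:
        raise ValueError("errors_by_subject and group_labels must align")
    if any(c.size == 0 for c in subj_cos):
        raise ValueError("every subject needs at least one trial")
    n_a = int(np.sum(labels == groups[0]))

    # warm-start location: Model-2 fit pooled over everyone
    all_errors = np.concatenate([np.asarray(e, float) for e in errors_by_subject])
    pooled = fit_mle(all_errors, model_id=2, n_starts=10, rng=rng)
    x0 = _pack(pooled.params.p_guess, 0.0, pooled.params.kappa, 2)

    def stat(index_a, index_b):
        cos_a = np.concatenate([subj_cos[i] for i in index_a])
        cos_b = np.concatenate([subj_cos[i] for i in index_b])
        fa = _group_param_fit(cos_a, params, x0, rng)
        fb = _group_param_fit(cos_b, params, x0, rng)
        return {p: fa[p] - fb[p] for p in params}

    idx_a = np.flatnonzero(labels == groups[0])
    idx_b = np.flatnonzero(labels == groups[1])
    observed = stat(idx_a, idx_b)

    n_subj = labels.size
    perm_stats = {p: np.empty(n_perm) for p in params}
    failures = 0
    max_failures = max(1, int(np.ceil(max_failure_frac * n_perm)))
    done = 0
    while done < n_perm:
        order = rng.permutation(n_subj)
        try:
            d = stat(order[:n_a], order[n_a:])
        except FitError:
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"more than {max_failure_frac:.0%} of permutation refits failed")
            continue
        for p in params:
            perm_stats[p][done] = d[p]
        done += 1

    results = {}
    for p in params:
        perm = perm_stats[p]
        mu, sd = float(perm.mean()), float(perm.std(ddof=1))
        if sd > 0:
            z_obs = (observed[p] - mu) / sd
            z_perm = (perm - mu) / sd
            pval = (1.0 + np.sum(np.abs(z_perm) >= np.abs(z_obs))) / (n_perm + 1.0)
        elif np.isclose(observed[p], mu):
            # degenerate permutation distribution, observed at its centre
            z_obs, pval = 0.0, 1.0
        else:
            z_obs, pval = float("nan"), 1.0
        results[p] = GroupComparison(
            parameter=p,
            group_order=tuple(groups),
            observed_diff=float(observed[p]),
            z=float(z_obs),
            p=float(pval),
            n_permutations=n_perm,
            n_redrawn=failures,
        )
    return results[parameter] if single else results


# ---------------------------------------------------------------------------
# GLM with covariates + effect size + Bayes factor
# ---------------------------------------------------------------------------

def _jzs_g_integral(n: int, r2: float, a: float) -> float:
    """Integrate the JZS g-prior marginal ratio
    ``int pi(g) (1+g)^a (1+g(1-r2))^(-(n-1)/2) dg`` with
    ``pi(g) = sqrt(n/2)/Gamma(1/2) g^(-3/2) exp(-n/(2g))``.

    The substitution ``g = s/(1-s)`` maps the integral onto (0, 1), where the
    integrand is bounded and quadrature is stable.
    """
    gamma_half = np.sqrt(np.pi)
    b = -(n - 1) / 2.0

    def f(s):
        g = s / (1.0 - s)
        prior = np.sqrt(n / 2.0) / gamma_half * g ** (-1.5) * np.exp(-n / (2.0 * g))
        like = (1.0 + g) ** a * (1.0 + g * (1.0 - r2)) ** b
        return prior * like / (1.0 - s) ** 2

    val, _ = integrate.quad(f, 0.0, 1.0, limit=200)
    return float(val)


def _jzs_regression_bf10(r2: float, n: int, n_pred: int) -> float:
    """JZS Bayes factor of a linear model with ``n_pred`` predictors against
    the intercept-only model, by numerical integration over the g-prior
    (Liang et al. mixture of g-priors with the default scale)."""
    if n_pred == 0:
        return 1.0
    return _jzs_g_integral(n, r2, (n - n_pred - 1) / 2.0)


def _code_design(table: pd.DataFrame, columns) -> np.ndarray:
    cols = []
    for c in columns:
        v = table[c]
        if v.dtype == object or str(v.dtype) == "category" or v.dtype == bool:
            levels = sorted(pd.unique(v.astype(str)))
            if len(levels) != 2:
                raise ValueError(
                    f"covariate {c!r} must be numeric or binary, has levels {levels}")
            cols.append((v.astype(str) == levels[1]).astype(float).to_numpy())
        else:
            x = v.astype(float).to_numpy()
            cols.append(x - x.mean())  # centring aids conditioning only
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def glm_effect(
    subjects_table: pd.DataFrame,
    dependent_variable: str,
    covariates=("age", "sex"),
    factor: str = "group",
    bf_method: str = "bic",
) -> EffectReport:
    """Test a two-level factor in an OLS model with covariates.

    Fits ``dv ~ covariates`` and ``dv ~ covariates + factor``; reports the
    nested-model F test, Cohen's f-squared for the R-squared change, and the
    Bayes factor for the comparison (``bf_method`` = ``"bic"`` or ``"jzs"``).
    Rows with a missing dependent variable are dropped.
    """
    table = subjects_table.dropna(subset=[dependent_variable]).reset_index(drop=True)
    n = len(table)
    levels = sorted(pd.unique(table[factor].astype(str)))
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly 2 levels, "
                         f"found {levels}")
    y = table[dependent_variable].astype(float).to_numpy()
    x_cov = _code_design(table, covariates)
    x_factor = (table[factor].astype(str) == levels[1]).astype(float).to_numpy()

    design_cov = sm.add_constant(x_cov, has_constant="add")
    design_full = np.column_stack([design_cov, x_factor])
    if n <= design_full.shape[1] + 2:
        raise ValueError(f"n = {n} too small for {design_full.shape[1]} model terms")
    if np.linalg.matrix_rank(design_full) < design_full.shape[1]:
        raise ValueError(
            "rank-deficient design: the factor or a covariate is collinear "
            "(is the factor constant?)")

    fit_cov = sm.OLS(y, design_cov).fit()
    fit_full = sm.OLS(y, design_full).fit()
    r2_cov, r2_full = fit_cov.rsquared, fit_full.rsquared
    df1 = 1
    df2 = int(n - design_full.shape[1])
    F = (r2_full - r2_cov) / df1 / ((1.0 - r2_full) / df2)
    p = float(stats.f.sf(F, df1, df2))
    f2 = (r2_full - r2_cov) / (1.0 - r2_full)

    if bf_method == "bic":
        bf01 = float(np.exp((fit_full.bic - fit_cov.bic) / 2.0))
        bf10 = 1.0 / bf01
    elif bf_method == "jzs":
        bf_full = _jzs_regression_bf10(r2_full, n, design_full.shape[1] - 1)
        bf_cov = _jzs_regression_bf10(r2_cov, n, design_cov.shape[1] - 1)
        bf10 = bf_full / bf_cov
        bf01 = 1.0 / bf10
    else:
        raise ValueError("bf_method must be 'bic' or 'jzs'")

    return EffectReport(
        dv=dependent_variable,
        factor=factor,
        covariates=tuple(covariates),
        F=float(F),
        df1=df1,
        df2=df2,
        p=p,
        f2=float(f2),
        bf10=bf10,
        bf01=bf01,
        bf_method=bf_method,
        n=n,
    )


# ---------------------------------------------------------------------------
# correlation with Bayes factor
# ---------------------------------------------------------------------------

def correlation_with_bf(x, y) -> CorrelationReport:
    """Pearson correlation with a two-sided p and a JZS-style Bayes factor.

    BF10 is computed by numerical integration of the Jeffreys-prior marginal
    likelihood ratio for the correlation coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 5:
        raise ValueError(f"need >= 5 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    r, p = stats.pearsonr(x, y)
    if 1.0 - r * r < 1e-12:  # perfect correlation: the integral diverges
        bf10 = np.inf
    else:
        bf10 = _jzs_g_integral(n, r * r, (n - 2) / 2.0)
    return CorrelationReport(r=float(r), p=float(p), bf10=float(bf10), n=n)


# ---------------------------------------------------------------------------
# power / calibration simulation
# ---------------------------------------------------------------------------

def power_simulation(
    cohort_spec,
    effect_grid,
    n_sims: int = 100,
    rng=None,
    n_perm: int = 200,
    alpha: float = 0.05,
    dv: str = "retrieval_success",
    cutoff_deg: float = 63.0,
    run_permutation: bool = True,
) -> pd.DataFrame:
    """Monte-Carlo power / calibration table over a grid of group effects.

    Each effect entry is a dict of additive shifts applied to the second
    group's generating means, e.g. ``{"p_guess": 0.1}`` or
    ``{"circ_sd_deg": 5.0}``; an empty dict is the null (type-I) row.  For
    every simulated cohort the permutation test on the shifted parameter(s)
    (or ``p_guess`` under the null) and the covariate-adjusted GLM on ``dv``
    are run, and rejection / evidence rates tabulated.
    """
    if n_sims < 50:
        raise ValueError("n_sims must be >= 50")
    rng = np.random.default_rng(rng)
    from dataclasses import replace

    rows = []
    for effect in effect_grid:
        perm_params = tuple(effect.keys() & set(PERM_PARAMETERS)) or ("p_guess",)
        perm_reject = {p: 0 for p in perm_params}
        glm_reject = 0
        bf10_gt3 = 0
        bf01_gt3 = 0
        for _ in range(n_sims):
            g1, g2 = cohort_spec.groups[0], cohort_spec.groups[1]
            shifted = g2
            for pname, delta in effect.items():
                mean, sd = getattr(g2, pname)
                shifted = replace(shifted, **{pname: (mean + delta, sd)})
            seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(cohort_spec, groups=(g1, shifted), master_seed=seed)
            subjects, trials = _taskgen.generate_cohort(spec)

            if run_permutation:
                eligible = trials[trials["identification_correct"].astype(bool)]
                by_subj = [
                    eligible.loc[eligible["subject_id"] == s, "error_deg"].to_numpy()
                    for s in subjects["subject_id"]
                ]
                res = permutation_parameter_test(
                    by_subj,
                    subjects["group"].to_numpy(),
                    parameter=perm_params,
                    n_perm=n_perm,
                    rng=rng,
                    group_order=(g1.name, g2.name),
                )
                for p in perm_params:
                    if res[p].p < alpha:
                        perm_reject[p] += 1

            table = _metrics.subject_metrics_table(trials, cutoff_deg, subjects)
            report = glm_effect(table, dv)
            if report.p < alpha:
                glm_reject += 1
            if report.bf10 > 3:
                bf10_gt3 += 1
            if report.bf01 > 3:
                bf01_gt3 += 1
        row = {"effect": repr(effect) if effect else "null"}
        for p in perm_params:
            row[f"perm_reject_rate_{p}"] = perm_reject[p] / n_sims
        row.update(
            glm_reject_rate=glm_reject / n_sims,
            bf10_gt3_rate=bf10_gt3 / n_sims,
            bf01_gt3_rate=bf01_gt3 / n_sims,
            n_sims=n_sims,
        )
        rows.append(row)
    return pd.DataFrame(rows)
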