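"""Model-informed single-subject memory metrics.

The group-level Model-2 fit supplies a guessing cutoff: an error magnitude
beyond which a localization is classified as a retrieval failure.  Two rules
are implemented:

* ``"responsibility"`` (default) — the smallest error magnitude at which the
  uniform component becomes the more probable source of a response, i.e.
  the crossover ``pU/360 >= pT * vm(e; 0, kappa)``.
* ``"k_sd"`` — a fixed multiple of the fitted circular SD (default 3.5,
  which for an 18-degree SD gives the conventional 63-degree cutoff).

Subject-level measures derived with that cutoff:

* retrieval success — proportion of eligible trials with ``|error| <= cutoff``;
* precision (imprecision) — the linear sample SD of signed errors restricted
  to the cutoff window, in degrees (lower = more precise);
* mean absolute error, nearest-neighbour distance (misbinding index),
  identification accuracy, and the per-subject correlation between absolute
  error and study-test delay (forgetting slope).

Eligible trials are those with a correct 2AFC identification, since
localization is only probed after a correct identification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import i0e

from .circular import vm_mass, wrap_angle
from .mixture import MixtureFit, MixtureParams

__all__ = [
    "GuessCutoff",
    "SubjectMetrics",
    "CutoffError",
    "MetricError",
    "derive_guess_cutoff",
    "retrieval_success",
    "precision_sd",
    "mean_abs_error",
    "nn_distance",
    "identification_accuracy",
    "auxiliary_metrics",
    "delay_slope",
    "expected_retrieval_success",
    "subject_metrics_table",
]

DEFAULT_K_SD = 3.5


class CutoffError(RuntimeError):
    """No guessing cutoff exists under the requested rule."""


class MetricError(ValueError):
    """A metric is undefined for the given trials (too few / degenerate)."""


@dataclass(frozen=True)
class GuessCutoff:
    """A guessing cutoff in degrees, with provenance of the rule that set it."""

    cutoff_deg: float
    rule: str
    p_guess: float
    circ_sd_deg: float
    k: float | None = None


@dataclass(frozen=True)
class SubjectMetrics:
    """Per-subject summary measures (NaN where undefined)."""

    subject_id: str
    retrieval_success: float
    precision_sd_deg: float
    mean_abs_error_deg: float
    nn_distance_deg: float
    identification_accuracy: float
    delay_slope: float
    n_trials_used: int


def _fit_params(fit) -> MixtureParams:
    if isinstance(fit, MixtureFit):
        return fit.params
    if isinstance(fit, MixtureParams):
        return fit
    raise TypeError("expected a MixtureFit or MixtureParams")


def derive_guess_cutoff(group_fit, rule: str = "responsibility",
                        k: float = DEFAULT_K_SD) -> GuessCutoff:
    """Derive the guessing cutoff from a group-level Model-2 fit.

    Under ``"responsibility"``, solve
    ``pT * exp(kappa*cos(e)) / I0(kappa) = pU`` for the smallest ``|e|``;
    above that magnitude a response is more probably a guess than a
    retrieved location.  Raises :class:`CutoffError` when ``pU = 0`` (no
    crossover exists; use ``"k_sd"``) or when the guess component never
    overtakes the target component within 180 degrees.
    """
    params = _fit_params(group_fit)
    sd = params.circ_sd_deg
    if rule == "k_sd":
        if k <= 0:
            raise ValueError("k must be > 0")
        return GuessCutoff(cutoff_deg=float(k * sd), rule=rule,
                           p_guess=params.p_guess, circ_sd_deg=sd, k=k)
    if rule != "responsibility":
        raise ValueError(f"unknown cutoff rule {rule!r}")
    p_u, p_t, kappa = params.p_guess, params.p_target, params.kappa
    if p_u <= 0:
        raise CutoffError(
            "p_guess = 0: the uniform component never dominates; "
            "use rule='k_sd' instead")
    # crossover condition: cos(e) = [log(pU) - log(pT) + log I0(kappa)] / kappa
    if p_t <= 0:
        return GuessCutoff(0.0, rule, p_u, sd)
    log_i0 = float(np.log(i0e(kappa)) + kappa)
    c = (np.log(p_u) - np.log(p_t) + log_i0) / kappa
    if c >= 1.0:
        cutoff = 0.0  # guessing dominates even at zero error
    elif c <= -1.0:
        raise CutoffError(
            "guess component never overtakes the target component within "
            "180 degrees; use rule='k_sd'")
    else:
        cutoff = float(np.degrees(np.arccos(c)))
    return GuessCutoff(cutoff_deg=cutoff, rule=rule, p_guess=p_u,
                       circ_sd_deg=sd)


def _as_errors(errors_deg) -> np.ndarray:
    e = np.asarray(errors_deg, dtype=float)
    if e.ndim != 1:
        raise ValueError("errors must be 1-D")
    if not np.all(np.isfinite(e)):
        raise ValueError("errors must be finite")
    return e


def retrieval_success(errors_deg, cutoff_deg: float) -> float:
    """Proportion of trials with ``|error| <= cutoff``."""
    e = _as_errors(errors_deg)
    if e.size == 0:
        raise MetricError("retrieval success undefined for zero trials")
    return float(np.mean(np.abs(e) <= cutoff_deg))


def precision_sd(errors_deg, cutoff_deg: float) -> float:
    """Sample SD (degrees) of signed errors within the cutoff window.

    Uses the ordinary linear SD: with the errors truncated well inside the
    circle, wrapping is immaterial.  Requires >= 3 retained trials.
    """
    e = _as_errors(errors_deg)
    retained = e[np.abs(e) <= cutoff_deg]
    if retained.size < 3:
        raise MetricError(
            f"precision undefined: only {retained.size} trials within cutoff")
    return float(np.std(retained, ddof=1))


def mean_abs_error(errors_deg) -> float:
    e = _as_errors(errors_deg)
    if e.size == 0:
        raise MetricError("mean absolute error undefined for zero trials")
    return float(np.mean(np.abs(e)))


def nn_distance(response_deg, object_angles_deg) -> float:
    """Mean distance from each response to the nearest object of its display.

    ``object_angles_deg`` is (n_trials, n_objects) including the target; a
    small value among error trials is the signature of misbinding.
    """
    resp = np.asarray(response_deg, dtype=float)
    objs = np.asarray(object_angles_deg, dtype=float)
    if resp.size == 0:
        raise MetricError("nearest-neighbour distance undefined for zero trials")
    if objs.ndim != 2 or objs.shape[0] != resp.size:
        raise ValueError("object angles must be (n_trials, n_objects)")
    d = np.abs(wrap_angle(resp[:, None] - objs))
    return float(d.min(axis=1).mean())


def identification_accuracy(correct_flags) -> float:
    f = np.asarray(correct_flags, dtype=bool)
    if f.size == 0:
        raise MetricError("identification accuracy undefined for zero trials")
    return float(f.mean())


def auxiliary_metrics(trials: pd.DataFrame, cutoff_deg: float | None = None,
                      errors_only: bool = False):
    """Mean absolute error, nearest-neighbour distance and identification
    accuracy for one subject's trial table.

    Identification accuracy is computed over all trials; the angular metrics
    over identification-correct trials.  With ``errors_only=True`` the
    nearest-neighbour distance is restricted to trials beyond the cutoff
    (the misbinding control analysis); this requires ``cutoff_deg``.
    """
    ident = identification_accuracy(trials["identification_correct"])
    eligible = trials[trials["identification_correct"].astype(bool)]
    if len(eligible) == 0:
        raise MetricError("no identification-correct trials")
    mae = mean_abs_error(eligible["error_deg"])
    nn_trials = eligible
    if errors_only:
        if cutoff_deg is None:
            raise ValueError("errors_only=True requires cutoff_deg")
        nn_trials = eligible[np.abs(eligible["error_deg"]) > cutoff_deg]
    obj_cols = ["target_angle_deg"] + sorted(
        c for c in trials.columns if c.startswith("distractor"))
    if len(nn_trials) == 0:
        nn = float("nan")
    else:
        nn = nn_distance(nn_trials["response_angle_deg"], nn_trials[obj_cols])
    return mae, nn, ident


def delay_slope(abs_errors_deg, delay_index) -> float:
    """Pearson correlation between absolute error and study-test delay.

    A positive value means performance degrades with longer delay.  Requires
    >= 5 trials with >= 2 distinct delays and non-constant errors.
    """
    e = np.abs(np.asarray(abs_errors_deg, dtype=float))
    d = np.asarray(delay_index, dtype=float)
    if e.size != d.size:
        raise ValueError("errors and delays must align")
    if e.size < 5:
        raise MetricError("delay slope undefined: fewer than 5 trials")
    if np.unique(d).size < 2:
        raise MetricError("delay slope undefined: constant delay")
    if np.ptp(e) == 0:
        raise MetricError("delay slope undefined: constant error")
    r, _ = stats.pearsonr(e, d)
    return float(r)


def expected_retrieval_success(params, cutoff_deg: float) -> float:
    """Analytic expected retrieval success under Model 2.

    ``pT * P(|vm| <= cutoff) + pU * 2*cutoff/360`` — the quadrature
    counterpart of the simulated proportion.
    """
    p = _fit_params(params)
    if p.p_swap != 0:
        raise ValueError("analytic form implemented for Model 2 (p_swap = 0)")
    return float(
        p.p_target * vm_mass(cutoff_deg, p.kappa)
        + p.p_guess * 2.0 * min(cutoff_deg, 180.0) / 360.0
    )


def _safe(fun, *args, **kwargs):
    try:
        return fun(*args, **kwargs)
    except MetricError:
        return float("nan")


def subject_metrics_table(trials: pd.DataFrame, cutoff: GuessCutoff | float,
                          subjects: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subject metrics table, one row per subject.

    Metrics that are undefined for a subject (e.g. too few within-cutoff
    trials) are NaN rather than an error.  When a subjects table is given its
    covariate columns are merged in.
    """
    cutoff_deg = cutoff.cutoff_deg if isinstance(cutoff, GuessCutoff) else float(cutoff)
    rows = []
    for subject_id, sub in trials.groupby("subject_id", sort=True):
        eligible = sub[sub["identification_correct"].astype(bool)]
        errors = eligible["error_deg"].to_numpy()
        mae, nn, ident = (float("nan"),) * 3
        try:
            mae, nn, ident = auxiliary_metrics(sub)
        except MetricError:
            pass
        rows.append(
            {
                "subject_id": subject_id,
                "group": sub["group"].iloc[0] if "group" in sub else None,
                "retrieval_success": _safe(retrieval_success, errors, cutoff_deg),
                "precision_sd_deg": _safe(precision_sd, errors, cutoff_deg),
                "mean_abs_error_deg": mae,
                "nn_distance_deg": nn,
                "identification_accuracy": ident,
                "delay_slope": _safe(
                    delay_slope, errors, eligible["delay_index"].to_numpy())
                if "delay_index" in sub
                else float("nan"),
                "n_trials_used": int(len(eligible)),
            }
        )
    table = pd.DataFrame(rows)
    if subjects is not None:
        covars = subjects.drop(
            columns=[c for c in subjects.columns
                     if c.startswith("true_") or c == "group"],
            errors="ignore",
        )
        table = table.merge(covars, on="subject_id", how="left")
    return table
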