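"""End-to-end analysis pipeline.

One call runs the full analysis a study of this kind reports: (optional)
cohort simulation -> pooled Model-2 fit and guessing cutoff -> per-group
model fits with DIC comparison -> per-subject metrics -> permutation tests on
the group-level parameters -> covariate-adjusted GLMs with effect sizes and
Bayes factors.  A single master seed spawns independent per-stage substreams,
so the same config always produces an identical report.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as _io
from . import metrics as _metrics
from . import taskgen as _taskgen
from .inference import glm_effect, permutation_parameter_test
from .metrics import CutoffError, derive_guess_cutoff, subject_metrics_table
from .mixture import McmcConfig, compare_models, fit_bayes, fit_mle

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("locmem")

GLM_DVS = (
    "identification_accuracy",
    "retrieval_success",
    "precision_sd_deg",
    "mean_abs_error_deg",
    "nn_distance_deg",
    "delay_slope",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulate`` (a :class:`~locmem.taskgen.CohortSpec`) or
    ``input_csv`` must be provided.  ``seed`` drives every stochastic stage.
    """

    seed: int
    outdir: str = "locmem_out"
    simulate: object = None  # CohortSpec | None
    input_csv: str | None = None
    backend: str = "bayes"  # backend for the pooled cutoff fit: mle | bayes
    cutoff_rule: str = "responsibility"
    cutoff_k: float = _metrics.DEFAULT_K_SD
    n_perm: int = 1000
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    glm_dvs: tuple = GLM_DVS
    bf_method: str = "bic"

    def __post_init__(self):
        if self.simulate is None and self.input_csv is None:
            raise ValueError("config needs either a cohort spec or an input CSV")
        if self.backend not in ("mle", "bayes"):
            raise ValueError("backend must be 'mle' or 'bayes'")


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run config.

    The ``simulate`` section, if present, maps onto
    :class:`~locmem.taskgen.CohortSpec`; a ``task`` subsection onto
    :class:`~locmem.taskgen.TaskConfig`; ``mcmc`` onto :class:`McmcConfig`.
    The master seed is mandatory.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError("config must declare a master seed")
    sim = raw.pop("simulate", None)
    if sim is not None:
        task = _taskgen.TaskConfig(**sim.pop("task", {}))
        groups = tuple(
            _taskgen.GroupSpec(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in g.items()}
            )
            for g in sim.pop("groups")
        )
        sim.setdefault("master_seed", raw["seed"])
        sim = _taskgen.CohortSpec(groups=groups, task=task, **sim)
    mcmc = McmcConfig(**raw.pop("mcmc", {}))
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(simulate=sim, mcmc=mcmc, **raw)


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write ``report.json`` + ``subject_metrics.csv``
    (and ``trials.csv`` when simulating) under ``config.outdir``.

    Returns the report dict.  Any stage failure propagates with the stage
    name in the log.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_fit, seed_compare, seed_perm = ss.spawn(3)

    t0 = _stage("load-or-simulate")
    if config.simulate is not None:
        subjects, trials = _taskgen.generate_cohort(config.simulate)
        _io.write_trials(trials, outdir / "trials.csv")
    else:
        trials = _io.read_trials(config.input_csv)
        subjects = (
            trials[["subject_id", "group", "age", "sex"]]
            .drop_duplicates("subject_id")
            .reset_index(drop=True)
        )
    log.info("  %d subjects, %d trials (%.1fs)", subjects.shape[0],
             trials.shape[0], time.perf_counter() - t0)
    if subjects["group"].nunique() != 2:
        raise ValueError("pipeline expects exactly two groups")
    groups = sorted(subjects["group"].unique())

    eligible = trials[trials["identification_correct"].astype(bool)]
    all_errors = eligible["error_deg"].to_numpy()
    offsets = (
        eligible[["distractor1_angle_deg", "distractor2_angle_deg"]].to_numpy()
        - eligible[["target_angle_deg"]].to_numpy()
    )
    from .circular import wrap_angle

    offsets = wrap_angle(offsets)

    t0 = _stage("pooled-fit-and-cutoff")
    if config.backend == "bayes":
        pooled = fit_bayes(all_errors, model_id=2, config=config.mcmc,
                           seed=seed_fit)
    else:
        pooled = fit_mle(all_errors, model_id=2,
                         rng=np.random.default_rng(seed_fit))
    try:
        cutoff = derive_guess_cutoff(pooled, rule=config.cutoff_rule,
                                     k=config.cutoff_k)
    except CutoffError:
        log.warning("cutoff rule %r failed; falling back to k_sd",
                    config.cutoff_rule)
        cutoff = derive_guess_cutoff(pooled, rule="k_sd", k=config.cutoff_k)
    log.info("  cutoff %.1f deg via %s (%.1fs)", cutoff.cutoff_deg, cutoff.rule,
             time.perf_counter() - t0)

    t0 = _stage("group-fits-and-model-comparison")
    group_fits = {}
    comparisons = {}
    comp_seeds = seed_compare.spawn(len(groups))
    for g, gseed in zip(groups, comp_seeds):
        mask = (eligible["group"] == g).to_numpy()
        comp = compare_models(all_errors[mask], offsets[mask],
                              config=config.mcmc, seed=gseed)
        comparisons[g] = comp.to_dict()
        best2 = comp.fits.get(2)
        group_fits[g] = best2.to_dict() if best2 is not None else None
    log.info("  done (%.1fs)", time.perf_counter() - t0)

    t0 = _stage("subject-metrics")
    table = subject_metrics_table(trials, cutoff, subjects)
    table.to_csv(outdir / "subject_metrics.csv", index=False)

    t0 = _stage("permutation-tests")
    by_subj = [
        eligible.loc[eligible["subject_id"] == s, "error_deg"].to_numpy()
        for s in subjects["subject_id"]
    ]
    perm = permutation_parameter_test(
        by_subj,
        subjects["group"].to_numpy(),
        parameter=("p_guess", "circ_sd_deg"),
        n_perm=config.n_perm,
        rng=np.random.default_rng(seed_perm),
        group_order=tuple(groups),
    )
    log.info("  done (%.1fs)", time.perf_counter() - t0)

    t0 = _stage("glm")
    glm = {}
    for dv in config.glm_dvs:
        try:
            glm[dv] = glm_effect(table, dv, bf_method=config.bf_method).to_dict()
        except ValueError as exc:
            glm[dv] = {"error": str(exc)}
    log.info("  done (%.1fs)", time.perf_counter() - t0)

    report = {
        "seed": config.seed,
        "settings": {
            "backend": config.backend,
            "cutoff_rule": config.cutoff_rule,
            "cutoff_k": config.cutoff_k,
            "n_perm": config.n_perm,
            "bf_method": config.bf_method,
            "mcmc": dataclasses.asdict(config.mcmc),
            "simulated": config.simulate is not None,
        },
        "cutoff": {
            "rule": cutoff.rule,
            "cutoff_deg": cutoff.cutoff_deg,
            "pooled_p_guess": cutoff.p_guess,
            "pooled_circ_sd_deg": cutoff.circ_sd_deg,
        },
        "pooled_fit": pooled.to_dict(),
        "group_fits": group_fits,
        "model_comparison": comparisons,
        "permutation": {p: c.to_dict() for p, c in perm.items()},
        "glm": glm,
        "n_subjects": int(subjects.shape[0]),
        "n_trials": int(trials.shape[0]),
    }
    _io.write_report(report, outdir / "report.json")
    return report
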