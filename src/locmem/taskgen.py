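"""Synthetic object-location memory task and cohort generator.

Emulates a continuous-report localization task: on each encoding display,
three objects sit on an invisible circle with a minimum pairwise angular
separation (62.04 degrees by default, preventing spatial overlap).  The task
runs in study-test blocks; each test trial asks for a 2AFC identity judgement
and, if correct, a continuous placement of the object at its studied angle.
The default configuration is 5 blocks x 5 displays x 3 objects = 75 test
trials.

Responses are simulated from the generative mixture the analysis assumes:
with probability ``p_guess`` a uniform guess, with probability ``p_swap`` a
von Mises draw centred on a randomly chosen distractor (a misbinding/swap
error), otherwise a von Mises draw centred on the target whose spread is the
subject's localization imprecision.

Cohorts are two (or more) genotype-labelled groups with subject-level
parameters drawn from group distributions and truncated to fittable ranges,
plus age and sex covariates.  The default cohort mirrors a published
APOE-genotyped sample: 26 e3e3 carriers (age 63.4 +/- 6.07, 13 female) versus
20 e3e4 carriers (age 64.8 +/- 6.83, 5 female), with group-level guess rates
of 0.31 / 0.29 and localization SDs of 17.9 / 18.84 degrees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circular import circ_sd_to_kappa, signed_error, wrap_angle

__all__ = [
    "TaskConfig",
    "DisplayLayout",
    "SubjectParams",
    "GroupSpec",
    "CohortSpec",
    "generate_display",
    "generate_display_layouts",
    "generate_task_structure",
    "simulate_responses",
    "generate_cohort",
    "default_cohort_spec",
    "null_cohort_spec",
]

# Truncation ranges applied to sampled subject-level parameters; these keep
# every synthetic subject inside the fittable region of the mixture model.
PROB_CLIP = (0.001, 0.999)
SD_CLIP_DEG = (2.0, 60.0)


def _rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class TaskConfig:
    """Structure of the localization task.

    ``interference_seconds`` (a backwards-counting filler between study and
    test) is carried as metadata only; it does not influence simulation.
    """

    n_blocks: int = 5
    displays_per_block: int = 5
    objects_per_display: int = 3
    min_separation_deg: float = 62.04
    interference_seconds: float = 12.0

    def __post_init__(self):
        for name in ("n_blocks", "displays_per_block", "objects_per_display"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.objects_per_display < 2:
            raise ValueError("objects_per_display must be >= 2 (need distractors)")
        if self.min_separation_deg < 0:
            raise ValueError("min_separation_deg must be >= 0")
        if self.objects_per_display * self.min_separation_deg >= 360.0:
            raise ValueError(
                "infeasible layout: objects_per_display * min_separation_deg "
                f"= {self.objects_per_display * self.min_separation_deg:.2f} >= 360"
            )

    @property
    def n_displays(self) -> int:
        return self.n_blocks * self.displays_per_block

    @property
    def n_trials(self) -> int:
        return self.n_displays * self.objects_per_display


@dataclass(frozen=True)
class DisplayLayout:
    """Angular object positions of one encoding display."""

    display_id: int
    object_angles_deg: tuple
    object_ids: tuple

    def __post_init__(self):
        if len(self.object_angles_deg) != len(self.object_ids):
            raise ValueError("object_angles_deg and object_ids must align")


@dataclass(frozen=True)
class SubjectParams:
    """Generative response parameters of one subject.

    ``p_guess`` and ``p_swap`` are mixture weights (their sum must not exceed
    1); ``circ_sd_deg`` is the von Mises spread of remembered placements;
    ``p_identify`` is 2AFC identification accuracy.
    """

    p_guess: float
    p_swap: float
    circ_sd_deg: float
    p_identify: float = 1.0

    def __post_init__(self):
        for name in ("p_guess", "p_swap", "p_identify"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_guess + self.p_swap > 1.0 + 1e-12:
            raise ValueError("p_guess + p_swap must be <= 1")
        if not self.circ_sd_deg > 0:
            raise ValueError("circ_sd_deg must be > 0")


@dataclass(frozen=True)
class GroupSpec:
    """Population distribution of one cohort group.

    Each parameter is a (mean, between-subject SD) pair; sampled values are
    truncated to valid ranges.  ``prop_female`` fixes the sex split exactly
    (``round(n * prop_female)`` females) rather than sampling it.
    """

    name: str
    n: int
    p_guess: tuple = (0.31, 0.18)
    p_swap: tuple = (0.0, 0.0)
    circ_sd_deg: tuple = (17.9, 5.0)
    p_identify: tuple = (0.83, 0.06)
    age: tuple = (63.4, 6.07)
    prop_female: float = 0.5

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"group {self.name!r} must have n >= 1")
        for name in ("p_guess", "p_swap", "circ_sd_deg", "p_identify", "age"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} between-subject SD must be >= 0")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValueError("prop_female must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a reproducible synthetic cohort."""

    groups: tuple
    master_seed: int
    task: TaskConfig = field(default_factory=TaskConfig)
    shared_displays: bool = True

    def __post_init__(self):
        if len(self.groups) < 1:
            raise ValueError("at least one group required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")


def default_cohort_spec(master_seed: int = 0) -> CohortSpec:
    """Two-group cohort anchored to the reference APOE sample.

    Group sizes, ages and sex ratios follow the published demographics; the
    generating guess rates and localization SDs are the group-level mixture
    estimates (e3e3: pU 0.31, SD 17.9 deg; e3e4: pU 0.29, SD 18.84 deg) and
    identification accuracies 0.83 / 0.82.  Between-subject dispersions are
    set so that subject-level retrieval success and precision spread out about
    as widely as in the reference sample.
    """
    return CohortSpec(
        groups=(
            GroupSpec(
                name="e3e3", n=26,
                p_guess=(0.31, 0.18), p_swap=(0.0, 0.0),
                circ_sd_deg=(17.90, 5.0), p_identify=(0.83, 0.06),
                age=(63.4, 6.07), prop_female=0.5,
            ),
            GroupSpec(
                name="e3e4", n=20,
                p_guess=(0.29, 0.18), p_swap=(0.0, 0.0),
                circ_sd_deg=(18.84, 4.0), p_identify=(0.82, 0.08),
                age=(64.8, 6.83), prop_female=0.25,
            ),
        ),
        master_seed=master_seed,
    )


def null_cohort_spec(master_seed: int = 0) -> CohortSpec:
    """Same group sizes and demographics, but identical generating memory
    parameters in both groups — the zero-effect condition used for
    calibration of the group tests."""
    spec = default_cohort_spec(master_seed)
    g1, g2 = spec.groups
    g2 = replace(
        g2,
        p_guess=g1.p_guess,
        p_swap=g1.p_swap,
        circ_sd_deg=g1.circ_sd_deg,
        p_identify=g1.p_identify,
    )
    return replace(spec, groups=(g1, g2))


def _min_pairwise_separation(angles: np.ndarray) -> np.ndarray:
    """Minimum absolute circular separation over all object pairs, rowwise."""
    angles = np.atleast_2d(angles)
    k = angles.shape[1]
    best = np.full(angles.shape[0], 360.0)
    for i, j in itertools.combinations(range(k), 2):
        d = np.abs(wrap_angle(angles[:, i] - angles[:, j]))
        best = np.minimum(best, d)
    return best


def generate_display_layouts(n: int, config: TaskConfig, rng=None) -> np.ndarray:
    """Sample ``n`` display layouts by rejection: draw all object angles
    uniformly and resample a display whenever any pair violates the minimum
    separation.  Conditional on acceptance the angles are exactly uniform.

    Returns an (n, objects_per_display) array of degrees in (-180, 180].
    """
    rng = _rng(rng)
    k = config.objects_per_display
    out = np.empty((n, k))
    pending = np.arange(n)
    while pending.size:
        cand = rng.uniform(0.0, 360.0, size=(pending.size, k))
        ok = _min_pairwise_separation(cand) >= config.min_separation_deg
        out[pending[ok]] = cand[ok]
        pending = pending[~ok]
    return wrap_angle(out)


def generate_display(config: TaskConfig, rng=None, display_id: int = 0) -> DisplayLayout:
    """Sample a single encoding display honouring the separation constraint."""
    angles = generate_display_layouts(1, config, rng)[0]
    return DisplayLayout(
        display_id=display_id,
        object_angles_deg=tuple(float(a) for a in angles),
        object_ids=tuple(range(config.objects_per_display)),
    )


def generate_task_structure(config: TaskConfig, rng=None, layouts=None) -> pd.DataFrame:
    """Build the ordered trial schedule for one subject.

    Within each block, all of the block's displays are studied first; the
    test order over the block's (display, object) pairs is then a random
    permutation.  ``delay_index`` counts the test trials that precede a trial
    within its block — the stand-in for study-test delay.

    ``layouts`` may supply a pre-generated (n_displays, objects) angle array
    so several subjects can share one stimulus set; if omitted, layouts are
    sampled here.
    """
    rng = _rng(rng)
    k = config.objects_per_display
    if layouts is None:
        layouts = generate_display_layouts(config.n_displays, config, rng)
    else:
        layouts = np.asarray(layouts, dtype=float)
        if layouts.shape != (config.n_displays, k):
            raise ValueError(
                f"layouts must have shape {(config.n_displays, k)}, got {layouts.shape}"
            )
    rows = []
    for block in range(config.n_blocks):
        display_ids = block * config.displays_per_block + np.arange(config.displays_per_block)
        pairs = [(d, t) for d in display_ids for t in range(k)]
        order = rng.permutation(len(pairs))
        for pos, idx in enumerate(order):
            d, t = pairs[idx]
            angles = layouts[d]
            distractors = np.delete(angles, t)
            row = {
                "block": block,
                "display_id": int(d),
                "target_id": int(t),
                "target_angle_deg": float(angles[t]),
                "delay_index": pos,
            }
            for j, a in enumerate(distractors, start=1):
                row[f"distractor{j}_angle_deg"] = float(a)
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_responses(
    schedule: pd.DataFrame, params: SubjectParams, rng=None
) -> pd.DataFrame:
    """Simulate identification and localization responses for one subject.

    Localization responses follow the generative mixture: uniform guesses with
    probability ``p_guess``, swaps to a uniformly chosen distractor with
    probability ``p_swap``, von Mises around the target otherwise.
    Identification is a Bernoulli(p_identify) outcome; responses are
    simulated for every trial and downstream analyses filter on the flag.
    """
    rng = _rng(rng)
    n = len(schedule)
    out = schedule.copy()
    target = schedule["target_angle_deg"].to_numpy()
    distr_cols = sorted(c for c in schedule.columns if c.startswith("distractor"))
    if not distr_cols:
        raise ValueError("schedule has no distractor columns")
    distractors = schedule[distr_cols].to_numpy()

    kappa = circ_sd_to_kappa(params.circ_sd_deg)
    u = rng.random(n)
    is_guess = u < params.p_guess
    is_swap = (~is_guess) & (u < params.p_guess + params.p_swap)
    noise_deg = np.degrees(rng.vonmises(0.0, kappa, size=n))
    which_distr = rng.integers(0, distractors.shape[1], size=n)
    uniform_resp = rng.uniform(-180.0, 180.0, size=n)
    identified = rng.random(n) < params.p_identify

    centre = target.copy()
    centre[is_swap] = distractors[is_swap, which_distr[is_swap]]
    response = wrap_angle(centre + noise_deg)
    response = np.where(is_guess, uniform_resp, response)

    out["response_angle_deg"] = response
    out["error_deg"] = signed_error(response, target)
    out["identification_correct"] = identified
    return out


def generate_cohort(spec: CohortSpec):
    """Generate a full cohort: a subjects table and a trial-level table.

    One master seed drives everything through spawned child streams, so the
    same spec always yields byte-identical tables.  When
    ``spec.shared_displays`` is true (the default) all subjects see the same
    stimulus set, as in a fixed-stimulus experiment, while test order remains
    per-subject random.

    Returns ``(subjects, trials)`` DataFrames.  The subjects table carries the
    covariates plus the true generating parameters (``true_*`` columns) for
    parameter-recovery work.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    layout_seed, param_seed, subject_seed = ss.spawn(3)
    layout_rng = np.random.default_rng(layout_seed)
    param_rng = np.random.default_rng(param_seed)

    shared_layouts = (
        generate_display_layouts(spec.task.n_displays, spec.task, layout_rng)
        if spec.shared_displays
        else None
    )

    n_total = sum(g.n for g in spec.groups)
    subject_seeds = subject_seed.spawn(n_total)

    subject_rows = []
    trial_frames = []
    sid = 0
    for group in spec.groups:
        p_guess = np.clip(
            param_rng.normal(*group.p_guess, size=group.n), *PROB_CLIP)
        p_swap = np.clip(
            param_rng.normal(*group.p_swap, size=group.n), 0.0, PROB_CLIP[1])
        # keep the weight simplex valid after truncation
        total = p_guess + p_swap
        over = total > PROB_CLIP[1]
        scale = np.where(over, PROB_CLIP[1] / total, 1.0)
        p_guess, p_swap = p_guess * scale, p_swap * scale
        circ_sd = np.clip(
            param_rng.normal(*group.circ_sd_deg, size=group.n), *SD_CLIP_DEG)
        p_ident = np.clip(
            param_rng.normal(*group.p_identify, size=group.n), *PROB_CLIP)
        age = param_rng.normal(*group.age, size=group.n)
        n_female = int(round(group.n * group.prop_female))
        sex = np.array(["F"] * n_female + ["M"] * (group.n - n_female))
        param_rng.shuffle(sex)

        for i in range(group.n):
            subject_id = f"S{sid:03d}"
            params = SubjectParams(
                p_guess=float(p_guess[i]),
                p_swap=float(p_swap[i]),
                circ_sd_deg=float(circ_sd[i]),
                p_identify=float(p_ident[i]),
            )
            srng = np.random.default_rng(subject_seeds[sid])
            schedule = generate_task_structure(
                spec.task, srng, layouts=shared_layouts)
            trials = simulate_responses(schedule, params, srng)
            trials.insert(0, "subject_id", subject_id)
            trials.insert(1, "group", group.name)
            trials.insert(2, "age", float(age[i]))
            trials.insert(3, "sex", sex[i])
            trial_frames.append(trials)
            subject_rows.append(
                {
                    "subject_id": subject_id,
                    "group": group.name,
                    "age": float(age[i]),
                    "sex": sex[i],
                    "true_p_guess": params.p_guess,
                    "true_p_swap": params.p_swap,
                    "true_circ_sd_deg": params.circ_sd_deg,
                    "true_p_identify": params.p_identify,
                }
            )
            sid += 1

    subjects = pd.DataFrame(subject_rows)
    trials = pd.concat(trial_frames, ignore_index=True)
    return subjects, trials
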