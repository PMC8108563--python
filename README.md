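# locmem

Mixture modelling and group inference for **continuous-report
object-location memory**.

In a continuous-report localization task, a participant studies objects
placed on an invisible circle and later recreates each object's position;
the datum is the signed angular error between response and target. Such
errors are not simply "right or wrong": they mix trials on which *something*
was retrieved (clustered around the target with some precision) with trials
carrying no information (uniform on the circle) and, possibly, misbinding
trials where the response tracks a *different* object's location. `locmem`
decomposes these sources, turns the decomposition into per-subject memory
metrics, and runs the group-level statistics used to compare two cohorts
(e.g. genotype risk groups in preclinical dementia research).

## The model

Errors `e ∈ (−180°, 180°]` are described by nested von Mises mixtures:

| Model | Density of `e` | Parameters |
|---|---|---|
| 1 | `vm(e; 0, κ)` | κ |
| 2 | `pT·vm(e; 0, κ) + pU/360` | pU, κ |
| 3 | `pT·vm(e; 0, κ) + pU/360 + pNT·mean_d vm(e; offset_d, κ)` | pU, pNT, κ |

with `pT = 1 − pU − pNT` the **retrieval success**, `pU` the **guess rate**,
`pNT` the **swap/misbinding weight**, and κ the von Mises concentration,
reported interchangeably as a circular standard deviation
`SD = √(−2 ln(I₁(κ)/I₀(κ)))` (**precision**; lower SD = more precise).
Fitting is by multistart maximum likelihood or by Metropolis-Hastings
sampling (posterior means, 95% credible intervals, R-hat diagnostics), with
DIC-based model comparison. A group-level Model-2 fit supplies a guessing
cutoff from which per-subject retrieval success and precision are computed,
and group differences are tested by subject-level permutation of the
group-level model parameters and by covariate-adjusted GLMs with Cohen's f²
and Bayes factors.

Because raw data from such studies are typically not public, the package
ships a first-class synthetic generator that emulates the task (3 objects
per display at ≥ 62.04° separation, 5 blocks × 5 displays, 75 test trials,
2AFC identification before localization) and two-group cohorts with
realistic demographics, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
import locmem as lm

# simulate the default two-group cohort (26 vs 20 subjects, 75 trials each)
subjects, trials = lm.generate_cohort(lm.default_cohort_spec(master_seed=2024))

# pool identification-correct errors and fit the standard mixture model
eligible = trials[trials.identification_correct]
fit = lm.fit_mle(eligible.error_deg.to_numpy(), model_id=2, rng=0)
print(f"pU = {fit.params.p_guess:.3f}, SD = {fit.circ_sd_deg:.1f} deg")

# per-subject metrics at the 63-degree cutoff, then the group GLM
table = lm.subject_metrics_table(trials, 63.0, subjects)
print(table.groupby("group")["retrieval_success"].mean().round(3))
rep = lm.glm_effect(table, "retrieval_success")
print(f"F({rep.df1}, {rep.df2}) = {rep.F:.2f}, p = {rep.p:.3f}, "
      f"f2 = {rep.f2:.3f}, BF01 = {rep.bf01:.2f}")
```

Output:

```
pU = 0.358, SD = 16.7 deg
group
e3e3    0.753
e3e4    0.806
Name: retrieval_success, dtype: float64
F(1, 42) = 0.84, p = 0.365, f2 = 0.020, BF01 = 4.30
```

Read: pooled across this cohort, ~36% of localizations are guesses and
remembered locations are recalled with a 16.7° spread; the groups retrieve
75–81% of locations at the 63° criterion, and with age and sex controlled
the group factor explains almost nothing (f² = 0.02), with the Bayes factor
favouring the null about 4:1 — evidence of absence, not just absence of
evidence.

A command-line interface wraps the same stages:

```bash
locmem simulate --seed 7 --out trials.csv
locmem fit trials.csv --seed 1 --model compare
locmem metrics trials.csv --cutoff 63 --out metrics.csv
locmem group-test trials.csv --seed 1 --n-perm 1000
locmem run --config config.yaml        # full pipeline -> report.json
```

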