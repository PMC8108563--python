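# Methods

## The measurement model

The package analyses continuous-report object-location memory: on each test
trial a participant replaces a studied object on an invisible circle, and the
datum is the signed angular error `e = response − target`, wrapped to
(−180°, 180°]. Trial-by-trial variation in `e` is decomposed with nested von
Mises mixture models:

* **Model 1 (von Mises).** Every response reflects the remembered location:
  `f(e) = vm(e; 0, κ)`, with `vm` the von Mises density per degree. The
  concentration κ is reported interchangeably as a circular standard
  deviation through `SD = √(−2 ln(I₁(κ)/I₀(κ)))` (radians, converted to
  degrees); lower SD means higher precision.
* **Model 2 (von Mises + uniform).** A fraction `pU` of trials carries no
  location information (uniform on the circle); the complement
  `pT = 1 − pU` is *retrieval success*:
  `f(e) = pT·vm(e; 0, κ) + pU/360`.
* **Model 3 (+ non-target swaps).** With weight `pNT` the response is
  centred on one of the display's distractors (misbinding):
  `f(e) = pT·vm(e; 0, κ) + pU/360 + pNT·mean_d vm(e; offset_d, κ)`,
  where `offset_d` is the wrapped angular offset of distractor *d* from the
  target. Target and non-target components share one κ; the two distractors
  get equal weight. Both choices are the standard ones in the swap-model
  literature and keep the model identified at typical trial counts.

Densities are expressed per degree so mixture weights are unit-free. All
public APIs take and return degrees; radians exist only inside function
bodies.

## Fitting backends

**Maximum likelihood** (`fit_mle`): L-BFGS-B in an unconstrained space
(logit / multinomial-logit weights, log κ), best of 20 random starts plus a
fixed default start; κ is bounded in [1e−3, 1e6]. Intervals are
normal-approximation from the numerical Hessian at the optimum, mapped back
through the monotone transforms (delta-method behaviour for the simplex);
the interval method is declared in the output. Degenerate samples (e.g. all
errors identical) are handled by the bounds: κ runs to its cap and the
weights to the boundary.

**Bayesian** (`fit_bayes`): random-walk Metropolis-Hastings on the same
transformed space. Priors: uniform over the mixture-weight simplex
(Jacobian-corrected in the sampling space) and log-uniform κ on
[0.25, 500] — a range covering circular SDs from roughly 2.6° to effectively
uniform. Defaults: 3 chains × 15,000 post-burn-in iterations, 2,000
burn-in, thinning 5. Per-coordinate proposal widths come from the inverse
Hessian at the MLE centre (clipped to [0.02, 3] so boundary-degenerate
curvature falls back to O(1) steps), and a single global factor on top of
them adapts toward ≈0.3 acceptance during burn-in only, so the retained
chain has a fixed kernel and is exactly reproducible under a seed. Chains start from a quick MLE solution with
overdispersed jitter (SD 0.5 per coordinate in the transformed space), which
makes split R-hat informative. Point estimates are posterior means,
intervals central 95% quantiles; any parameter with R-hat > 1.05 flags the
fit unconverged (the result is still returned, never silently dropped).

**DIC** is computed as `D̄ + pD` with `pD = D̄ − D(θ̄)`, `D = 2·NLL`, using
the per-draw NLLs accumulated during sampling. `compare_models` ranks
Models 1–3 but declares as winner the *simplest* model within 5 deviance
units of the DIC minimum. The margin is essential: when a weight's
posterior collapses onto the zero boundary, DIC assigns it almost no
complexity penalty, so on data truly generated by a nested simpler model the
richer model's DIC advantage is approximately the boundary likelihood-ratio
statistic — a 50:50 mixture of 0 and χ²₁ — which exceeds 2 on about 8% of
datasets but 5 on only about 1%. Five units is also the conventional
"hard to call" band for DIC differences, and genuinely present extra
components separate the models by hundreds of units at group-level trial
counts. Setting `parsimony_margin=0` restores the plain argmin.

Group-level fits pool all trials of a group's subjects, ignoring subject
identity; hierarchical mixture modelling is out of scope.

## The guessing cutoff and subject metrics

A group-level Model-2 fit sets a cutoff beyond which a response is
classified as a retrieval failure. The default `responsibility` rule finds
the smallest |e| at which the uniform component becomes the more probable
source, i.e. the crossover of `pU/360` and `pT·vm(e; 0, κ)`; it is solved in
closed form via `cos(e*) = [ln(pU/pT) + ln I₀(κ)]/κ`. The alternative
`k_sd` rule returns `k × SD` (default k = 3.5, which maps an 18° SD onto the
conventional 63° cutoff). When `pU = 0` the responsibility rule has no
crossover and fails explicitly, directing the caller to `k_sd`. The cutoff
is derived once from the pooled full-sample fit and applied to every subject
(per-group cutoffs are possible but off by default).

Per-subject measures, computed over identification-correct trials only
(localization is only probed after a correct 2AFC identification):

* retrieval success — fraction of trials with |e| ≤ cutoff;
* precision — linear sample SD of the retained signed errors (the truncation
  makes wrapping irrelevant); reported as imprecision, lower is better;
* mean absolute error;
* nearest-neighbour distance — mean distance from the response to the
  closest object of its display (target or distractor); the misbinding
  control variant restricts it to error trials (|e| > cutoff), where swaps
  sit near a distractor and guesses do not — on all trials the measure is
  nearly flat in the swap rate, because correct and swapped responses are
  equally close to *some* object;
* identification accuracy (all trials);
* delay slope — per-subject Pearson correlation between |e| and the trial's
  study-test delay (a rank variant would be a one-line change; Pearson is
  the default as the plain reading of "correlation").

Metrics undefined for a subject (too few retained trials, constant delay)
are NaN in the metrics table; the low-level functions raise instead.

## Group inference

**Permutation test.** Model 2 is fitted to each group's pooled errors; the
observed difference (first group minus second, by a caller-fixed order) is
standardized against the distribution over 1000 (default) permutations that
reassign *whole subjects* to pseudo-groups of the original sizes — trial
-level shuffling would break within-subject dependence and be
anti-conservative. `z = (Δ_obs − mean Δ_perm)/sd Δ_perm`; the two-sided
p-value uses the add-one estimator. Permutation refits use two optimizer
starts, one warmed at the pooled-sample solution — the Model-2 likelihood in
two parameters is well-behaved, and the warm start tracks the refit
optimum across permutations. Failed refits are redrawn; more than 5%
failures aborts.

**GLM.** OLS of a subject metric on covariates (age centred, sex binary)
with the two-level group factor added; the F statistic comes from the
nested-model comparison, the effect size is Cohen's
`f² = (R²_full − R²_cov)/(1 − R²_full)`, and a Bayes factor accompanies
every test. The default BF is the BIC approximation
`BF01 = exp((BIC_full − BIC_cov)/2)`; a JZS option integrates the Liang
et al. mixture-of-g-priors marginal likelihoods numerically. The BF method
is always reported next to the value — BF magnitudes are prior-dependent,
and matching any particular external package's default prior is not a goal.

**Correlations.** Pearson r with a JZS Bayes factor computed by numerical
integration over the g-prior (the Wetzels-style variant); the prior is named
in the output.

## The synthetic cohort generator

The generator emulates the task: displays of 3 objects on the circle with a
minimum pairwise separation of 62.04°, sampled by rejection (uniform given
the constraint); 5 blocks × 5 displays × 3 objects = 75 test trials; within
a block all displays are studied before a randomly ordered test phase.
Study-test delay is operationalized as the number of test trials preceding a
trial within its block — the task's real delay variable is not defined more
precisely anywhere we can anchor it, so trial lag is the declared stand-in.
All subjects in a cohort share one stimulus set (as in a fixed-stimulus
experiment); test order and responses are per-subject random. The 12 s
interference interval is carried as config metadata only.

Responses follow the generative mixture (guess / swap / target-centred von
Mises); 2AFC identification is a Bernoulli outcome with per-subject accuracy
(foil similarity is not modelled). Localization responses are simulated for
every trial and analyses filter on the identification flag, keeping
generator and filter separable.

The default cohort reproduces the reference study conditions: 26 low-risk
(e3e3) subjects, age 63.4 ± 6.07, 13 female, guess rate 0.31, SD 17.9°,
identification 0.83; versus 20 higher-risk (e3e4) subjects, age 64.8 ± 6.83,
5 female, guess rate 0.29, SD 18.84°, identification 0.82. Group-level
means are published quantities; the *between-subject* dispersions are not,
so they are set once to values that reproduce the published subject-level
spread: pU SD 0.18 (subject-level retrieval-success SD ≈ 0.13–0.16, and
retrieval success moves ≈0.65 per unit pU at these settings), circular-SD SD
5.0°/4.0°, identification SD 0.06/0.08. Sampled parameters are truncated
(probabilities to [0.001, 0.999], jointly rescaled if a weight sum exceeds
the cap; SD to [2°, 60°]) so every synthetic subject is fittable. Sex
counts are fixed exactly (round(n·prop_female)) rather than sampled.

What the generator does **not** emulate: response times, foil similarity in
the 2AFC, perceptual or motor error structure, serial-position and fatigue
effects, and any heavy-tailed or subject-specific deviation from the von
Mises shape. Passing tests therefore demonstrate that the pipeline is
correct and calibrated *under the model's own assumptions*, not that the
model is adequate for any particular real dataset.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the tolerance they assert: 20,000 errors for parameter recovery
(MLE SE on pU ≈ 0.004), 200,000 for the retrieval-success proportion
(SE ≈ 0.001), 10,000 displays for the separation bound, 10,000 trials per
model-selection replicate, 100 replicates of 1,950 errors (one group's
pooled trial count) for credible-interval coverage, 200 null cohorts ×
200 permutations for type-I calibration, and 500 null cohorts for the
evidence-of-absence rate. Reduced MCMC settings (2–3 chains, 3,000–4,000
draws) are used in repeated-fit studies; the posterior for 2–3 parameters at
these data sizes is effectively Gaussian and well past the burn-in by then,
and R-hat is checked per fit.

Other numerics: the κ ↔ SD map inverts by bracketed root-finding on log κ
(round-trip guard at 1e−6 relative — the noise floor of the Bessel ratio at
extreme κ); von Mises densities use exponentially scaled Bessel functions
throughout, so κ up to 1e6 neither overflows nor loses the tail; mixture
densities are floored at 1e−300 inside the NLL so optimizers probing the
boundary see a finite objective; the wrap convention maps −180° to +180°,
making the signed representative unique.

## Known limitations

* No hierarchical pooling: per-subject metrics at 75 trials are noisy, which
  is precisely why group-level pooled fits drive the permutation test.
* The BIC Bayes factor is an approximation (unit-information prior); use the
  JZS option when prior sensitivity matters, and expect neither to equal any
  external package's default-prior value exactly.
* DIC with boundary-collapsing weights under-penalizes complexity; the
  parsimony margin mitigates but does not remove this, and very small true
  weights (pNT ≲ 0.02) will be folded into the simpler model.
* The permutation p-value is conditional on successful Model-2 refits;
  pathological pseudo-groups (e.g. a handful of trials) are redrawn, which
  very slightly biases the reference distribution at tiny cohort sizes.
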