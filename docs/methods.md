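# Methods

## Task generators

The three generators reproduce the printed experimental designs exactly and
are deterministic given an integer seed (numpy `default_rng`).

**Multi-cue.** The 16 stimuli are the full Cartesian product of four binary
design cues C1–C4; the table mapping cue patterns to p(high) spans 0.100 to
0.900, with stimuli in the band p(high) ∈ [0.4, 0.6] labelled *ambiguous*
and the rest *unambiguous*. Presentation is blocked: each of the 8 repeats
is a shuffled pass over all 16 stimuli (128 experimental trials). A trial's
rating is drawn by comparing p(high) against a fresh uniform number —
per-trial Bernoulli, as the design prescribes. A random permutation maps
physical cue slots to design columns per participant; this relabels only the
displayed cue levels, never the contingency table. Eight catch trials (the
label itself is shown) are inserted at inter-trial slots drawn uniformly
without replacement.

**Single-cue.** One of the four binary features is the target. Outcomes are
fixed at 50 trials per category. In the deterministic condition the target
level matches the category on every trial. In the probabilistic condition we
realise the 75% predictive strength as a *fixed count* — exactly 75 of 100
trials congruent, the 25 incongruent trials split 12/13 between categories
with the odd one assigned at random — rather than per-trial Bernoulli. The
fixed count guarantees the stated predictive strength in every generated
session and gives an exact test target; the multi-cue task keeps its
Bernoulli rule because there the per-trial draw *is* the stated mechanism.
Non-target features are i.i.d. uniform bits: with three binary nuisance
features over 100 trials, literal stimulus uniqueness is impossible, so the
surface variation of real stimuli is abstracted away.

**Bandit.** One option, chosen uniformly at random, is "better" and carries
the reward with probability 0.7 independently per trial; outcomes are
strictly anti-correlated (exactly one option rewarded per trial), which is
the premise that licenses counterfactual updating. 20 experimental trials,
2 catch trials, no reversals.

*Correctness* on any trial means choosing the most probable outcome given
the design (the better bandit option; the category the target level
predicts; "high" iff p(high) > 0.5). The early/late phase flag halves the
experimental trials by presentation order; catch trials never enter the
count.

## Learning models

All three models are delta rules over reward R ∈ {−1, +1} with values
initialised at 0 for every option, so values stay in [−1, 1] for any
trajectory. The likelihood uses predict-then-learn ordering: the softmax
probability of the observed choice is accrued before the values are updated
with the observed reward. The choice rule is a softmax on the value
difference with inverse temperature β; the zero-prediction-error tie in the
posneg model takes the α⁺ branch. β is bounded to [0, 10] and learning rates
to (0, 1). Timed-out and catch trials contribute no likelihood term and
trigger no update. The trajectory engine is vectorised over arbitrary
leading axes (participants × posterior draws × parameter grids), which is
what makes grid-search oracles and draw-wise pointwise likelihoods cheap.

## Estimation

**Maximum likelihood** (`fit_mle`): multi-start L-BFGS-B inside the bounds,
seeded jitter for the starts, best of n restarts. When the optimum sits at
β ≈ 0 the likelihood is flat in α; the fit is flagged `alpha_identifiable =
False` rather than reporting a meaningless learning rate.

**Hierarchical Bayes** (`HierarchicalRW`): per group, individual parameters
are non-centred — raw_ij = μ_j + σ_j·z_ij with z ~ N(0, 1) — and mapped to
the natural scale by a probit link, Φ(raw) for learning rates and 10·Φ(raw)
for β. Hyperpriors are weakly informative: μ_j ~ N(0, 1), σ_j ~
half-Normal(1).

No gradient-based sampler is assumed; the posterior is explored with an
adaptive Metropolis-within-Gibbs scheme written for this model family:

* one vectorised random-walk proposal per participant on its z row
  (accept/reject elementwise), target acceptance ≈ 0.25;
* scalar random-walk updates for each μ_j and each log σ_j (half-Normal
  prior plus log-Jacobian), target acceptance ≈ 0.44;
* step sizes adapted by Robbins–Monro during warmup only.

Defaults are 4 chains × (1000 warmup + 1000 draws), all seeded through numpy
`SeedSequence`, so a fit is bit-reproducible. Convergence is monitored with
split-chain R-hat and bulk ESS (via arviz) on all hyperparameters; R-hat
above 1.1 raises a warning and sets `converged = False`, but results are
still returned for inspection. A random-walk sampler has no divergence
diagnostic; acceptance rates are reported instead. With the study-scale
design (20 trials per participant) the group-scale parameters σ mix slowest;
short test-suite chains can trip the R-hat warning without affecting
group-location estimates, which is exactly what the warning is for.

Pointwise log-likelihoods are recorded at every saved draw, giving the
(draws × included-trials) matrix model comparison needs.

## Model comparison

`compute_loo` implements PSIS-LOO: per observation, the raw importance
ratios are the negative pointwise log-likelihoods; the largest
min(S/5, 3√S) weights are replaced by expected order statistics of a
generalized Pareto distribution fitted to the tail exceedances
(empirical-Bayes profile fit with a weak prior pulling the shape toward 0.5),
truncated at the raw maximum. LOOIC = −2·elpd_loo with the usual √(n·Var)
standard error, and the Pareto shape k̂ is reported per observation. The
implementation is validated against an independent reference (arviz) in the
test suite. `compare_models` refuses fits whose observation sets differ,
sorts by LOOIC per group, and breaks exact ties by parsimony (fewer
parameters, then the simple → posneg → counterfactual order).

## Behavioural statistics

d′ = z(hit) − z(false alarm), with rates of exactly 0 or 1 moved to 0.01 /
0.99 before the quantile transform. Accuracy tables aggregate
participant-level proportions correct per group × task × condition × phase,
with one-sample t-tests against chance (0.5). Group comparisons use the
pooled-variance (Student) two-sample t-test — df = n₁ + n₂ − 2, the
convention implied by a reported df of 102 with 52 + 52 participants.
Outliers are flagged by the 1.5·IQR boxplot rule, the natural reading when
results are presented as boxplots; a zero-IQR vector flags nothing.
Mixed-effects and GAMM analyses are deliberately not reimplemented — they
are off-the-shelf fits; `make_long_table` exports the model-ready long
table (participant, group, task, condition, phase, item, correct, optional
d′ covariates) for any downstream package.

## Synthetic cohorts

`CohortSpec` defaults encode the study conditions: two groups of 52, bandit
sessions of 20 trials at the 70% contingency, generating model
counterfactual, true learning rates drawn from Normal(0.39, 0.05) and
Normal(0.34, 0.06) truncated to (0, 1), β ~ Normal(3, 0.5) truncated to
(0, 10), 2% trial timeouts and 2% catch-trial errors. β's distribution is a
package choice (the source designs report no β); Normal(3, 0.5) puts agents
in a regime where 20 trials carry signal but choices stay stochastic, which
is what two-armed-bandit participants look like. The single-/multi-cue
responder is a cue-weight associative learner (delta rule on ±1-coded cue
features, learning rate 0.3, softmax read-out with inverse temperature 2) —
it exists only so accuracy summaries have realistic, above-chance inputs; it
is not a model of the bandit analysis and no claims hang on it.

What the generator does *not* emulate: demographic covariates, session
dropout, reaction times, within-session attention drift, and any systematic
group difference outside the learning-rate distributions. Passing recovery
tests therefore show the *pipeline* is sound under the assumed generative
structure, not that real data satisfy that structure.

`recovery_experiment` chains simulate → exclude → fit (all models, per
group) → LOOIC-select, and scores generating-model selection rate,
correlation/bias of recovered vs true learning rates, and the group
t-test — the validation harness for the whole pipeline. With 20 trials per
participant individual-level recovery is intrinsically weak; group-level
quantities (ordering, means) are the primary recovery target, and
trials-per-session is exposed as a dial for studying how recovery sharpens
with longer sessions.

## Numerical choices and problem sizes

* Logistic log-probabilities via `-logaddexp(0, -x)`; probit links via
  `scipy.special.ndtr`.
* Truncated-normal draws by rejection sampling (cheap at these scales);
  a zero-SD specification degenerates to the (clipped) mean.
* The test suite runs hierarchical fits with 2 chains × (400 + 400) draws
  and 3 replicates for the recovery checks; MLE recovery uses a 9 × 3
  (α × β) grid of 200-trial sessions. These sizes keep the full suite at
  about two minutes while leaving the statistical margins comfortable;
  larger runs go through `recovery_experiment` or the CLI with default
  sampler settings.
* The acceptance script pools 500 × 20 bandit trials (binomial SE ≈ 0.46
  percentage points at p = 0.7).

## Known limitations

* The Metropolis-within-Gibbs sampler needs more iterations per effective
  draw than a gradient-based sampler would; group-scale parameters (σ) have
  the lowest ESS. Absolute LOOIC values also depend on priors and sampler
  settings that published tables rarely pin down — model *ranking* is the
  robust, reproducible quantity.
* Posterior means of hierarchically fitted individual parameters are shrunk
  toward the group mean; two-sample t statistics computed on them overstate
  the evidence relative to a test on true parameters. The package reports
  them because that is the downstream convention, but group-level posterior
  contrasts are the cleaner inference.
* The associative responder for the cue tasks is a stand-in for human
  category learning, adequate for exercising accuracy summaries only.
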