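# Methods

## The valuation model

ASCOT SCT4 describes a social care-related quality-of-life (SCRQoL) state
by one level (1 best … 4 worst) on each of 8 domains. The package
estimates a value set for these states in two stages.

**Stage 1 — best–worst scaling.** Each profile-case (case 2) BWS task
shows one full 8-domain profile; the respondent sequentially names the
best, worst, second-best and second-worst domain. Under random utility
theory with iid Gumbel errors, each pick is a conditional-logit choice
over the domains still on the table (alternative sets of size 8, 7, 6, 5),
so one task contributes four choice occasions to an exploded rank-ordered
logit. The linear index has 31 parameters: domain constants β_p for the 7
non-reference domains ("control over daily life" is the reference) and
level effects β_pq for levels 1–3 of every domain (level 4 is the
reference). Worst-side occasions are coded by negating the design entries
(−1 coding), which makes the worst pick the conditional-logit maximum of
negated utilities.

Assumptions inherited from this likelihood: independence of the four
occasions within a task given the coefficients (fresh Gumbel draws per
occasion), symmetric preference intensity on the best and worst sides
(one shared β vector), and no position or ordering effects.

**Stage 2 — anchoring.** Item coefficients β_p + β_pq (32 of them, the
two reference conventions make control L4 exactly 0) are rescaled by the
linear map pinning control L1 to 1 and control L4 to 0, yielding the
weight table. A state's latent BWS score is the sum of its eight weights.
Mean composite time trade-off (cTTO) valuations of 64 states — x/10 for a
conventional answer of x years, y/10 − 1 for a lead-time answer of y years,
the lead-time design flooring the scale at −1 — give the anchoring
regression TTO_i = a·BWS_i + b + ε_i, constrained so that the best state
[11111111] maps exactly to 1. The constraint leaves one free parameter
with a closed-form solution (see below). SC-QALY scores of arbitrary
states are then a·(latent score) + b.

## Estimators

* `BestWorstMNL` — pooled conditional logit. The log likelihood is
  globally concave; Newton–Raphson with the analytic gradient and Hessian
  from the zero vector converges in a handful of iterations. Convergence
  is declared at max |score component| / n_occasions < 1e-8 (the fitted
  optima in the test suite reach ~1e-12). Standard errors are
  cluster-robust (sandwich) with respondents as clusters, since the four
  occasions of a task and the eight tasks of a respondent are pooled as
  if independent.
* `BestWorstMixedLogit` — simulated maximum likelihood. Random
  coefficients sit on the 7 domain constants only (the heterogeneity
  equation is written for β_p; level effects stay fixed — a config flag is
  deliberately *not* provided because the 31-random-coefficient model is
  not identified at the study's block sizes). Normal mixing:
  β_p = m_p + s_p·η; log-normal mixing: β_p = exp(m_p + s_p·η), with the
  log-scale location m_p reported as the domain constant. The likelihood
  contribution of a cluster is the average over draws of the product of
  its occasions' probabilities; clusters are respondents, or each
  respondent's best-side and worst-side occasions separately
  (`cluster_scheme="respondent_by_sign"`, for the reading that best and
  worst choices carry separate heterogeneity). Draws are scrambled Halton
  sequences (burn-in 100, seed-deterministic, assigned to clusters in
  sorted-id order so fits are invariant to row order); default 500 draws
  per cluster, with the validation suite using 100 (recovery tolerances
  are SE-based and adapt to the extra simulation noise). Optimization is
  L-BFGS-B on the analytic gradient, warm-started from the MNL solution
  with all scales at 0.1; scales are reported as absolute values since
  the likelihood is even in s. Standard errors use the
  outer-product-of-scores (BHHH) estimator at the optimum, asymptotically
  equivalent to the inverse Hessian at the MLE and far cheaper than
  differentiating a 38-parameter simulated likelihood twice;
  `se_method="hessian"` (central finite differences of the analytic
  gradient) is available.

The mixing-scale sign convention, draw count and SE method matter only
for the heterogeneity parameters; the mean coefficients and everything
downstream (weights, tariffs, scores) are insensitive to them in the
recovery experiments.

## Anchoring numerics

With anchor (x*, 1), a = Σ(TTO_i − 1)(BWS_i − x*) / Σ(BWS_i − x*)² and
b = 1 − a·x*; residuals are orthogonal to (BWS − x*) at the optimum and
the constraint holds to machine precision. State means enter unweighted
(one observation per state). R² is reported as 1 − SSR/SST with SST about
the observed mean — for a constrained fit this is not guaranteed
nonnegative, so the squared correlation between fitted and observed values
is reported alongside. The slope SE is the one-free-parameter delta
method, SE(a)² = σ̂²/Σ(BWS_i − x*)² with σ̂² = SSR/(n−1); the intercept
inherits SE(b) = |x*|·SE(a). t statistics from constrained fits are
descriptive, not a reproduction target.

## Synthetic data generator

The generator is first-class, tested code; it defines the conditions under
which every estimator is validated.

* **Design.** 32 BWS profiles in 4 blocks and 64 cTTO states in 8 blocks.
  The original studies drew profiles from an unpublished
  fractional-factorial design; the generator substitutes a level-balanced
  random design (each domain's column is a permutation of equal numbers of
  each level), which preserves the marginal balance that identification
  relies on. Respondent r receives block r mod n_blocks.
* **BWS arm.** Item utilities β_p + β_pq from a truth table (default: the
  published Japanese conditional-logit coefficients — the canonical study
  condition), optional normal/log-normal heterogeneity on domain
  constants, fresh Gumbel noise per occasion. Picks are argmax of
  sign·V + Gumbel, matching the estimator's likelihood exactly.
* **cTTO arm.** True state value = truth conversion (default slope 0.221,
  intercept −0.496) applied to the latent score of the truth-implied
  tariff (derived by the same rescaling the analysis applies, keeping
  generator and analyzer consistent), plus N(0, 0.1) noise, clamped to
  [−1, 1]. Values ≥ 0 become conventional answers x = 10v; negative values
  become lead-time answers y = 10(v+1). Answers snap to a 0.5-year grid
  (the response bar shows whole and half years; granularity is
  configurable, and exactness tests switch the grid off).
* **Response times.** Log-normal per respondent, parameters matched to the
  observed time distributions (BWS median 9.6 min, IQR 7.3–12.7; cTTO
  median 10.1, IQR 7.6–13.3), which places ≈3% of BWS times under the
  4.5-minute exclusion threshold and ≈5% of cTTO times under 5.0 minutes.
  These rates are emergent, not asserted.

What the generator does **not** emulate: interviewer effects, learning or
fatigue across tasks, the randomized on-screen ordering of domain
descriptions, correlated heterogeneity across domains, respondent-specific
cTTO noise scales, and any systematic difference between best-side and
worst-side preference intensity. Passing recovery tests therefore show the
estimators are correct for their assumed data-generating process, not that
the model is adequate for real survey behaviour.

## Exclusion filters

Respondents with total BWS time < 4.5 minutes leave the BWS analysis set;
total cTTO time < 5.0 minutes leaves the TTO analysis set. The thresholds
are strict (a respondent at exactly the threshold is retained) and the two
filters are independent, matching the separately reported exclusion
counts. Negative times are rejected as data errors.

## Published tariffs and the cross-country comparison

The Japanese and UK weight tables ship as packaged data exactly as
printed (3 decimals), with conversions (0.221, −0.496) and
(0.203, −0.466); they are not re-derived at load time. A transcription
regression test confirms that the published Japanese coefficient table
maps onto every printed Japanese weight within 0.001.

Scoring all 65,536 states under both published tariffs gives: UK score
strictly higher for 63,528 states (96.9%), Pearson correlation 0.949,
ICC(A,1) 0.757 (the full six-variant ICC sweep is reported; no variant
falls below 0.74). The comparison statistics originally reported alongside
these tariffs (91.0% = 59,666 states, Pearson 0.91, ICC 0.70) are *not*
recovered from the printed tables: Pearson is invariant to the choice of
conversion parameters, so no affine re-anchoring can reconcile the
difference, and re-deriving the Japanese weights from any of the published
coefficient columns moves the count by < 0.6 points. The package reports
what the printed tables imply; the corresponding regression test asserts
the originally reported values and is expected to fail until the source of
the discrepancy is identified.

ICC uses the closed-form two-way mean-squares decomposition (vectorised
over the 65,536 pairs); the test suite cross-checks all six variants
against an independent implementation. "Higher" is strict inequality and
ties are counted separately, so the three counts always partition the
state space.

## Problem sizes and seeds

Validation runs at the study's own scale where that is cheap: MNL recovery
at 500 respondents (16,000 occasions, ~1 s), anchoring recovery at 64
states × 1050 respondents, and the full pipeline at 1050 respondents
(~2 s end-to-end with the conditional logit). Mixed-logit recovery runs at
800 respondents with 100 Halton draws (~2–5 minutes). A single pipeline
seed fans out to per-stage seeds via `numpy.random.SeedSequence.spawn`, so
stages are independently reproducible and reruns are byte-identical.

## Known limitations

* The exact published 32-profile design and 64-state cTTO set are not
  public; the balanced random design is a stand-in, so design-specific
  efficiency properties of the original study are not reproduced.
* Point estimates of the original coefficient tables cannot be reproduced
  without the raw survey data; the estimators are validated by parameter
  recovery instead.
* Log-normal mixing reports location/scale on the log scale; it is not a
  numerical reproduction of the originally published log-normal column,
  whose reporting convention is unclear.
* No handling of incomplete pick sequences or missing ASCOT items, and no
  imputation; responses enter whole or not at all.
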