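# Methods

`crt-effects` estimates treatment effects in two-arm cluster randomized
trials (CRTs): trials in which intact groups — clinics, communities,
facilities — are randomized, while covariates and a binary outcome are
measured on the individuals inside them. This note documents the model,
the estimators, the synthetic data-generating processes, and the numerical
and design choices the package makes.

## Estimands

For cluster j with N_j participants, the cluster-level outcome is a
weighted sum `Yc_j = sum_i alpha_ij * Y_ij`; the default weight
`alpha_ij = 1/N_j` makes `Yc_j` the within-cluster proportion. Two
families of effects are supported, on the ratio (default) or difference
scale:

* **Cluster-level effect** — contrast of `E[Yc(a)]`, each cluster
  weighted equally, e.g. `E[Yc(1)] / E[Yc(0)]`.
* **Individual-level effect** — contrast of pooled participant-level
  means `E[Y(a)]`, each participant weighted equally.

When cluster size varies — and especially when it modifies the treatment
effect ("informative cluster size") — these two effects differ in both
interpretation and magnitude, so the target must be chosen before the
estimator. A cluster-level analysis targets the individual-level effect
by carrying the analysis weights `J/NT * 1/alpha_ij` (with the default
alpha, `J*N_j/NT` per cluster) through every step of the analysis;
conversely a pooled individual-level analysis targets the cluster-level
effect by weighting each participant by `alpha_ij`.

## TMLE estimators

All three TMLEs are logistic-fluctuation, double-robust plug-in
estimators. The generic recipe: (1) fit an initial outcome regression;
(2) fit (or fix at the known design value 0.5) the propensity score; (3)
update the initial fit by one weighted logistic regression of the outcome
on the two "clever covariates" `H(1) = 1(A=1)/pi`, `H(0) = 1(A=0)/(1-pi)`
with the initial logit as offset — a single MLE with both covariates
solves the efficient score equation exactly, no iteration is needed; (4)
average the targeted predictions; (5) estimate the variance from the
per-cluster influence function (IF), `D(a) = H(a)(Y - mu*) + mu* - psi(a)`.

* `cluster_tmle` aggregates to one row per cluster and runs the recipe at
  the cluster level (cluster covariates and/or alpha-weighted means of
  individual covariates, suffixed `c`, may be adjusted for).
* `hierarchical_tmle` runs the recipe on the pooled participant rows,
  then aggregates the individual-level IF to the cluster — the
  independent unit — before taking the variance. Analysis weights enter
  every step (initial fit, fluctuation, averaging, IF); with the default
  alpha and a cluster-level target this weights each participant by
  1/N_j, so the empty-adjustment special case reproduces the unadjusted
  cluster-level estimator exactly.
* `hybrid_tmle` fits the individual-level outcome regression, aggregates
  its predictions within clusters (`muc_j(a) = sum_i alpha_ij mu(a, E_j,
  W_ij)`), and then proceeds exactly like the cluster-level TMLE.

Ratio contrasts use the delta method on the log scale: the per-unit IF of
the log ratio is `D(1)/psi(1) - D(0)/psi(0)`; the SE is the sample SD of
these contributions over sqrt(n); CIs exponentiate a symmetric t interval.
The reference distribution is t with J-2 degrees of freedom, a deliberate
finite-sample hedge for trials with 10-30 clusters.

Numerical guards: cluster outcomes exactly 0 or 1 are nudged into
[1e-6, 1-1e-6] before the logit offset; estimated propensities are
truncated to [0.05, 0.95]; an outcome regression that separates falls back
to the unadjusted candidate with a warning; an empty propensity
specification means the known 0.5 — it is never estimated. Outcomes must
lie in [0, 1] (binary or proportions); unbounded continuous outcomes are
rejected because the logistic fluctuation is not defined for them.

## Adaptive Prespecification

With few clusters, the adjustment set cannot be chosen well a priori.
The analyst instead prespecifies a small candidate library (always
including the unadjusted model) and a CV scheme — leave-one-cluster-out,
or leave-one-pair-out when the randomization pairs are kept. Stage 1
scores every outcome candidate by the cross-validated mean squared
held-out IF of the log-ratio contrast, computed with the known propensity
0.5; stage 2 holds the winner fixed and scores the propensity candidates
the same way (candidates are re-fit within every training fold). Ties
break toward the smaller adjustment set, then lexicographically, favoring
parsimony. Selection is deterministic given the data: folds are defined
by cluster identity. The default candidate shape is singleton adjustment
sets — at most one covariate in the outcome regression and one in the
propensity — which is where the efficiency gains concentrate in trials
of this size.

Inference for the selected TMLE does not reuse the full-sample IF
variance of the winning fit: the same data picked the winner, so that
variance is optimistic and its CIs undercover. Instead the winner's own
cross-validated loss — the mean squared held-out IF, an honest estimate
of the per-unit variance — is the SE basis for the ratio-scale contrast
(divided by J for leave-one-cluster-out; for leave-one-pair-out the fold
value is a squared pair sum, so by 4·J/2). In replicated trials this
restores nominal-or-conservative coverage and Type-I control while
leaving the point estimate untouched. Fixed-adjustment TMLEs keep the
standard full-sample IF variance.

## Matched-pair designs

Both simulation processes pair-match clusters on a baseline covariate
(exact minimum-weight perfect matching on |difference|, blossom algorithm
up to 200 clusters, sorted-adjacent pairing — the 1-D optimum — beyond)
and randomize one cluster per pair. Analyses may break the matches
(clusters independent, df = J-2) or keep them: the pair-level IF
contribution is the average of its two clusters' contributions, the
variance uses n = J/2 and df = J/2-1. When within-pair IF contributions
are negatively correlated — the purpose of matching on outcome
predictors — the kept-pair variance is smaller; with useless matching the
two variances agree in expectation. The pair-average convention (rather
than the pair sum) is what makes the kept-match variance estimate the
sampling variance of the same point estimator.

## Classical comparators

* **Unadjusted contrast** — arm means of (analysis-weighted) cluster
  outcomes; delta-method log-ratio inference. Identical (to numerical
  precision) to any of the TMLEs with empty adjustment sets.
* **Geometric-mean log t-test** — Welch t-test on arm means of log
  cluster outcomes; exponentiation targets the ratio of geometric means, a
  different estimand from the arithmetic-mean ratio (AM >= GM).
* **CARE** — pooled logistic outcome regression *excluding treatment*;
  per-cluster ratio residuals observed/expected events; Student t-test on
  log residuals. Also targets the geometric-mean ratio.
* **GEE** — log-link Poisson-variance working model on pooled rows
  (the standard relative-risk GEE for a binary outcome), independence
  working correlation by default, robust sandwich variance with the
  Fay-Graubard small-sample correction: each cluster's score is inflated
  by `(1 - min(0.75, H_jj))^(-1/2)` before entering the meat, so the
  corrected variance never undercuts the naive sandwich. Wald inference
  against t(J-2).
* **Augmented GEE** — the marginal (treatment-only) log-link GEE score
  minus the augmentation term `sum_a [1(A_j=a) - 0.5] *
  D'V^{-1}(mu(a,E,W) - mu(a))`, with the conditional regressions from a
  pooled logistic fit; solved with a Newton root-finder started at the
  GEE solution. Restores the marginal interpretation of `exp(beta_A)`
  under covariate adjustment; with no covariates it reduces to GEE
  exactly.

GEE and Aug-GEE target individual-level effects only; weighting GEE
toward cluster-level effects is known to be bias-prone and is deliberately
not offered.

## Synthetic data-generating processes

Two hierarchical processes emulate a pair-matched CRT with J = 20
clusters of widely varying size; both are documented in
`crt_effects.dgp`, and all distribution parameters are read as mean/SD.

* **Study 1** (mean size 150, SD 80, floor 30): cluster covariates
  E1~N(2,1), E2~N(0,1); latent cluster factors UE1~U(-0.2,1.5),
  UE2~U(-0.5,0.5); individual covariates W1~N(2·UE1, 0.35),
  W2~N(4·UE1, 0.9), W3, W4~N(UE2, 0.5); outcome
  `P(Y=1) = expit(-0.75 - 0.35A + 0.8W1 + 0.4W2 - 0.3E1 - 0.2A·W2)`.
  W1 and W2 proxy the same latent factor, so adjusting for either (or
  their cluster means) removes nearly all between-cluster heterogeneity —
  adaptive selection splits between them and never picks the noise pair
  W3/W4. Pairs are matched on E2, which is deliberately unrelated to the
  outcome. The published account of this process garbles the
  latent-factor declarations; the package follows the printed covariate
  equations literally, under which the true cluster-level and
  individual-level ratios are ~0.77 and the geometric ratio ~0.75, and the
  resulting operating characteristics (unadjusted power and coverage,
  adaptive-selection splits, CARE and log-t-test power) line up with the
  published table. The alternative resolution of the garbled line
  reproduces the published truth values (~0.83/0.81) instead but
  contradicts those operating characteristics, so it was rejected.
* **Study 2** (informative cluster size; mean size 400, SD 250, floor
  30): E1, E2~N(0,1); three independent latent factors U(-1,1) behind
  W1-W3 (SD 0.5); outcome
  `P(Y=1) = expit(0.5 + W1/6 + W2/2 + W3/4 + E1/5 + E2/5 - Ñ/8 - A·Ñ/5)`
  with Ñ = N/150. Risk falls with cluster size and the treatment effect
  strengthens with it, so the cluster-level ratio (~0.78) and the
  individual-level ratio (~0.69) diverge.

Truth values are computed on a large generated population (2500 clusters
for Study 1, 1000 for Study 2) from coupled counterfactuals: one uniform
draw per individual evaluated under both treatment assignments, so under
the null variant (all treatment terms zeroed) the true ratios are exactly
1. Cluster sizes are clamped at 30 and rounded; the truth population is
generated without pair-matching (matching does not change the estimand).

What the generators do not emulate: missing outcomes, participant
selection, time-varying covariates, more than two arms, unequal
allocation. Passing the replication tests therefore says nothing about
robustness to those features of real trials.

## Replication harness and reported metrics

`run_study` regenerates the trial with seed `base + r` for replicate r
and is bit-reproducible from the base seed. Per estimator it reports the
mean point estimate and bias on the ratio scale, the SD of log estimates
(sigma) and the mean log-scale SE (sigma-hat), CI coverage of the truth,
and the rejection rate at the 5% level. Estimator failures in a replicate
are excluded from aggregates and counted. Default replicate counts in the
shipped tests and the acceptance script are 200-500, with truth
populations at 2500/1000 clusters; these sizes keep the Monte Carlo error
of a rejection rate near one to two percentage points.

## Known limitations

* Candidate libraries are small by design; many-covariate adjustment
  (screening, lasso-style selection) is out of scope.
* The matched-pair variance uses the pair-average IF construction; no
  attempt is made to re-estimate nuisance parameters within pairs.
* GEE options cover independence and exchangeable working correlation
  only, log link only.
* CARE requires at least one observed event per cluster (log residuals);
  the arithmetic-residual variant is not implemented.
* The cross-validated variance for the adaptive TMLE is implemented for
  ratio contrasts only; a difference-scale adaptive analysis falls back
  to the full-sample IF variance.
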