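# Methods

## Setting and notation

A cluster randomized trial (CRT) assigns a binary intervention `A^c` to
each of `N` clusters (communities, clinics, schools) and measures
outcomes on individuals within clusters.  For each participant we
observe baseline covariates `W`, post-baseline covariates `M`, a
measurement indicator `Delta`, and the outcome `Y` only when
`Delta = 1`; at the cluster level we observe baseline covariates `E^c`
and the randomized arm `A^c`.  Outcome measurement is typically
*differential*: the intervention can change both outcomes and the
chance that they are measured, often through the same post-baseline
pathway `M` (for example, care engagement raises both viral
suppression and the chance of a viral-load measurement).  Complete-case
analyses are then biased, and the bias is not removed by standard CRT
regressions because `M` simultaneously mediates the treatment effect
and confounds the missingness–outcome relationship.

## The two-stage estimator

**Stage 1 (per cluster).**  Within one cluster the arm and cluster
covariates are constants, so the data reduce to `(W, M, Delta,
Delta*Y)` and the target is the cluster endpoint

    Y^c = E[ E(Y | Delta = 1, W, M) ],

the mean outcome had everyone been measured, identified under
missingness-at-random given `(W, M)` within the cluster plus
positivity.  `Y^c` is estimated with a targeted minimum loss-based
estimator (TMLE):

1. outcome regression `Qbar0(W, M) = E(Y | Delta=1, W, M)` by Super
   Learner on the measured participants;
2. measurement mechanism `g(W, M) = P(Delta=1 | W, M)` by Super Learner
   on all participants, truncated below at `g_min`;
3. fluctuation: an intercept-only logistic submodel with offset
   `logit(Qbar0)` fit to the measured participants with weights `1/g`
   (the weighted variant of the fluctuation; it solves the same
   estimating equation as the unweighted clever-covariate submodel and
   is the more stable choice under small measurement probabilities);
4. endpoint `Yhat^c` = mean of the targeted predictions over *all*
   `S^c` participants.

After the fluctuation the inverse-probability-weighted residual
`(1/S^c) sum_j (Delta_j / g_j)(Y_j - Qstar_j)` — the efficient
influence function's estimating equation — is zero to solver precision;
the per-cluster fit records it, along with the fluctuation coefficient
and the number of truncated `g` values, as diagnostics.  The estimator
is doubly robust within each cluster: it is consistent if either
`Qbar` or `g` is estimated consistently.  Because each cluster is
analyzed completely separately, the missingness mechanism may differ
arbitrarily across clusters, at the price of needing clusters large
enough to fit two regressions each.

Variants supplied for other endpoint types: the complete-case empirical
mean (valid under MCAR; used by the comparators), the Kaplan–Meier
cumulative risk at a horizon for survival endpoints under
nondifferential right-censoring (via `lifelines`), and ratio-type
endpoints for cross-sectional designs (for example suppressed-and-
infected over infected), estimated as the ratio of two per-cluster
TMLEs with the numerator event nested in the denominator event.
TMLE for *differential* censoring of survival endpoints is not
implemented.

**Stage 2 (across clusters).**  The trial reduces to one record per
cluster, `O^c = (E^c, W^c, A^c, Yhat^c)`, with `W^c` cluster-level
summaries (by default within-cluster means) of the individual baseline
covariates.  The treatment-specific mean `psi(a) = E[E(Yhat^c | A^c=a,
E^c, W^c)]` is estimated by a cluster-level TMLE: a logistic working
regression of the `[0,1]`-scaled endpoint on arm (and at most one
adjustment covariate) is fluctuated with the two clever covariates
`A^c/g^c` and `(1-A^c)/(1-g^c)`, where `g^c` is the known randomization
probability (0.5) unless an adjusted propensity working model is
selected, in which case it is estimated and bounded to `[0.1, 0.9]`.
Effects are reported as the risk difference `psi(1) - psi(0)` or the
risk ratio `psi(1)/psi(0)`.  With no adjustment covariates the TMLE
collapses exactly to the difference (ratio) of arm means of the
cluster endpoints.  Each cluster contributes equally regardless of its
size, matching the aggregate-then-analyze convention for CRTs.

**Adaptive Prespecification.**  With few clusters the adjustment set
cannot be chosen by hand without risking over-fitting.  From a
prespecified candidate list of cluster-level covariates the procedure
selects, by leave-one-out cross-validation, the single-covariate
working models for the outcome regression and then the propensity
score whose TMLE has the smallest cross-validated variance of the
estimated influence curve.  The unadjusted choice is always a
candidate and wins ties, so by this criterion the procedure can only
match or improve on the unadjusted estimator; if no covariate helps it
returns the unadjusted TMLE.  Concretely, for each candidate the
held-out cluster's influence-curve value is evaluated at the
training-fold nuisance fits and the full-data point estimates, and the
sample variance of these held-out values is the selection loss.  When
the matched randomization is preserved, selection leaves out one
*pair* at a time and the loss is the variance of pair-averaged
influence-curve values, aligning the selector with the matched
variance estimator.  The search is sequential (outcome regression
first, then propensity score), following the procedure's original
description; an exhaustive search over pairs would cost little here
but is not the cited procedure.

**Inference.**  The estimator is asymptotically linear with cluster-
level influence curve

    IC(a) = I(A^c=a)/g^c(a) * (Yhat^c - Qstar(a)) + Qstar(a) - psi(a),

combined across arms as `IC(1) - IC(0)` for the risk difference and,
via the delta method on the log scale, `IC(1)/psi(1) - IC(0)/psi(0)`
for the risk ratio.  Breaking the matches: the variance estimate is
the sample variance of the `N` cluster ICs divided by `N`, with a
Student's t reference on `N - 2` degrees of freedom.  Keeping the
matches: ICs are averaged within each of the `J = N/2` pairs, the
variance is the sample variance of pair ICs over `J`, and the
reference is t with `J - 1` degrees of freedom.  Risk-ratio intervals
are formed on the log scale and exponentiated.  The asymptotics
additionally require the Stage-1 contribution to the remainder to be
negligible (fast-enough nuisance rates, weak within-cluster
dependence, and clusters large relative to their number); these
conditions are documented, not checked, and they are shared by any
two-stage CRT analysis including the t-test on complete-case means.

## Comparators

* **Unadjusted t-test** — pooled-variance two-sample t-test on the
  complete-case cluster means (`N - 2` df), or a paired t-test on
  within-pair differences (`N/2 - 1` df).  Welch variances are
  available behind a flag; the pooled form is the classic CRT t-test
  and matches the degrees-of-freedom convention above.
* **CARE** (covariate-adjusted residuals estimator) — a pooled
  individual-level logistic regression of `Y` on the baseline
  covariates (never the treatment) over measured participants; each
  cluster's residual is its complete-case mean outcome minus the mean
  model prediction over the same measured participants; residuals are
  compared by arm with the same t-tests.  Prediction is averaged over
  the measured subset only, matching the complete-case endpoint; with
  an empty covariate list CARE reduces exactly to the unadjusted
  t-test.  Whether the original description used pooled or unequal
  variances is unstated; pooled is used.
* Mixed models, GEE and doubly robust GEE are deliberately not
  re-implemented: they are off-the-shelf package fits with default
  standard errors, and the benchmark's aggregation works from
  per-replicate records, so externally computed estimates can be
  scored through the same tables if desired.

## The synthetic-data generator

Each cluster draws three latent variables — `U1, U2 ~ Unif(-1, 1)`
shifting the means of the individual baseline covariates
`W1 ~ N(U1, 0.5)`, `W2 ~ N(U2, 0.5)` (0.5 is a standard deviation),
and `U3 ~ N(0, 1)` inducing residual within-cluster dependence and
driving the pair matching.  Observed cluster covariates `E1^c, E2^c`
are the within-cluster empirical means of `W1, W2`.  Cluster sizes are
drawn uniformly from {100, 150, 200}; a trial has `N = 30` clusters,
pair-matched by adjacent ranks of `U3` with one cluster per pair
treated.  The structural equations (probabilities through the
inverse-logit):

    M     : -1 + 2*A + W1 + W2 + 0.2*(1 - A)*(E1 + E2) + 0.25*U3
    Y     :  1 - 2.5*A + 4*M + 0.5*W1 + 0.5*W2 + 0.2*E1 + 0.2*E2 + 0.25*U3
    Delta :  A * invlogit(3 - 3*M - 0.5*W1 - 0.5*W2)
           + (1-A) * invlogit(-2 + 3*M + 0.5*W1 + 0.5*W2)

Treatment raises the mediator, the mediator raises the outcome and —
differentially by arm — the chance the outcome is measured, so
complete-case contrasts are badly biased.  Counterfactual `M`, `Y` and
`Delta` under both arms are generated from shared uniform draws, so
observed data equal the counterfactual at the realized arm exactly and
the cluster-level true outcomes `Y^c(a)` are deterministic given the
draws.  Truth (`psi(a)`, risk difference, risk ratio) is computed from
a generated population of 5000 clusters; its Monte-Carlo error is
accepted (the truth test uses a +-0.5pp tolerance on the risk
difference).  A `null_effect` switch removes every treatment term from
the `M` and `Y` equations (the measurement mechanism stays
differential), giving a true risk difference of exactly 0 for type-I
error studies.  Coefficients of every equation can be overridden for
user variants; no survival or ratio-endpoint presets are provided.

What the generator does *not* emulate: informative cluster sizes,
more than two arms, individually randomized designs, non-logistic
link structures, unmeasured individual-level confounding of
missingness (within a cluster, `(W, M)` suffices by construction), or
outcome missingness mechanisms that depend on the outcome itself.
Passing the benchmark therefore shows correct behaviour under a
favourable-but-hard missingness structure (MAR given measured
covariates, highly differential by arm), not robustness to
outcome-dependent missingness.

One caveat found while validating the generator: the structural
equations above imply mean measured fractions of about 62% in the
intervention arm and 32% in the control arm (confirmed by direct
Monte-Carlo integration of the equations, independent of the trial
generator), and correspondingly the control-arm measurement
probabilities reach the truncation floor for a nontrivial share of
individuals.  The equations are kept exactly as specified because the
same equations reproduce the reference true effects and complete-case
biases; the measured-fraction test records the original 70%/43%
expectation and fails honestly.

## Super Learner

Candidate learners: the empirical mean, a main-terms logistic
regression, and an additive logistic model with cubic B-spline terms
(interior knot at the median; a covariate with fewer than 10 distinct
values enters linearly, since a smoother on a near-binary covariate is
unstable).  Risks are V-fold cross-validated negative log-likelihoods
(V = 5, folds stratified on the outcome) with predictions bounded to
`[1e-4, 1 - 1e-4]`.  The default is discrete selection — the single
learner with the lowest CV risk — which is simpler to audit at
per-cluster sample sizes; a convex combination minimizing the CV loss
over the simplex is available.  A learner that fails on a fold is
dropped with a warning; a degenerate (constant) outcome short-circuits
to a bounded constant predictor.  The benchmark's default library is
{empirical mean, main-terms logistic}, which keeps 500 replicates at
desk scale; the spline learner can be added back via a flag.

## Numerical choices

* Working logistic fits (including fractional/quasi-binomial outcomes)
  use a compact Newton–Raphson IRLS with step-halving; a singular or
  non-convergent fit is retried with a small ridge penalty (1e-4) and
  a warning.  Coefficients are verified against statsmodels GLM in the
  test suite.
* The Stage-1 fluctuation is a monotone one-dimensional root problem
  solved by Newton with a bisection fallback; the Stage-2 fluctuation
  is the two-parameter offset logistic fit above.
* `g_min = 0.025` truncates estimated measurement probabilities
  (positivity protection; configurable).  Stage-2 estimated propensity
  scores are bounded to `[0.1, 0.9]`; the known randomization
  probability is used untruncated when no propensity covariate is
  selected.
* Outcomes outside `[0, 1]` are linearly rescaled before the logistic
  fluctuation and back-transformed afterwards.
* Ties in Adaptive Prespecification break toward the unadjusted choice,
  then candidate-list order.  With fewer than 4 clusters, or if every
  candidate's leave-one-out fits degenerate, the unadjusted spec is
  returned with a warning.
* Unmeasured outcomes are an explicit absent state (empty CSV cells,
  `None` per record, compacted measured-only vectors internally) —
  never a sentinel number — so an unmeasured outcome cannot silently
  enter an estimator.
* Reproducibility: one top-level seed per benchmark; per-replicate
  generators are spawned from a `SeedSequence`, so results are
  bit-reproducible and independent of which estimators are requested.

## Problem sizes

The benchmark defaults to the study's full scale: 500 replicates of
N = 30 clusters with sizes in {100, 150, 200}, truth from 5000
clusters, measurement rates from 200 trials, and a separate
500-replicate null-effect run for type-I error; one full benchmark
takes a few minutes on a single core.  Property tests use smaller
fixtures (single clusters up to S = 5000 for the double-robustness
checks, 100-replicate selection studies).

## Known limitations

* Stage-1 adjustment happens within each cluster separately, so very
  small clusters or rare outcomes force strong assumptions; a pooled
  single-stage TMLE is out of scope.
* The cluster-level propensity score is only relevant for restricted
  randomization or finite-sample imbalance; the implementation assumes
  a randomized `A^c` (no observational extension).
* Candidate adjustment sets are single covariates by default; working
  models with several covariates are possible in principle but not
  exposed, matching the recommendation for CRTs with few clusters.
* Comparator output is risk-difference only; relative-scale comparator
  results belong to the regression estimators that are not
  re-implemented.
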