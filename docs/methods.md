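# Methods

## Model family and estimation

All four models share the proportional-hazards form
h(t | X, G) = h0(t) · exp(Xᵀa + Gᵀb), with X the p standardized clinical
covariates, G the m standardized expression levels, and an arbitrary
baseline hazard h0 that is eliminated by working with the log partial
likelihood. Ties in event times are handled by the Efron correction by
default (Breslow available everywhere via `ties="breslow"`); the two
coincide exactly when no event times are tied, which is the generic case for
continuous follow-up. The implementation computes the partial-likelihood
value, its gradient in the linear predictor, the diagonal of the negative
Hessian (the IRLS weights), and the negative Hessian projected onto an
arbitrary design — the n×n Hessian is never materialized; all risk-set sums
are cumulative sums over the time-sorted sample, so a likelihood/gradient
evaluation is O(n log n) and a projected Hessian O(events · q²) for a
q-column design.

**Clinical-only Cox** (`CoxPH`): safeguarded Newton–Raphson with
step-halving; convergence when the gradient max-norm falls below 1e-8, cap
50 iterations; coefficients larger than 50 in absolute value flag monotone
likelihood (separation) and mark the fit non-converged. Wald standard
errors come from the inverse observed information.

**Penalized Cox** (`CoxElasticNet`): maximizes, in glmnet's scaling,
(1/n)·pl(Xa + Gb) − λ·Σ_j[α|b_j| + (1−α)/2·b_j²]. Clinical effects are
never penalized by default: they are the benchmark every comparison is made
against, and shrinking them would handicap it. The solver is an outer IRLS
loop (quadratic expansion of the partial likelihood around the current
linear predictor, using the exact Hessian diagonal as weights) around a
cyclic coordinate-descent inner loop with soft-thresholding and active-set
iteration, written as a numba kernel. λ_max — the smallest λ with all gene
coefficients zero — is the max absolute gene-gradient of (1/n)·pl at the
clinical-only fit divided by α; the default grid is 100 log-spaced values
down to 0.01·λ_max. Convergence is max coefficient change < 1e-6.

Two safeguards matter when m ≫ n: below some λ the penalized MLE stops
existing (quasi-separation; the linear predictor diverges), so the solver
detects runaway predictors and returns the last stable iterate; and a
warm-started path fit stops early once 99% of the null deviance is
explained, with a per-λ sweep budget (default 500) so the statistically
useless saturated tail cannot dominate runtime. Both affect only the deep
end of the path, far below where held-out tuning ever selects.

Tuning follows a subsampling strategy: `n_subsample` (default 20) random
80/20 splits of the training data; the whole path is fitted on each 80% and
scored on the 20% by held-out C-index (default) or held-out partial
likelihood deviance; the λ with the best mean score wins. `coxlasso` is
α = 1, `coxenet` is α = 0.5.

**Mixed-effects Cox** (`MixedCox`): b_j ~ N(0, σ²_b) i.i.d. With
K = G Gᵀ = U L Uᵀ (rank r ≤ n) and Z = U L^{1/2}, the genetic predictor is
G b = Z z with z ~ N(0, σ²_b I_r), and the prior mass of b orthogonal to the
rows of G integrates out exactly — the reduction to r dimensions involves
no approximation beyond Laplace itself. The inner problem (joint penalized
mode of (a, z) at fixed σ²_b) is the same safeguarded Newton with a ridge
1/σ²_b on the z coordinates; the minimal-norm gene effects are recovered as
b = Gᵀ U L^{-1/2} z. The Laplace marginal is

    pl(η̂) − ẑᵀẑ/(2σ²_b) − (r/2)·log σ²_b − ½·log det(H_zz + I/σ²_b)

with H_zz the negative partial-likelihood Hessian in the z block only
(fixed effects are refitted jointly at each σ²_b, and the curvature
correction is taken over the random effects — the integrated-partial-
likelihood convention). Plain ML, no REML-style correction. The outer
problem is 1-D bounded Brent on log(m·σ²_b) — the per-sample genetic
variance, the interpretable scale — over [1e-8, 1e3], tolerance 1e-4 in
the log; an optimum at a bound is flagged `at_boundary` (legitimately so
for null data, where the variance estimate is effectively zero).

Known behavior: the Laplace ML variance component shows the usual
small-sample downward attenuation — at n=400, m=500, 30% censoring the mean
estimate over 20 datasets is ≈0.77 for a true per-sample variance of 1.0,
tightening toward truth at larger n (≈0.88 at n=1000). Recovery checks are
therefore stated on the mean over replicates with a band wide enough for
this attenuation, and PGE inherits a proportional share of it.

## Variance partition

On the log-hazard scale the survival variation decomposes into the clinical
share v_c = var(Xᵀâ) (sample variance of the fitted clinical predictor),
the transcriptomic share v_g = m·σ̂²_b (the model-based per-sample genetic
variance; the empirical variance of G·b̂ is shrunken and available only as a
sensitivity option), and a residual constant. The residual defaults to
π²/6 ≈ 1.645 — the variance of the standard Gumbel minimum-extreme-value
residual that underlies proportional hazards on the log scale — and is
configurable, since other conventions exist. Then

PCE = v_c/(v_c+v_g+c), PGE = v_g/(v_c+v_g+c), PVE = PCE+PGE (an identity,
asserted to machine precision).

Confidence intervals use the delete-one jackknife over samples: each
replicate re-standardizes the reduced dataset and refits the full mixed
model including σ²_b; SE² = (n−1)/d · Σ(θ_(i) − θ̄)², where d is the number
of deletions (a seeded random subset when n > `max_delete`, default 100 —
the (n−1)/d scaling keeps the estimator unbiased for the full-jackknife
variance under random deletion choice); the CI is the normal approximation
around the full-sample estimate. Applied to the sample mean, this machinery
reproduces the classical s/√n exactly, which the suite asserts to 1e-10.

## Evaluation harness

**C-index.** A pair is permissible iff the member with the strictly smaller
observed time had an event; pairs with tied times are never compared
(strict-ordering convention). Concordant means the shorter survivor has the
strictly higher risk score; score ties count ½. The implementation is
checked exactly against brute-force pair enumeration (including tied times
and tied scores) and against scikit-survival on tie-free instances (that
reference additionally compares event-vs-censored pairs at tied times, a
deliberate convention difference).

**MCCV.** `n_rep` (default 100) random 80/20 splits; one shared split per
replicate across models; penalized-model tuning runs entirely inside the
training fold. Splits whose training or test part has fewer than 2 events
are redrawn (cap 10); stratified splitting by event status is available but
off by default. Per-replicate seeds derive from one master seed through
`numpy.random.SeedSequence.spawn`, so results are bit-reproducible. Global
standardization of the full dataset before splitting is the default (the
preprocessing convention for the pan-cancer matrices this mirrors); a
`fold_standardize` option learns the transform on each training fold
instead, for leakage-free evaluation.

**Permutation control.** Rows of G are shuffled jointly (one seeded
permutation), preserving gene–gene correlation while destroying any
gene–outcome association; the MCCV is repeated on the permuted copy with
identical splits.

**Gene-number sweep.** Per replicate: split; rank genes by univariate
(single-gene, unadjusted) Cox Wald p-values computed on the training fold
only, or draw a seeded random subset; fit the mixed model on the selected
columns; score on the test fold. Grid values above m are clipped with a
warning.

## Synthetic data generator

The generator draws from exactly the model the estimators assume, so every
recovery test has a well-defined truth: X standard normal; G multivariate
normal with exchangeable correlation ρ (or block correlation, blocks of 50,
as a co-expression-module stand-in); gene effects polygenic
(b_j ~ N(0, v_g/m)), sparse (k causal genes sharing v_g), or null; latent
times by inverse-transform sampling under an exponential or Weibull
baseline; censoring independent exponential with the rate solved
numerically (Brent) so the expected censored fraction over the realized
latent times hits the target (realized fractions land within ±0.03 at
n=1000). A scalar `a_true` is interpreted as the total clinical variance
split equally over the p covariates. True PCE/PGE are computed under the
same decomposition convention as the estimator (residual π²/6), making
recovery tests internally consistent rather than a claim about any external
convention. The generator returns standardized matrices; truths refer to
the generative population scale.

What the generator does *not* emulate: RNA-seq count noise and
normalization artifacts, batch effects, informative censoring, and real
co-expression structure beyond exchangeable/block correlation. Passing
recovery and ordering tests therefore demonstrates correctness of the
estimators under their own assumptions, not robustness to real-data
violations of them.

## Experiment scales and conditions

The heavy experiments run at a deliberate desk scale chosen to keep the full
suite in minutes while leaving each effect well above Monte Carlo noise:

- variance/PGE recovery: 20 datasets, n=400, m=500, per-sample genetic
  variance 1.0, clinical variance 1.0, 30% censoring;
- model ordering: n=400, m=500, clinical variance 0.5, genetic variance 1.0,
  20 MCCV replicates; the penalized models use a reduced tuning workload
  (25-λ path to 0.05·λ_max, 5 subsamples) — the selected λ sits well inside
  this range;
- permutation control and sweep: same sizes; the sweep's sparse condition
  uses per-sample genetic variance 2.0 across 10 causal genes.

That last choice is substantive, not cosmetic: with 10 causal genes sharing
variance 1.0 at this sample size, individual causal effects are marginally
undetectable, and in-fold univariate ranking selects mostly winner's-curse
noise genes — ranked-then-fit then genuinely *underperforms* random
selection (a real selection-bias phenomenon, reproduced and verified
directly). Pre-ranking helps precisely when marginal effects are
detectable, so the sweep condition doubles the sparse signal. Similarly,
under fully polygenic truth the elastic net's edge over the clinical
benchmark is small by construction (no individual gene is worth selecting),
while the mixed model's edge is large; the ordering experiment reflects
both.

## Data handling conventions

Expression matrices are read from the genes-in-rows TSV dialect (first
column gene identifiers) with duplicate identifiers and non-numeric cells
rejected by name, and round-trip float parsing. Clinical tables require
sample id, survival time and event status; status strings (alive/dead etc.)
map through a configurable dictionary; gender/stage/grade are dummy-coded
against the lexicographically first level, with an ordinal-stage option;
rows missing required fields are dropped and counted; no imputation is
performed. Merging intersects sample sets (clinical order wins). QC removes
genes with zero-expression fraction strictly above 0.5, then genes whose
variance lies strictly below the 20% quantile of the *survivors'* variances
— the filters are sequential and order matters. Standardization is
column-wise to sample mean 0/variance 1 with the transform retained for
held-out rows. Datasets with n strictly greater than 175 and an adequate
event proportion are labelled low-censored; because "proportion of censored
event less than 15%" admits two readings for observational registries, the
comparison (event fraction ≥ threshold, the default, vs censored fraction <
threshold) is an explicit config switch rather than hard-coded.

## Known limitations

- The Laplace ML variance component is attenuated in small samples (see
  above); no bias correction is attempted.
- The jackknife CI is normal-theory; for PGE near 0 it can cross zero.
- The elastic-net path in the quasi-separated regime returns last-stable
  iterates rather than polished solutions (which do not exist there).
- Time-varying covariates, stratified baselines, left truncation,
  competing risks and time-dependent accuracy measures are out of scope.
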