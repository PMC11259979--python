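# Methods

`mdsustain` implements subtype and stage inference for progressive diseases
from cross-sectional biomarker data — a mixture of event-sequence models in
which each cluster ("subtype") is a strict ordering of Z-score events and
each subject occupies a discrete stage along their subtype's ordering — with
first-class support for missing biomarker values via marginalisation, and a
synthetic benchmark comparing that approach against deletion and imputation.

## Model

Data are a matrix of covariate-corrected Z-scores `x_ij` (subject `j`,
biomarker `i`), referenced to a control population so that 0 means "normal"
and larger values mean more abnormal.  Each biomarker `i` is given a set of
event levels `Z_i1 < Z_i2 < … < Z_iR_i` (defaults 1, 2, 3) and a ceiling
`z_max_i` (default 5).  An *event* is the biomarker's expected trajectory
reaching one of its levels.  A subtype is an ordering of all
`N = Σ_i R_i` events.

The expected trajectory `g_i(t)` of biomarker `i` is piecewise linear on an
arbitrary pseudo-time axis `t ∈ [0, N+1]`: anchored at `(0, 0)`, passing
through `(p, Z)` for each of the biomarker's events at sequence position
`p`, and ending at `(N+1, z_max_i)`.  There is no calendar time anywhere in
the model; stage `k ∈ {0, …, N}` occupies the interval `[k, k+1]`, and
stage 0 means "no events reached" (normal appearing).

An observed value is Gaussian around the trajectory,
`P(x_ij | t) = N(x_ij; g_i(t), σ_i)`, with `σ_i = 1` by default (the data
are control-referenced Z-scores; override per biomarker when a control
cohort suggests otherwise).  The data likelihood of a `C`-subtype model with
mixture fractions `f_c` and stage prior `P(k)` is

    P(X | M) = Π_j Σ_c f_c Σ_k P(k) ∫_{k}^{k+1} Π_i P(x_ij | t) dt

with independence across biomarkers (no residual covariance) and across
subjects.

### Missing data

A missing `x_ij` contributes the constant density `1 / z_max_i` — a uniform
distribution over the biomarker's Z-score range — in place of the Gaussian
factor.  Because the constant does not depend on `t`, the sequence, or the
subtype, it factors out of every posterior: missing entries are inert for
sequence estimation, while the subject's observed biomarkers still drive
their subtype and stage assignment.  A fully missing record therefore
receives exactly the prior, `P(c, k) = f_c / (N+1)`, and the model remains
fittable and appliable at any missingness level.  The constant is
`1 / z_max_i` as configured, not renormalised to the observed data range and
not truncated; an alternative would be a proper uniform on `[0, z_max_i]`
evaluated only inside the interval, which is identical for values in range.

The benchmark comparators are ordinary data transforms: complete-case
deletion; column-mean imputation; and K-nearest-neighbour imputation with
two feature variants — the 3-vector (mean, range, SD) of each subject's
observed values, or the raw Z-score rows with distances over
pairwise-complete coordinates rescaled by `sqrt(I / shared)`.  KNN details
the source description leaves open, fixed here: neighbours must observe the
target biomarker; all lookups read the original (pre-imputation) matrix, so
imputation order cannot matter; distance ties keep the lower subject index;
`K = 5` by default and if fewer neighbours are eligible all of them are used
(with a warning).  Subject-level summary features use the population SD
(`ddof = 0`) so single-observation subjects get 0 rather than NaN.

## Numerics

* **Stage integral.**  Midpoint rule: the integrand is evaluated once per
  stage at `t = k + 0.5` (interval width 1).  On piecewise-linear
  trajectories whose kinks sit at integer positions this is exact to
  O(h²) within each stage; `quad_points > 1` switches to an n-point
  midpoint composite for verification (tested against adaptive quadrature).
* **Log space.**  All likelihood accumulation uses log densities and
  log-sum-exp; natural-scale densities appear only at API edges.  The
  per-sequence log-likelihood factors as
  `const_j + (x/σ²)·μ − ½ (mask/σ²)·μ²`, two small matrix products, which is
  what makes the greedy search affordable (~0.3 ms per candidate ordering at
  500×10, N = 30).
* **Stage prior.**  Uniform `1/(N+1)` by default; configurable.
* **Assignments.**  ML subtype and stage are the arg-max of the joint
  `(C × N+1)` posterior table, ties to the lowest index.  (Arg-maxing the
  stage-summed subtype marginal instead changes benchmark accuracy by at
  most ~1.5 points; the joint convention is kept for its direct reading.)
* **Credible sets.**  The 0.95 credible set takes cells in decreasing
  probability order until the mass is reached; ties break deterministically
  by flat cell index, giving the minimal set (a uniform posterior over 20
  cells yields 19 cells).

## Fitting

* **Sequence search.**  Greedy ascent with random restarts
  (`n_startpoints`, default 25): from a uniform-random valid ordering, take
  each event in turn (random order), try every reinsertion position that
  respects within-biomarker level order, keep the best move, and repeat
  until a full pass yields no improvement.  The objective is the weighted
  sum of per-subject log stage-marginals under the uniform stage prior.
* **EM.**  Responsibilities `r_jc ∝ f_c Σ_k P(k) P(x_j | seq_c, k)`, then
  `f_c ← mean_j r_jc` and per-subtype re-optimization of the sequence by
  hill climbing from its current state with weights `r_jc`.  Stops when the
  log-likelihood improves by less than `em_tol` (default 1e-6) or after
  `n_em_iter_max` (default 100) iterations; the trace is nondecreasing up to
  numerical tolerance.  An emptied cluster is re-seeded with a random
  sequence and a warning.
* **Model building.**  `C = 1` is fitted directly.  Each subsequent `C`
  splits every cluster of the `C−1` solution in turn: `n_split_trials`
  (default 5) uniform-random bipartitions of the cluster's ML-assigned
  subjects each seed an internal 2-subtype EM on the subset; the best split
  by subset likelihood initializes one full-cohort EM refit, and the best
  refit over clusters wins.  If no split improves the likelihood, the
  largest cluster is duplicated (which reproduces the `C−1` likelihood
  exactly), so the per-`C` maximum likelihood is nondecreasing.  Model
  choice is by comparing these likelihoods; no cross-validation criterion is
  provided.
* **Uncertainty.**  Metropolis–Hastings over orderings: per iteration one
  randomly chosen event of one randomly chosen subtype moves to a random
  valid position, the fractions receive Gaussian noise (sd 0.01, clipped at
  0, renormalised), and the joint proposal is accepted with
  `min(1, L_new/L_old)`.  The default chain length is 100 000.  Outputs are
  the sample trace and, per subtype, the event×position frequency matrix
  (the positional variance diagram).  The fraction proposal is only
  approximately symmetric near the simplex boundary; the chain is used for
  uncertainty display, not for estimates.
* **Determinism.**  All randomness flows from one seeded generator;
  identical seed, options and data give bit-identical results.

## Synthetic benchmark design

The generator reproduces the validation design the uniform missing-data
likelihood was benchmarked on: `J = 500` subjects, `I = 10` biomarkers,
levels (1, 2, 3) and `z_max = 5` for every biomarker (`N = 30`), `C = 3`
subtypes with independent uniform-random valid orderings and mixture
fractions `f_c = (2 + (C−c)) / (2C + Σ_c (C−c))` — `(4/9, 3/9, 2/9)` at
`C = 3` — stages uniform on `{0, …, N}`, unit Gaussian noise with identity
covariance, and exactly 150 (3%) or 2000 (40%) cells deleted completely at
random.  Subjects are generated at their stage's representative timepoint
`k + 0.5`, matching the likelihood quadrature (stage-0 subjects are noise
around `g(0.5) ≈ 0`); a `continuous_t` flag samples `t` uniformly within the
stage instead.

What the generator does **not** emulate: between-biomarker residual
covariance, non-random (MAR/MNAR) missingness, covariate effects,
measurement floors/ceilings, and any calendar-time structure.  Passing the
benchmark therefore shows correct recovery under the model's own
assumptions, not robustness to their violation.

## Evaluation metrics

* **Sequence similarity**: `1 − (discordant event pairs) / (N(N−1)/2)` —
  a [0, 1] normalized Kendall similarity (1 = identical, 0 = reversed),
  computed per cluster after matching and also averaged.
* **Cluster matching**: the Hungarian algorithm on the estimated-vs-true
  confusion matrix (subject agreement), so accuracy is invariant to label
  permutations.
* **Subtyping accuracy**: percent of scored subjects whose matched estimated
  subtype equals the truth.  ML-stage-0 ("normal appearing") subjects are
  excluded by default — no abnormality means no subtype — configurable.
* **Staging error**: mean and sample SD (ddof = 1) across individuals of
  the absolute difference |estimated − true| stage, pooled and per subtype.
  (An error magnitude is the natural reading of a staging "mean diff"; a
  signed convention would hide compensating errors.)
* **Longitudinal consistency**: a follow-up is subtype-consistent if it
  keeps the baseline ML subtype or the baseline was normal appearing;
  stage-consistent if the ML stage did not regress; CI-consistent if the
  0.95 credible sets of the two visits intersect.
* **Modality ablation**: mask one modality's biomarkers, re-assign under the
  uniform likelihood, and report subtype agreement, mean |Δstage|, and the
  fraction of subjects whose full-data assignment lies in the ablated
  credible set.

## Preprocessing

Per biomarker, OLS on the control subjects with complete covariates;
covariates with two-sided coefficient `p ≥ 0.05` are dropped in a single
pass and the model refitted (iterated elimination behind a flag).  The
control residual mean and SD (ddof = 1) define the Z-transform, so the
fitting controls score mean 0 / SD 1 identically.  Decreasing biomarkers are
multiplied by −1.  Missing raw values stay missing; a subject missing a
retained covariate loses that biomarker's Z-score (logged).  Event config
derivation: `z_max` is the rounded (half away from zero) 95th percentile of
the observed Z-scores (linear-interpolation quantile), the event levels are
the candidate levels (1, 2, 3, 5) strictly below `z_max`, and a biomarker
whose ceiling does not clear the smallest level is excluded with a warning.
The α = 0.05 threshold, the quantile method and the rounding convention are
this package's choices; only "significant associations" and a "rounded 95th
percentile" are externally specified.

## Problem sizes used by the test suite and acceptance script

The analytic and oracle tests run on instances small enough for exhaustive
enumeration (N ≤ 9, J ≤ 25).  Parameter-recovery tests use single- and
two-subtype cohorts of 200–300 subjects with 5 biomarkers.  The strategy
comparison runs at a reduced scale (200 subjects × 5 biomarkers, 2 subtypes,
3 repetitions) chosen so the whole suite completes in well under half an
hour on one CPU, and the full-design reproduction (500 × 10, 3 subtypes)
runs on 3 cohort realizations with 8 greedy restarts and 8 split trials per
fit — enough that further search effort changes the attained likelihood
only marginally — and without the MCMC pass, which does not enter the
point-estimate metrics.  `scripts/acceptance.py` runs one full-design
realization end to end at the same search effort.

At the reduced benchmark scale one comparison inverts relative to the
full design: with only 5 biomarkers, complete-case deletion still retains
~8% of subjects at 40% missingness and scores them from complete records,
which beats scoring every subject from ~3 observed markers; at the full
design's 10 biomarkers deletion is simply infeasible at 40%
(0.6¹⁰ ≈ 0.6% of subjects complete).  The accuracy reachable at 40%
missingness also sits several points below the full-data value for purely
informational reasons, and varies by ~5 points (SD) across realizations of
the random-ordering design — the separability of random orderings differs
from draw to draw — so single-realization reference numbers carry that
uncertainty.

## Known limitations

* Arbitrary pseudo-time: stages order events but have no clock; stage
  differences are not durations.
* No biomarker covariance; correlated residuals will inflate confidence.
* The uniform missing-value density assumes missingness carries no
  information (MCAR/MAR-like); informative missingness biases assignments.
* Greedy + EM finds local optima; restarts and split trials trade time for
  reliability, and hard problems (heavy missingness, many subtypes) may need
  more of both.
* The MCMC fraction proposal is approximate near the simplex boundary.
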