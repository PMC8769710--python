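# Methods

This note records the statistical conventions, default parameters and
numerical choices behind `survfilter`, and what the synthetic-data tests
do and do not establish about real data.

## Data model and target transformations

A data set holds a continuous feature matrix `X` (n × p, common
unscaled measurement scale), observed times `T = min(T_true, C) > 0` and
event indicators `Δ = 1(T_true ≤ C)`.  Left truncation, interval
censoring, competing risks and missing values are out of scope.

Several filters need an uncensored surrogate outcome.  We use the
null-model martingale residual `M_i = Δ_i − Ĥ(T_i)`, where `Ĥ` is the
Nelson–Aalen cumulative hazard `Ĥ(t) = Σ_{t_j ≤ t} d_j / r_j` — the
Breslow baseline of a covariate-free Cox model.  Tied event times use
the Breslow increment `d_j / r_j`: closed-form, standard, and identical
to the Efron convention when event times are unique.  (Survival-analysis
software often defaults to Efron; with heavily tied data the residuals
can differ slightly.)  The residuals sum to zero by construction and are
bounded above by 1.

For the mutual-information filters, residuals and features are cut into
`q = max(min(⌊n/3⌋, 10), 2)` equal-width bins over their observed range
(`n/3` floored, since a bin count must be integral).  Intervals are
right-closed with the minimum included in bin 1; this fixed convention
makes the categorization bit-exact reproducible.  Constant features
cannot be binned by range and receive a single category — zero mutual
information with everything, so they are never preferred.

Cross-validation folds are stratified on the event indicator: each
stratum is shuffled with the seed and dealt round-robin, so per-fold
event counts deviate from proportionality by at most one.  Fold counts
exceeding a stratum size are allowed with a warning.

## Filter scores

* **variance** — sample variance (denominator n−1).  Only sensible when
  features share an unscaled common scale; the generator below
  deliberately never standardizes columns.
* **correlation** — |Pearson correlation| between a feature and the
  martingale residuals.
* **cox.score** — the score-test statistic `U(0)²/I(0)` of the
  univariate Cox model, with risk-set means and population variances
  accumulated over event times (Breslow ties).  Affine-invariant in the
  feature.
* **carss** — correlation-adjusted regression survival scores:
  1. IPC weights from the Kaplan–Meier estimate `Ĝ` of the censoring
     distribution on the log-time scale: `w_i = Δ_i / Ĝ(log t_i⁻)`,
     normalized to sum 1 (censored observations weigh 0).
  2. Weighted marginal correlations of each feature with `log T`:
     weighted covariance and weighted target variance, unweighted
     (population-form) feature variance — with equal weights this is
     exactly the Pearson correlation.
  3. Shrinkage intensity λ of the feature correlation matrix toward the
     identity by the analytic Ledoit–Wolf/Schäfer–Strimmer estimator
     `λ = Σ_{k≠l} V̂ar(r_kl) / Σ_{k≠l} r_kl²`, clamped to [0, 1] and
     computed with Gram-matrix identities in O(n²p).
  4. Scores `|R_shrink^{−1/2} R_{X,log T}|` with
     `R_shrink = λI + (1−λ)R`, evaluated through the SVD of the
     standardized feature matrix in the n-dimensional sample space —
     no dense p × p matrix is formed, so p ≫ n is routine.  A dense
     eigendecomposition oracle verifies the route in the tests.

  Constant features score 0 in all four filters ("no evidence" rather
  than an error keeps full-matrix filtering total).

* **Random survival forest** importances come from an in-package forest:
  bootstrap samples, survival trees that exhaustively scan
  midpoint-of-consecutive-values thresholds on `mtry` sampled features
  and split by the maximal two-sample log-rank statistic, leaves storing
  member Nelson–Aalen curves.  Splitting stops below `2·min_node_size`
  rows or without a positive-statistic split leaving both children
  `min_node_size` rows.  *impurity* sums the split log-rank statistics
  per feature; *permutation* averages the out-of-bag drop of Harrell's C
  (risk = leaf cumulative hazard summed over training event times) after
  permuting a feature, one seeded permutation per (tree, feature).
  Defaults: 500 trees, `mtry = ⌊√p⌋`, `min_node_size = 3`; tests use far
  smaller forests.
* **boosting** — first-order gradient boosting on the Cox
  partial-likelihood loss: each round fits a depth-limited least-squares
  regression tree (scikit-learn) to the martingale-type gradients
  `g_i = Δ_i − Ĥ₀(T_i) e^{f_i}` and advances the scores by the step
  size; importance is each feature's summed squared-error split gain.
  Defaults 2000 rounds / step 0.05 / depth 10; tests use ≤ 50 rounds.
  This is a deliberately simplified analogue of second-order
  implementations — the importances are defined by the construction
  (split-gain sums), not by numeric parity with any external library.
* **Mutual-information filters** use plug-in entropies in bits
  (`0·log 0 := 0`) from empirical contingency tables, joint quantities
  through composite variables, and no smoothing.  The six greedy
  selectors start from the argmax-MI feature and add, per iteration, the
  candidate maximizing their criterion (mean-redundancy-corrected
  relevance; joint-MI sum/min; joint-MI normalized by the 3-way joint
  entropy, sum/min; conditional-MI min).  Argmax ties go to the lowest
  column index.  When a full ranking is needed, the greedy prefix is
  followed by the remaining features in first-iteration relevance order
  (or the greedy run is extended to k = p).

## Ridge Cox model and metrics

The penalized partial log-likelihood (Breslow ties) is maximized by
damped Newton iterations; convergence at max |penalized gradient| <
1e-8 within 100 iterations, otherwise an error reporting the gradient
norm.  Risk-set second moments are accumulated segment-wise with BLAS
products, and the exponential terms are max-centered for overflow
safety.  The Breslow baseline at the solution defines
`Ŝ(t|x) = exp(−Ĥ₀(t) e^{xᵀβ})`.

The penalty is chosen on a 100-point log-spaced grid descending by a
factor 1e-4 from `λ_max = 100 · max|U(0)|` — the smallest top-of-grid
penalty whose ridge solution `≈ U/λ` is numerically negligible; a
larger multiplier would compress the informative part of the path into
the bottom of the grid.  The held-out criterion is the
Verweij–van Houwelingen partial-likelihood deviance
`−2 [pl(all; β̂_{−k}) − pl(train_{−k}; β̂_{−k})]`, averaged over
event-stratified folds, with warm starts along the path; deviance ties
resolve to the larger penalty.  Fold counts exceeding the event count
are reduced with a warning.

The Brier score at horizon t weights past events by `1/Ĝ(t_i⁻)` and
still-at-risk observations by `1/Ĝ(t)`, with `Ĝ` the Kaplan–Meier
estimate of the censoring distribution on the *training* outcome.  The
IBS integrates BS(t) by the trapezoid rule over the unique test event
times up to τ (the largest test time with `Ĝ(τ) > 0`) and divides by
the grid span; this time-average guarantees the [0, 1] range.  The
grid and weighting conventions are held fixed across all filters so
comparisons are internally consistent.  Harrell's C counts pairs
`(i, j)` with `t_i < t_j, Δ_i = 1`; risk ties score 1/2.

## Stability and similarity

SMA-Count averages, over all unordered pairs of selected sets, the
chance-corrected score
`S = (|Vi ∩ Vj| + Adj − E) / (√(|Vi||Vj|) − E)`, where the adjustment
`Adj = min{A(Vi,Vj), A(Vj,Vi)}` counts features unique to one set with a
partner in the other set's unique features at similarity ≥ θ (default
θ = 0.9, |Pearson correlation| computed on the data the sets were
selected from).  The expectation `E[|Vi ∩ Vj| + Adj]` under random
equal-cardinality selections uses the exact hypergeometric mean
`|Vi||Vj|/p` for the intersection and seeded Monte Carlo (default 1000
draws) for the adjustment, which has no simple closed form under
arbitrary similarity structure.  Identical sets score exactly 1 by
algebraic cancellation, independent of the Monte-Carlo estimate.

The OL score between two rankings is
`Σ_{k=1..r} w_k |Li[1..k] ∩ Lj[1..k]|` with linearly decreasing weights
`w_k = (r+1−k) / Σ_i i(r+1−i)` and default r = 100.  It is computed as
an integer numerator over the closed-form denominator
`r(r+1)(r+2)/6`, so identical rankings score exactly 1.0 in floating
point.  Method-by-method mean OL matrices are ordered by single-linkage
clustering on distance 1 − OL (dendrogram leaf order).

## Benchmark design

Each filter's single hyperparameter `prop` (proportion of features
kept, `n_select = max(1, round(prop · p))`, half rounds up) is tuned by
nested, event-stratified cross-validation over the squared grid
`{0.01, …, 1}²` (denser near zero): features are ranked on each inner
training part, a ridge Cox model is fitted on the top features for
every grid value, and the grid value minimizing mean inner-validation
IBS wins, ties to the smallest `prop` (sparser models).  The outer loop
refits on the outer training part and records validation IBS, the
wall-clock time of filtering + fitting + predicting, and the selected
set; the per-inner-fold selected sets at the chosen `prop` feed the
stability analysis.  Baselines: ridge Cox on all features (no `prop`)
and the feature-free Kaplan–Meier curve.  The same fold assignments are
used for every method (fingerprinted in the records), and all child
seeds derive from the master seed by stable hashing keyed on
(purpose, filter, fold), so removing one method never changes
another's records; failures are isolated per record.

Aggregations across data sets: the pairwise-wins matrix (rows ordered
by row sums), per-filter relative mean IBS (best filter per data set
at 0) and relative log10 median runtime (fastest at 0) with
min/median/max spreads, and summaries of the tuned proportions.

Default design is 10 outer × 10 inner folds with the 100-point grid.
The test suite exercises a reduced problem — n = 120, p = 300, three
filters plus both baselines, 3 outer / 3 inner folds, a 10-point grid,
and a 3-fold, 20-point ridge-penalty search — chosen so a complete
nested run with all contracts checked finishes in minutes on one core
while exercising every code path of the full design.

## Synthetic data generator

Features are block-correlated Gaussians (`√ρ`-weighted shared block
factor plus idiosyncratic noise; default block size 10, ρ = 0.7) scaled
by a log-normal standard-deviation profile (σ = 0.4) — heterogeneous
and never standardized, since the variance filter is only meaningful on
an unscaled common scale.  True event times follow a Cox model with
Weibull baseline (shape 1.5, scale 0.1) by exact inversion sampling;
effect sizes are per standard deviation of the feature (default: 3
informative features with |β| = 1 and alternating sign, each leading a
distinct correlated block).  Censoring is independent exponential — the
IPCW estimators in scope assume random censoring — with the default
rate 0.39 fixed once by the package's own bisection calibration to an
event fraction of ≈ 0.35, the middle of the range typical of
TCGA-style cohorts (0.10–0.50); `calibrate_censoring` retargets any
rate in that range.

What the generator does **not** emulate: real expression marginals
(skewness, zero-inflation), batch effects, RNA/miRNA composition, or
censoring that depends on covariates.  Passing recovery tests on this
generator therefore show that a filter detects proportional-hazards
signal in correlated Gaussian designs under random censoring — not that
it wins on any particular real cohort.

## Known limitations

* The IPC-weighted marginal correlations inside `carss` are intrinsically
  high-variance under heavy censoring: raw weights `1/Ĝ(t⁻)` grow large
  at late event times, shrinking the effective sample size well below
  the event count.  On p ≫ n data with moderate signal, the extreme
  null correlations can then reach the signal level, so top-k recovery
  of individual features is unreliable at event fractions ≤ 0.5 even
  though the score remains consistent and performs well when selecting
  larger feature fractions.  The package implements the weighting
  exactly as defined and does not truncate weights.
* Martingale residuals use Breslow tie handling throughout; Efron-based
  references may differ slightly on tied data.
* The boosting and forest components are simplified analogues; their
  importances agree with the defining constructions, not with any
  external implementation's numbers.
* Wall-clock runtimes recorded by the benchmark are hardware-dependent
  and only meaningful as relative comparisons within one run.
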