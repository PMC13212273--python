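# Methods note

This note records the statistical model, the default parameters and the
numerical choices behind `profilex`, including the places where the
implementation makes a judgement call and why.

## 1. Latent profile model

The three indicators — APS, GPS and UWES-S scale totals — are z-scored
(SD with denominator n−1) and modelled as a K-class Gaussian mixture
with **diagonal covariance and class-invariant variances**:

- local independence: indicators are conditionally independent given
  class (diagonal Σ);
- equal dispersion: σ_j² is shared by all classes, pooled in the
  M-step with denominator n.

This is the most parsimonious standard LPA parameterization
(class-varying means only), with (K−1) + 3K + 3 free parameters. It is
also the assumption under which the synthetic generator draws its
indicators, so generator and model are matched by construction.

Fitting is EM to a relative log-likelihood tolerance of 1e-8 with at
most 1,000 iterations and 50 random starts (defaults). Variances are
floored at 1e-6 and a fit that touches the floor is flagged. All
starts for one fit (and, in the BLRT, all bootstrap datasets) run as
one vectorized batch of "chains" that iterate in lockstep and drop out
as they converge.

### Start strategy

Half of the starts use random soft assignments (Dirichlet(1)
responsibilities). Random assignments place every class mean near the
grand mean, and on strongly separated data EM can converge to a
genuine spurious optimum where classes split on noise instead of on
the real structure. The other half of the starts therefore initialize
the class means at K records chosen by k-means++ distance-squared
sampling, with pooled variances and uniform weights. Mixing the two
strategies keeps the cheap-and-unbiased soft starts while making
well-separated optima reliably reachable.

### Class enumeration

For K = 1…K_max the report shows log-likelihood, AIC (−2ℓ+2p), BIC
(−2ℓ+p·ln n), sample-size-adjusted BIC (−2ℓ+p·ln((n+2)/24)),
normalized entropy E = 1 − Σ(−p_ik ln p_ik)/(n ln K) and the BLRT
p-value. Entropy is refused (not given a convention) for K=1.

The chosen K walks up from 1: K+1 is accepted only when the BLRT for
K+1 is significant at α=0.05 **and** every class share of the
(K+1)-class solution is at least 5% — tiny classes can win on fit
indices while being uninterpretable.

### BLRT

The parametric bootstrap compares K against K−1: B datasets are drawn
from the fitted (K−1)-class model and p = (1 + #{LR_b ≥ LR_obs})/(B+1).
Two decisions matter for calibration and cost:

- **Symmetry.** The observed and the bootstrap datasets are fitted
  with *identical* EM settings (5 starts, tolerance 1e-6, 500
  iterations). Fitting the observed data more thoroughly than the
  bootstrap data inflates LR_obs relative to the simulated null
  distribution and makes the test anti-conservative; exchangeability
  of the whole fitting procedure is what keeps the p-value calibrated.
- **Batching.** All B bootstrap fits for each model order run as one
  batched EM computation, which is what makes 100-replicate BLRTs
  inside a 5-model enumeration affordable on one CPU.

A replicate whose fit fails is dropped; more than 10% dropped is an
error. Note the p-value floor is 1/(B+1): with B=19 the smallest
reachable p equals 0.05, so enumeration at α=0.05 needs B ≥ 39.

### Labeling

For the 2-class solution, the class with higher mean APS and UWES-S
and lower mean GPS is labeled "High Self-Regulators". If the three
orderings disagree, the UWES-S ordering (the most separated indicator)
decides, with a logged warning.

## 2. Univariate statistics

- **Chi-square**: Pearson with Yates continuity correction exactly on
  2×2 tables (the correction clamps |O−E|−0.5 at 0 per cell); larger
  tables are uncorrected. Any zero expected count is an error that
  points to Fisher's test.
- **Fisher exact**: 2×2 via the hypergeometric two-sided rule
  (probabilities ≤ observed). r×c tables are enumerated exactly
  (recursive fill over the margins, 1e-7 relative slack on probability
  ties) when the total is ≤ 200 and the enumeration bound (product of
  per-row compositions) is ≤ 2×10⁵; otherwise a Monte-Carlo p with 1e5
  fixed-margin draws and the (1+#)/(B+1) estimator, flagged in
  `notes`. SciPy's own r×c path is Monte-Carlo and unseeded, so it is
  not used.
- **Mann-Whitney**: U from midranks; tie-corrected normal Z with no
  continuity correction, Z = (U₂ − n₁n₂/2)/√[n₁n₂/12·((n+1) −
  Σ(t³−t)/(n(n−1)))]; the sign convention makes Z positive when the
  second sample (High profile) ranks higher. Agrees with SciPy's
  asymptotic method to machine precision.
- **Sparse-cell screen**: a categorical variable with any
  profile-by-level cell below 10 is excluded from multivariate
  modelling (kept for description); ordinal/continuous variables are
  always candidates. Applied to the published cross-tabs this yields
  the 9-variable candidate set.

## 3. Bootstrap relaxed-LASSO stability selection

Outcome: 1 = Low Self-Regulators. Binary predictors stay 0/1 (odds
ratios per category); other predictors are z-scored on the fitting
sample and coefficients are reported per raw unit (β_raw = β_std/SD).

Per bootstrap replicate (B=1000 default):

1. resample n records with replacement (single-class samples are
   redrawn; >5% redraws is an error);
2. re-standardize the continuous columns on the bootstrap sample;
3. tune λ by 10-fold stratified CV over a 100-point geometric grid
   from λ_max = max_j |x_jᵀ(y−ȳ)|/n down to 0.001·λ_max;
4. fit the L1-penalized logistic regression at λ*, record the active
   set;
5. refit the selected columns unpenalized (Newton-Raphson with
   step-halving) and de-standardize.

Aggregation per predictor: selection frequency (retained iff ≥ the 50%
vote threshold); median odds ratio, percentile 95% CI and empirical
two-sided p over the non-separated replicates where it was selected
(p floored at 2/m for m such replicates).

### Penalty rule: 1-SE, not the deviance minimizer

λ* defaults to the **largest λ within one standard error of the CV
deviance minimum**, not the minimizer itself. With n=517, a 12:1 class
imbalance and 9 candidates, the deviance minimizer systematically
overselects: on synthetic cohorts with three real predictors and six
nulls, null predictors reach 56–73% selection frequency under the
minimizer — above the 50% retention vote — while the 1-SE rule leaves
nulls at ≤ 20% and keeps the real predictors at 84–100%. Only the
1-SE rule reproduces the qualitative ">90% for real predictors, <50%
for the rest" pattern that motivates majority-vote retention.
`rule="min"` remains available.

### Solver

The L1 solver is IRLS with cyclic coordinate descent and
soft-thresholding (glmnet-style), an unpenalized intercept, weight
floor 1e-5, and warm starts along the decreasing λ grid; it is
compiled with numba. Convergence is the largest coefficient change in
a sweep < tol (1e-7 for final fits). KKT violations of returned fits
are ≤ 1e-5. The soft-threshold comparison carries a 1e-12 relative
slack so that λ ≥ λ_max yields the null model exactly. CV paths run
at tol 1e-5: held-out deviance is insensitive to coefficient precision
(the chosen λ was verified identical at tol 1e-7/1e-5/1e-4), and the
looser tolerance halves CV cost. The unpenalized refit flags a
replicate as separated when any |β_std| exceeds 15; separated
replicates count toward selection frequency but not toward the OR
aggregates.

## 4. Synthetic cohorts

The generator draws covariates from simple marginals (Bernoulli rates
and rounded/clipped Gaussians matched to the survey's Table-2
margins), then each record's class, then the indicators from the
class-conditional Gaussians, rounded and clipped to each scale's legal
range.

- **Class model**: either fixed shares or a logistic link on the
  covariates. In the link, predictors are centered at their
  theoretical means so each exp(coef) is the literal generating odds
  ratio per raw unit; the intercept is **calibrated by bisection** on
  a fixed 200k Monte-Carlo draw so the marginal Low share hits its
  target (a plain logit(0.919) intercept would miss it by several
  points — Jensen's inequality).
- **Defaults**: n=517; Low share 91.9%; class means (37,24,106) High /
  (29,30,68) Low with shared SDs (4,6,10); Low-membership ORs 0.79
  (GSES, per point), 0.93 (PSSS), 0.81 (exercise days), all other
  covariates null.
- **Clipping**: under the defaults the analytic probability that an
  indicator draw falls outside its legal range is ≈0.9% averaged over
  the three indicators (highest for APS in the small high class). Note
  that clipping shifts the realized High-class APS mean to ≈36.6, so
  exact-mean oracles must use the clipped-Gaussian expectation.
- **Streams**: seeds are spawned per predictor and per stage
  (SeedSequence), so adding a predictor or a pipeline stage never
  perturbs the other streams; the same seed yields a byte-identical
  table.

## 5. Pipeline

`run_all` executes cohort → LPA enumeration → assignment → univariate
screen → sparse exclusion → stability selection → figures → summary,
with per-stage seeds derived as sha256(master_seed:stage_name) mod
2³¹. Outputs are plain CSV/JSON/SVG plus a markdown summary; the
manifest records config, seeds, files, timings and warnings. Any stage
error aborts with the stage named; partial outputs are preserved. The
full default run (n=517, B=1000, BLRT 100) is a single-CPU run of a
few minutes, byte-identical across repeats.

## 6. Limitations

- The generator draws covariates independently; real survey covariates
  are correlated. Marginals and class effects are faithful, joint
  structure is not.
- The downstream profile labels used in selection come from the modal
  LPA assignment; classification error (~0.5% at the default
  separation) slightly attenuates odds ratios.
- BLRT power depends on the shallow bootstrap fit settings; data whose
  class structure lives on a single noisy dimension may need more
  bootstrap starts (`n_starts_boot`).
- The Mann-Whitney p is the asymptotic normal approximation; exact
  small-sample p-values are out of scope.
- The r×c Fisher enumeration bound is a work cap, not a statistical
  threshold; beyond it the Monte-Carlo p carries 1/√B noise.
- With the default 91.9%/8.1% class split the minority class holds only
  ~35–45 records, so a single synthetic draw can realize a
  bootstrap-stable spurious association in a null covariate (observed:
  a null covariate with Mann-Whitney |Z|>3 in the generated data, as
  strong as a designed effect) or wash out a weak true effect.
  Structure-recovery checks over a handful of cohort draws therefore
  have a non-trivial failure probability at this n and imbalance; the
  selection frequencies track the realized univariate structure of
  each draw.
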