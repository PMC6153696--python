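# Methods

## The problem

Untargeted MS-based metabolomics matrices of population cohorts typically
lose 20–30% of their entries. Three mechanisms dominate: values below the
instrument's limit of detection (LOD; left-censoring, missing-not-at-random),
run-day (batch) effects that move the effective LOD from day to day, and
unsystematic causes (sample preparation, peak alignment). How those missing
cells are filled changes every downstream estimate — correlations,
regression coefficients, partial-correlation networks, genetic association
p-values. `metimpute` packages (i) diagnostics that identify which mechanism
is at work, (ii) a simulator that generates data with those mechanisms under
known truth, (iii) a registry of 31 imputation method variants plus the
complete-case baseline, and (iv) three evaluation schemes: statistical
calibration on simulations, pathway modularity of Gaussian graphical model
(GGM) networks, and power/effect preservation in SNP–metabolite regression.

## Data model and preprocessing

A `MetaboliteMatrix` holds samples × metabolites abundances, an explicit
boolean missingness mask, and a per-sample run-day label. Preprocessing
follows the standard pipeline for this data type: each metabolite is divided
by its run-day median (computed on observed values of that day), values are
natural-log transformed (abundances are approximately log-normal; the log
base only shifts the scale), and outlier samples are excluded when their
Mahalanobis distance exceeds `mean + 4·SD` of the distance distribution.
Because Mahalanobis distance is undefined under missingness, it is computed
on the submatrix of fully observed metabolites; when none exists, a
pairwise-complete covariance with 10% diagonal shrinkage is used instead.
Correlation-based analyses restrict to metabolites with strictly more than
10% and strictly less than 70% overall missingness: below that window the
mechanism is unidentifiable, above it too little is observed.

## Missingness diagnostics

The censored values themselves are unobservable, so LOD tendency is read off
an *auxiliary* metabolite — the best-correlated partner (pairwise-complete
Pearson r, minimum 0.3, at least 3 shared observations, ties broken toward
the lower column index). A one-sided Wilcoxon–Mann–Whitney test asks whether
the auxiliary reads *lower* where the target is missing (one-sided because
left-censoring predicts a direction; a two-sided variant is available via
the `alternative` flag), with Bonferroni correction over the tested family.
Run-day diagnostics report, per metabolite and day, the missing fraction
normalized by the metabolite's median per-day missing fraction (1 = an
average day), the SD of per-day fractions, and the correlation across days
between day mean and day missing fraction — strongly negative values are
the fingerprint of a day-varying LOD.

## Simulator

Complete data are multivariate normal with zero means and unit variances:
two main variables at correlation `rho` ∈ [0, 0.4], each with `n_aux`
auxiliary variables at `aux_corr`, realized by the factor construction
`aux = aux_corr·main + √(1−aux_corr²)·noise` (identical covariance to a
direct MVN draw; positive definite whenever |rho|, |aux_corr| < 1). Samples
are randomly assigned to `round(n/34)` run days of as-equal-as-possible
size, 34 being the typical batch size of a cohort-scale MS experiment.

Missingness is injected into the main pair, each column independently:

- **fixed_lod** — exactly the `round(q·n)` lowest values are masked.
- **prob_lod** — a cell is masked with probability Φ((c − x)/blur); the
  probit form is smooth and calibratable, `blur = 0.5` on the unit-variance
  scale reproduces the "blurred" censoring boundary seen in real data, and
  `c` is solved by bisection so the expected masked fraction over the
  realized column equals `q` to machine tolerance.
- **runday_fixed_lod / runday_prob_lod** — instrument sensitivity drifts
  between days: the recorded values acquire a day-level shift
  δ_d ~ N(0, runday_lod_sd²) and the (re-calibrated) global limit is applied
  to the shifted values. Relative to the true concentrations this is a
  day-specific LOD c_d = c − δ_d; carrying δ_d in the recorded values is
  what makes low-sensitivity days read low *and* lose more values, i.e. it
  reproduces the negative day-mean/day-missingness correlation that real
  data show. A pure threshold shift on unshifted values cannot: censoring
  from below *raises* the observed day mean, flipping the correlation
  positive. Default `runday_lod_sd = 0.3` encodes moderate between-day
  variability; the day shifts inflate the marginal variance to 1 + sd²
  (≈ 1.09) and attenuate the realized main-pair correlation accordingly,
  which is part of the condition being simulated, not corrected away.
- **random** — a uniformly random subset of `round(q·n)` cells, independent
  of the values (missing completely at random).
- **mixture** — per cell, the run-day probabilistic LOD mask with
  probability `mixture_weight = 0.5`, the random mask otherwise (the
  logistic-regression condition of the simulation design).

The SNP fixture draws genotypes Binomial(2, maf), age ~ N(61, 8.8²), sex ~
Bernoulli(0.5), and builds the metabolite from the additive model
`β₁·SNP + β₂·age + β₃·sex + ε` with the coefficients recorded as truth.

## Imputation methods

All 31 variants share two contracts: observed cells are never altered, and
every masked cell is filled in every completed dataset.

**Constant fills.** `mean` and `min` replace missing entries of a column by
its observed mean/minimum.

**LOD-assuming (RC/ITS/MITS).** The observed values of a column are modeled
as a left-truncated normal; `(μ, σ)` of the parent are estimated by
maximizing the truncated likelihood (Nelder–Mead on (μ, log σ), moment
start, 1e-8 objective tolerance; a censored-likelihood variant that also
scores the count below the LOD is available behind `censored=True`). The
LOD itself is unrecorded, so the minimum observed value within the fitting
scope stands in for it. RC fills every missing cell with the constant
E[x | x ≤ LOD] = μ − σ·φ(a)/Φ(a), a = (LOD−μ)/σ; ITS draws i.i.d. from the
parent conditioned below the LOD; MITS repeats ITS m = 20 times sharing one
fit. When Φ(a) underflows the LOD itself is imputed, with a warning.
Run-day variants (RC-R/ITS-R/MITS-R) fit and fill per run day wherever at
least 17 observations are available; leftover cells get the mean of the
available per-day conditional expectations (RC-R; the observed column mean
if no day qualified) or a chained-equations ICE-norm fill (ITS-R/MITS-R,
one per fill).

**Chained equations (ICE/MICE).** Incomplete columns are mean-initialized
and visited in random order for 10 sweeps; each visit regresses the column
on the others and refills its missing entries from the imputation model:
`norm` draws σ² from its scaled inverse-χ² posterior and β from
N(β̂, σ²(XᵀX)⁻¹) before adding residual noise; `pmm` performs type-1
predictive mean matching with a 5-donor pool (donated values are always
observed values, so fills stay in the data's support); `adjR` adds a
per-run-day random intercept estimated by shrinking day-mean residuals
toward zero with weight n_d/(n_d + λ), λ from a method-of-moments variance
decomposition — a deliberately simple stand-in for a full mixed model,
documented and swappable. Optional predictor screening keeps covariates
with pairwise-complete |r| ≥ 0.1 (useful for wide matrices; low-dimensional
simulated data keeps all columns). MICE runs m = 20 independent chains and
pools analyses by Rubin's rules; MICE-avg instead averages the 20 fills
cellwise into one dataset — simpler, but the averaging shrinks imputed-cell
variability and understates variances downstream.

**K-nearest neighbors.** Columns are standardized by observed mean/SD so
the e^(−d) weights are scale-free; fills are returned on the original
scale. Distances are Euclidean over shared observed coordinates, rescaled
by √(p_full/p_shared) to stay comparable under partial overlap; neighbor
ties break by index. `var` uses the K nearest *columns* observed at the
cell's row; `obs` the K nearest *rows* with the target column observed;
`obs-sel` restricts the distance to the 5–10 columns most correlated with
the target (|r| ≥ 0.2, topping up to 5 with the best-ranked when fewer
pass). K ∈ {1, 3, 5, 10, 20}.

**CCA.** The complete-case baseline imputes nothing; the analysis layer
deletes rows incomplete in the analyzed columns.

## Pooling

Rubin's rules combine m estimates q_i with within variances u_i:
q̄ = mean(q_i), W = mean(u_i), B = var(q_i), T = W + (1 + 1/m)B, classical
df (m−1)(1 + W/((1+1/m)B))²; when B = 0 (or df overflows) the normal
reference is used. Barnard–Rubin small-sample df is available behind a
flag; with m = 20 the difference is negligible. Correlations and partial
correlations pool on the Fisher-z scale with within variance
1/(n − 3 − k), k the number of conditioned variables, and back-transform.

## Evaluation schemes

**Simulation calibration.** Per scenario × method, `run_scenario` simulates,
censors, imputes and analyzes (Pearson, partial correlation given the
auxiliaries, linear regression, logistic regression on the
median-dichotomized second main; median ties go to 0, a measure-zero event
for continuous data). A null twin (rho = 0) of every replicate feeds the
type-1 error; the alternative feeds power and bias. Truths: rho for Pearson
and the regression slope (unit variances), the closed-form partial
correlation implied by the generating covariance for the partial analysis;
the logistic coefficient has no closed-form truth under this design, so its
bias is not reported. Logistic fits that separate or fail to converge are
dropped per-method and counted. The full experiment uses 250 replicates;
the packaged directional checks run 100 (problem sizes chosen to keep the
whole suite minutes-scale).

**Pathway modularity.** A GGM is estimated from completed data: partial
correlations from the inverse of a shrinkage correlation matrix (analytic
optimal shrinkage toward the identity, which keeps the estimate
well-conditioned at any n/p ratio), p-values from Fisher z with effective
df n − 3 − (p − 2), multiple fills pooled per edge, and edges kept after
Bonferroni at α/(p(p−1)/2). The original analysis used an empirical-null
significance procedure on shrinkage partial correlations; Fisher-z
p-values are used here as the documented, simpler equivalent. Modularity
Q = Σ_i [A(V_i,V_i)/A(V,V) − (A(V_i,V)/A(V,V))²] over pathway node sets,
with A counting adjacency entries (A(V,V) = 2·#edges). Uncertainty comes
from B = 1000 bootstrap resamples of the rows with re-imputation and
re-estimation per resample (percentile CI, widened to include the point
estimate when the resampling distribution is off-center; failed replicates
dropped and counted).

**SNP associations.** Additive model metabolite ~ β₀ + β₁·SNP + β₂·age +
β₃·sex, with metabolite values beyond 4 SD removed and the metabolite
z-scored, so β₁ is a standardized effect ("standardized" means z-scored
response on the raw 0/1/2 genotype; full standardization of the genotype is
a flag away). Multiple fills pool by Rubin's rules; bootstrap (500 draws by
default; the original count is unstated) provides variance estimates.
Power gain: r_p = −log₁₀(p_imp/p_CCA)/−log₁₀(p_CCA) (> 0 iff the p-value
dropped). Effect preservation: r_β = log₂|β_imp/β_CCA| (0 = identical).

## What the simulator does and does not emulate

It reproduces the *structure* of cohort-scale untargeted MS data that
matters for imputation: left-censoring with a blurred, day-varying limit,
batch sizes of ~34, realistic missing fractions (10–70%), correlated
auxiliary metabolites, and pathway-modular correlation blocks (in the
network tests). It does not emulate: heavy-tailed or skewed abundance
distributions beyond log-normality, correlated missingness *between*
metabolites (each target column is censored independently), drift within a
run day, matrix effects, or truly absent compounds (e.g. drug metabolites
with no correlated partners). Passing tests therefore certify behavior
under Gaussian, independently censored conditions — not under every
pathology of real data. Notably, with independently censored columns,
constant fills (min/RC) leave the null correlation test calibrated or
conservative — they destroy power and distort marginal distributions, but
cannot couple two columns; inflation of false positives from imputation
arises here through single multivariate imputation (ICE), which
understates estimate variability by treating one conditional draw as real
data.

## Numerical choices and degenerate inputs

Probit-threshold calibration by Brent bisection to 1e-12; truncated-normal
sampling via the inverse-CDF (scipy's truncated normal); Φ underflow guards
fall back to the LOD constant; singular design matrices in chained
equations get a small ridge with a warning; screening that removes every
predictor falls back to mean imputation with a warning; zero-variance
bootstrap inputs are rejected before resampling; Fisher pooling refuses
|r| = 1. All randomness flows from a single seed through named
`numpy.random.Generator` streams, so every method, scenario and bootstrap
is replayable.

## Known limitations

The adjR random intercept is a shrinkage approximation, not a REML mixed
model. The LOD surrogate (minimum observed value) biases the truncation
point upward at small n, which is one reason run-day-wise ML fits (17
observations per day) are unstable — an instability the evaluation is
designed to expose, not hide. GGM edge significance ignores the shrinkage
in its null distribution (p-values are mildly conservative at high
shrinkage). The logistic-regression analysis reports no bias for lack of a
closed-form truth.
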