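# Methods

## The model

`splicecor` tests whether alternative splicing of a predictor gene X
modulates its co-expression with a response gene Y across bulk-tissue
samples.  Let `y` and `x` be mean-centered total-expression (TE) vectors
over `n` samples, `Z` an `n x p` covariate matrix with intercept.  The
working model is the linear mixed model

    y = x * beta1 + diag(x) * b2 + Z * gamma + u + eps,

where `beta1` is the shared TE-TE slope, `b2 ~ N(0, sigma_Int^2 * Sigma)`
is a per-sample random slope, `u ~ N(0, sigma_u^2 * Sigma)` a per-sample
random intercept, and `eps ~ N(0, sigma_e^2 * I)` noise.  `Sigma` is the
n x n sample-sample covariance of X's isoform composition, measured
through LeafCutter-style intron excision ratios (IERs): samples with
similar splicing of X are modelled as having similar regression
coefficients on Y.  A nonzero `sigma_Int^2` means the TE-TE correlation
varies across samples with X's isoform composition — a TE-splicing
interaction.

### The splicing kernel

`Sigma` is not observable and must be built from the intron x sample IER
block of gene X.  The block is transposed, each intron standardized to
mean 0 / variance 1 (constant introns dropped — they carry no
between-sample information), and the Gram matrix `W W' / k` formed and
rescaled to `trace(Sigma) = n`.  Standardizing before the Gram product
stops high-variance introns from dominating the kernel, and the trace
normalization puts `sigma_u^2` and `sigma_Int^2` on a per-sample variance
scale comparable across genes with different intron counts; a
raw-covariance mode (`standardize=False`) is kept for sensitivity
analysis.  Introns of one cluster sum to 1 per sample and are therefore
linearly dependent; the Gram construction is indifferent to this rank
deficiency, so no intron is dropped for collinearity.  Eigenvalues below
`1e-8` of the largest are truncated to exactly zero, and the same
truncation applies to all downstream mixture weights.  The identical
construction applied to an arbitrary covariate block
(`kernel_from_covariates`) generalizes the test to any set of
sample-varying exposures; the covariate count may exceed `n`.

### The interaction test

`H0: sigma_Int^2 = 0` is tested with a variance-component score test.
With the null maximum-likelihood fit (fixed effects plus the
kernel-structured random intercept) giving residuals `r` and plug-in
covariance `V = sigma_u^2 Sigma + sigma_e^2 I`, the statistic is

    Q = r' V^-1 diag(x) Sigma diag(x) V^-1 r.

Under the null, `Q` is distributed as a weighted sum of independent 1-df
chi-squares.  The default weights are the eigenvalues of `B' P B`, where
`B` satisfies `B B' = diag(x) Sigma diag(x)` and
`P = V^-1 - V^-1 M (M' V^-1 M)^-1 M' V^-1` projects out the fixed-effect
design `M = [x, Z]`.  This is the form that accounts for the `diag(x)`
envelope and for fixed-effect estimation; a mode using the raw
eigenvalues of `Sigma` is exposed (`weights="kernel_only"`) for
comparison but does not calibrate and is not the default.  Calibration of
the default is verified by simulation: 2,000 null replicates at n=300,
k=5 give an empirical 5%-level rejection rate of ~0.052 and p-values that
pass a Kolmogorov-Smirnov uniformity check.

### The joint association test

Rewriting the model as `y = diag(x)(beta1*1 + b2) + Z gamma + u + eps`
shows the predictor's total effect is a random vector with covariance
`sigma^2 [(1-rho) 11' + rho Sigma]`, where

    rho = sigma_Int^2 / (sigma_Int^2 + sigma_X^2)

is the proportion of the predictor's contribution attributable to
splicing-induced inter-sample variation (`sigma_X^2` is the fixed slope's
squared magnitude).  The joint test targets fixed and random slope
simultaneously: its null model excludes `x` entirely (covariates plus
random intercept only), and for each `rho` on the grid {0, 0.1, ..., 1}
the quadratic statistic

    Q(rho) = r' V^-1 diag(x) [(1-rho) 11' + rho Sigma] diag(x) V^-1 r

gets a mixture-of-chi-squares p-value with projected weights as above.
Since the true mixing proportion is unknown, the grid p-values are
aggregated with the Cauchy combination rule, which is valid under
arbitrary dependence and concentrates on the best-fitting `rho`.  The
grid argmin `rho_star` is reported alongside, but the quotable estimate
of `rho` comes from the full four-component ML fit (below); the two are
clearly distinguished in the output.  At `rho = 0` the statistic equals
the squared GLS z-statistic for the slope of x under `V`, so the joint
test collapses onto the standard correlation test adjusting for
covariates and IERs — verified to 1e-6 in the tests.

### Estimating rho

`sigma_X^2` and `sigma_Int^2` are estimated by ML in the four-component
model

    V = sigma_X^2 x x' + sigma_Int^2 diag(x) Sigma diag(x)
        + sigma_u^2 Sigma + sigma_e^2 I,

with covariates as the only fixed effects.  Because `Sigma` has rank at
most the intron count k, the first three terms have combined rank
<= 2k+1; a Woodbury identity reduces every likelihood evaluation to
O((2k+1)^3) after an O(n k^2) precomputation, verified exact against
dense-matrix evaluation to 1e-6.  Optimization is L-BFGS-B on
log-variances from three starting points; estimates below 1e-8 of
`var(y)` are snapped to zero.  Non-convergence is flagged on the result
rather than raised, so a genome scan continues past pathological pairs.
`rho_hat = sigma_Int^2 / (sigma_Int^2 + sigma_X^2)`, reported as 0 with a
flag when both components sit at the zero boundary (judged relative to
the fitted nuisance variances).

Two properties of boundary ML matter for interpreting `rho_hat`.  First,
a variance component whose truth is zero is estimated as exactly zero
with probability about one half and as a small positive excursion
otherwise — per-pair estimates at the boundary are noisy by nature, and
medians over pairs are the stable summary.  Second, `sigma_X^2` is a
rank-one (single-degree-of-freedom) component: its median over
replicates understates the truth by the median-of-chi-square-1 factor
(~0.45) when the slope itself is redrawn every replicate, which also
biases the ratio `rho_hat` upward at intermediate truths.  With the slope
held fixed — the natural reading for a single gene pair, whose `beta1`
is a constant — recovery is unbiased: at n=1000 over 100 replicates the
median `rho_hat` lands within 0.01-0.07 of truths {0, 0.5, 0.75, 1}.

### Null-model fitting

The interaction test's null model (`fit_null`) profiles the single
variance ratio `delta = sigma_u^2 / sigma_e^2`: at fixed `delta` the
fixed effects are generalized least squares and `sigma_e^2` has a closed
form, leaving a 1-D bounded search on `log delta` over [1e-6, 1e6]
(tolerance 1e-8) warm-started from a 25-point grid; a `delta = 0`
boundary fit is always compared, so `sigma_u^2 = 0` is returned when the
ordinary-regression submodel wins, silently.  All solves run through the
rank-k eigenbasis of `Sigma` in O(n k) per evaluation, verified against
dense solves to 1e-8.  Estimation is ML; REML is not used (boundary
likelihood-ratio machinery is never invoked, so no boundary correction
is needed).  The kernel and its eigendecomposition are built once per
predictor gene and shared across all response genes — the decisive cost
saving for a scan quadratic in gene count.

### Mixture-of-chi-square p-values

Three evaluators are implemented, with an accuracy-driven dispatch:

* `liu_pvalue` — Liu-Tang-Zhang four-cumulant moment matching to a
  (non)central chi-square.  Exact for a single distinct weight.
* `davies_pvalue` — the exact tail, computed by Ruben's series of central
  chi-square tails with `beta = min(weight)` (all mixing coefficients
  then non-negative and summing to one, so the truncation remainder —
  held below 1e-11 — bounds the error directly; the O(terms^2) recursion
  is JIT-compiled).  Weight sets spanning more than ~3 orders of
  magnitude fall back to numerical inversion of the characteristic
  function (Imhof's integral, adaptive quadrature), then to Liu with a
  logged warning.  Weights below 1e-7 of the maximum are dropped first;
  they shift the tail by less than the evaluation tolerance.
* `mixture_pvalue(..., method="auto")` — the scan default.  Measured
  against the exact tail, the moment match is accurate to ~1e-3 only in
  the window p in [1e-4, 1e-2]; through the body of skewed mixtures its
  error reaches several percent (the joint statistic at small `rho` has
  one dominant weight and is the worst case — large enough to break the
  uniformity of null p-values).  Auto therefore keeps Liu inside its
  window and uses the exact tail everywhere else.

### Multiple testing and networks

A scan over g genes produces g(g-1) directed pairs per test.  Bonferroni
and Benjamini-Hochberg are standard; stratified FDR applies BH within
strata, by default one stratum per response gene (each response's
candidate-predictor family is corrected on its own — matching the
many-predictors-per-response geometry; the key is configurable since the
right stratification is analysis-dependent).  Storey's pi0 uses the
lambda-average estimator on the default grid {0.05, ..., 0.95} — chosen
over the spline smoother for determinism — and is clipped to [0, 1].

Networks draw a directed edge predictor -> response for each pair
significant at the stratified FDR level; hubs are genes with outdegree
>= 5, ties broken lexicographically.  Pathway summaries divide the sum of
member outdegrees by pathway size.  Multi-tissue sharing counts, per
pair and per hub, are both computed (sharing can reasonably be defined at
either level).  Differential correlation between two sample groups is a
Wald test of the `x:group` coefficient in the stacked covariate-adjusted
regression — this respects adjustment exactly; a Fisher-z contrast of
residual correlations is available as an alternative.

## The synthetic-data generator

`simulate_pair` draws from the generative model exactly: per-sample IER
compositions from a symmetric Dirichlet (one intron cluster per gene),
the kernel built by the same code path the analysis uses, `b2` and `u`
drawn through the kernel factor so their covariance is exactly
`sigma^2 * Sigma`, Gaussian covariates and noise.  Defaults: n=300
samples, k=5 introns, Dirichlet concentration 1 (substantial inter-sample
splicing heterogeneity), `sigma_u^2=0.3`, `sigma_e^2=1`, three
covariates with effect 0.5.  Scenario presets fix the signal parameters:
`fixed_only` sets `beta1=0.3` (the slope explains ~8% of response
variance) and `interaction_only` sets `sigma_Int^2=0.5` (interaction
variance ~0.5 per sample on average) — moderate effects that separate
the tests' operating characteristics without saturating power.
`simulate_cohort` places signal pairs acyclically (lower-index predictor
to higher-index response) so each response is generated given its
realized predictors; `simulate_multitissue` splits interaction pairs
into tissue-specific and shared sets over independent per-tissue
cohorts.

What the generator does *not* emulate: read-level noise and LeafCutter
quantification error (IERs are exact compositions), realistic covariate
structure (PEER factors, genotype PCs), cell-type mixtures, non-Gaussian
expression, and inter-gene correlation beyond the planted directed
effects.  Passing tests therefore demonstrate correctness of the
statistics under the model's own assumptions — calibration, exactness,
recovery, power ordering — not robustness to the full messiness of real
RNA-seq data.

## Problem sizes in the shipped checks

Monte-Carlo sizes were fixed in advance of running the checks: null
calibration uses 2,000 replicates at n=300, k=5 (the binomial 99% band
at 5% is [0.038, 0.062]); power ordering 300-500 replicates at the same
size; rho recovery 100 replicates at n=1000; the end-to-end cohort 10
genes x 150 samples with a strong planted signal (`sigma_Int^2 = 0.8`).
`scripts/acceptance.py` re-derives all of these from a command-line seed.

## Known limitations

* Plug-in score tests treat the ML variance components as known; at
  n=300 this leaves a small anti-conservative drift (empirical 5%-level
  rejection ~0.052-0.058), vanishing with n.
* The Cauchy combination's validity is asymptotic in the tail; its body
  behavior is checked empirically (KS at 2,000 replicates), not proved.
* Missing IERs are mean-imputed per intron before kernel construction —
  neutral after standardization but it understates kernel uncertainty
  when missingness is heavy.
* The scan assumes each pair in isolation; residual correlation between
  response genes is ignored (stratified FDR, not a joint graphical
  model).
* `rho_hat` is a ratio of boundary-constrained variance estimates and is
  meaningful in aggregate (medians over many pairs), not as a per-pair
  point estimate with error bars; no confidence intervals are provided.
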