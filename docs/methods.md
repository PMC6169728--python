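# Methods

This note records the statistical model the package implements, the
generating model of the synthetic twin cohort, the numerical choices that
affect results, and the known limitations. It is the companion to the API
documentation in the module docstrings.

## The analysis

The package addresses a question of genetic specificity: how much of the
association between a polygenic risk score (PRS) for ADHD and a broad set
of childhood psychiatric symptoms reflects a *general* liability shared
across symptom dimensions, and how much is specific to particular
dimensions such as hyperactivity/impulsivity (H/I)?

The analysis proceeds in three stages.

### 1. Polygenic scoring (`genfactor.prs`)

Discovery GWAS summary statistics provide, per variant, a z-score, an
effective sample size `n_eff` and an effect-allele frequency `p`. These
are converted to standardized per-genotype-SD effects

    beta_std = z / sqrt(2 p (1 - p) (n_eff + z^2)),

the usual summary-statistic conversion when per-allele effects are not
published. Variants are filtered (MAF >= 0.05, INFO >= 0.8; indels,
multi-allelic and strand-ambiguous A/T or C/G variants removed), then
greedily clumped: the most significant unassigned variant becomes an index
and absorbs all unassigned variants within +-1000 kb with LD r² > 0.1,
ties in p broken deterministically by (chromosome, position, id). LD is
computed from dosage correlations in the target panel. Scoring follows
PLINK 1.9 `--score` semantics with `no-mean-imputation`: the score at
p-value threshold T is

    PRS_i(T) = sum_{v: p_v <= T, dosage observed} dosage_iv * beta_std_v
               / (2 * #observed included variants),

so missing genotypes contribute to neither numerator nor denominator, and
a sample with no scorable variant gets a missing score, never zero.
Ungenotyped MZ co-twins can be added by verbatim copy of the genotyped
twin's dosages (provenance-flagged).

### 2. Ordinal measurement model (`genfactor.polycor`)

Symptom items are graded 0/1/2 ("no", "to some extent", "yes"). Each item
is modelled as a discretized standard-normal latent response with
thresholds tau estimated from the margins, tau_k = Phi^{-1}(cumulative
proportion). Item-item associations are polychoric correlations (two-step
ML: thresholds fixed from margins, correlation maximizes the
bivariate-normal cell likelihood); item-covariate associations are
polyserial correlations (conditional ML given the standardized covariate);
covariate-covariate cells are Pearson and treated as fixed (fixed-x
conditioning). Estimation is pairwise-complete with a minimum-n guard.
If the assembled matrix is not positive semidefinite it is repaired by
eigenvalue flooring at 1e-6 and the repair is flagged.

For every estimated correlation the package also computes per-observation
influence values that linearize the estimator around its probability
limit. For two-step estimators the delta method is applied so that the
sampling variability of the estimated thresholds (and, for polyserial, of
the covariate standardization) is propagated. These influence values are
the basis for (i) the DWLS weights, (ii) the robust test-statistic
scaling, and (iii) the cluster sandwich. Derivatives entering the
corrections are computed by central finite differences of the cell
probabilities / mean score (step 1e-4); the rho-score itself uses the
analytic Plackett identity (d cell probability / d rho equals the signed
sum of bivariate densities at the cell corners). The bivariate-normal CDF
is a vectorized implementation of the standard Gauss-Legendre quadrature
algorithm (6/12/20 nodes by correlation magnitude, transformed integrand
beyond |rho| = 0.925), accurate to ~5e-9 against quadrature references.

### 3. Structural models (`genfactor.sem`)

Two confirmatory structures are fitted to the mixed correlation matrix:

* **Correlated-factors model.** Each item loads on exactly one specific
  latent trait factor; specific factors correlate freely.
* **General-factor (bifactor) model.** Additionally, every item loads on
  a general psychopathology factor whose disturbance is orthogonal to the
  specific factors' disturbances.

Every latent factor is regressed on the PRS and the covariates (sex, age,
principal components); all latent factors have total variance fixed at 1,
so loadings and regression coefficients are standardized and the variance
in a factor explained by the PRS is R² = beta². Estimation is diagonally
weighted least squares (DWLS): minimize

    F(theta) = sum_k (s_k - sigma_k(theta))² / w_k

over the free parameters, where s collects the item-item and
item-covariate correlations, sigma(theta) their model-implied values
(Sigma_yy = Lambda Psi Lambda', Sigma_yx = Lambda Gamma Phi, with Phi the
fixed covariate correlation block and Psi the implied latent correlation
matrix with unit diagonal), and w_k the influence-implied sampling
variances. The optimizer is L-BFGS-B with an analytic Jacobian; start
values are 0.5 for loadings, 0.2 for disturbance correlations, 0 for
regression paths; bounds keep loadings and paths in (-0.999, 0.999);
convergence at projected-gradient norm 1e-6 (fits that stop short are
flagged and reported, never silently accepted). Sign indeterminacy is
resolved by making each factor's first loading positive. Items whose
implied communality exceeds 1 are flagged (Heywood-adjacent).

Degrees of freedom follow a fixed convention: fitted moments are the
p(p-1)/2 item-item plus p*q item-covariate correlations; thresholds and
covariate-covariate correlations are margin-fixed and counted in neither
moments nor parameters. Under this convention the 62-item, 8-factor,
9-covariate configuration gives df = 2287 (correlated factors) and 2216
(general factor), difference 71 = 62 general loadings + 9 general-factor
regression paths.

**Robust statistics.** The test statistic is mean-adjusted: T = n F df /
tr(U Gamma), with U = W - WJ(J'WJ)^{-1}J'W the DWLS residual operator and
Gamma the asymptotic covariance of the sample moments assembled from the
influence values - aggregated within family clusters when clusters are
declared, so twin dependence enters both the statistic and the standard
errors. CFI uses the zero-correlation baseline on the same moments; RMSEA
is sqrt(max(T - df, 0)/(df n)) with a 90% CI by noncentral-chi-square
inversion (Brent root search). Standard errors are sandwich estimates
A^{-1} B A^{-1} with A = J'WJ and B the outer product of per-cluster
aggregated moment scores; with singleton clusters this reduces to the
naive independence sandwich.

**Nested comparison.** The correlated-factors model is the restriction of
the general-factor model with all general loadings and general-factor
paths removed. The default difference test is the scaled (Satorra-Bentler
style) statistic T_d = (nF_r - nF_f)/c_d with c_d = (tr(U_r Gamma) -
tr(U_f Gamma))/(df_r - df_f). Simulation shows this test is accurately
sized for restrictions at interior points (e.g. testing zero disturbance
correlations: 5% empirical size at nominal 5%). It is **anti-conservative
at the zero-general-factor boundary**: when the data contain no general
factor, the general loadings enter the implied moments only through
products, the regression paths of the absent factor are unidentified, and
the chi-square reference understates the fit gain the richer model can
extract from noise (empirical size 25-75% at reduced designs). This is a
structural property of chi-square difference testing for the *presence of
a factor*, not an implementation artifact; the tendency of bifactor
models to win fit comparisons is well documented. For boundary-safe
inference the package provides `method="boundary_boot"`: a parametric
simulation at the moment level that draws correlation vectors from
N(sigma_r(theta_hat), Gamma_hat/n) under the restricted model, refits both
models (the observed gain is recomputed under the identical warm-started
protocol so observed and simulated gains are exchangeable), and compares
gains; with (n_boot+1)*alpha integral the Monte-Carlo test has exact size
under its null. Empirical size at the boundary is ~5% (200-replicate
studies). The scaled test remains the default because it is standard,
cheap, and calibrated for interior restrictions and power; the bootstrap
is recommended when the existence of the general factor is itself in
question.

## Synthetic twin cohort (`genfactor.simulate`)

The generator produces data with exactly the structure the fitted models
assume, so that recovery tests are well-posed:

* **Discovery GWAS**: variant frequencies ~ U(0.01, 0.5); a configurable
  fraction of variants is causal with per-allele effects scaled to a
  target heritability (default 0.25); z = sqrt(n_eff) b sqrt(2p(1-p)) +
  N(0,1) at n_eff = 55,000 (a large ADHD-scale discovery); a fraction of
  records is flagged indel/ambiguous/low-INFO/multi-allelic to exercise
  QC.
* **Twin genotypes**: parental haplotypes drawn per frequency, children
  receive Mendelian transmissions; MZ pairs (deterministically the first
  `round(mz_fraction * n_families)` families, default one third) share
  genotypes exactly, DZ pairs share each parental allele with probability
  1/2. An optional block-exchangeable LD mode (latent Gaussian
  thresholding) exists solely to exercise clumping.
* **Latent factors**: the general factor is gamma_gp * PRS_true +
  covariate effects + disturbance (total variance 1), with gamma_gp = 0.10
  by default; the specific H/I factor receives gamma_hi = 0.07; specific
  disturbances share an exchangeable cross-factor correlation (default
  0.2) and every factor disturbance carries a family-shared component
  (default share 0.2) so twins cluster. PRS_true is the standardized
  true-effect genotype score.
* **Items**: latent response y* = lambda_g GP + lambda_s S + unique error
  (unit variance), graded by per-item thresholds (default (0.6, 1.5),
  giving roughly 73/20/7% category shares - symptom-like skew). The
  default loading plan is four factors by four items with general
  loadings ordered neurodevelopmental > externalizing > internalizing,
  echoing published bifactor solutions for these instruments.
* **Covariates**: sex (shared within pair), age 9 or 12 (shared), and
  standard-normal PCs (child-level, no phenotypic effect by default -
  they exist to be conditioned on). ADHD diagnosis combines a symptom
  count rule (items scored 2 on a dimension, cutoff 8) with a liability-
  linked register flag; medical exclusion flags are Bernoulli at a
  configurable prevalence.

What the generator does **not** emulate: realistic LD beyond exchangeable
blocks, ascertainment/attrition, rater effects, item-level residual
dependence beyond the factor structure, and polygenic family resemblance
beyond the scored variants (twin correlations are therefore milder than
in real twin data; the family-shared disturbance supplies the clustering
the sandwich errors must absorb). Passing recovery tests demonstrates the
estimators are correct under the assumed model, not that the model is
true of any real cohort.

## Reduced test designs and problem sizes

The replicate studies in the test suite run on one CPU and therefore use
reduced designs, chosen once: parameter recovery and CI coverage use 200
replicates of n = 4000 children (2000 families) with the default
4-factor x 4-item plan and covariates (PRS, sex, age); null calibration
of the per-path tests uses 200 replicates at n = 2000 children; null
calibration of the boundary bootstrap uses 200 replicates of a 3-factor x
3-item design at n = 2000 with 19 bootstrap draws (exact 5% size
construction). PCs are omitted from these covariate sets because their
generating effects are zero; the pipeline itself always accepts them.
Recovery studies regress on the generating score (`prs_true`): the
estimand of the recovery claim is the effect of the score used, and a
constructed PRS would attenuate it by its correlation with the true score
- a measurement property of PRS, not an estimator property.

At these scales the bifactor model with freely correlated specifics is
weakly identified (the exchangeable part of the specific correlations is
nearly absorbable by the general factor), which inflates standard errors
relative to the 62-item configuration; estimates remain approximately
unbiased and the sandwich intervals attain nominal coverage, which is
what the tests assert.

## Psychometric summaries (`genfactor.metrics`)

Explained common variance of the general factor,
ECV = 100 sum(lambda_g²) / (sum(lambda_g²) + sum(lambda_s²)); domain
summaries (mean/min/max of general loadings per neurodevelopmental /
externalizing / internalizing domain, with the scale-to-domain map
overridable); R² = 100 beta². The package ships a reference loading table
for the A-TAC / SMFQ / SCARED battery (62-item and 99-item designs) in
the Table-layout the summaries accept, used by the worked examples and
the acceptance script.

## Numerical choices

* Polychoric/polyserial optimization: bounded Brent on (-0.999, 0.999),
  xatol 1e-8; boundary estimates clipped and flagged.
* Observed information for the polychoric variance by central second
  difference (step 1e-4).
* PSD repair floor 1e-6; moment-variance floor 1e-12 in DWLS weights.
* RMSEA CI root search: Brent, xtol 1e-10, bracket doubling.
* Degenerate inputs: empty outer or middle ordinal categories raise with
  advice to collapse or exclude (items with any category under 5
  endorsements warn); constant covariates and |r| > 0.999 collinearity
  raise; models with negative df raise.
* All simulation randomness flows from a single `numpy` Generator seeded
  by `SimulationConfig.seed`; fixed seed implies byte-identical outputs.

## Known limitations

* Thresholds are margin-estimated and then conditioned on (delta-method
  corrections aside); full joint ML and full-weight-matrix WLS are out of
  scope.
* The scaled difference test's boundary behaviour is documented above;
  digit-level agreement with any particular proprietary implementation is
  not claimed, only calibration- and power-level equivalence.
* The SMFQ/SCARED configuration's published df difference (107) is one
  less than naive enumeration suggests (99 + 9 = 108); the discrepancy is
  unexplained upstream, so df identities are asserted only for the
  62-item configuration.
* Sex-stratified refits drop sex as a covariate within strata;
  interaction modelling is not implemented.
* The exact endorsement count behind "very few endorsements" for
  excluding sparse items is not fixed anywhere; the package warns below 5
  endorsements and leaves exclusion to configuration.
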