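# Methods

`exertrait` reimplements, on synthetic data with recorded ground truth, an
integration of multi-tissue endurance-exercise-training transcriptomics
with human complex-trait genetics. This note documents the models, the
generator that defines the study conditions, the numerical choices, and
what passing tests do and do not demonstrate.

## The scientific setting

A multi-tissue training study measures, per gene, tissue, sex and
timepoint (1, 2, 4, 8 weeks), a differential-expression (DE) log2
fold-change and p-value, and assigns each gene x tissue x timepoint a
pair of per-sex states in {-1, 0, 1}. Genes in state (1, 1) or (-1, -1)
at 8 weeks — up- or down-regulated in both sexes in the adapted state —
form each tissue's DEG set. On the human side, TWAS-style summary
statistics give per gene x tissue x trait association z-scores with
signs; expression cohorts give per-gene variance and SNP-heritability;
and a gene-disease evidence-score table supplies curated gene-trait links.
The package asks three questions: where does exercise shift expression by
more than human standing (or genetic) variation; are TWAS hits enriched
inside DEG sets; and do the intersect genes move expression in the
trait-increasing ("disease-like") or trait-decreasing direction.

## Synthetic data generator

The generator is first-class, tested code; every downstream recovery test
reads planted truth only from its records.

* **DE study.** Per tissue, a fraction `de_fraction` (default 0.1) of
  expressed genes (`expressed_fraction` 0.9) is planted DE with a random
  sign and a random onset timepoint (probabilities 0.15/0.20/0.25/0.40
  over 1w/2w/4w/8w, so most genes are late responders and trajectories
  regress toward 0.5 when traced backwards). Active gene x timepoint
  combinations draw z = sign * |N(noncentrality, 1)| with noncentrality 4
  (the alternative law is a package choice; two-sided p-values follow from
  z, and log2FC = 0.25 z so signs always agree). Null combinations draw
  z ~ N(0, 1), so null p-values are exactly Uniform(0, 1).
* **Human cohort.** Per tissue, a genetic relatedness matrix (GRM) is
  built from standardized simulated dosages (Z Z'/m, 500 SNPs), so it is
  PSD with diagonal near 1. Each gene's log2-scale signal is
  baseline + C b + g + e with Cov(g) = h2 * var * GRM and
  Var(e) = (1 - h2) * var; genetic values are drawn directly from the
  multivariate normal by default (an explicit-SNP mode draws effects and
  rescales, for REML testing against an architecture with real dosages).
  Per-gene total variances follow InvGamma(3, 2); heritabilities follow a
  mixture with 8% of genes uniform on [0.2, 0.8) and the rest exactly 0,
  mirroring the empirical situation in which the large majority of gene x
  tissue pairs carry no detectably heritable expression. The counts-like
  matrix is 2^signal - 1 clamped at 0, which the analysis-side pseudolog
  log2(x + 1) inverts exactly.
* **TWAS table.** Hit probability per gene x tissue x trait is
  inverse-logit(base + d * 1[DEG]) with base = logit(0.05) and
  d = alpha* + beta*_i + gamma*_j + eps*_ij (default alpha* = 1, other
  grids zero), reproducing the additive logit decomposition the
  enrichment model estimates. Hit indicators share a gene-level latent
  Gaussian (copula correlation 0.3), so units are gene-wise correlated —
  the structure the tetrachoric matrices are meant to capture. Hits carry
  |z| ~ |N(4.5, 1)|; in the DEG intersect the product of DE and TWAS
  signs is positive with probability inverse-logit(mu*_j), where the
  per-trait direction means mu* are drawn from a multivariate normal with
  correlation theta_true * G_SNP + (1 - theta_true) * I (theta_true
  default 0.5, unit scale) — exactly the covariance the direction model
  inverts. Non-hits draw z ~ N(0, 1).
* **Evidence and G_SNP.** Evidence scores follow Beta(0.4, 1.6) (a
  right-skewed law leaving a realistic minority above the 0.8 threshold).
  G_SNP comes from a 3-factor loading model normalized to a correlation
  matrix, or from exchangeable within-category blocks when
  `gsnp_block_r` is set (used to make the mixing weight identifiable in
  recovery tests).

Defaults are 10 tissues x 20 traits x 4 categories x 2,000 genes x 200
human samples: large enough for parameter recovery, small enough that
full analyses run in minutes. What the generator does *not* emulate:
negative-binomial count noise and library-size effects, linkage
disequilibrium, sex-specific DE beyond the sex-consistent states, and
rat-human ortholog mapping (a shared gene universe stands in for it).
Passing tests therefore demonstrate statistical correctness of the
methods under their own assumptions, not robustness to real RNA-seq
artifacts.

## Effect standardization

Expression is pseudolog-transformed, covariates (default q = 5, the
cohort covariate count being study-specific) are residualized out by
least squares, and per-gene sample variances use divisor n (consistent
with the sum-of-squares sufficient statistic of a zero-mean normal, the
mean having been removed by residualization). An inverse-gamma prior is
fit to each stratum's variances by minimum Cramér–von Mises distance
(Kolmogorov–Smirnov and Anderson–Darling are selectable; CvM is the
customary default for this estimator family), with moment-matching as a
flagged fallback for degenerate input. The conjugate update is
a + n/2, b + n s2/2, and the posterior mean b'/(a' - 1) is the shrunken
variance. Strata are tissue x sex by default, with a pooled option; the
per-sex default matches the sex-conditioned reporting of standardized
effects downstream.

Heritability is estimated per gene by REML under
y ~ N(0, sg2 GRM + se2 I): the GRM is eigendecomposed once per tissue,
the total variance is profiled out, and the ratio h2 = sg2/(sg2 + se2) is
optimized by bounded Brent search on [0, 1] (constrained optimization,
rather than unconstrained estimation with truncation). The test against
h2 = 0 sits on the parameter boundary, so the likelihood-ratio statistic
is referred to the 50:50 chi2_0/chi2_1 mixture. Significance filtering is
within-tissue Benjamini–Hochberg at alpha = 0.10 — a stratified-FDR
stand-in for covariate-weighted FDR with tissue as the covariate, flagged
in output metadata. Standardized effects are
log2FC / sqrt(posterior variance) (SD_pheno) and, for filtered genes,
log2FC / sqrt(h2 * posterior variance) (SD_geno); |SD_geno| >= |SD_pheno|
always, because h2 <= 1.

## Correlation structure

Unit-level correlation matrices guard the hierarchical models against
pseudo-replication: the same genes underlie many tissue/trait units, so
unit effects are not independent evidence. Binary gene x unit indicators
(per-tissue DEG membership; per-trait hit membership pooled over tissues;
per-cell intersect membership — which family feeds which matrix is a
documented, configurable choice) are reduced to pairwise tetrachoric
correlations: the ML correlation of a latent bivariate normal with
thresholds fixed at the marginal frequencies, optimized by bounded Brent
search over (-0.999, 0.999) (the clamp keeps downstream Cholesky factors
stable). Zero cells receive a 0.5 continuity correction; zero margins
make the pair undefined (imputed 0 with a warning). The bivariate normal
CDF uses a 48-point Gauss–Legendre quadrature of the correlation
integral, accurate to ~1e-10 over the clamped range. Pairwise estimation
does not guarantee a jointly possible matrix, so the assembled matrix is
projected to the nearest unit-diagonal PSD correlation matrix by
alternating projections with Dykstra correction (eigenvalue clipping /
unit-diagonal restoration); PSD input is a fixed point and the operation
is idempotent to 1e-10. As in the source analyses, the repaired matrices
enter the models as fixed plug-ins; their estimation uncertainty is not
propagated.

## The enrichment model

Per tissue i and trait j, hits among DEGs and among the remaining
expressed genes are Binomial with logit locations pi_ij +/- d_ij/2,
d_ij = alpha + beta_i + gamma_j + eps_ij (the symmetric split avoids
placing more prior uncertainty on one of the two composite
probabilities). Priors: alpha ~ N(0,1); beta ~ MVN(0, s^2 Sigma_tissue);
gamma ~ MVN(mu_k(j), s^2 Sigma_trait) with category means
mu_k ~ N(0, s); eps ~ MVN(0, s^2 Sigma_cell); the baseline pi gets the
mirror hierarchy (eta_j, lambda_k, grand mean ~ N(0, 2)); all scales
half-normal(0, 1). Every multivariate-normal level uses covariance
scale^2 * Sigma uniformly (the consistent parameterization, matching the
half-normal scale priors). Cells with an empty DEG pool contribute a
constant Binomial(0, .) likelihood and are retained so the grid stays
rectangular. Partial pooling regularizes every difference term toward its
population mean, which is what removes the need for post-hoc multiplicity
adjustment; calls are made where >= 95% of a marginal posterior's mass
lies on one side of 0. Reported levels are the model's own parameters
(overall alpha, tissue beta_i, trait gamma_j — which carries its category
mean — and category mu_k), plus the per-draw cell composite
alpha + beta_i + gamma_j + eps_ij.

A null-calibration utility refits the model on uniformly resampled,
size-matched gene sets (reusing the plug-in correlation matrices), and
reports the distribution of flags — the guard against reading pooled
enrichment where there is none.

## The direction model

Over DEG x hit intersect genes, y_ij counts positive DE x TWAS sign
products out of n_ij, compared against a null frequency of one half.
Direction signal cannot be pooled across traits (traits differ in whether
an increase is harmful), so pooling acts on scales only:
pi_ij ~ N(mu_j, sigma_j) with sigma_j = rho e^(lambda_j),
mu ~ MVN(0, S R S') with diag(S) = delta e^(gamma_k(j)) (each trait's
scale uses its category's factor), R = theta G_SNP + (1 - theta) I,
theta ~ Beta(1, 1), rho, delta ~ half-normal(0, 2), hyper-scales
half-normal(0, 1). The genetic-correlation matrix proxies the
environmental correlation of trait responses (Cheverud's conjecture run
in reverse), with theta estimating how much of it the data support. The
"null of one half" enters through the zero-centered logit-scale priors
(the equivalent reading of comparing against log-odds 0); the scalar
Normal(mu_j, sigma_j) level is read as i.i.d. tissue deviations — the
model introduces no tissue-level correlation here. Trajectory tracing
takes each trait's 8-week intersect set backwards: at earlier timepoints
a gene with a sex-consistent DE state contributes 1 or 0 by its sign
product, a gene without one contributes 0.5; at 8 weeks every member
contributes 0 or 1 by construction.

## Sampling

No probabilistic-programming framework is part of the stack; the package
carries its own No-U-Turn sampler (recursive slice-variant tree building)
over hand-derived log-posterior gradients, verified against finite
differences in the test suite. Warmup uses dual averaging toward a target
acceptance statistic of 0.95 with a diagonal mass matrix re-estimated at
50% and 80% of warmup; divergences are declared at an energy error of
1000. The enrichment model is non-centered at every multivariate-normal
level; the direction model is non-centered at the trait level but
centered at the univariate cell level, where binomial counts inform each
proportion directly and a non-centered cell layer would create a funnel.
The derivative of the Cholesky factor of R(theta) uses the standard
forward-mode identity dL = L Phi(L^-1 dR L^-T). Diagnostics follow a
fixed contract — split R-hat < 1.01, bulk and tail ESS > 500, divergent
iterations < 0.05% — computed with arviz; a failing fit is flagged and
its summaries withheld unless explicitly overridden. Defaults are 4
chains x 2,500 warmup + 2,500 sampling iterations; tests and the
acceptance script use fewer chains and iterations (typically 1-2 chains,
250-500 + 300-500), which is why their fits may be flagged as not meeting
the ESS contract while still estimating posterior means well.

## GSEA and harmonic-mean aggregation

The frequentist complement is classic permutation preranked GSEA:
running-sum enrichment score with statistic-weighted increments (weight
exponent 1), p = (1 + #{|ES_perm| >= |ES_obs|}) / (1 + n_perm) over
uniform gene-label permutations — exactly defined and oracle-checkable,
with the +1 pseudo-count so p is never 0. The implementation evaluates
the score from hit positions only (extremes of the running sum occur
adjacent to hits), which a test verifies against the full running-sum
scan. Rankings are -log10 TWAS p-values per cell; the multi-tissue
variant uses the set of genes DE in >= 3 tissues against per-gene
harmonic means of cross-tissue p-values. Cell-level p-values are
aggregated by the harmonic mean p-value in its simple uninflated form
with uniform weights (the asymptotically exact correction is out of
scope), then Bonferroni-adjusted across groups at alpha = 0.05; Bonferroni
for cell-level results is applied across all cells tested, with the
family size reported.

## Pipeline and reproducibility

All randomness derives from per-stage substreams keyed on (master seed,
stage name), so stages can be re-run in isolation and a fixed
configuration reproduces every table byte-for-byte; each run records a
configuration hash and stage timings. MCMC diagnostic failure withholds
the affected summaries rather than halting or silently proceeding. The
consolidated report lists one row per (trait, tissue, gene) in the DEG x
hit intersect with DE and TWAS signs, the sign product, per-sex
standardized effect sizes, and the evidence score; a validation utility
scores sign accuracy, hit sensitivity/specificity, heritability RMSE and
enrichment recovery against the generator's truth records.

## Numerical choices and degenerate inputs

* Signed z-transform: sign(log2FC = 0) is taken as +1 (the convention
  must be fixed; zero fold-changes are a measure-zero event).
* Spearman concordance uses average ranks for ties; conditions with zero
  rank variance yield missing entries; genes with any missing condition
  are dropped listwise.
* Jaccard of two empty sets is defined as 0.
* Tetrachoric boundary clamp 0.999; continuity correction 0.5.
* REML requires a non-identity GRM (identity makes the variance split
  unidentifiable) and n >= 30.
* The inverse-gamma fit requires >= 50 positive variances.
* Permutation p-values and HMP are clamped into (0, 1].

## Known limitations

* Plug-in correlation matrices understate posterior uncertainty (by
  design, following the source analysis).
* The stratified-BH stand-in is not covariate-weighted FDR; hit calls at
  the margin can differ from a weighted procedure.
* The sampler's diagnostics contract is conservative at small draw
  budgets: short test fits report `passed=False` on ESS grounds even when
  point estimates are accurate.
* Synthetic realism limits are listed under the generator section above;
  in particular the pipeline has never seen real count noise, and
  quantitative headline numbers from real studies are not reproducible at
  this scale.
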