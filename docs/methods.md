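# Methods

`drugmr` implements a drug-target Mendelian randomization (MR) workflow for
summary statistics: genetic variants in the cis region of a drug-target gene
proxy pharmacological modulation of that target, and two-sample MR against a
disease outcome estimates the effect of target modulation. The package covers
instrument selection, harmonization, causal estimation by several methods,
sensitivity diagnostics, multi-dataset meta-analysis, colocalization,
summary-data MR with the HEIDI test, two-step mediation, and a phenome-wide
scan, together with a synthetic-GWAS generator that supplies ground truth for
every stage.

## Model and assumptions

For SNP *i*, let `beta_x_i` (SE `s_x_i`) be its per-allele association with
the exposure (the target gene's effect on the biomarker, e.g. LDL-C) and
`beta_y_i` (SE `s_y_i`) its association with the binary outcome on the
log-odds scale. Under the instrumental-variable assumptions (relevance,
exchangeability, exclusion restriction), each SNP gives a Wald ratio
`beta_y_i / beta_x_i` for the causal effect `theta` (log-odds per exposure
SD). The estimators:

- **IVW** — weighted regression of `beta_y` on `beta_x` through the origin
  with weights `1/s_y^2`. Default is the multiplicative random-effects
  variant, which inflates the fixed-effect SE by `sqrt(max(1, Q/(n-1)))`;
  both variants are exposed.
- **Weighted median** — weighted median of the Wald ratios (inverse-variance
  weights), consistent when at least half the weight comes from valid
  instruments; SE by seeded parametric bootstrap (default 1000 draws).
- **cML-MA** — constrained maximum likelihood with model averaging. For each
  allowed count K of invalid instruments a profile likelihood is maximized
  by coordinate descent (given `theta`, the K largest standardized residuals
  absorb free direct effects; given the invalid set, `theta` is the
  fixed-effect IVW of the valid set), and estimates are BIC-averaged over K
  (effective sample size `n_snp`; `max_invalid` defaults to
  `floor(n_snp/2)`). The SE combines within- and between-model variance.
- **MR-Egger** — weighted regression with an intercept; the intercept
  estimates average directional pleiotropy and its p-value is the
  pleiotropy diagnostic. Exposure effects are oriented positive before the
  fit, the standard Egger convention.

Because the drugs *inhibit* their targets, estimates are negated before
conversion to odds ratios (`orient_for_inhibition`), so OR < 1 reads as
"inhibition is protective". Two-sided p-values use the normal distribution
throughout, the usual summary-data MR convention.

The decision rule for one exposure: significant if `p < 0.05/n_tests`
(`n_tests` defaults to 9 — eight targets plus the biomarker itself) with all
method estimates sharing one sign; suggestive for `0.05/n_tests <= p < 0.05`
with consistent signs. At the target level across datasets the pipeline
additionally requires the per-dataset IVW estimates to agree in direction —
the replication standard the multi-dataset design implies.

## Instrument selection

Cis instruments: SNPs within ±250 kb of the gene body (inclusive at both
ends; the source convention does not state endpoint handling), `p < 5e-8`,
greedy LD clumping at `r^2 < 0.3` (retain smallest p, discard linked,
repeat; p-ties broken by chrom/pos/id for platform-stable output). Trans
instruments for mediator GWAS: `p < 5e-6`, `r^2 < 0.001` within 10,000 kb.
Exposure-specific instruments (for the pathway-exclusion check): genome-wide
`p < 5e-8`, `r^2 < 0.001`, 10,000 kb, then removal of every SNP within any
target-gene window (the exclusion radius, not stated at the source, is the
same ±250 kb cis window). Per-SNP instrument strength uses the `F =
(beta/se)^2` approximation with `F < 10` excluded (F exactly 10 is kept);
MAF < 0.01 removed (folded; the bound itself is kept). Harmonization joins
on SNP id without proxies, aligns swapped and strand-flipped alleles, and
removes palindromic (A/T, C/G) SNPs unconditionally at all frequencies.

## Sensitivity diagnostics

Cochran's Q with weights `(beta_x/s_y)^2` on `n_snp - 1` df. MR-PRESSO
compares the observed standardized leave-one-out IVW residual sum to a
parametric-bootstrap null (default 1000 seeded simulations); per-SNP outlier
p-values are Bonferroni-corrected at 0.05. The distortion test is not
implemented. MR-PRESSO requires more than 3 SNPs; at 3 or fewer the pipeline
reports the Egger intercept test instead. Radial IVW refits with modified
second-order weights, decomposes Q into per-SNP chi-square(1) contributions
and removes SNPs with contribution p < 0.05; removing outliers can only
decrease Q at the refitted estimate. Binary-outcome power uses
`Phi(|beta| * sqrt(n * r2 * phi * (1-phi)) - z_{1-alpha/2})` with `phi` the
case fraction — the standard approximation behind the commonly used online
calculator.

## Colocalization

Per-SNP Wakefield log approximate Bayes factors
(`0.5*log(1-r) + 0.5*r*z^2`, `r = sd_prior^2/(sd_prior^2 + se^2)`) with
prior effect SDs 0.15 (quantitative) and 0.2 (binary), and priors
`p1 = p2 = 1e-4`, `p12 = 1e-5` — the defaults of the standard coloc
implementation. Hypothesis sums use log-sum-exp and stay finite for |z| well
above 50. Both 100 kb and 250 kb windows are first-class runs, since the
posterior is window-sensitive; a shared-variant call requires PPH4 > 0.75.

## SMR and HEIDI

SMR tests the top cis-eQTL (smallest eQTL p below 5e-8 after MAF > 0.01
filtering): `b_SMR = beta_GWAS/beta_eQTL`, `T = z_G^2 z_E^2/(z_G^2+z_E^2)`
on chi-square(1). HEIDI selects cis SNPs with eQTL `p < 1.57e-3` and `r^2`
to the top SNP in [0.05, 0.9] (at most 20 by ascending eQTL p, at least 3),
forms `d_i = b_SMR(i) - b_SMR(top)`, derives the covariance of `d` from LD
and the per-SNP SEs by the delta method, and refers `sum z_d^2` to the
matching quadratic form in correlated normals. The quadratic-form tail is
evaluated by Imhof's numerical inversion with a Satterthwaite
moment-matching fallback; a Monte-Carlo multivariate-normal oracle backs it
in the tests. HEIDI p > 0.05 is read as "not driven by linkage".

## Meta-analysis and mediation

Per-dataset estimates are pooled by inverse-variance fixed-effect and
DerSimonian-Laird random-effects meta-analysis; the headline model is fixed
effects when the between-study Q p-value exceeds 0.05, random effects
otherwise (the source reports both side by side without naming a selection
rule). Mediation decomposes the meta-analyzed total effect `c` into the
indirect product `c' = a*b` (meta-analyzed exposure→mediator `a`, MR
mediator→outcome `b`, with the target's cis window removed from the
mediator's instruments) and the direct effect `c - c'`; proportion mediated
is `c'/c` on the log-odds scale. The SE of `c'` is first-order Sobel,
`sqrt(a^2 se_b^2 + b^2 se_a^2)` (second-order option available). The
published mediation table is internally inconsistent — its printed `a` and
`b` multiply to −0.850, not the printed −0.576, and neither matches the
printed proportion — so the package asserts the output of the stated
formulas and flags that row as non-reproducible. Multiple testing uses
Bonferroni (the operative rule); Benjamini–Hochberg is exposed as an option
but is not a default.

## Synthetic data: what it emulates and what it does not

One region is simulated as `m` markers with AR(1) LD (`r[i,j] = rho^|i-j|`),
EAFs uniform on the MAF range with random allele orientation, and `n_causal`
causal variants whose standardized effects propagate through LD
(`beta_marginal = R @ beta_causal`) before conversion to per-allele units.
Sampling noise is multivariate normal with correlation R — the structure of
single-cohort summary statistics. Binary outcomes are generated directly on
the log-odds scale with `se = 1/sqrt(2p(1-p) n phi(1-phi))`; an
individual-level logistic path cross-validates this at small m. Palindromic
SNPs are planted at 10%, and outcome rows are re-expressed with swapped
alleles (30%) or on the opposite strand (10%) to exercise harmonization.

Default sample sizes emulate the study sources: exposures of 1.3M/170k/70k,
an outcome GWAS of 409,127 with case fraction 725/409,127, protein
(mediator) GWAS of 3,301, and a positive-control outcome with case fraction
23,888/405,940. The default causal effect in the scan, +2.867 log-odds per
exposure SD, mirrors the magnitude of the reported pooled total effect (OR
0.057 after inhibition orientation). Mediator loci carry cis effects of
0.3–0.6 SD, the scale at which protein GWAS of a few thousand samples have
usable instruments. Coloc/HEIDI scenarios use a dense block (rho = 0.9,
several hundred markers) with causal |z| targets of 8 (coloc) or 30
(eQTL-like); the distinct-variant scenario separates the two causal SNPs so
that `r^2 <= 0.09`, and HEIDI's linkage fixture moves them closer
(`r^2 ~ 0.43`) — heterogeneity in dependent instruments is only detectable
when the two signals actually overlap in LD.

Two modelling choices deserve emphasis:

- **Region-scale LD is weak by design (`rho = 0.1`).** The scan pipeline
  clumps at `r^2 < 0.3` and then treats instruments as independent, as the
  workflow it reproduces does. In an AR(1) chain with strong adjacent
  correlation, clumping at 0.3 necessarily retains instruments with pairwise
  `r^2` near 0.3, and IVW's nominal SEs would be understated by a factor
  ~1.3–1.7 — the Bonferroni calibration of the whole design would be
  fiction. The generator therefore models markers at tag-SNP spacing
  (tens of kb apart, where adjacent correlation is genuinely modest), and
  exercises dense LD in the coloc/HEIDI scenarios where the methods model
  it explicitly.
- **The recovery experiment draws independent outcome noise per exposure
  dataset.** The real design tests three exposure datasets against a single
  outcome GWAS and meta-analyzes the three estimates as if independent;
  with 725 cases the outcome noise dominates, the three estimates are
  nearly perfectly correlated, and a fixed-effect meta of them understates
  the SE by up to sqrt(3). The generator's default reproduces the shared
  outcome; the calibration experiments use independent outcome replicates,
  the regime in which the meta-analysis is valid. Passing tests therefore
  show the pipeline is correct under its own statistical assumptions, not
  that sharing one underpowered outcome GWAS across datasets is harmless.

What the generator does not emulate: realistic human LD panels (haplotype
blocks, MAF-dependent LD), population stratification, sample overlap between
exposure and outcome cohorts, winner's-curse-corrected instrument effects,
imputation error, or the X chromosome. Results on synthetic data bound what
can be claimed about real data accordingly.

## Numerical choices and degenerate inputs

p-values of 0 are clamped to 1e-300 on read (and exempted from the
z-consistency check); asymmetric LD matrices are symmetrized as `(R+R^T)/2`
with a warning above 1e-6 deviation; LD PSD tolerance is −1e-8 on the
smallest eigenvalue. Empty instrument sets, unharmonizable pairs and
untestable probes degrade to explicit status records, never exceptions, and
every configured target/phenotype appears in reports with a status. Greedy
clumping output is invariant to input row order. cML-MA flags
non-convergence after 200 coordinate-descent iterations per K. The weighted
median interpolates the standardized cumulative weight at 0.5. Mediation
with `c = 0` reports the proportion as missing.

Simulation-based checks report recovery of the mediated effect through
means over replicates (`mean(c'_hat)` and the ratio of means) rather than
the mean of per-replicate proportions: with 725 outcome cases the total
effect `c` is noisy, and a ratio of noisy estimates is finite-sample biased
even when both components are unbiased.

## Problem sizes

Calibration suites use 60-marker regions (8 targets × 3 datasets × 50 seeds
for the end-to-end scan), 300–500-marker dense regions (100 seeds for
coloc and SMR/HEIDI), 1000 null simulations for IVW type-I error, 1000
bootstrap draws per MR-PRESSO run (100 seeds), and 100 replicates of the
two-locus mediation chain — sizes at which every targeted property is
resolvable with margin on a single CPU in a few minutes.

## Known limitations

BWMR (Bayesian weighted MR) is not implemented; the consensus trio here is
IVW + weighted median + cML-MA under the same sign-consistency rule.
MR-RAPS, multivariable MR, Steiger filtering, proxy-SNP search, SuSiE-based
colocalization, the MR-PRESSO distortion test and BESD binary eQTL formats
are out of scope. LD is supplied as per-region correlation matrices; the
package does not compute LD from genotype panels.
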