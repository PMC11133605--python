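# Methods

This note documents the generative model behind the synthetic three-cohort
study, the statistical procedures, the numerical choices, and what passing
tests do and do not establish about real data.

## Study design emulated

The pipeline mirrors a genetics-only ("virtual") metabolomics study built
from three non-overlapping cohorts:

1. a **discovery biobank** with individual-level genotypes, PheCode event
   records and covariates, where metabolite PGS are scanned against
   clinical phenotypes and per-SNP outcome associations are estimated;
2. an **exposure GWAS cohort** providing per-variant metabolite summary
   statistics (the exposure side of two-sample MR and the source of PGS
   weights);
3. an independent **outcome GWAS cohort** providing replication summary
   statistics for the phenotype.

Cohort disjointness is enforced by construction (disjoint random streams
and sample-id namespaces), so the two-sample assumption of the MR
estimators holds exactly in simulation.

## Synthetic data generator

**Genotypes.** Variants are organised into LD blocks placed ≥ 10 Mb apart
(cycling over 22 chromosomes, 10 kb between neighbours within a block), so
any physically sensible clumping window never spans blocks. Haplotype
alleles come from a Gaussian copula: a latent AR(1) process per block,
thresholded at the MAF quantile. The latent autocorrelation is calibrated
numerically (bivariate-normal orthant probability + Brent root-finding) so
the *genotype* correlation of adjacent variants matches the requested
`within_block_r`. One MAF is drawn per block and shared by its variants:
thresholded binary variables obey a Fréchet bound, and equal thresholds
keep high LD targets attainable — this also matches real data, where
variants in tight LD have similar allele frequencies. Default MAFs are
uniform on (0.05, 0.5). Dosages are hard calls in {0, 1, 2}; an optional
dosage-noise switch adds clipped Gaussian jitter emulating imputed dosages.

**Metabolites.** Each metabolite is a sparse linear function of
`snps_per_metabolite` dosages (default 3, drawn from distinct blocks when
possible so clumped instruments retain that many independent SNPs) plus
Gaussian noise. Effects are scaled against the *population* dosage
variance so that the genetic variance fraction equals `h2_metabolite`
(default 0.3) and the total variance is 1; the same ground-truth weights
therefore generate every cohort, and realized sample variances deviate
only by sampling error. Effect magnitudes default to the `"equal"`
distribution (fixed magnitude, random sign), which fixes per-SNP instrument
strength — the quantity the MR stages are sensitive to; a `"normal"`
distribution is available when a long-tailed architecture is wanted.

**Phenotype.** Case probability is logistic:
`logit P = α + causal_effect·metabolite + Σ_j direct_j·(d_j − mean) +
age/sex effects`, with `α` solved by root-finding so the marginal
prevalence matches the target (default 0.1). `direct_j` are horizontally
pleiotropic variant effects (default none); `directional` mode gives them
one shared sign, `balanced` mode symmetric random signs. Pleiotropic
variants preferentially overlap the causal metabolite's instrument so the
violation is visible to the MR diagnostics. Cases receive exactly two
event rows of the target PheCode (the minimum satisfying the two-instance
case rule; a jitter option adds more); a small fraction of non-cases
receive one event of a closely related code to exercise exclusion-range
logic. Covariates: age ~ U(18, 85), sex ~ Bernoulli(0.5), 10 standard
normal PC columns, independent of genotypes unless the confounding switch
ties PC1 to genotype burden.

**Summary statistics.** Exposure tables come from vectorized per-variant
simple linear regression in the exposure cohort; outcome tables from
per-variant additive logistic regression adjusted for age, sex and 10 PCs.
All p-values are two-sided normal, which keeps the `p ↔ beta/se`
consistency invariant of the file dialect exact.

**What the generator does not emulate**: genuine recombination maps and
long-range LD, population stratification beyond the single PC switch,
imputation uncertainty beyond dosage jitter, metabolite-metabolite
correlation beyond shared SNPs, ICD-level coding noise, and case/control
misclassification. Passing tests therefore demonstrate correctness of the
algorithms under a well-specified generative model, not robustness to
every artefact of real biobank data.

## Analysis defaults and their origins

| parameter | default | role |
|---|---|---|
| `pgs_snp_p` | 5×10⁻⁸ | genome-wide cut for PGS weights |
| `instrument_p` | 5×10⁻⁶ | suggestive cut for MR instrument candidates |
| `clump_r2`, `clump_kb` | 0.05, 1000 | LD-reduction of instruments |
| `fdr` | 0.05 | BH level at every gate |
| `min_cases`, `min_instances` | 100, 2 | PheCode analyzability and case rule |
| `min_snps_validation` | 3 | instrument size gate for replication |
| `het_p` | 0.05 | Cochran's Q gate; below it, MR-PRESSO runs |
| `outlier_alpha` | 0.05 | PRESSO per-SNP outlier call |
| `presso_nsim` | 5000 | Monte-Carlo size (1000 in tests) |
| `palindromic_maf` | 0.42 | frequency-ambiguity cut for A/T, C/G SNPs |

FDR is applied within each phenotype across metabolites (a global switch
exists). Non-converged logistic fits are flagged and excluded from the BH
denominator rather than assigned p = 1, so artifacts cannot deflate the
step-up procedure.

## Numerical and procedural choices

* **PGS**: standardized to SD 1 before association, so effects are log-odds
  per SD and comparable across metabolites; missing dosages are mean-imputed
  with 2×EAF (PLINK convention) by default, with a drop-variant
  alternative. Relabelling an entry's effect allele (with negated weight)
  shifts scores by a constant, leaving association betas unchanged — a
  tested invariance.
* **Clumping** is greedy in ascending p with ties broken by (chrom, pos);
  the window is inclusive at exactly `clump_kb`, measured index-SNP to
  candidate; r² is the squared dosage Pearson correlation on the supplied
  LD reference (in-sample by default). Candidates missing from the LD
  source are dropped or assumed independent per policy, and logged.
* **Harmonization** tries direct allele match, then strand complement;
  swapped effect alleles negate the outcome beta and reflect its EAF.
  Palindromic SNPs are aligned by allele frequency only when the minor
  allele frequency is below 0.42 in both tables, otherwise dropped. Every
  action is appended to the instrument's provenance log, and re-harmonizing
  an aligned instrument is a no-op (tested).
* **IVW** uses first-order Wald-ratio weights γ²/σ_Y²; the random-effects
  SE is the fixed-effect SE times max(1, √(Q/(n−1))) — multiplicative
  overdispersion floored at 1, so it never undercuts the fixed-effect SE.
  A single-SNP instrument collapses to the Wald ratio with Q undefined.
* **MR-Egger** orients exposure effects non-negative before the weighted
  fit (the InSIDE convention) and carries the same overdispersion floor
  with n−2 degrees of freedom. Closed-form 2-parameter WLS; statsmodels
  WLS serves as the independent oracle in tests, never the implementation.
* **Weighted median** uses the IVW weights and a step-function cumulative
  weight scan: the first ordered ratio whose cumulative normalized weight
  exceeds ½ (midpoint of the bracketing ratios on an exact boundary).
  A SNP carrying > 50 % of the weight therefore returns its own ratio.
  This differs from the kernel-smoothed interpolation in some R
  implementations; the step rule is the documented contract here. The SE
  is a parametric bootstrap (normal redraws of both effect columns, fixed
  seed, default 2000 draws).
* **MR-PRESSO** uses leave-one-out IVW predictions for both the observed
  RSS and the per-SNP residuals; Monte-Carlo p-values use the
  (1+k)/(1+n_sim) estimator and are therefore never 0. Per-SNP outlier
  p-values are Bonferroni-adjusted over the instrument before the 0.05
  call. The distortion null removes random non-outlier subsets of the same
  size as the outlier set. At least 4 SNPs and 1000 simulations are
  required.
* **Consistency across methods** is sign agreement of the point estimates.
  It is recorded in the ledger but not used as a hard gate: the
  replication-eligibility rule is exactly (≥ 3 SNPs, Q p > 0.05,
  IVW FDR p < 0.05). With 3-SNP instruments the Egger slope has one
  residual degree of freedom and its sign is nearly uninformative, so
  gating on it would mostly veto true positives.
* p-values are two-sided normal throughout (not t), the large-sample GWAS
  convention; Monte-Carlo p-values are the empirical-tail estimators above.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence checks run hundreds of random instruments against
statsmodels WLS/OLS fits and hand-coded references (exhaustive greedy
clumping, cumulative-weight scan, BH step-up, IRLS). Calibration uses 1000
to 2000 summary-level replicates and a 500–1000-variant null cohort of
2000 individuals. Recovery and robustness use 200–1000 simulated
instruments of 20–30 SNPs at GWAS-scale standard errors. The end-to-end
scenario uses the default study (20,000 discovery individuals, 6,000
exposure-GWAS, 20,000 outcome-GWAS, 20 metabolites of 3 SNPs each, one
causal metabolite at 0.5 log-odds per SD, prevalence 0.1) over 50 causal
and 20 global-null runs in the test suite, and 20/10 runs in
`scripts/acceptance.py`. These sizes give Monte-Carlo error comfortably
inside the asserted bands while keeping a full run in minutes on one CPU.

## Known limitations

* Wald-ratio SEs are first-order (exposure-side noise ignored); with weak
  instruments this understates uncertainty and inflates Q slightly. The
  defaults keep per-SNP instrument strength high.
* The distortion-test null is conditional on the flagged outlier set, as
  in the original procedure; it is not a test of outlier identity.
* The case/control age window uses the covariate age (the generator has no
  event dates); with dated events a last-event age would be preferable.
* Logistic effects are non-collapsible: covariate-conditional log-odds
  estimates are slightly attenuated relative to the marginal generative
  effect, which is visible as a small systematic gap between the
  generative `causal_effect` and the discovery IVW estimate. Replication
  compares directions and FDR significance, not raw magnitudes, so the
  funnel is unaffected.
* Strand complementation handles SNP alleles only; indels are out of scope
  for the variant model.
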