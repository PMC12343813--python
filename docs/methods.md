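# Methods

## The model

The package studies dyad-level genetic similarity on a fixed panel of
independent trait-associated SNPs. Three quantities are computed:

1. **Weighted polygenic scores.** raw<sub>i</sub> = Σ<sub>j</sub>
   g<sub>ij</sub>·w<sub>j</sub>, with g the effect-allele dosage and w the
   per-allele GWAS effect estimate; scores are z-standardized within role
   (mothers, partners, children separately — a flag is not needed because each
   role is scored from its own genotype file). Missing dosages are skipped by
   default (the per-individual SNP count is reported); `mean_impute` replaces
   a missing dosage with its HWE expectation 2p.

2. **Proportion of similarity.** The panel-restricted identity-by-state
   proportion: the count of SNPs at which both members carry the same unphased
   dosage, divided by the number of SNPs compared. Heterozygotes match
   heterozygotes regardless of phase. Under missingness the denominator is
   pairwise-complete (SNPs missing on either side leave both numerator and
   denominator); the fixed-denominator reading (divide by the full panel size)
   is available as a flag, and the two coincide on complete data. Scores with
   call rate below `min_callrate` (default 0.8 of the panel) are set missing.
   Before regression, similarity is z-standardized within dyad type, so betas
   are per similarity-SD; the report also emits the per-unit-proportion
   rescaling (divide by the raw proportion SD).

3. **Associations.** OLS with both exposure and outcome z-scored on the
   complete-case analysis sample, classical (non-robust) standard errors,
   95% CI = β ± 1.96·SE, and a two-sided p from the t distribution. With no
   covariates the standardized beta equals the Pearson correlation. No
   multiple-testing correction is applied to the reported p-values; a
   Benjamini–Hochberg column is attached for information only. Strata below
   `min_n` (default 30) complete cases are flagged rather than fitted.

### Closed-form expectations (the simulator's oracle)

Under HWE with effect-allele frequency p (q = 1 − p), the per-SNP probability
that two genotypes match is

- unrelated pairs: q⁴ + (2pq)² + p⁴ (sum of squared genotype probabilities);
- parent-offspring: q³ + pq + p³ (sum over parent genotype × transmitted
  allele × random mate allele of the event "child dosage equals parent
  dosage").

At p = 0.5 these give 0.375 and 0.5. Parent-offspring match probability
dominates the unrelated one at every p, which is why mother-child similarity
distributions sit above couple distributions. By linearity, a panel's expected
proportion is the mean of per-SNP match probabilities; the same argument gives
the parent-child PGS correlation of 0.5 under random mating (per-SNP
Cov(parent, child) = p(1−p) against Var = 2p(1−p)).

## The synthetic cohort

The generator emulates a trio cohort with maternal-report outcomes. Defaults
are the study conditions and are not tuned per run:

| parameter | default | meaning |
|---|---|---|
| `n_trios` | 4704 | complete-data mother/partner/child trios |
| `n_snps` | 109 | trait panel size (control panel: 87) |
| `freq_low, freq_high` | 0.1, 0.9 | uniform effect-allele frequency range |
| `weight_sd` | 1.0 | N(0, weight_sd) panel weights |
| `spousal_rho` | 0.05 | target couple PGS correlation |
| `beta_similarity` | 0.15 | enjoyment effect, outcome-SD per similarity-SD |
| `beta_similarity_male` | 0.0 | additional effect in mother-son dyads |
| `beta_conflict` | −0.09 | conflict effect |
| `beta_similarity_marital` | 0.0 | marital-scale link to couple similarity |
| `noise_sd` | 1.0 | outcome noise SD |
| `cts2_*` | 21.61 / 7.25 / 10–49 | marital-conflict scale moments and bounds |
| `depression_rate` | 98/4704 ≈ 0.021 | severe-symptom subgroup rate |

Mechanics: founders are Binomial(2, p<sub>j</sub>) per SNP; assortative mating
is implemented at the couple level by rank-coupling the two founder pools on
raw PGS through a Gaussian copula with correlation `spousal_rho` (genotypes
are untouched; only the pairing changes; ties break by stable sort). Children
receive one allele from each parent with probability dosage/2. Child sex is
Bernoulli(0.5). Outcomes are linear-Gaussian in standardized mother-child
similarity; the marital-conflict score is a rounded, clipped Normal on its
scale, optionally shifted by couple similarity in scale-SD units (default off:
no generative effect size is assumed for the couple-level link; studies that
need one inject it explicitly). Optional missingness is
uniform at random over the dosage grid (default 0). The son-specific extra
effect defaults to zero so the injected overall effect is exactly
`beta_similarity`; setting it positive reproduces a son-specific pattern.

What the generator deliberately does **not** model: linkage disequilibrium
between panel SNPs (the panels are independent variants), sibling or
longitudinal structure, latent factor structure behind the parenting outcomes
(factor scores enter as observed continuous variables), population
stratification, genotyping error, and informative missingness. Passing tests
therefore demonstrate correctness of the statistical machinery under a clean
generative model, not robustness to those real-data features.

## File handling

Panels are TSV (snp_id, effect_allele, other_allele, weight, freq); genotypes
are either a TSV dosage matrix (individuals as rows, `NA` missing) or VCF 4.2
bi-allelic SNVs read from the GT field only (hard calls; no DS/GP dosages).
VCF records are harmonized to the panel's effect allele: ALT = effect counts
directly, REF = effect flips to 2 − ALT-count, strand-ambiguous pairs
(A/T, C/G) are excluded with a warning by default since orientation is
undecidable, mismatching and multi-allelic records are skipped with warnings.
Written VCFs use REF = other allele so round trips are exact, including
missing calls.

## Numerical and design choices

- Quantile stratification defaults to q = 0.25 (joint top/bottom quartile of
  mother and child PGS, thresholds computed within role); q = 0.5 is a
  supported alternative. Membership is inclusive (≥ the 1−q quantile, ≤ the
  q quantile).
- The positive-control marital outcome is sign-flipped standardized marital
  conflict (higher = better relationship quality); the direction is explicit
  and configurable because conflict scales and "quality" wording point in
  opposite directions.
- Standardization uses the sample SD (ddof = 1); zero-variance exposures,
  outcomes or similarity vectors raise errors rather than producing NaNs.
- Seeds: every stochastic routine takes a `numpy.random.Generator` or derives
  per-replicate seeds from a `SeedSequence`, keeping all derived seeds below
  2³¹; fixed seed implies bit-identical outputs (the pipeline manifest
  records file digests to verify this).
- Study sizes: the oracle-agreement study uses 50,000 dyads × 8 independent
  SNPs per frequency (averaging across the small panel tightens Monte-Carlo
  error by linearity without changing the estimand); effect recovery uses 600
  full-cohort replicates at n = 4,704 and checks coverage against the
  standardized truth β/√(β² + σ²) = 0.148 for β = 0.15, σ = 1; the
  negative-control study uses 800 replicates. The analysis scripts default to
  smaller replicate counts for a quick narrative run.

## Known limitations

- The IBS proportion is a panel-restricted similarity statistic, not a
  relatedness estimator; it is not comparable across panels with different
  allele-frequency spectra, which is why observed ranges from any particular
  cohort are not reproduction targets.
- Copula rank-pairing matches the target couple correlation only
  approximately for extreme ρ with heavily tied scores.
- Classical OLS standard errors assume homoscedastic residuals; the
  linear-Gaussian generator satisfies this by construction, so the suite does
  not probe robust-SE behaviour.
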