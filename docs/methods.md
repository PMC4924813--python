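# Methods

This note documents the statistical models implemented in `brainvar`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for reproducing
any number the package prints.

## SNP–ROI association model

Per SNP and ROI, ordinary least squares of the ROI measure on minor-allele
dosage (additive, 0/1/2) plus covariates: age (continuous), sex, ethnicity
and handedness (categorical, dummy-coded against the lexicographically first
level), and a trait-matched global measure (total brain volume for volume,
total surface area for surface area, mean cortical thickness for thickness).
The validation-cohort variant of the model — scanner field strength in,
handedness out — is expressed purely through the covariate list
(`VALIDATION_COVARIATES`); no separate code path exists. Complete-case
analysis per SNP×ROI pair.

The per-pair statistic is the squared Wald t of the dosage coefficient,
i.e. the 1-df Wald chi-square. A likelihood-ratio chi-square would be an
equally defensible 1-df statistic for this model; the Wald form was chosen
because it is the only per-test quantity directly available from the fitted
coefficient and its standard error, and for Gaussian OLS the two are
asymptotically identical.

Default ROI sets: volume uses {lh.insula, rh.ACC, CC, lh.tempWM, lh.SMG};
surface area and thickness drop the two subcortical/white-matter structures
(CC, lh.tempWM), which have no surface-based measures.

## Aggregate statistic and permutation inference

A SNP's aggregate statistic is X²₀ = Σ over the ROI set of the per-pair
chi-squares. Inference is by genotype permutation: one subject permutation
per replicate is applied to **all** genotype columns simultaneously, leaving
the phenotype–covariate pairing untouched. This (a) conditions on the
observed covariate structure, (b) preserves inter-SNP LD, which is what
makes the max-T family-wise modes exchangeable across SNPs, and (c) is valid
when genotype is independent of covariates, the natural assumption for
common variants in healthy cohorts. A Freedman–Lane residual-permutation
scheme is available behind `scheme="freedman_lane"` for designs where that
assumption is in doubt; on the synthetic data both schemes give
indistinguishable p-values.

Three correction modes:

- `per_snp` — each SNP's X²₀ against its own permutation distribution (one
  test per anatomical trait; this is the default and is a documented choice,
  not a certified reconstruction of any published procedure);
- `max_t_snps` — against the per-replicate maximum X²ₙ across SNPs
  (family-wise over SNPs);
- `max_t_snp_roi` — each SNP×ROI chi-square against the per-replicate
  maximum over all pairs (family-wise over pairs; the post-hoc test).

Permutation p-values use the add-one rule, p = (1 + #{X²ₙ ≥ X²₀})/(1 + N),
so they are valid p-values and never exactly zero. Missing genotypes travel
with the shuffled genotype vector and are dropped per fit.

Implementation: the permutation loop uses the Frisch–Waugh–Lovell
decomposition — phenotypes and permuted genotype columns are residualized
against the covariate design with a precomputed orthonormal basis (one QR),
after which the per-replicate t² is a vectorized inner-product computation.
This is algebraically identical to a full refit (the acceptance suite checks
the fit path against explicit normal-equations solves to 1e-8 relative) and
is what makes 500 null datasets × 1000 replicates run in seconds. When a
SNP has missing dosages the slower complete-case path is used for that SNP.

A `bonferroni(p, k)` helper (multiply, cap at 1) covers the
fixed-endpoint correction across the three anatomical traits.

## Genotype QC and LD

- MAF is folded to ≤ 0.5; when the coded allele turns out to be the major
  one, the flip is recorded so dosage direction remains reconstructible.
- Hardy–Weinberg: the exact conditional test (Wigginton-style recurrence
  over heterozygote counts given allele counts), summing configurations no
  more probable than the observed; optional mid-p. An exact test rather than
  the chi-square because per-SNP counts in targeted panels are small.
  Monomorphic SNPs return p = 1 with a warning flag.
- Pairwise r²: default EM over the two-locus haplotype ambiguity (start at
  linkage equilibrium, stop at max change < 1e-8 or 100 iterations), with
  r² = D²/(pA·pa·pB·pb); `dosage_correlation` (squared Pearson of dosages)
  as the fallback. Note these are different estimators: even with phase
  fully determined (no double heterozygotes), the dosage correlation also
  absorbs in-sample within-individual (trans-haplotype) disequilibrium, so
  exact equality between the two holds only in expectation under random
  haplotype pairing. The EM estimator is instead tested for exact agreement
  with direct haplotype-frequency arithmetic on phase-unambiguous fixtures.
- Tagging: greedy pairwise set cover — repeatedly take the SNP covering the
  most uncovered SNPs at r² ≥ threshold (ties to the lower index) until all
  are covered. Pairwise-only (no multi-marker tags); random 8-SNP instances
  are checked against exhaustive minimum covers (greedy ≤ 2× optimum
  observed throughout).

## Expression and eQTL

Expression samples (one per individual × region) are averaged per individual
with unweighted arithmetic means — no region weighting, since none is
defined for the data this emulates — then regressed on dosage by simple
linear regression with no covariates (a covariate hook exists but defaults
empty). No multiplicity correction is applied on the eQTL path when a
single probe is tested; only the TF screen corrects.

The TF screen computes Pearson r between each candidate TF's averaged
expression and the target's, with p from the regression F-test (identical to
the two-sided correlation t-test) and a Bonferroni multiplier equal to the
number of TFs considered (configurable `n_tests`, default 127). Zero-
variance TF vectors are reported NA with a reason rather than dropped.

The lack-of-fit F-test partitions the residual SS around the linear fit
into pure error (within replicated x levels) and lack of fit:
F = (SS_lof/df_lof)/(SS_pe/df_pe), df_lof = levels − 2, df_pe = n − levels.
For continuous predictors with no replicated levels this partition does not
exist, so the overall regression F is returned with an explicit
`no_replication` flag (two distinct levels, which the line saturates, flag
`saturated_linear`; zero pure-error SS, `degenerate_pure_error`).

## Allele-specific motif analysis

PWMs are JASPAR position frequency matrices (parsed/written via
Bio.motifs, rows normalized to A,C,G,T). Probabilities use the
background-proportional pseudocount convention:
p = (count + pc·bg)/(colsum + pc), pc default 0.8, background uniform —
both configurable, including pc = 0 for exact count arithmetic.

The relative score of a window is the min-max normalized log2-odds sum,
(S − Smin)/(Smax − Smin), where Smin/Smax are the per-column minimal/maximal
attainable sums — the convention used by JASPAR-ecosystem scanners. The
consensus scores exactly 1 and the anti-consensus exactly 0.

Each variant is scanned as flank(50) + allele + flank(50); only windows
overlapping the variable base are eligible (windows elsewhere cannot be
genotype-sensitive), both strands by default, ties broken toward the
forward strand then the lower offset. A *differential* (genotype-sensitive)
call requires (a) at least one allele's best overlapping window at relative
score ≥ 0.8 and (b) information content ≥ 1 bit at the PWM column aligned
with the variable base at that window, where IC = 2 + Σ p·log2 p. For indel
alleles rule (b) is undefined (no single aligned column) and the call falls
back to the score rule alone, with fold-affinity reported NA.

Fold-affinity between two single-base alleles is the ratio of the aligned
column's pseudocounted probabilities. When every other window column is
shared between alleles this equals the ratio of whole-site odds scores, so
the two natural definitions coincide for substitutions.

TF prioritization is a pure function of (expression-correlation sign,
expression-increasing allele, per-allele calls, differential flag):
not-genotype-sensitive if the differential flag is false; inconsistent if a
positively correlated TF prefers the non-increasing allele or a negatively
correlated TF prefers the increasing allele; retained otherwise. The full
truth table is tested.

## Synthetic data

The generator exists so the chain can be exercised end-to-end with known
ground truth at cohort scale (~100-subject discovery-style tables,
~134-individual multi-region expression, optionally thousands of subjects
for validation-style runs).

- **Genotypes**: haplotypes from a Gaussian copula — within an LD block all
  haplotypes share a latent factor with weight √r (`within_block_r`),
  thresholded at each SNP's allele-frequency quantile, so marginal MAFs are
  exact and within-block correlation is controlled; blocks are independent.
  2n haplotypes are paired at random, so Hardy–Weinberg proportions hold by
  construction. `within_block_r = 1` with equal MAFs yields r² = 1 exactly.
  Missingness is injected as a separate post-step (default rate 0) so QC
  tests can control it precisely.
- **Phenotypes**: each trait:ROI column is intercept + planted per-allele
  effects + covariate contributions + a 0.2-weight coupling to the trait's
  global measure + Gaussian noise (default SD 1, so planted betas are in SD
  units). Covariates: age ~ U(18, 65); sex, ethnicity (3 levels),
  handedness, scanner field sampled uniformly — these exercise dummy coding
  without imitating any cohort's demographics, which are not modeled.
- **Expression**: per-individual target = 5 + β_eQTL·dosage + λ·TF + noise,
  TF standard normal, λ solved so the population target–TF correlation
  equals `tf_target_r`; region-level samples add independent noise around
  the individual value (default 10 regions, region SD 0.5).
- **PWMs**: the designated column's distribution is solved by root-finding
  on the (p, q, q, q) family so its information content hits the requested
  value within 0.05 bits over [0, 2]; the motif consensus is embedded in the
  101-base context so that its designated column sits exactly on the
  variant for the first allele.

What passing tests on this data do **not** show: robustness to population
stratification, genotyping error, scanner/site batch effects beyond a
binary field-strength covariate, realistic genome-wide LD, non-Gaussian
phenotype tails, or expression normalization artifacts — none of which the
generator emulates.

## Problem sizes and numerical conventions

The test and acceptance runs use: 500 null cohorts × 1000 permutations
(n = 100, 5-ROI volume aggregate) for calibration; 20 six-subject fixtures
comparing 10,000 Monte-Carlo draws to all 720 permutations; 50 random
designs against normal-equations solves at 1e-8 relative; 100 replicates at
n = 1000 for recovery of a 0.3-SD-per-allele planted effect (and n = 134
for a 0.5-unit eQTL slope); 100 random (PWM, sequence) pairs against
brute-force window enumeration; 25 random 8-SNP LD matrices against
exhaustive minimum covers. These sizes give stable Monte-Carlo estimates at
desk scale while every check remains a from-scratch recomputation.

Other conventions: coordinates are 0-based half-open; categorical reference
levels are lexicographic; permutation RNG is `numpy.random.default_rng`
seeded explicitly per call (same seed ⇒ identical p-values, and results are
invariant to subject ordering of the input tables); a numerically perfect
fit (zero residual SE) reports t = 0 for a zero coefficient and ±inf
otherwise rather than 0/0.

## Known limitations

- No mixed models or kinship/stratification correction; subjects are
  assumed unrelated and exchangeable under the null.
- Two-locus EM phasing only; no multi-marker tagging or imputation.
- The eQTL model carries no covariates by default.
- Motif scoring uses a mononucleotide background; no dinucleotide models or
  score p-value calibration.
- The pipeline's `run` stage currently orchestrates simulated bundles
  end-to-end; file-input analyses compose the stage CLIs
  (`qc`, `tag`, `assoc`, `eqtl`, `tfscreen`, `tfscan`).
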