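# Methods

## The analysis model

The pipeline treats each immune trait as a quantitative phenotype and
each biallelic SNP as an additive dosage (0/1/2 alternate-allele copies).
Associations are ordinary least squares per (SNP, trait) pair:

    y = μ + β·g + Γ·C + ε

with y the prepared trait, g the dosage, C the covariates and ε i.i.d.
Gaussian. Cell-trait scans adjust for age, sex and season; cytokine scans
additionally adjust for the major-cell-type proportions (monocyte,
lymphocyte, T, B, NK), since cytokine output scales with the producing
compartment. p-values come from the t distribution with residual degrees
of freedom, not the normal approximation — at a few hundred samples the
difference matters in the tails. The scan is computed by
Frisch–Waugh–Lovell residualisation, which is algebraically identical to
the full OLS fit but lets all SNPs sharing a missingness pattern be
processed as one matrix product. Complete cases are taken per (SNP,
trait) pair rather than listwise, maximising n.

Assumptions worth stating: no relatedness or population-structure
correction is applied (no kinship/mixed model); trait preparation is
relied on to make residuals approximately Gaussian; effect alleles are
the VCF alternate alleles throughout.

## Trait preparation

Cell proportions are count(node)/count(parent) on the gating hierarchy;
a zero parent yields a missing value rather than an error because empty
parent gates are a real feature of cytometry data. Proportions are
mapped to normal scores with the rank-based inverse normal transform
using the Blom offset c = 3/8 (the conventional choice in cohort QTL
work; the transform makes downstream betas unit-free, expressed in
normal-score SDs). Ties receive average ranks. Cytokines are
log2-transformed; non-positive values are a hard error naming the cells,
because below-detection readings must be floored upstream, a decision
that belongs to the measurement protocol, not this package.

Season is encoded as sin/cos(2π·day/365) — a smooth periodic confounder
— rather than calendar-quarter dummies, avoiding arbitrary season
boundaries; the covariate screen tests the pair with a joint F-test. The
cell × cytokine correlation map uses Spearman correlation (robust to the
heavy right tails of counts and concentrations) with Benjamini–Hochberg
control across all pairs.

## Genotype QC

Variants are kept when call rate ≥ 0.99, MAF ≥ 0.01 and HWE exact p ≥
1e-5; the exclusion reason recorded for a multiply failing variant is the
first in that fixed order. The HWE test is the standard exact test
(summing probabilities of heterozygote configurations no more probable
than observed, conditional on allele counts); mid-p is not used, matching
common tooling. In two-cohort runs HWE is assessed in the healthy cohort
only, since disease status can distort genotype frequencies for
biological reasons. Samples with heterozygosity rate outside mean ± 3 SD
are excluded; the degenerate SD = 0 case excludes nobody (anything else
would mass-exclude constant panels). MAF thresholds are parameters, not
constants, because array pipelines typically apply different cutoffs
before and after imputation.

## Meta-analysis

Fixed-effect inverse-variance weighting on (snp, trait) keys shared by
all cohorts, after aligning each cohort's effect allele to the first
cohort's orientation (swapped alleles flip the beta sign; palindromic
A/T and C/G SNPs are kept but flagged, preserving information without
silent loss; incompatible allele pairs are dropped with a log message).
Cochran's Q and its p-value are reported as heterogeneity diagnostics but
never used to filter — the default effect-size/SE scheme is pure fixed
effect. No random-effects or sample-size weighting is offered.

## GWAS-set permutation procedures

Top SNPs from multiple association studies are merged into loci by greedy
clumping from the lowest GWAS p at r² > 0.1; proxies are SNPs at r² > 0.8
with a lead; the null pool is obtained by sliding-window greedy pruning
that drops the lower-MAF member of any pair at r² ≥ 0.2, so retained
pairs sit below 0.2 (the only internally consistent reading of "pruned
independent SNPs"). All r² are composite LD: squared Pearson correlation
of dosages.

The enrichment statistic is the count of suggestive (p < 0.05, strict
inequality) SNP–trait pairs over the set × one trait category; the
variance-explained statistic is the R² of one multivariate OLS of the
phenotype on all set SNPs simultaneously, with covariates residualised
out of the phenotype first (joint fitting is available but residualising
keeps the statistic interpretable as covariate-adjusted variance). Null
distributions redraw equally sized sets uniformly (no MAF matching; a
stratified option exists but is off by default) and the empirical p is
the literal exceedance fraction #{null ≥ observed}/B — so an observation
above every null draw reports p = 0; the (r+1)/(B+1) estimator is
available via `add_one=True`. Permutations are reproducible bit-for-bit
from (seed, B). Note the null baseline of R²: for k regressors and an
independent phenotype E[R²] = k/(n−1), i.e. ≈ 0.296 at k = 63, n = 214 —
raw variance explained at these dimensions is meaningless without the
permutation null, which is the point of the test.

## Colocalization

Per-SNP Wakefield log ABFs, log ABF = 0.5·log(1−r) + 0.5·r·z² with
r = W/(V+W), V = se², and effect-prior variance W = 0.15² for
quantitative traits (0.2² recommended for log-odds effects). Hypothesis
sums are computed entirely in log space via log-sum-exp — at strong loci
z ≈ 40 and naive exponentials overflow — with the distinct-causal term
obtained as log-difference: Σ_{i≠j} = exp(L1+L2) − exp(L12). Priors
default to p1 = p2 = 1e-4, p12 = 1e-5, the cited framework's convention.
Single-causal-variant assumption per trait; no SuSiE-style multi-signal
extension, conditional analysis or credible sets.

## The synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the biology of any real assay:

* **Genotypes**: per-SNP MAF uniform on (0.05, 0.5); two haplotypes per
  sample, each a latent Gaussian AR(1) series (correlation ρ = 0.6
  between adjacent SNPs, reset at 10-SNP block boundaries) thresholded
  at Φ⁻¹(MAF). This gives tunable, analytically predictable pairwise r²
  and exactly independent blocks.
* **Cell counts**: log-normal root count (median 10⁴ cells, log-SD 0.3);
  each internal node splits into children by logistic-normal fractions
  exp(lᵢ)/(1+Σexp(lⱼ)), guaranteeing sibling sums < 1 with an ungated
  remainder. Child logits carry planted genotype effects (per allele
  copy), covariate effects, and Gaussian noise of SD 0.4
  (`cell_logit_sd`) — the natural scale for planted cell-trait effects.
  The distributional choices are modelling conventions, not estimates
  from data.
* **Cytokines**: log2 concentration = intercept (uniform 4–10, roughly
  pg/ml on a log2 scale) + planted effects + covariate effects +
  N(0, noise_sd = 1).
* **Covariates**: age uniform 20–75 y, sex Bernoulli(½), sampling day
  uniform over the year, entering phenotypes through the same sin/cos
  encoding the screen tests.
* **GWAS set**: a requested number of mutually LD-independent SNPs
  (greedy acceptance at pairwise r² < 0.2), optionally with effects
  planted on every trait of one lineage, recorded in a truth table.

Defaults are desk scale — two cohorts of 300, 5,000 SNPs, 40 cell +
20 cytokine traits — so the full pipeline runs in minutes; the cohort
asymmetry of a patient-vs-population design is obtained by passing
`n_samples_per_cohort=(215, 451)`. What the generator deliberately does
not model: flow-cytometry gating noise, batch effects between cohorts,
genotyping error beyond missingness, and the MHC region's exceptional LD.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to those artefacts.

All randomness flows from one integer seed through named substreams
(MAFs, genotypes per cohort, covariates, cell noise, cytokine noise, set
choice), so identical configs reproduce identical datasets and shared
variant panels across cohorts.

## Validation studies and problem sizes

`immunoqtl.experiments` packages the reference studies the test suite
and the reproduction script run. Chosen sizes: permutation-test
calibration uses 200 replicates of (n = 300, 2,000 SNPs, 20 T-subset
traits, 20-SNP set, B = 200); power uses 100 replicates with per-SNP
effects of 0.25 × `cell_logit_sd` on the T-trait logits; effect recovery
uses 100 replicates of a single MAF-0.3 SNP at n = 500; inflation uses
50 null scans of 5,000 SNPs × 5 traits; the null variance-explained
study uses 200 draws at the 63-SNP / 214-sample dimensions; locus
recovery plants five QTLs (β = 0.8, common variants MAF 0.2–0.5) on five
chromosomes at n = 400. Each study completes in seconds to a couple of
minutes on one core.

## Numerical choices and degenerate inputs

* Exact-fit p-values underflow to the smallest positive float rather
  than 0, keeping −log10 finite.
* Monomorphic or rank-deficient dosages yield records with missing
  statistics and a note, never an exception mid-scan.
* r² of a constant dosage vector is defined as 0 with a warning.
* Singular multivariate SNP designs fall back to the pseudoinverse
  (minimum-norm) fit with a warning.
* The λ denominator is the exact χ²₁ median (0.45493642…), and λ is
  computed from all non-missing p-values; fewer than 100 triggers a
  warning but still computes.
* Locus grouping is greedy by ascending p within ±250 kb of the lead;
  ties in p resolve by sort stability.

## Known limitations

No mixed models or kinship correction; no imputation or genotype
calling; no HLA allelic analysis; the clumping and pruning heuristics
are greedy (order-dependent in ways shared by standard tooling); the
colocalization assumes at most one causal variant per trait per locus;
and the synthetic cohorts cannot certify behaviour under real-data
artefacts they do not model.
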