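# immunoqtl

Genetic analysis of immune phenotypes: QTL mapping of immune-cell
proportions and stimulated cytokine production, two-cohort fixed-effect
meta-analysis, permutation tests of the cumulative impact of a disease
GWAS SNP set, and approximate-Bayes-factor colocalization — together with
a synthetic two-cohort generator that provides ground truth for every
stage.

## Who this is for

Functional-genomics cohort studies measure hundreds of immune traits per
participant — flow-cytometry cell counts on a gating hierarchy, and
cytokine concentrations after ex vivo stimulation of PBMCs — alongside
genome-wide SNP genotypes. This package implements the statistical
pipeline such studies need, end to end, for settings where individual-level
data are access-restricted and methods must be validated on simulated
cohorts with known truth.

## The statistics at the core

**Trait preparation.** Cell proportions are counts of a node divided by
its parent on the gating tree, then mapped to normal scores by the
rank-based inverse normal transform z_i = Φ⁻¹((r_i − 3/8)/(n + 1/4));
cytokines are log2-transformed. Age (Spearman), sex (linear regression)
and season (joint F-test on sin/cos of day-of-year) are screened per trait
with Benjamini–Hochberg control at FDR < 0.05.

**QTL scan.** For each SNP–trait pair, OLS of the prepared trait on the
additive dosage plus covariates (age, sex, season for cell traits; plus
major-cell-type proportions for cytokines), complete-case, with two-sided
t p-values, λ = median(χ²)/0.4549 inflation diagnostics and genome-wide
calling at p < 5×10⁻⁸ grouped into ±250 kb loci.

**Meta-analysis.** Inverse-variance-weighted fixed effect:
β = Σwₖβₖ/Σwₖ, se = (Σwₖ)^(−1/2), wₖ = 1/seₖ², with allele
harmonisation and Cochran's Q as a diagnostic.

**GWAS-set permutation tests.** For a curated set of disease-associated
SNPs (clumped at r² > 0.1), the suggestive-association count
#{(SNP, trait): p < 0.05} over one trait category, and the multivariate
R² of a phenotype on all set SNPs jointly, are each compared with the same
statistic for random equally sized sets drawn from LD-independent SNPs
(pruned at r² < 0.2); empirical p = #{null ≥ observed}/B.

**Colocalization.** Per-SNP Wakefield log ABFs
(0.5·log(1−r) + 0.5·r·z², r = W/(V+W)) accumulated in log space into
posteriors PP0–PP4 of the five locus hypotheses with priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵.

## Worked example

```python
from immunoqtl import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(
    outdir="demo", seed=11,
    n_samples_per_cohort=(80, 80), n_snps=300,
    n_cell_traits=15, n_cytokine_traits=5,
    gwas_set_size=8, planted_beta=0.4, n_permutations=50,
))
print(summary["lambda_disease"], summary["enrichment_observed"],
      summary["enrichment_p"])
```

prints

```
1.0474269375517957 14.0 0.0
```

i.e. the null portion of the scan is well calibrated (λ ≈ 1.05), the
8-SNP planted "GWAS" set shows 14 suggestive associations with T-cell
traits, and none of the 50 random independent SNP sets reaches that count
(empirical p = 0). Full tables (summary statistics, null distributions,
QC reports, colocalization ABFs) are written under `demo/` with a
manifest recording parameters and the seed.

The same stages are available from the shell:

```sh
immunoqtl run --seed 11 --outdir demo
immunoqtl qc --vcf demo/disease.vcf --out filtered.vcf --maf 0.01 --hwe 1e-5
immunoqtl coloc --trait1 a.tsv --trait2 b.tsv --region 3:46000000-46500000
```

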