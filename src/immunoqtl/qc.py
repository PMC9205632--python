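"""Variant- and sample-level genotype quality control.

Filters follow common array-genotyping practice: per-variant call rate,
minor allele frequency, Hardy-Weinberg exact test (applied to the healthy
cohort when one is designated), and a per-sample heterozygosity-rate screen
at mean +/- 3 SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "QcReport",
    "compute_maf",
    "hwe_exact_test",
    "filter_variants",
    "heterozygosity_outliers",
]


@dataclass
class QcReport:
    """Outcome of variant filtering: per-variant metrics and exclusions.

    Each excluded variant carries exactly one primary reason, assigned in
    the fixed order call_rate -> maf -> hwe.
    """

    variant_metrics: pd.DataFrame
    excluded: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def reason_counts(self) -> pd.Series:
        return self.excluded["reason"].value_counts()

    def to_tsv(self, path) -> None:
        self.variant_metrics.to_csv(path, sep="\t", index=False)


def compute_maf(dosages) -> float:
    """Minor allele frequency of a dosage vector (missing ignored).

    Alt frequency is sum(dosages) / (2 * n_nonmissing); the MAF folds it to
    [0, 0.5].
    """
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("cannot compute MAF: all genotypes missing")
    f = d[ok].sum() / (2.0 * n)
    return float(min(f, 1.0 - f))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic variant.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote configuration whose probability does not exceed that
    of the observed one (the standard exact test, not mid-p). Monomorphic
    variants return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # minor allele count
    if n_rare == 0:
        return 1.0

    # recurrence over heterozygote counts with fixed allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.zeros(len(hets))
    # start at the mode-ish midpoint for numerical stability
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    idx_mid = int(np.searchsorted(hets, mid))
    probs[idx_mid] = 1.0
    for i in range(idx_mid, 0, -1):  # going down in het count
        het = hets[i]
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        probs[i - 1] = probs[i] * het * (het - 1) / (4.0 * (rare_hom + 1) * (common_hom + 1))
    for i in range(idx_mid, len(hets) - 1):  # going up
        het = hets[i]
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        probs[i + 1] = probs[i] * 4.0 * rare_hom * common_hom / ((het + 1.0) * (het + 2.0))
    probs /= probs.sum()
    p_obs = probs[int(np.searchsorted(hets, n_Aa))]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    ok = ~np.isnan(column)
    d = column[ok]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def filter_variants(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.99,
    maf_min: float = 0.01,
    hwe_min: float = 1e-5,
    hwe_samples: list[str] | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Keep variants passing call-rate, MAF and HWE thresholds.

    ``hwe_samples`` restricts the HWE test to a subset (e.g. the healthy
    cohort of a merged case/control panel); the other filters always use
    all samples. The exclusion reason recorded for a variant failing
    several filters is the first in the order call_rate, maf, hwe.
    """
    for thr in (call_rate_min, maf_min, hwe_min):
        if not (0.0 <= thr <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
    if genotypes.n_snps == 0 or genotypes.n_samples == 0:
        raise ValueError("empty genotype matrix")

    D = genotypes.dosages
    if hwe_samples is not None:
        lookup = {s: i for i, s in enumerate(genotypes.samples)}
        hwe_rows = [lookup[s] for s in hwe_samples]
        D_hwe = D[hwe_rows, :]
    else:
        D_hwe = D

    call_rate = 1.0 - np.isnan(D).mean(axis=0)
    mafs = np.empty(genotypes.n_snps)
    hwe_p = np.empty(genotypes.n_snps)
    for j in range(genotypes.n_snps):
        col = D[:, j]
        mafs[j] = compute_maf(col) if not np.all(np.isnan(col)) else 0.0
        hcol = D_hwe[:, j]
        if np.all(np.isnan(hcol)):
            hwe_p[j] = 1.0
        else:
            hwe_p[j] = hwe_exact_test(*_genotype_counts(hcol))

    metrics = pd.DataFrame(
        {
            "snp": genotypes.variants["snp"].to_numpy(),
            "call_rate": call_rate,
            "maf": mafs,
            "hwe_p": hwe_p,
        }
    )
    reason = np.full(genotypes.n_snps, "", dtype=object)
    reason[(reason == "") & (call_rate < call_rate_min)] = "call_rate"
    reason[(reason == "") & (mafs < maf_min)] = "maf"
    reason[(reason == "") & (hwe_p < hwe_min)] = "hwe"
    keep = reason == ""
    excluded = metrics.loc[~keep].copy()
    excluded["reason"] = reason[~keep]

    kept = GenotypeMatrix(
        D[:, keep],
        list(genotypes.samples),
        genotypes.variants.loc[keep].reset_index(drop=True),
    )
    report = QcReport(
        variant_metrics=metrics,
        excluded=excluded.reset_index(drop=True),
        thresholds={
            "call_rate_min": call_rate_min,
            "maf_min": maf_min,
            "hwe_min": hwe_min,
        },
    )
    return kept, report


def heterozygosity_outliers(genotypes: GenotypeMatrix, n_sd: float = 3.0) -> list[str]:
    """Sample ids whose heterozygosity rate lies outside mean +/- n_sd * SD.

    The rate is #heterozygous / #non-missing genotypes per sample. With a
    degenerate SD of 0 (all samples identical) nobody is excluded.
    """
    if genotypes.n_samples < 3:
        raise ValueError("heterozygosity screening needs at least 3 samples")
    D = genotypes.dosages
    het = (D == 1).sum(axis=1)
    nonmiss = (~np.isnan(D)).sum(axis=1)
    if (nonmiss == 0).any():
        raise ValueError("sample with no called genotypes")
    rate = het / nonmiss
    mu, sd = rate.mean(), rate.std(ddof=1)
    if sd == 0.0:
        return []
    out = (rate < mu - n_sd * sd) | (rate > mu + n_sd * sd)
    return [s for s, o in zip(genotypes.samples, out) if o]
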