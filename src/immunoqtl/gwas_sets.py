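"""Cumulative-impact tests for a disease GWAS SNP set on immune traits.

Implements the study's bespoke procedures around a curated list of
disease-associated top SNPs:

* LD utilities (composite r^2, greedy clumping from the lowest GWAS p,
  proxy extraction, sliding-window pruning),
* an allelic case-control chi-square test,
* a permutation enrichment test that counts suggestive (p < alpha)
  SNP-trait associations in one trait category and compares the count with
  that of random same-size sets of LD-independent SNPs,
* a permutation variance-explained test comparing the multivariate R^2 of
  the GWAS set against random sets.

Empirical p-values use the literal exceedance definition
#{null >= observed}/B (so a never-exceeded observation gives p = 0); the
(r+1)/(B+1) estimator is available via ``add_one=True``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix

__all__ = [
    "PermutationResult",
    "ld_r2",
    "clump_gwas_snps",
    "find_proxies",
    "case_control_allelic_test",
    "ld_prune",
    "enrichment_test",
    "variance_explained",
    "variance_explained_test",
]

log = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    """Observed statistic with its permutation null."""

    observed: float
    null: np.ndarray
    p: float
    seed: int
    B: int
    alpha: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.null = np.asarray(self.null, dtype=float)
        if len(self.null) != self.B:
            raise ValueError("null draws must have length B")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("empirical p outside [0,1]")


def ld_r2(dosage_a, dosage_b) -> float:
    """Composite LD: squared Pearson correlation of dosages, complete-case."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        raise ValueError("need >=3 complete dosage pairs")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant dosage vector: r^2 defined as 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(D: np.ndarray) -> np.ndarray:
    """Pairwise dosage r^2 for the columns of D (missing mean-imputed)."""
    X = np.where(np.isnan(D), np.nanmean(D, axis=0, keepdims=True), D)
    sd = X.std(axis=0)
    sd[sd == 0] = np.nan
    Z = (X - X.mean(axis=0)) / sd
    R = Z.T @ Z / len(Z)
    R2 = R * R
    R2[np.isnan(R2)] = 0.0
    np.fill_diagonal(R2, 1.0)
    return R2


def clump_gwas_snps(
    top_snps: pd.DataFrame, genotypes: GenotypeMatrix, r2_threshold: float = 0.1
) -> pd.DataFrame:
    """Merge GWAS top SNPs in LD into loci, keeping the lowest-p SNP.

    ``top_snps`` needs columns snp, p (risk_allele and study are carried
    through). Greedy clumping from the lowest GWAS p: each lead absorbs
    every unclaimed SNP with r^2 > threshold; the leads form the returned
    set, each annotated with its absorbed members.
    """
    if top_snps.empty:
        raise ValueError("empty GWAS top-SNP list")
    present = set(genotypes.variants["snp"])
    absent = [s for s in top_snps["snp"] if s not in present]
    if absent:
        log.warning("dropping %d GWAS SNPs absent from genotypes: %s",
                    len(absent), absent[:5])
    snps = top_snps.loc[top_snps["snp"].isin(present)].copy()
    if snps.empty:
        raise ValueError("no GWAS top SNPs present in the genotype panel")
    snps = snps.sort_values("p", kind="stable").reset_index(drop=True)
    sub = genotypes.subset_snps(snps["snp"].tolist())
    R2 = _r2_matrix(sub.dosages)

    claimed = np.zeros(len(snps), dtype=bool)
    rows = []
    for i in range(len(snps)):
        if claimed[i]:
            continue
        members = np.nonzero(~claimed & (R2[i] > r2_threshold))[0]
        claimed[members] = True
        claimed[i] = True
        row = snps.iloc[i].to_dict()
        row["clump_members"] = ",".join(snps["snp"].iloc[members])
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def find_proxies(
    lead_snp: str, genotypes: GenotypeMatrix, r2_min: float = 0.8
) -> list[str]:
    """All SNPs in strong LD (r^2 > r2_min) with the lead, lead included."""
    lead = genotypes.column(lead_snp)  # raises KeyError if absent
    out = []
    for j, snp in enumerate(genotypes.variants["snp"]):
        if snp == lead_snp:
            out.append(snp)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if ld_r2(lead, genotypes.dosages[:, j]) > r2_min:
                out.append(snp)
    return out


def case_control_allelic_test(dosages, status) -> tuple[float, float, float]:
    """Allelic chi-square test of a SNP against case/control status.

    Builds the 2x2 allele-count table (two alleles per sample, missing
    genotypes dropped) and applies the 1-df chi-square test without
    continuity correction. Returns (chi2, p, odds ratio); a zero margin
    gives (0, 1, nan).
    """
    d = np.asarray(dosages, dtype=float)
    s = np.asarray(status)
    ok = ~np.isnan(d)
    d, s = d[ok], s[ok]
    if len(np.unique(s)) < 2:
        raise ValueError("both case and control samples required")
    alt_case = d[s == 1].sum()
    ref_case = 2 * (s == 1).sum() - alt_case
    alt_ctrl = d[s == 0].sum()
    ref_ctrl = 2 * (s == 0).sum() - alt_ctrl
    table = np.array([[alt_case, ref_case], [alt_ctrl, ref_ctrl]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, float("nan")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    if table[0, 1] * table[1, 0] == 0:
        odds = float("inf") if table[0, 0] * table[1, 1] > 0 else float("nan")
    else:
        odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    return chi2, p, odds


def ld_prune(
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.2,
    window_snps: int = 50,
    step: int | None = None,
) -> list[str]:
    """Sliding-window greedy LD pruning.

    Within each window, while any pair has r^2 >= threshold, the member of
    the pair with the lower MAF is dropped. Surviving SNPs have no
    within-window pair at or above the threshold.
    """
    if genotypes.n_snps == 0:
        raise ValueError("no SNPs to prune")
    if step is None:
        step = max(1, window_snps // 2)
    from .qc import compute_maf

    D = genotypes.dosages
    m = genotypes.n_snps
    mafs = np.array([compute_maf(D[:, j]) for j in range(m)])
    keep = np.ones(m, dtype=bool)
    for start in range(0, m, step):
        idx = np.nonzero(keep[start:start + window_snps])[0] + start
        if len(idx) < 2:
            continue
        R2 = _r2_matrix(D[:, idx])
        np.fill_diagonal(R2, 0.0)
        active = np.ones(len(idx), dtype=bool)
        while True:
            pairs = np.argwhere(np.triu(R2 >= r2_threshold, k=1))
            pairs = pairs[active[pairs[:, 0]] & active[pairs[:, 1]]]
            if len(pairs) == 0:
                break
            i, j = pairs[0]
            drop = i if mafs[idx[i]] <= mafs[idx[j]] else j
            active[drop] = False
            R2[drop, :] = 0.0
            R2[:, drop] = 0.0
        keep[idx[~active]] = False
    return [s for s, k in zip(genotypes.variants["snp"], keep) if k]


def _empirical_p(observed: float, null: np.ndarray, add_one: bool, strict: bool) -> float:
    """Exceedance p-value. ``strict`` counts null > observed, else >=."""
    exceed = (null > observed) if strict else (null >= observed)
    r = int(exceed.sum())
    B = len(null)
    return (r + 1) / (B + 1) if add_one else r / B


def enrichment_test(
    assoc_pvals: pd.DataFrame,
    gwas_set,
    category_traits,
    independent_pool,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    add_one: bool = False,
    label: str = "",
) -> PermutationResult:
    """Are suggestive associations enriched in the GWAS set for a category?

    Counts (SNP, trait) pairs with p < alpha over gwas_set x
    category_traits, then recounts for B random same-size SNP sets drawn
    without replacement from the LD-independent pool. Empirical
    p = #{null >= observed} / B.
    """
    gwas_set = list(gwas_set)
    category_traits = list(category_traits)
    pool = list(independent_pool)
    if B < 1:
        raise ValueError("B must be >= 1")
    if not category_traits:
        raise ValueError("empty trait category")
    if len(pool) < len(gwas_set):
        raise ValueError(
            f"pool of {len(pool)} independent SNPs smaller than set size {len(gwas_set)}"
        )
    sub = assoc_pvals.loc[assoc_pvals["trait"].isin(category_traits)]
    # suggestive-association count per SNP over the category's traits
    hits = (
        sub.assign(hit=(sub["p"] < alpha).astype(int))
        .groupby("snp", sort=False)["hit"]
        .sum()
    )
    missing = [s for s in gwas_set if s not in hits.index]
    if missing:
        raise ValueError(f"GWAS set SNPs missing from association results: {missing[:5]}")
    observed = float(hits.loc[gwas_set].sum())

    pool_in = [s for s in pool if s in hits.index]
    if len(pool_in) < len(gwas_set):
        raise ValueError("independent pool too small after intersecting with results")
    pool_hits = hits.loc[pool_in].to_numpy()
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    k = len(gwas_set)
    for b in range(B):
        draw = rng.choice(len(pool_hits), size=k, replace=False)
        null[b] = pool_hits[draw].sum()
    p = _empirical_p(observed, null, add_one, strict=False)
    return PermutationResult(observed, null, p, seed, B, alpha=alpha, label=label)


def _complete_case(*arrays) -> np.ndarray:
    ok = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        ok &= ~(np.isnan(a).any(axis=1) if a.ndim == 2 else np.isnan(a))
    return ok


def variance_explained(
    genotypes_subset, phenotype, covariates=None
) -> float:
    """Proportion of phenotype variance jointly explained by a SNP set.

    Fits one multivariate OLS of the phenotype on all set SNPs at once and
    returns its R^2. Covariates (if given) are residualised out of the
    phenotype first, so the R^2 refers to covariate-adjusted variance.
    Singular designs fall back to the pseudoinverse (minimum-norm) fit
    with a warning.
    """
    G = genotypes_subset.dosages if isinstance(genotypes_subset, GenotypeMatrix) else np.asarray(genotypes_subset, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    y = np.asarray(phenotype, dtype=float)
    C = None if covariates is None else np.asarray(covariates, dtype=float)
    if C is not None and C.ndim == 1:
        C = C[:, None]
    ok = _complete_case(y, G, C)
    G, y = G[ok], y[ok]
    n, k = G.shape
    n_cov = 0 if C is None else C.shape[1]
    if n <= k + n_cov + 1:
        raise ValueError(f"n={n} too small for k={k} SNPs and {n_cov} covariates")
    if C is not None:
        Cd = np.column_stack([np.ones(n), C[ok]])
        y = y - Cd @ np.linalg.lstsq(Cd, y, rcond=None)[0]
    X = np.column_stack([np.ones(n), G])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("singular SNP design: using pseudoinverse fit", stacklevel=2)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant phenotype")
    return float(1.0 - float(resid @ resid) / tss)


def variance_explained_test(
    genotypes: GenotypeMatrix,
    phenotype,
    covariates,
    gwas_set,
    independent_pool,
    B: int = 1000,
    seed: int = 0,
    add_one: bool = False,
    label: str = "",
) -> PermutationResult:
    """Permutation test of the variance explained by the GWAS set.

    The observed statistic is ``variance_explained`` for the GWAS set; the
    null redraws same-size SNP sets from the LD-independent pool. The
    empirical p is the fraction of null draws strictly greater than the
    observed R^2.
    """
    gwas_set = list(gwas_set)
    pool = list(independent_pool)
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(pool) < len(gwas_set):
        raise ValueError("independent pool smaller than the GWAS set")
    observed = variance_explained(genotypes.subset_snps(gwas_set), phenotype, covariates)
    rng = np.random.default_rng(seed)
    pool_mat = genotypes.subset_snps(pool)
    null = np.empty(B)
    for b in range(B):
        draw = rng.choice(len(pool), size=len(gwas_set), replace=False)
        null[b] = variance_explained(pool_mat.dosages[:, draw], phenotype, covariates)
    p = _empirical_p(observed, null, add_one, strict=True)
    return PermutationResult(observed, null, p, seed, B, label=label)
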