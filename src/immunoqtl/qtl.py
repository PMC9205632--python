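"""Genome-wide linear-model QTL scan with inflation diagnostics.

Each (SNP, trait) pair is tested by ordinary least squares of the prepared
trait on the additive dosage plus covariates, complete-case per pair. The
dosage coefficient is obtained via Frisch-Waugh-Lovell residualisation,
which lets the scan run as matrix operations across all SNPs sharing a
missingness pattern while remaining exactly equal to the full OLS fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix

__all__ = [
    "ScanConfig",
    "map_qtl",
    "genomic_inflation",
    "significant_loci",
    "qq_points",
]

log = logging.getLogger(__name__)

# median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))

RECORD_COLUMNS = [
    "snp", "chrom", "pos", "effect_allele", "other_allele",
    "trait", "beta", "se", "t", "p", "n", "note",
]


@dataclass
class ScanConfig:
    """Scan settings: covariate columns and the significance threshold.

    Cell-trait scans adjust for age, sex and season; cytokine scans add
    the major-cell-type proportions. ``season`` expands to the sin/cos
    pair of day-of-year.
    """

    covariates: tuple[str, ...] = ("age", "sex", "season")
    threshold: float = 5e-8

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("significance threshold must be in (0,1)")


def _design(covariates: pd.DataFrame | None, index) -> np.ndarray:
    """Intercept + covariate design; 'day' becomes the sin/cos season pair."""
    from .simulate import season_design

    if covariates is None:
        return np.ones((len(index), 1))
    cov = covariates.loc[index]
    cols = [np.ones(len(cov))]
    for name in cov.columns:
        x = cov[name].to_numpy(dtype=float)
        if name == "day":
            sc = season_design(x)
            cols.extend([sc[:, 0], sc[:, 1]])
        else:
            cols.append(x)
    return np.column_stack(cols)


def _scan_block(G: np.ndarray, y: np.ndarray, C: np.ndarray):
    """OLS dosage coefficients for all SNP columns of G against y given
    covariate design C (no missing values). Returns beta, se, t, p, df."""
    n, p_cov = C.shape
    pinv = np.linalg.pinv(C)
    Gr = G - C @ (pinv @ G)
    yr = y - C @ (pinv @ y)
    gg = np.einsum("ij,ij->j", Gr, Gr)
    gy = Gr.T @ yr
    df = n - p_cov - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = float(yr @ yr) - beta * gy
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # exact fits underflow: report the smallest representable p, not 0
    p = np.where((t != 0) & (p == 0.0), np.nextafter(0, 1), p)
    bad = gg <= 0  # monomorphic / rank-deficient dosage
    for arr in (beta, se, t, p):
        arr[bad] = np.nan
    return beta, se, t, p, df, bad


def map_qtl(
    genotypes: GenotypeMatrix,
    traits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    min_samples: int | None = None,
) -> pd.DataFrame:
    """Associate every SNP with every trait; returns AssociationRecords.

    ``traits`` is a samples x traits frame of prepared values (inverse-rank
    cell proportions or log2 cytokines); ``covariates`` a samples x
    covariates frame whose ``day`` column is expanded into the sin/cos
    season pair. Complete cases are taken per (SNP, trait) pair. SNPs with
    a degenerate design for some trait are emitted with missing statistics
    and a note.
    """
    shared = [s for s in genotypes.samples if s in traits.index]
    geno = genotypes if len(shared) == genotypes.n_samples else genotypes.subset_samples(shared)
    traits = traits.loc[geno.samples]

    var = geno.variants
    n_cov_cols = _design(covariates, traits.index).shape[1]
    if min_samples is None:
        min_samples = n_cov_cols + 3

    out_frames = []
    D = geno.dosages
    snp_nan = np.isnan(D)
    any_snp_nan = snp_nan.any()
    for trait in traits.columns:
        y_full = traits[trait].to_numpy(dtype=float)
        trait_ok = ~np.isnan(y_full)
        C_full = _design(covariates, traits.index)
        trait_ok &= ~np.isnan(C_full).any(axis=1)

        beta = np.full(geno.n_snps, np.nan)
        se = np.full(geno.n_snps, np.nan)
        tstat = np.full(geno.n_snps, np.nan)
        pval = np.full(geno.n_snps, np.nan)
        nvec = np.zeros(geno.n_snps, dtype=int)
        note = np.full(geno.n_snps, "", dtype=object)

        if not any_snp_nan:
            groups = {(): np.arange(geno.n_snps)}
        else:
            # group SNPs by their missing-sample pattern within trait_ok rows
            patt = [tuple(np.nonzero(snp_nan[trait_ok, j])[0]) for j in range(geno.n_snps)]
            groups = {}
            for j, key in enumerate(patt):
                groups.setdefault(key, []).append(j)
            groups = {k: np.asarray(v) for k, v in groups.items()}

        base_rows = np.nonzero(trait_ok)[0]
        for miss_pattern, snp_idx in groups.items():
            rows = np.delete(base_rows, list(miss_pattern)) if miss_pattern else base_rows
            n = len(rows)
            nvec[snp_idx] = n
            if n < min_samples:
                note[snp_idx] = "too_few_samples"
                continue
            C = C_full[rows]
            b, s, tt, pp, _df, bad = _scan_block(D[np.ix_(rows, snp_idx)], y_full[rows], C)
            beta[snp_idx], se[snp_idx], tstat[snp_idx], pval[snp_idx] = b, s, tt, pp
            if bad.any():
                note[snp_idx[bad]] = "degenerate_design"
                log.warning(
                    "trait %s: %d SNPs with degenerate design", trait, int(bad.sum())
                )

        out_frames.append(
            pd.DataFrame(
                {
                    "snp": var["snp"].to_numpy(),
                    "chrom": var["chrom"].to_numpy(),
                    "pos": var["pos"].to_numpy(),
                    "effect_allele": var["alt"].to_numpy(),
                    "other_allele": var["ref"].to_numpy(),
                    "trait": trait,
                    "beta": beta,
                    "se": se,
                    "t": tstat,
                    "p": pval,
                    "n": nvec,
                    "note": note,
                }
            )
        )
    return pd.concat(out_frames, ignore_index=True)[RECORD_COLUMNS]


def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor: median observed 1-df chi-square over the
    null median (0.4549). Values near 1 indicate a calibrated scan."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ValueError("no p-values")
    if len(p) < 100:
        log.warning("genomic_inflation computed from only %d p-values", len(p))
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def significant_loci(
    records: pd.DataFrame, threshold: float = 5e-8, window_kb: float = 250.0
) -> pd.DataFrame:
    """Group genome-wide significant records into loci.

    Records below ``threshold`` are sorted by p; each record joins an
    existing locus when it lies within ``window_kb`` of that locus's lead
    SNP on the same chromosome, otherwise it seeds a new locus. The lead
    is therefore always the lowest-p SNP of its locus.
    """
    sig = records.loc[records["p"] < threshold].sort_values("p")
    window = window_kb * 1000.0
    loci: list[dict] = []
    for _, rec in sig.iterrows():
        placed = False
        for locus in loci:
            if rec["chrom"] == locus["chrom"] and abs(rec["pos"] - locus["pos"]) <= window:
                locus["n_snps"] += 1
                locus["traits"].add(rec["trait"])
                placed = True
                break
        if not placed:
            loci.append(
                {
                    "lead_snp": rec["snp"],
                    "chrom": rec["chrom"],
                    "pos": rec["pos"],
                    "trait": rec["trait"],
                    "p": rec["p"],
                    "n_snps": 1,
                    "traits": {rec["trait"]},
                }
            )
    out = pd.DataFrame(loci, columns=["lead_snp", "chrom", "pos", "trait", "p", "n_snps", "traits"])
    if not out.empty:
        out["traits"] = out["traits"].map(lambda s: ",".join(sorted(s)))
    return out


def qq_points(pvalues) -> pd.DataFrame:
    """Expected vs observed -log10 p pairs for a Q-Q plot."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ValueError("no p-values")
    obs = np.sort(p)
    n = len(obs)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"expected": expected, "observed": -np.log10(obs)})
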