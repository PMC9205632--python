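"""Approximate-Bayes-factor colocalization of two association tracks.

For each SNP at a locus a Wakefield asymptotic Bayes factor is computed
from the estimated effect and its standard error; per-hypothesis evidence
is accumulated in log space and converted to posterior probabilities of
the five locus hypotheses:

* H0 — no association with either trait,
* H1 / H2 — association with trait 1 / trait 2 only,
* H3 — both traits, two distinct causal variants,
* H4 — both traits, one shared causal variant.

Priors p1, p2 (per-SNP association with one trait) and p12 (shared causal
SNP) follow the conventional single-variant colocalization defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["ColocResult", "wakefield_log_abf", "coloc_abf"]

# conventional effect-size prior SDs: quantitative trait / case-control
PRIOR_SD_QUANT = 0.15
PRIOR_SD_CC = 0.2


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities and per-SNP log ABFs."""

    pp: dict[str, float]
    snp_abf: pd.DataFrame
    priors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.pp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors sum to {total}, not 1")

    def __getitem__(self, key: str) -> float:
        return self.pp[key]


def wakefield_log_abf(beta, se, prior_w: float = PRIOR_SD_QUANT**2) -> np.ndarray:
    """Log approximate Bayes factor for association at one SNP.

    With V = se^2, z = beta/se and shrinkage r = prior_w / (V + prior_w):
    log ABF = 0.5 * log(1 - r) + 0.5 * r * z^2. ``prior_w`` is the prior
    variance of the true effect (default 0.15^2, the quantitative-trait
    convention; use 0.2^2 for log-odds effects from case-control scans).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or np.any(np.isnan(se)):
        raise ValueError("standard errors must be positive")
    if prior_w <= 0:
        raise ValueError("prior_w must be positive")
    V = se**2
    r = prior_w / (V + prior_w)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * r * z**2


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when the difference vanishes."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    track1: pd.DataFrame,
    track2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_w1: float = PRIOR_SD_QUANT**2,
    prior_w2: float = PRIOR_SD_QUANT**2,
) -> ColocResult:
    """Colocalize two summary-statistic tracks over one locus.

    Each track needs columns snp, beta, se; the SNP rosters are
    intersected. Hypothesis evidence is accumulated in log space
    (log-sum-exp), so loci with very large |z| do not overflow:

    * H1 ∝ p1 * sum_i ABF1_i          (trait 1 only)
    * H2 ∝ p2 * sum_j ABF2_j          (trait 2 only)
    * H3 ∝ p1*p2 * sum_{i != j} ABF1_i ABF2_j   (distinct causal SNPs)
    * H4 ∝ p12 * sum_i ABF1_i ABF2_i  (shared causal SNP)
    * H0 ∝ 1.
    """
    for name, pr in (("p1", p1), ("p2", p2), ("p12", p12)):
        if not (0.0 < pr < 1.0):
            raise ValueError(f"prior {name} must be in (0,1)")
    merged = track1.merge(track2, on="snp", suffixes=("_1", "_2"))
    if len(merged) < 2:
        raise ValueError(
            f"need >=2 shared SNPs at the locus, found {len(merged)}"
        )
    l1 = wakefield_log_abf(merged["beta_1"], merged["se_1"], prior_w1)
    l2 = wakefield_log_abf(merged["beta_2"], merged["se_2"], prior_w2)

    L1 = float(logsumexp(l1))
    L2 = float(logsumexp(l2))
    L12 = float(logsumexp(l1 + l2))

    lH0 = 0.0
    lH1 = np.log(p1) + L1
    lH2 = np.log(p2) + L2
    # sum over ordered distinct pairs = full product sum minus diagonal
    lH3 = np.log(p1) + np.log(p2) + _log_diff_exp(L1 + L2, L12)
    lH4 = np.log(p12) + L12

    logs = np.array([lH0, lH1, lH2, lH3, lH4])
    post = np.exp(logs - logsumexp(logs))
    post = post / post.sum()

    snp_abf = pd.DataFrame(
        {"snp": merged["snp"], "log_abf_1": l1, "log_abf_2": l2}
    )
    return ColocResult(
        pp={f"PP{i}": float(post[i]) for i in range(5)},
        snp_abf=snp_abf,
        priors={"p1": p1, "p2": p2, "p12": p12, "prior_w1": prior_w1, "prior_w2": prior_w2},
    )
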