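"""Fixed-effect inverse-variance-weighted meta-analysis of per-cohort
association records, with allele harmonisation.

Each (SNP, trait) key shared by the cohorts is combined with weights
w_k = 1/se_k^2: beta_meta = sum(w_k beta_k)/sum(w_k), se_meta =
1/sqrt(sum(w_k)), and a two-sided normal p from z = beta_meta/se_meta.
Cochran's Q is reported as a heterogeneity diagnostic but never used to
filter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["harmonize_alleles", "meta_fixed_effect", "PALINDROMIC_PAIRS"]

log = logging.getLogger(__name__)

PALINDROMIC_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def is_palindromic(effect: str, other: str) -> bool:
    return frozenset((effect.upper(), other.upper())) in PALINDROMIC_PAIRS


def harmonize_alleles(record_a: dict, record_b: dict) -> tuple[dict, dict]:
    """Align record_b's effect allele to record_a's, flipping beta if needed.

    Both records need ``effect_allele``, ``other_allele`` and ``beta``.
    Swapped alleles flip the second beta's sign; palindromic (A/T, C/G)
    SNPs are flagged ``palindromic`` on both outputs; incompatible allele
    pairs raise.
    """
    a = dict(record_a)
    b = dict(record_b)
    ea, oa = a["effect_allele"].upper(), a["other_allele"].upper()
    eb, ob = b["effect_allele"].upper(), b["other_allele"].upper()
    if (ea, oa) == (eb, ob):
        pass
    elif (ea, oa) == (ob, eb):
        b["effect_allele"], b["other_allele"] = a["effect_allele"], a["other_allele"]
        b["beta"] = -b["beta"]
    else:
        raise ValueError(
            f"incompatible alleles: {ea}/{oa} vs {eb}/{ob} for {a.get('snp', '?')}"
        )
    flag = is_palindromic(ea, oa)
    a["palindromic"] = flag
    b["palindromic"] = flag
    return a, b


def meta_fixed_effect(records_by_cohort: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """IVW fixed-effect meta-analysis over cohort summary-statistic frames.

    Frames must carry snp, trait, effect_allele, other_allele, beta, se, n.
    Only (snp, trait) keys present in every cohort are combined. Records
    whose alleles cannot be harmonised to the first cohort's orientation
    are dropped with a log message.
    """
    if len(records_by_cohort) < 2:
        raise ValueError("meta-analysis needs at least two cohorts")
    names = list(records_by_cohort)
    frames = []
    for name in names:
        f = records_by_cohort[name].copy()
        f = f.dropna(subset=["beta", "se"])
        f = f.loc[f["se"] > 0]
        frames.append(f.set_index(["snp", "trait"]))
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    frames = [f.loc[common] for f in frames]

    ref = frames[0]
    betas = [ref["beta"].to_numpy(dtype=float)]
    ses = [ref["se"].to_numpy(dtype=float)]
    keep = np.ones(len(common), dtype=bool)
    ref_e = ref["effect_allele"].str.upper().to_numpy()
    ref_o = ref["other_allele"].str.upper().to_numpy()
    for f in frames[1:]:
        e = f["effect_allele"].str.upper().to_numpy()
        o = f["other_allele"].str.upper().to_numpy()
        same = (e == ref_e) & (o == ref_o)
        swapped = (e == ref_o) & (o == ref_e)
        bad = ~(same | swapped)
        if bad.any():
            log.warning("dropping %d records with incompatible alleles", int(bad.sum()))
            keep &= ~bad
        beta = f["beta"].to_numpy(dtype=float).copy()
        beta[swapped] *= -1.0
        betas.append(beta)
        ses.append(f["se"].to_numpy(dtype=float))

    B = np.column_stack(betas)[keep]
    S = np.column_stack(ses)[keep]
    idx = common[keep]
    if len(idx) == 0:
        cols = ["snp", "trait", "effect_allele", "other_allele", "beta_meta",
                "se_meta", "z", "p", "q_het", "q_het_p", "direction", "palindromic"]
        return pd.DataFrame(columns=cols)
    W = 1.0 / S**2
    beta_meta = (W * B).sum(axis=1) / W.sum(axis=1)
    se_meta = 1.0 / np.sqrt(W.sum(axis=1))
    z = beta_meta / se_meta
    p = 2.0 * stats.norm.sf(np.abs(z))
    q_het = (W * (B - beta_meta[:, None]) ** 2).sum(axis=1)
    q_p = stats.chi2.sf(q_het, df=B.shape[1] - 1)
    direction = np.apply_along_axis(
        lambda row: "".join("+" if b > 0 else "-" if b < 0 else "0" for b in row), 1, B
    )
    palindromic = np.array(
        [is_palindromic(e, o) for e, o in zip(ref_e[keep], ref_o[keep])]
    )

    out = pd.DataFrame(
        {
            "snp": [k[0] for k in idx],
            "trait": [k[1] for k in idx],
            "effect_allele": ref.loc[idx, "effect_allele"].to_numpy(),
            "other_allele": ref.loc[idx, "other_allele"].to_numpy(),
            "beta_meta": beta_meta,
            "se_meta": se_meta,
            "z": z,
            "p": p,
            "q_het": q_het,
            "q_het_p": q_p,
            "direction": direction,
            "palindromic": palindromic,
        }
    )
    for name, b_col, s_col in zip(names, B.T, S.T):
        out[f"beta_{name}"] = b_col
        out[f"se_{name}"] = s_col
        nvals = records_by_cohort[name].set_index(["snp", "trait"])
        if "n" in nvals.columns:
            out[f"n_{name}"] = nvals.loc[idx, "n"].to_numpy()
    return out
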