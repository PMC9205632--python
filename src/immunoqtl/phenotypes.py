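"""Phenotype preparation: hierarchy proportions, rank-based normalisation,
log2 cytokines, the covariate association screen and the cell x cytokine
correlation map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import season_design

__all__ = [
    "TraitTable",
    "derive_proportions",
    "inverse_rank_transform",
    "log2_transform",
    "covariate_screen",
    "correlate_cells_cytokines",
]

log = logging.getLogger(__name__)


@dataclass
class TraitTable:
    """Samples x traits values plus per-trait metadata.

    ``meta`` is indexed by trait and carries ``trait_class``
    (cell-proportion | cytokine), ``category`` (T/B/monocyte/NK or empty),
    ``parent``/``grandparent`` hierarchy links, ``stimulation`` and the
    transform applied.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate trait names")
        if not self.values.columns.equals(self.meta.index):
            self.meta = self.meta.reindex(self.values.columns)

    @property
    def traits(self) -> pd.Index:
        return self.values.columns

    def traits_in_category(self, category: str) -> list[str]:
        return self.meta.index[self.meta["category"] == category].tolist()

    def concat(self, other: "TraitTable") -> "TraitTable":
        overlap = self.values.columns.intersection(other.values.columns)
        if len(overlap):
            raise ValueError(f"trait names collide: {list(overlap)[:5]}")
        return TraitTable(
            pd.concat([self.values, other.values], axis=1),
            pd.concat([self.meta, other.meta], axis=0),
        )


def _parents(hierarchy: pd.DataFrame) -> dict[str, str | None]:
    out = {}
    for node, parent in zip(hierarchy["node"], hierarchy["parent"]):
        out[node] = None if (parent is None or (isinstance(parent, float) and np.isnan(parent))) else parent
    return out


def derive_proportions(counts: pd.DataFrame, hierarchy: pd.DataFrame) -> TraitTable:
    """Per-node proportions: count(node) / count(parent).

    A zero parent count yields a missing proportion rather than an error.
    The root node has no parent and produces no trait.
    """
    parent_of = _parents(hierarchy)
    cat = dict(zip(hierarchy["node"], hierarchy["category"]))
    missing = [n for n in parent_of if n not in counts.columns]
    if missing:
        raise ValueError(f"hierarchy nodes absent from counts table: {missing[:5]}")

    values = {}
    meta_rows = []
    for node, parent in parent_of.items():
        if parent is None:
            continue
        p = counts[parent].to_numpy(dtype=float)
        c = counts[node].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            prop = np.where(p > 0, c / p, np.nan)
        values[node] = prop
        meta_rows.append(
            {
                "trait": node,
                "trait_class": "cell-proportion",
                "category": cat.get(node, ""),
                "parent": parent,
                "grandparent": parent_of.get(parent) or "",
                "stimulation": "",
                "transform": "proportion",
            }
        )
    vals = pd.DataFrame(values, index=counts.index)
    meta = pd.DataFrame(meta_rows).set_index("trait")
    return TraitTable(vals, meta)


def inverse_rank_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset by default).

    z_i = Phi^-1((rank_i - c) / (n - 2c + 1)) over the non-missing entries;
    ties receive their average rank and missing values stay missing.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    x = v[ok]
    if len(np.unique(x)) < 2:
        raise ValueError("inverse rank transform needs >=2 distinct values")
    ranks = stats.rankdata(x, method="average")
    n = len(x)
    out[ok] = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def log2_transform(cytokines: pd.DataFrame) -> TraitTable:
    """Elementwise log2 of cytokine concentrations (all must be > 0)."""
    arr = cytokines.to_numpy(dtype=float)
    bad = ~np.isnan(arr) & (arr <= 0)
    if bad.any():
        rows, cols = np.nonzero(bad)
        cells = [
            f"({cytokines.index[r]}, {cytokines.columns[c]})"
            for r, c in list(zip(rows, cols))[:10]
        ]
        raise ValueError(f"non-positive cytokine values at {cells}")
    vals = pd.DataFrame(np.log2(arr), index=cytokines.index, columns=cytokines.columns)
    meta = pd.DataFrame(
        {
            "trait_class": "cytokine",
            "category": "",
            "parent": "",
            "grandparent": "",
            "stimulation": [c.split("_", 1)[1] if "_" in c else "" for c in cytokines.columns],
            "transform": "log2",
        },
        index=pd.Index(cytokines.columns, name="trait"),
    )
    return TraitTable(vals, meta)


def _season_f_test(y: np.ndarray, day: np.ndarray) -> tuple[float, float]:
    """Joint F-test of the sin/cos season pair in an OLS fit."""
    X = np.column_stack([np.ones(len(y)), season_design(day)])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df2 = len(y) - X.shape[1]
    if df2 <= 0 or rss1 <= 0:
        return np.nan, np.nan
    f = ((rss0 - rss1) / 2.0) / (rss1 / df2)
    return f, float(stats.f.sf(f, 2, df2))


def covariate_screen(
    traits: TraitTable | pd.DataFrame,
    covariates: pd.DataFrame,
    min_pairs: int = 10,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Screen each trait against age, sex and season.

    Age uses a Spearman correlation test, sex a linear regression on the
    binary code, and season a joint F-test of the sin/cos(day-of-year)
    pair. Benjamini-Hochberg adjustment is applied within each covariate
    across traits. Traits with fewer than ``min_pairs`` complete pairs are
    skipped with a log message.
    """
    values = traits.values if isinstance(traits, TraitTable) else traits
    values = values.loc[values.index.intersection(covariates.index)]
    cov = covariates.loc[values.index]
    rows = []
    for trait in values.columns:
        y_all = values[trait].to_numpy(dtype=float)
        for name in ("age", "sex", "season"):
            c = cov["day" if name == "season" else name].to_numpy(dtype=float)
            ok = ~np.isnan(y_all) & ~np.isnan(c)
            if ok.sum() < min_pairs:
                log.warning("trait %s skipped for %s: %d complete pairs", trait, name, ok.sum())
                continue
            y = y_all[ok]
            if name == "age":
                rho, p = stats.spearmanr(y, c[ok])
                stat = rho
            elif name == "sex":
                res = stats.linregress(c[ok], y)
                stat, p = res.slope, res.pvalue
            else:
                stat, p = _season_f_test(y, c[ok])
            rows.append({"trait": trait, "covariate": name, "statistic": stat, "p": p})
    out = pd.DataFrame(rows, columns=["trait", "covariate", "statistic", "p"])
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    out["q"] = np.nan
    for name, grp in out.groupby("covariate"):
        valid = grp["p"].notna()
        if valid.any():
            q = multipletests(grp.loc[valid, "p"], method="fdr_bh")[1]
            out.loc[grp.index[valid], "q"] = q
    out["significant"] = out["q"] < q_threshold
    return out


def correlate_cells_cytokines(
    cell_counts: pd.DataFrame,
    cytokines: pd.DataFrame,
    q_threshold: float = 0.05,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Spearman correlation of every cell count with every cytokine trait.

    Returns one row per (cell, cytokine) pair with rho, p and a
    Benjamini-Hochberg q across all pairs; pairs significant at
    ``q_threshold`` are flagged.
    """
    shared = cell_counts.index.intersection(cytokines.index)
    if len(shared) < min_pairs:
        raise ValueError(f"only {len(shared)} shared samples (need >= {min_pairs})")
    A = cell_counts.loc[shared].to_numpy(dtype=float)
    B = cytokines.loc[shared].to_numpy(dtype=float)
    n = len(shared)
    # rank-transform columns, then Pearson of ranks == Spearman (complete data)
    Ar = np.apply_along_axis(stats.rankdata, 0, A)
    Br = np.apply_along_axis(stats.rankdata, 0, B)
    Az = (Ar - Ar.mean(0)) / Ar.std(0)
    Bz = (Br - Br.mean(0)) / Br.std(0)
    rho = Az.T @ Bz / n
    rho = np.clip(rho, -1.0, 1.0)
    # t-approximation for the Spearman p-value
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), np.where(np.abs(rho) >= 1.0, 0.0, np.nan), p)

    rows = pd.DataFrame(
        {
            "cell": np.repeat(cell_counts.columns, len(cytokines.columns)),
            "cytokine": np.tile(cytokines.columns, len(cell_counts.columns)),
            "rho": rho.ravel(),
            "p": p.ravel(),
        }
    )
    rows["q"] = multipletests(rows["p"].fillna(1.0), method="fdr_bh")[1]
    rows["significant"] = rows["q"] < q_threshold
    return rows
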