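"""Synthetic two-cohort immune-genomics data generator.

Emulates the statistical structure of a functional-genomics cohort study in
which diploid SNP genotypes are tested against immune-cell composition
(counts on a gating hierarchy) and stimulated cytokine production:

* genotypes with block-wise linkage disequilibrium (latent AR(1) Gaussian
  haplotypes thresholded at the allele frequency),
* hierarchical, compositional cell counts (log-normal root, logistic-normal
  child fractions whose logits carry planted genotype and covariate effects),
* log-normal cytokine concentrations (additive effects on the log2 scale),
* age / sex / season covariates with per-trait effects,
* a designated set of mutually LD-independent "GWAS" SNPs with effects
  planted in one trait category, recorded in a ground-truth table.

Every draw flows from a single integer seed through named substreams, so a
config reproduces its dataset bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "CohortDataset",
    "GenotypeMatrix",
    "default_hierarchy",
    "validate_hierarchy",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_cell_counts",
    "simulate_cytokines",
    "designate_gwas_set",
    "plant_category_effects",
    "simulate_cohort",
    "simulate_study",
]

CATEGORIES = ("T", "B", "monocyte", "NK")

# substream ids: one per independent source of randomness
_SUB_MAF = 11
_SUB_GENO = 23
_SUB_COV = 37
_SUB_CELLS = 41
_SUB_CYTO = 43
_SUB_GWAS = 53


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix with variant metadata.

    ``dosages`` holds 0/1/2 with ``nan`` for missing genotypes.
    ``variants`` carries snp, chrom, pos, ref, alt (one row per column).
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x snps)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample count does not match dosage rows")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant count does not match dosage columns")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or missing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.variants["snp"])

    def column(self, snp: str) -> np.ndarray:
        """Dosage vector for one SNP id."""
        idx = self.variants.index[self.variants["snp"] == snp]
        if len(idx) == 0:
            raise KeyError(f"SNP {snp!r} not in genotype matrix")
        return self.dosages[:, idx[0]]

    def subset_snps(self, snps) -> "GenotypeMatrix":
        pos = self.variants.reset_index(drop=True)
        lookup = {s: i for i, s in enumerate(pos["snp"])}
        missing = [s for s in snps if s not in lookup]
        if missing:
            raise KeyError(f"SNPs absent from matrix: {missing[:5]}")
        cols = [lookup[s] for s in snps]
        return GenotypeMatrix(
            self.dosages[:, cols],
            list(self.samples),
            pos.iloc[cols].reset_index(drop=True),
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        rows = [lookup[s] for s in sample_ids]
        return GenotypeMatrix(
            self.dosages[rows, :], list(sample_ids), self.variants.copy()
        )


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohorts.

    Defaults give a desk-scale study (2 x 300 samples, 5,000 SNPs,
    40 cell + 20 cytokine traits) that runs through the full pipeline in
    minutes while preserving the cohort asymmetry of the emulated study
    (a smaller "disease" and a larger "healthy" cohort is obtained by
    passing ``n_samples_per_cohort=(215, 451)``).
    """

    n_samples_per_cohort: tuple[int, ...] = (300, 300)
    n_snps: int = 5000
    ld_block_size: int = 10
    ld_rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    cell_hierarchy: pd.DataFrame | None = None
    n_cell_traits: int = 40
    n_cytokine_traits: int = 20
    qtl_effects: list[tuple[str, str, float]] = field(default_factory=list)
    gwas_set_size: int = 63
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    cell_logit_sd: float = 0.4
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_samples_per_cohort):
            raise ValueError("cohort sizes must be positive")
        if self.n_snps <= 0 or self.ld_block_size <= 0:
            raise ValueError("n_snps and ld_block_size must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.noise_sd <= 0 or self.cell_logit_sd <= 0:
            raise ValueError("noise scales must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.cell_hierarchy is None:
            self.cell_hierarchy = default_hierarchy(self.n_cell_traits)
        validate_hierarchy(self.cell_hierarchy)

    def validate_effects(self, snp_ids, trait_ids) -> None:
        snps = set(snp_ids)
        traits = set(trait_ids)
        for snp, trait, _ in self.qtl_effects:
            if snp not in snps:
                raise ValueError(f"planted effect references unknown SNP {snp!r}")
            if trait not in traits:
                raise ValueError(f"planted effect references unknown trait {trait!r}")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class CohortDataset:
    """One cohort: genotypes, raw counts, cytokines, covariates and truth."""

    name: str
    genotypes: GenotypeMatrix
    counts: pd.DataFrame
    cytokines: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame
    hierarchy: pd.DataFrame


def default_hierarchy(n_cell_traits: int = 40) -> pd.DataFrame:
    """Build a rooted gating tree over the four major lineages.

    Root -> {T, B, monocyte, NK} -> subset nodes (-> sub-subset nodes),
    with surplus nodes distributed round-robin across lineages so each
    category keeps a comparable trait count.
    """
    if n_cell_traits < len(CATEGORIES) + 1:
        raise ValueError("hierarchy needs at least the root and 4 lineages")
    rows = [("leukocytes", None, "root")]
    for cat in CATEGORIES:
        rows.append((cat, "leukocytes", cat))
    remaining = n_cell_traits - len(rows)
    level1: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    i = 0
    while remaining > 0:
        cat = CATEGORIES[i % len(CATEGORIES)]
        depth1 = level1[cat]
        # grow two subset tiers: lineage subsets first, then sub-subsets
        if len(depth1) < 4:
            name = f"{cat}_sub{len(depth1) + 1}"
            rows.append((name, cat, cat))
            depth1.append(name)
        else:
            parent = depth1[(i // len(CATEGORIES)) % len(depth1)]
            name = f"{parent}_s{i}"
            rows.append((name, parent, cat))
        i += 1
        remaining -= 1
    return pd.DataFrame(rows, columns=["node", "parent", "category"])


def validate_hierarchy(hierarchy: pd.DataFrame) -> str:
    """Check the hierarchy is a single rooted tree; return the root node."""
    required = {"node", "parent", "category"}
    if not required.issubset(hierarchy.columns):
        raise ValueError(f"hierarchy needs columns {sorted(required)}")
    nodes = hierarchy["node"].tolist()
    if len(set(nodes)) != len(nodes):
        raise ValueError("duplicate nodes in hierarchy")
    parent = dict(zip(hierarchy["node"], hierarchy["parent"]))
    roots = [n for n, p in parent.items() if p is None or (isinstance(p, float) and np.isnan(p))]
    if len(roots) != 1:
        raise ValueError(f"hierarchy must have exactly one root, found {roots}")
    for n in nodes:
        seen = set()
        cur = n
        while cur is not None and not (isinstance(cur, float) and np.isnan(cur)):
            if cur in seen:
                raise ValueError(f"cycle in hierarchy at node {n!r}")
            seen.add(cur)
            if cur != roots[0] and parent.get(cur) not in parent and parent.get(cur) is not None:
                raise ValueError(f"parent {parent.get(cur)!r} of {cur!r} not in hierarchy")
            cur = parent.get(cur)
    return roots[0]


def _rng(config: SimulationConfig, substream: int, cohort_index: int = 0):
    return np.random.default_rng(
        np.random.SeedSequence((config.seed, substream, cohort_index))
    )


def _draw_mafs(config: SimulationConfig) -> np.ndarray:
    """Per-SNP MAFs, shared across cohorts (drawn from the config seed only)."""
    rng = _rng(config, _SUB_MAF)
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_snps)


def variant_table(config: SimulationConfig) -> pd.DataFrame:
    """Variant metadata for the simulated panel: one chromosome per LD block
    group of 100 blocks, 5 kb SNP spacing."""
    m = config.n_snps
    block = np.arange(m) // config.ld_block_size
    chrom = (block // 100 % 22 + 1).astype(int)
    pos = (np.arange(m) % (100 * config.ld_block_size)) * 5000 + 10_000
    return pd.DataFrame(
        {
            "snp": [f"snp{i:06d}" for i in range(m)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )


def simulate_genotypes(
    config: SimulationConfig, n_samples: int | None = None, cohort_index: int = 0
) -> GenotypeMatrix:
    """Diploid dosages with AR(1) linkage disequilibrium within blocks.

    Each of the two haplotypes per sample is a latent Gaussian AR(1) series
    (correlation ``ld_rho`` between adjacent SNPs, restarted at every block
    boundary) thresholded at the normal quantile of the SNP's allele
    frequency, so adjacent-SNP haplotype correlation decays as rho^distance
    and blocks are exactly independent.
    """
    n = int(config.n_samples_per_cohort[cohort_index] if n_samples is None else n_samples)
    m = config.n_snps
    if n <= 0:
        raise ValueError("n_samples must be positive")
    rng = _rng(config, _SUB_GENO, cohort_index)
    mafs = _draw_mafs(config)
    thresh = stats.norm.ppf(mafs)

    dosage = np.zeros((n, m))
    rho = config.ld_rho
    innov_sd = np.sqrt(1.0 - rho**2)
    for _hap in range(2):
        z = np.empty((n, m))
        eps = rng.standard_normal((n, m))
        starts = np.arange(0, m, config.ld_block_size)
        for s in starts:
            e = min(s + config.ld_block_size, m)
            z[:, s] = eps[:, s]
            for j in range(s + 1, e):
                z[:, j] = rho * z[:, j - 1] + innov_sd * eps[:, j]
        dosage += (z < thresh).astype(float)

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosage[miss] = np.nan

    samples = [f"C{cohort_index}_S{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosage, samples, variant_table(config))


def simulate_covariates(
    config: SimulationConfig, n_samples: int, cohort_index: int = 0
) -> pd.DataFrame:
    """Age (years), sex (0/1) and sampling day-of-year per sample."""
    rng = _rng(config, _SUB_COV, cohort_index)
    age = rng.uniform(20, 75, size=n_samples)
    sex = rng.integers(0, 2, size=n_samples).astype(float)
    day = rng.integers(1, 366, size=n_samples).astype(float)
    idx = [f"C{cohort_index}_S{i:04d}" for i in range(n_samples)]
    return pd.DataFrame({"age": age, "sex": sex, "day": day}, index=idx)


def season_design(day: np.ndarray) -> np.ndarray:
    """Smooth periodic encoding of day-of-year: [sin, cos](2*pi*day/365)."""
    ang = 2.0 * np.pi * np.asarray(day, dtype=float) / 365.0
    return np.column_stack([np.sin(ang), np.cos(ang)])


def _covariate_shift(
    trait: str, covariates: pd.DataFrame, config: SimulationConfig
) -> np.ndarray:
    eff = config.covariate_effects.get(trait)
    if not eff:
        return np.zeros(len(covariates))
    sincos = season_design(covariates["day"].to_numpy())
    shift = (
        eff.get("age", 0.0) * (covariates["age"].to_numpy() - 45.0) / 15.0
        + eff.get("sex", 0.0) * covariates["sex"].to_numpy()
        + eff.get("season_sin", 0.0) * sincos[:, 0]
        + eff.get("season_cos", 0.0) * sincos[:, 1]
    )
    return shift


def _effects_for(trait: str, config: SimulationConfig) -> list[tuple[str, float]]:
    return [(snp, beta) for snp, t, beta in config.qtl_effects if t == trait]


def _dosage_centered(genotypes: GenotypeMatrix, snp: str) -> np.ndarray:
    g = genotypes.column(snp)
    g = np.where(np.isnan(g), np.nanmean(g), g)
    return g - g.mean()


def simulate_cell_counts(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
    cohort_index: int = 0,
) -> pd.DataFrame:
    """Cell counts per hierarchy node with logistic-normal branching.

    Root counts are log-normal. For each internal node its children receive
    fractions ``exp(l_i) / (1 + sum_j exp(l_j))`` of the parent count, which
    guarantees sibling fractions sum to < 1 (the remainder is ungated).
    Each child logit ``l_i`` carries the planted genotype effects (per
    dosage copy), the configured covariate effects and Gaussian noise.
    """
    hier = config.cell_hierarchy
    root = validate_hierarchy(hier)
    if covariates is None:
        covariates = simulate_covariates(config, genotypes.n_samples, cohort_index)
    config.validate_effects(
        genotypes.snp_ids,
        list(hier["node"]) + cytokine_trait_names(config.n_cytokine_traits),
    )
    rng = _rng(config, _SUB_CELLS, cohort_index)
    n = genotypes.n_samples

    counts = pd.DataFrame(index=genotypes.samples, columns=hier["node"], dtype=float)
    counts[root] = np.exp(rng.normal(np.log(1e4), 0.3, size=n))

    children: dict[str, list[str]] = {}
    for node, parent in zip(hier["node"], hier["parent"]):
        if parent is not None and not (isinstance(parent, float) and np.isnan(parent)):
            children.setdefault(parent, []).append(node)

    frontier = [root]
    while frontier:
        parent = frontier.pop(0)
        kids = children.get(parent, [])
        if not kids:
            continue
        k = len(kids)
        base = np.log((0.75 / k) / 0.25)  # expected total occupancy ~75%
        logits = np.empty((n, k))
        for j, kid in enumerate(kids):
            shift = _covariate_shift(kid, covariates, config)
            for snp, beta in _effects_for(kid, config):
                shift = shift + beta * _dosage_centered(genotypes, snp)
            logits[:, j] = base + shift + rng.normal(0.0, config.cell_logit_sd, size=n)
        expl = np.exp(logits)
        frac = expl / (1.0 + expl.sum(axis=1, keepdims=True))
        for j, kid in enumerate(kids):
            counts[kid] = counts[parent].to_numpy() * frac[:, j]
        frontier.extend(kids)
    return counts


def cytokine_trait_names(n_cytokine_traits: int) -> list[str]:
    cytokines = ["IL6", "IL1b", "TNFa", "IL10", "IFNg", "IL17", "IL22", "IL8"]
    stims = ["LPS", "Calbicans", "Saureus", "PolyIC", "MTB", "Ecoli", "Pam3Cys"]
    names = [f"{c}_{s}" for s in stims for c in cytokines]
    if n_cytokine_traits > len(names):
        names += [f"cytokine{i}_stim" for i in range(len(names), n_cytokine_traits)]
    return names[:n_cytokine_traits]


def simulate_cytokines(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
    cohort_index: int = 0,
) -> pd.DataFrame:
    """Stimulated cytokine concentrations (strictly positive).

    log2 concentration = intercept + planted genotype effects + covariate
    effects + N(0, noise_sd); the returned table is on the concentration
    scale (2 ** log2).
    """
    if covariates is None:
        covariates = simulate_covariates(config, genotypes.n_samples, cohort_index)
    traits = cytokine_trait_names(config.n_cytokine_traits)
    config.validate_effects(
        genotypes.snp_ids, list(config.cell_hierarchy["node"]) + traits
    )
    rng = _rng(config, _SUB_CYTO, cohort_index)
    n = genotypes.n_samples
    out = pd.DataFrame(index=genotypes.samples, columns=traits, dtype=float)
    for trait in traits:
        intercept = rng.uniform(4.0, 10.0)
        log2 = intercept + _covariate_shift(trait, covariates, config)
        for snp, beta in _effects_for(trait, config):
            g = genotypes.column(snp)
            g = np.where(np.isnan(g), np.nanmean(g), g)
            log2 = log2 + beta * g
        log2 = log2 + rng.normal(0.0, config.noise_sd, size=n)
        out[trait] = np.exp2(log2)
    return out


def plant_category_effects(
    gwas_snps, hierarchy: pd.DataFrame, category: str, beta: float
) -> list[tuple[str, str, float]]:
    """Effect entries (snp, trait, beta) for every trait in one lineage."""
    traits = hierarchy.loc[hierarchy["category"] == category, "node"].tolist()
    if not traits:
        raise ValueError(f"no traits in category {category!r}")
    return [(snp, trait, beta) for snp in gwas_snps for trait in traits]


def designate_gwas_set(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    size: int | None = None,
    r2_max: float = 0.2,
    category: str | None = None,
    effect: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pick a set of mutually LD-independent SNPs as the disease "GWAS" set.

    Returns ``(gwas_set, truth)``: the set table (snp, risk_allele, p, study)
    and a truth table of planted (snp, trait, beta) rows for ``category``
    (empty when ``effect`` is 0). Append the truth rows to
    ``config.qtl_effects`` before simulating phenotypes to realize them.
    """
    from .gwas_sets import ld_prune, ld_r2

    size = config.gwas_set_size if size is None else int(size)
    pool = ld_prune(genotypes, r2_threshold=r2_max, window_snps=2 * config.ld_block_size)
    if size > len(pool):
        raise ValueError(
            f"requested {size} independent SNPs but only {len(pool)} available at r2<{r2_max}"
        )
    rng = _rng(config, _SUB_GWAS)
    # windowed pruning leaves distant pairs unchecked, so accept candidates
    # greedily only when independent of everything already accepted
    order = rng.permutation(len(pool))
    pool_mat = genotypes.subset_snps(pool).dosages
    snps: list[str] = []
    cols: list[int] = []
    for i in order:
        if all(ld_r2(pool_mat[:, i], pool_mat[:, j]) < r2_max for j in cols):
            snps.append(pool[i])
            cols.append(i)
            if len(snps) == size:
                break
    if len(snps) < size:
        raise ValueError(
            f"requested {size} mutually independent SNPs but only {len(snps)} found at r2<{r2_max}"
        )
    snp_order = {s: k for k, s in enumerate(genotypes.variants["snp"])}
    snps.sort(key=snp_order.__getitem__)
    var = genotypes.variants.set_index("snp")
    gwas_set = pd.DataFrame(
        {
            "snp": snps,
            "risk_allele": var.loc[snps, "alt"].to_numpy(),
            "p": np.full(len(snps), 1e-8),
            "study": "synthetic",
        }
    )
    if effect != 0.0:
        if category is None:
            raise ValueError("category required when planting effects")
        rows = plant_category_effects(snps, config.cell_hierarchy, category, effect)
        truth = pd.DataFrame(rows, columns=["snp", "trait", "beta"])
    else:
        truth = pd.DataFrame(columns=["snp", "trait", "beta"])
    return gwas_set, truth


def simulate_cohort(
    config: SimulationConfig, cohort_index: int = 0, name: str | None = None
) -> CohortDataset:
    """Generate one full cohort (genotypes, counts, cytokines, covariates)."""
    genotypes = simulate_genotypes(config, cohort_index=cohort_index)
    covariates = simulate_covariates(config, genotypes.n_samples, cohort_index)
    counts = simulate_cell_counts(genotypes, config, covariates, cohort_index)
    cytokines = simulate_cytokines(genotypes, config, covariates, cohort_index)
    truth = pd.DataFrame(config.qtl_effects, columns=["snp", "trait", "beta"])
    return CohortDataset(
        name=name or f"cohort{cohort_index}",
        genotypes=genotypes,
        counts=counts,
        cytokines=cytokines,
        covariates=covariates,
        truth=truth,
        hierarchy=config.cell_hierarchy,
    )


def simulate_study(config: SimulationConfig) -> dict[str, CohortDataset]:
    """Two-cohort study sharing the variant panel and planted truth.

    The first cohort is labelled ``disease`` and the second ``healthy``,
    mirroring a patient cohort analyzed against a population cohort.
    """
    names = ["disease", "healthy"] + [
        f"cohort{i}" for i in range(2, len(config.n_samples_per_cohort))
    ]
    return {
        names[i]: simulate_cohort(config, cohort_index=i, name=names[i])
        for i in range(len(config.n_samples_per_cohort))
    }
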