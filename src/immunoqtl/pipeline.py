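"""End-to-end orchestration: simulate -> QC -> prep -> scan -> meta ->
GWAS-set tests -> colocalization, from a single config with one seed.

Every stage writes its outputs under the configured directory plus a row
in ``manifest.json`` (stage, parameters, seed, output paths and row
counts). All randomness flows from the top-level seed through named
substreams, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas_sets, meta, phenotypes, qc, qtl, vcfio
from .simulate import SimulationConfig, designate_gwas_set, simulate_study

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "prep", "map", "meta", "gwas_tests", "coloc")


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for a full pipeline run."""

    outdir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # simulation scale
    n_samples_per_cohort: tuple[int, ...] = (300, 300)
    n_snps: int = 5000
    n_cell_traits: int = 40
    n_cytokine_traits: int = 20
    ld_rho: float = 0.6
    gwas_set_size: int = 63
    planted_category: str | None = "T"
    planted_beta: float = 0.25
    # thresholds
    call_rate_min: float = 0.99
    maf_min: float = 0.01
    hwe_min: float = 1e-5
    genome_wide_p: float = 5e-8
    suggestive_alpha: float = 0.05
    clump_r2: float = 0.1
    prune_r2: float = 0.2
    n_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stages", "n_samples_per_cohort"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _manifest_row(out: Path, stage: str, seed: int, params: dict, outputs: dict) -> None:
    row = {
        "stage": stage,
        "seed": seed,
        "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "params": params,
        "outputs": outputs,
    }
    with open(out / "manifest.json", "a") as fh:
        fh.write(json.dumps(row) + "\n")


def _rows(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns a summary.

    The summary collects the headline quantities of each stage (QC
    exclusions, inflation factor, significant loci, permutation p-values,
    colocalization posteriors) for programmatic use; full tables live in
    the output directory.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "outdir": str(out)}
    enabled = set(config.stages)

    sim_cfg = SimulationConfig(
        n_samples_per_cohort=config.n_samples_per_cohort,
        n_snps=config.n_snps,
        n_cell_traits=config.n_cell_traits,
        n_cytokine_traits=config.n_cytokine_traits,
        ld_rho=config.ld_rho,
        gwas_set_size=config.gwas_set_size,
        seed=config.seed,
    )

    # ---------------- simulate ----------------
    if "simulate" not in enabled:
        raise ValueError("file-based entry is handled by the CLI subcommands; "
                         "run_pipeline always starts from simulation")
    log.info("stage simulate: %s cohorts, %d SNPs", len(config.n_samples_per_cohort), config.n_snps)
    proto = simulate_study(sim_cfg)["disease"].genotypes  # panel for GWAS-set choice
    gwas_set, truth = designate_gwas_set(
        proto,
        sim_cfg,
        category=config.planted_category,
        effect=config.planted_beta if config.planted_category else 0.0,
    )
    sim_cfg = sim_cfg.replace(
        qtl_effects=[tuple(r) for r in truth.itertuples(index=False)]
    )
    study = simulate_study(sim_cfg)
    outputs = {}
    for name, ds in study.items():
        vcfio.write_vcf(ds.genotypes, out / f"{name}.vcf")
        vcfio.write_tsv(ds.counts, out / f"{name}_counts.tsv")
        vcfio.write_tsv(ds.cytokines, out / f"{name}_cytokines.tsv")
        vcfio.write_tsv(ds.covariates, out / f"{name}_covariates.tsv")
        outputs[f"{name}_vcf"] = _rows(out / f"{name}.vcf")
    gwas_set.to_csv(out / "gwas_set.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    sim_cfg.cell_hierarchy.to_csv(out / "hierarchy.tsv", sep="\t", index=False)
    _manifest_row(out, "simulate", config.seed,
                  {"n_snps": config.n_snps, "cohorts": list(config.n_samples_per_cohort)},
                  outputs)
    summary["n_planted_effects"] = len(truth)

    # ---------------- qc ----------------
    hierarchy = sim_cfg.cell_hierarchy
    if "qc" in enabled:
        has_healthy = "healthy" in study
        for name, ds in study.items():
            # HWE is assessed in the healthy cohort only (disease cohorts can
            # deviate for biological reasons); single-cohort runs apply it.
            hwe_min = config.hwe_min if (name == "healthy" or not has_healthy) else 0.0
            kept, report = qc.filter_variants(
                ds.genotypes,
                call_rate_min=config.call_rate_min,
                maf_min=config.maf_min,
                hwe_min=hwe_min,
            )
            het_out = qc.heterozygosity_outliers(kept)
            if het_out:
                kept = kept.subset_samples([s for s in kept.samples if s not in het_out])
            ds.genotypes = kept
            report.to_tsv(out / f"{name}_qc_metrics.tsv")
            summary[f"qc_excluded_{name}"] = report.n_excluded
            summary[f"qc_het_outliers_{name}"] = len(het_out)
        _manifest_row(out, "qc", config.seed, report.thresholds,
                      {f"excluded_{n}": summary[f"qc_excluded_{n}"] for n in study})
    else:
        log.warning("QC disabled: downstream stages run on raw genotypes")

    # ---------------- prep ----------------
    prepared: dict[str, phenotypes.TraitTable] = {}
    if "prep" in enabled:
        for name, ds in study.items():
            props = phenotypes.derive_proportions(ds.counts, hierarchy)
            irt = props.values.apply(
                lambda col: phenotypes.inverse_rank_transform(col.to_numpy()), axis=0,
                result_type="expand",
            )
            irt.index = props.values.index
            cell_tt = phenotypes.TraitTable(irt, props.meta.assign(transform="inverse-rank"))
            cyto_tt = phenotypes.log2_transform(ds.cytokines)
            prepared[name] = cell_tt.concat(cyto_tt)
            vcfio.write_tsv(prepared[name].values, out / f"{name}_traits.tsv")
            prepared[name].meta.to_csv(out / f"{name}_trait_meta.tsv", sep="\t")
            screen = phenotypes.covariate_screen(cell_tt, ds.covariates)
            screen.to_csv(out / f"{name}_covariate_screen.tsv", sep="\t", index=False)
        corr = phenotypes.correlate_cells_cytokines(
            study["disease"].counts, study["disease"].cytokines
        )
        corr.to_csv(out / "cell_cytokine_correlation.tsv", sep="\t", index=False)
        summary["n_significant_cell_cytokine_pairs"] = int(corr["significant"].sum())
        _manifest_row(out, "prep", config.seed, {},
                      {"traits": prepared["disease"].values.shape[1]})

    # ---------------- map ----------------
    sumstats: dict[str, pd.DataFrame] = {}
    if "map" in enabled:
        for name, ds in study.items():
            recs = qtl.map_qtl(ds.genotypes, prepared[name].values, ds.covariates)
            recs.to_csv(out / f"{name}_sumstats.tsv", sep="\t", index=False)
            sumstats[name] = recs
            lam = qtl.genomic_inflation(recs["p"])
            summary[f"lambda_{name}"] = lam
        loci = qtl.significant_loci(sumstats["disease"], threshold=config.genome_wide_p)
        loci.to_csv(out / "disease_loci.tsv", sep="\t", index=False)
        summary["n_significant_loci_disease"] = len(loci)
        qtl.qq_points(sumstats["disease"]["p"]).to_csv(out / "disease_qq.tsv", sep="\t", index=False)
        _manifest_row(out, "map", config.seed, {"threshold": config.genome_wide_p},
                      {f"records_{n}": len(sumstats[n]) for n in sumstats})

    # ---------------- meta ----------------
    if "meta" in enabled and len(sumstats) >= 2:
        combined = meta.meta_fixed_effect(sumstats)
        combined.to_csv(out / "meta_sumstats.tsv", sep="\t", index=False)
        meta_loci = qtl.significant_loci(
            combined.rename(columns={"p": "p", "beta_meta": "beta"})
            .merge(study["disease"].genotypes.variants[["snp", "chrom", "pos"]], on="snp"),
            threshold=config.genome_wide_p,
        )
        summary["n_significant_loci_meta"] = len(meta_loci)
        _manifest_row(out, "meta", config.seed, {}, {"records": len(combined)})

    # ---------------- gwas_tests ----------------
    if "gwas_tests" in enabled:
        disease = study["disease"]
        pool = gwas_sets.ld_prune(disease.genotypes, r2_threshold=config.prune_r2)
        category = config.planted_category or "T"
        cat_traits = prepared["disease"].traits_in_category(category)
        enr = gwas_sets.enrichment_test(
            sumstats["disease"],
            gwas_set["snp"],
            cat_traits,
            pool,
            B=config.n_permutations,
            alpha=config.suggestive_alpha,
            seed=config.seed,
            label=category,
        )
        summary["enrichment_observed"] = enr.observed
        summary["enrichment_p"] = enr.p
        pd.DataFrame({"null_count": enr.null}).to_csv(
            out / "enrichment_null.tsv", sep="\t", index=False
        )
        # variance explained for the first category trait, aligned to the
        # post-QC sample set
        trait = cat_traits[0]
        samples = [s for s in disease.genotypes.samples
                   if s in prepared["disease"].values.index]
        geno = (disease.genotypes if len(samples) == disease.genotypes.n_samples
                else disease.genotypes.subset_samples(samples))
        cov_design = qtl._design(disease.covariates, samples)[:, 1:]
        vex = gwas_sets.variance_explained_test(
            geno,
            prepared["disease"].values.loc[samples, trait].to_numpy(),
            cov_design,
            gwas_set["snp"],
            pool,
            B=config.n_permutations,
            seed=config.seed,
            label=trait,
        )
        summary["variance_explained_observed"] = vex.observed
        summary["variance_explained_p"] = vex.p
        pd.DataFrame({"null_r2": vex.null}).to_csv(
            out / "variance_explained_null.tsv", sep="\t", index=False
        )
        _manifest_row(out, "gwas_tests", config.seed,
                      {"B": config.n_permutations, "alpha": config.suggestive_alpha},
                      {"enrichment_p": enr.p, "variance_explained_p": vex.p})

    # ---------------- coloc ----------------
    if "coloc" in enabled and len(sumstats) >= 2:
        from .coloc import coloc_abf

        # colocalize the two cohorts' tracks at the strongest shared locus
        d = sumstats["disease"].dropna(subset=["p"])
        top = d.loc[d["p"].idxmin()]
        block = study["disease"].genotypes.variants
        near = block.loc[
            (block["chrom"] == top["chrom"]) & (abs(block["pos"] - top["pos"]) < 250_000),
            "snp",
        ]
        t1 = d.loc[(d["trait"] == top["trait"]) & d["snp"].isin(near), ["snp", "beta", "se"]]
        h = sumstats["healthy"]
        t2 = h.loc[(h["trait"] == top["trait"]) & h["snp"].isin(near), ["snp", "beta", "se"]]
        t1 = t1.dropna()
        t2 = t2.dropna()
        if len(t1.merge(t2, on="snp")) >= 2:
            res = coloc_abf(t1, t2)
            summary["coloc_lead_trait"] = str(top["trait"])
            summary.update({f"coloc_{k}": v for k, v in res.pp.items()})
            res.snp_abf.to_csv(out / "coloc_snp_abf.tsv", sep="\t", index=False)
            _manifest_row(out, "coloc", config.seed, res.priors, res.pp)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
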