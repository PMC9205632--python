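"""Reading and writing the pipeline's on-disk formats.

Genotypes travel as plain VCF with a GT field (``./.`` for missing);
phenotypes, covariates, hierarchies and summary statistics as TSV with a
header row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = ["write_vcf", "read_vcf", "write_tsv", "read_tsv"]

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with unphased GT calls."""
    var = genotypes.variants
    D = genotypes.dosages
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for j in range(genotypes.n_snps):
            calls = "\t".join(
                "./." if np.isnan(d) else _GT[d] for d in D[:, j]
            )
            fh.write(
                f"{var['chrom'].iloc[j]}\t{var['pos'].iloc[j]}\t{var['snp'].iloc[j]}\t"
                f"{var['ref'].iloc[j]}\t{var['alt'].iloc[j]}\t.\t.\t.\tGT\t{calls}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (alt-allele count per genotype)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    meta = []
    for rec in vcf:
        gts = rec.genotype.array()
        dose = gts[:, 0].astype(float) + gts[:, 1].astype(float)
        dose[(gts[:, 0] < 0) | (gts[:, 1] < 0)] = np.nan
        rows.append(dose)
        alt = rec.ALT[0] if rec.ALT else "."
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}", str(rec.CHROM), rec.POS, rec.REF, alt))
    vcf.close()
    variants = pd.DataFrame(meta, columns=["snp", "chrom", "pos", "ref", "alt"])
    dosages = np.array(rows).T if rows else np.zeros((len(samples), 0))
    return GenotypeMatrix(dosages, samples, variants)


def write_tsv(frame: pd.DataFrame, path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, index_label="sample" if index else None)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
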