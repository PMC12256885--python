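"""Genotype and embedding IO.

Genotypes travel either as a dosage matrix + sidecar variant TSV (primary,
round-trips exactly) or as an uncompressed VCF carrying dosages in a DS
FORMAT field (written here, read back through cyvcf2).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .synthgen import GenotypeMatrix

__all__ = [
    "write_genotype_matrix",
    "read_genotype_matrix",
    "write_vcf",
    "read_vcf",
    "write_embeddings",
    "read_embeddings",
]

_VARIANT_COLS = ["id", "chrom", "pos", "ref", "alt", "maf", "info", "missing_frac", "hwe_p"]


def write_genotype_matrix(gm: GenotypeMatrix, prefix: str) -> None:
    """Write ``<prefix>.dosages.tsv`` (sample x variant) and ``<prefix>.variants.tsv``."""
    pd.DataFrame(gm.dosages, index=pd.Index(gm.sample_ids, name="sample_id"),
                 columns=gm.variants["id"]).to_csv(f"{prefix}.dosages.tsv", sep="\t")
    cols = [c for c in gm.variants.columns if c in _VARIANT_COLS or c == "monomorphic"]
    gm.variants[cols].to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)


def read_genotype_matrix(prefix: str) -> GenotypeMatrix:
    dos = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t", index_col="sample_id")
    var = pd.read_csv(f"{prefix}.variants.tsv", sep="\t", dtype={"chrom": str})
    return GenotypeMatrix(list(dos.index.astype(str)), dos.to_numpy(dtype=float), var)


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Uncompressed VCF with per-sample DS (dosage) FORMAT values."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=MISS,Number=1,Type=Float,Description="Missing call fraction">\n')
        fh.write('##INFO=<ID=HWE,Number=1,Type=Float,Description="Hardy-Weinberg exact test p">\n')
        for chrom in gm.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j, row in gm.variants.iterrows():
            info = (f"INFO={row['info']:.6g};MAF={row['maf']:.6g};"
                    f"MISS={row['missing_frac']:.6g};HWE={row['hwe_p']:.6g}")
            ds = "\t".join(f"{d:.6g}" for d in gm.dosages[:, j])
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t{info}\tDS\t{ds}\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF with DS dosage fields via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    sample_ids = list(vcf.samples)
    rows, cols = [], []
    for v in vcf:
        ds = np.asarray(v.format("DS"), dtype=float).ravel()
        cols.append(ds)
        rows.append({
            "id": v.ID, "chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0],
            "maf": float(v.INFO.get("MAF", np.nan)),
            "info": float(v.INFO.get("INFO", np.nan)),
            "missing_frac": float(v.INFO.get("MISS", np.nan)),
            "hwe_p": float(v.INFO.get("HWE", np.nan)),
        })
    vcf.close()
    variants = pd.DataFrame(rows)
    return GenotypeMatrix(sample_ids, np.stack(cols, axis=1), variants)


def write_embeddings(sample_ids, values: np.ndarray, path: str) -> None:
    d = values.shape[1]
    pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                 columns=[f"e{i + 1}" for i in range(d)]).to_csv(path, sep="\t")


def read_embeddings(path: str) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return list(df.index.astype(str)), df.to_numpy(dtype=float)
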