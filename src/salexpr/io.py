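"""Readers and writers for the study's on-disk formats.

Genotypes travel as minimal VCFv4.2 (GT only; inbred calls, phase ignored),
expression/fitness/traits as tab-separated tables with a header row, the
simulation ground truth as a JSON sidecar. Coordinates are 1-based inclusive
everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    MISSING,
    ExpressionMatrix,
    FitnessTable,
    GenotypeMatrix,
    SimulationTruth,
)

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> Path:
    """Write dosages as a minimal VCFv4.2 with REF=A, ALT=C placeholder alleles.

    The ALT allele carries the dosage count, so a round-trip through
    ``read_vcf`` recovers the dosage matrix exactly.
    """
    path = Path(path)
    chroms = pd.unique(geno.chrom.astype(str))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=salexpr\n")
        for c in chroms:
            length = int(geno.pos[geno.chrom == c].max()) + 1 if geno.n_snps else 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.accession_ids))
            + "\n"
        )
        for j in range(geno.n_snps):
            calls = "\t".join(_GT_CODE[int(d)] for d in geno.dosage[:, j])
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.snp_ids[j]}\t"
                f"A\tC\t.\tPASS\t.\tGT\t{calls}\n"
            )
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic SNP dosages (ALT-allele count) from a VCF via cyvcf2."""
    vcf = VCF(str(path), gts012=True)
    accessions = np.asarray(vcf.samples, dtype=object)
    snp_ids, chrom, pos, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic SNPs only
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append(g)
    vcf.close()
    dosage = (
        np.asarray(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(accessions), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        accession_ids=accessions,
        snp_ids=np.asarray(snp_ids, dtype=object),
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        dosage=dosage,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(expr.values, columns=expr.transcript_ids)
    meta = pd.DataFrame(
        {
            "plant_id": expr.plant_ids,
            "accession": expr.accession,
            "environment": expr.environment,
            "block": expr.block,
        }
    )
    pd.concat([meta, df.set_index(meta.index)], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
    return path


def read_expression(
    path: str | Path, gene_positions: pd.DataFrame | None = None
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["plant_id", "accession", "environment", "block"]
    transcripts = [c for c in df.columns if c not in meta_cols]
    kwargs = {}
    if gene_positions is not None:
        gp = gene_positions.loc[transcripts]
        kwargs = dict(
            gene_chrom=gp["chrom"].to_numpy(object),
            gene_start=gp["start"].to_numpy(np.int64),
            gene_end=gp["end"].to_numpy(np.int64),
        )
    return ExpressionMatrix(
        plant_ids=df["plant_id"].to_numpy(object),
        accession=df["accession"].to_numpy(object),
        environment=df["environment"].to_numpy(object),
        block=df["block"].to_numpy(np.int64),
        transcript_ids=np.asarray(transcripts, dtype=object),
        values=df[transcripts].to_numpy(float),
        **kwargs,
    )


def write_fitness(fit: FitnessTable, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "plant_id": fit.plant_ids,
            "fecundity": fit.fecundity,
            "environment": fit.environment,
            "block": fit.block,
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def read_fitness(path: str | Path) -> FitnessTable:
    df = pd.read_csv(path, sep="\t")
    return FitnessTable(
        plant_ids=df["plant_id"].to_numpy(object),
        fecundity=df["fecundity"].to_numpy(np.int64),
        environment=df["environment"].to_numpy(object),
        block=df["block"].to_numpy(np.int64),
    )


def write_gene_positions(positions: pd.DataFrame, path: str | Path) -> Path:
    """4-column TSV: gene, chrom, start, end (1-based inclusive)."""
    path = Path(path)
    positions.reset_index().rename(columns={"index": "gene"}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_gene_positions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    return df.set_index("gene")[["chrom", "start", "end"]]


def write_term_map(terms: dict, path: str | Path) -> Path:
    """Two-column TSV term<TAB>transcript, one membership per line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("term\ttranscript\n")
        for term in sorted(terms):
            for t in terms[term]:
                fh.write(f"{term}\t{t}\n")
    return path


def read_term_map(path: str | Path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {term: list(g["transcript"]) for term, g in df.groupby("term", sort=True)}


def write_truth(truth: SimulationTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    return path


def read_truth(path: str | Path) -> SimulationTruth:
    with open(path) as fh:
        return SimulationTruth.from_dict(json.load(fh))


def write_matrix(mat: np.ndarray, ids: np.ndarray, path: str | Path) -> Path:
    """Square matrix with a shared id header row/column (GRM, G)."""
    path = Path(path)
    pd.DataFrame(mat, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format="%.8g"
    )
    return path
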