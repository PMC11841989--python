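"""Small synthetic constructions shared by the acceptance script."""

from __future__ import annotations

import numpy as np
import pandas as pd

from salexpr.datatypes import ExpressionMatrix, GenotypeMatrix


def geno_from_dosage(dosage: np.ndarray) -> GenotypeMatrix:
    dosage = np.asarray(dosage, np.int8)
    n_acc, n_snps = dosage.shape
    return GenotypeMatrix(
        accession_ids=np.asarray([f"a{i}" for i in range(n_acc)], object),
        snp_ids=np.asarray([f"s{j}" for j in range(n_snps)], object),
        chrom=np.asarray(["chr1"] * n_snps, object),
        pos=np.arange(1, n_snps + 1) * 1000,
        dosage=dosage,
    )


def linked_pair_genotypes(n_acc: int, flip_prob: float, seed: int = 0,
                          n_extra: int = 0) -> GenotypeMatrix:
    """Two inbred {0,2} SNPs in LD (dosage r ~ 1 - 2*flip_prob)."""
    rng = np.random.default_rng(seed)
    xc = rng.choice([0, 2], n_acc)
    flip = rng.uniform(size=n_acc) < flip_prob
    xt = np.where(flip, 2 - xc, xc)
    cols = [xc, xt] + [rng.choice([0, 2], n_acc) for _ in range(n_extra)]
    return geno_from_dosage(np.column_stack(cols))


def single_record(snp: str, beta: float, p: float = 1e-6, pos: int = 1000,
                  chrom: str = "chr1", gene: str = "g",
                  cls: str = "cis") -> pd.DataFrame:
    return pd.DataFrame({
        "snp": [snp], "chrom": [chrom], "pos": [pos], "gene": [gene],
        "beta": [beta], "t": [5.0], "p": [p], "q": [p], "class": [cls],
        "lead": [True],
    })


def correlated_block(n: int, k: int, r: float,
                     rng: np.random.Generator) -> np.ndarray:
    shared = rng.normal(size=(n, 1))
    return np.sqrt(r) * shared + np.sqrt(1 - r) * rng.normal(size=(n, k))


def two_env_expression(vals_normal: np.ndarray,
                       vals_saline: np.ndarray) -> ExpressionMatrix:
    vals = np.vstack([vals_normal, vals_saline])
    vals = vals - vals.min() + 0.01
    n = len(vals)
    env = ["normal"] * len(vals_normal) + ["saline"] * len(vals_saline)
    return ExpressionMatrix(
        plant_ids=np.asarray([f"p{i}" for i in range(n)], object),
        accession=np.asarray([f"a{i}" for i in range(n)], object),
        environment=np.asarray(env, object),
        block=np.ones(n, np.int64),
        transcript_ids=np.asarray([f"t{j}" for j in range(vals.shape[1])],
                                  object),
        values=vals,
    )
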