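"""eQTL mapping on accession-mean expression.

Genotype hard filters (MAF, call rate, heterozygosity, 1-kb thinning),
kinship principal components as population-structure covariates, and
per-environment association scans: for every SNP-gene pair, the slope of an
OLS regression of replicate-mean expression on dosage plus covariates, with
Benjamini-Hochberg control across all tested pairs in the environment. The
full scan is computed by residualizing both sides on the covariates
(Frisch-Waugh-Lovell), which reproduces per-pair OLS t statistics exactly.
GxE loci are mapped by the same machinery on the normal-minus-saline
difference of accession means. cis = same chromosome and < 100 kb from the
gene body; trans = different chromosome or >= 1 Mb away; the 100 kb - 1 Mb
gap is left unclassified and excluded from cis/trans contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix
from .respond import grm

CIS_MAX = 100_000
TRANS_MIN = 1_000_000


def filter_genotypes(
    geno: GenotypeMatrix,
    maf: float = 0.05,
    max_missing: float = 0.2,
    max_het: float = 0.05,
    thin_bp: int = 1000,
    seed: int = 0,
) -> GenotypeMatrix:
    """Hard filters + seeded random thinning to one SNP per ``thin_bp`` bin."""
    keep = (
        (geno.maf() >= maf)
        & (geno.missing_fraction() <= max_missing)
        & (geno.het_fraction() <= max_het)
    )
    idx = np.flatnonzero(keep)
    if thin_bp and len(idx):
        rng = np.random.default_rng(seed)
        bins = pd.DataFrame(
            {
                "chrom": geno.chrom[idx].astype(str),
                "bin": geno.pos[idx] // thin_bp,
                "idx": idx,
            }
        )
        idx = np.sort(
            bins.groupby(["chrom", "bin"], sort=True)["idx"]
            .apply(lambda s: s.iloc[rng.integers(0, len(s))])
            .to_numpy()
        )
    if len(idx) == 0:
        raise ValueError("all SNPs removed by the genotype filters")
    return geno.take_snps(idx)


def kinship_pcs(geno: GenotypeMatrix, k: int = 5) -> np.ndarray:
    """Top-k eigenvectors of the GRM (orthonormal), sign-stabilized."""
    if k == 0:
        return np.empty((geno.n_accessions, 0))
    if geno.n_accessions < k + 1:
        raise ValueError("need at least k+1 accessions")
    vals, vecs = np.linalg.eigh(grm(geno))
    top = vecs[:, np.argsort(vals)[::-1][:k]]
    for j in range(top.shape[1]):  # deterministic sign convention
        i = np.argmax(np.abs(top[:, j]))
        if top[i, j] < 0:
            top[:, j] = -top[:, j]
    return top


def map_eqtl(
    mean_expr: pd.DataFrame,
    geno: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    fdr: float = 0.001,
    environment: str = "normal",
    keep_all: bool = False,
) -> pd.DataFrame:
    """All SNP x gene associations; records kept at BH q < ``fdr``.

    ``mean_expr`` is accessions x genes (replicate means, one environment),
    indexed and ordered like ``geno.accession_ids``.
    """
    if list(mean_expr.index) != list(geno.accession_ids):
        mean_expr = mean_expr.reindex(geno.accession_ids)
        if mean_expr.isna().any().any():
            raise ValueError("expression accessions do not match genotypes")
    y = mean_expr.to_numpy(float)
    x = geno.dosage_imputed()
    n = len(y)
    n_cov = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    df = n - n_cov - 2  # intercept + SNP
    if df < 1:
        raise ValueError("not enough accessions for the covariate count")

    c = np.column_stack([np.ones(n)] + ([covariates] if n_cov else []))
    q_c, _ = np.linalg.qr(c)
    y = y - q_c @ (q_c.T @ y)
    x = x - q_c @ (q_c.T @ x)

    sx2 = (x**2).sum(axis=0)
    sy2 = (y**2).sum(axis=0)
    ok_snp = sx2 > 1e-12
    ok_gene = sy2 > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (x.T @ y) / sx2[:, None]
        rss = sy2[None, :] - beta**2 * sx2[:, None]
        sigma2 = np.clip(rss, 0.0, None) / df
        t = beta * np.sqrt(sx2)[:, None] / np.sqrt(np.where(sigma2 > 0, sigma2, np.inf))
    tested = ok_snp[:, None] & ok_gene[None, :]
    p = np.where(tested, 2 * stats.t.sf(np.abs(t), df), np.nan)

    flat_p = p[tested]
    m = flat_p.size
    order = np.argsort(flat_p)
    ranked = flat_p[order] * m / (np.arange(m) + 1)
    qmin = np.minimum.accumulate(ranked[::-1])[::-1]
    q_flat = np.empty(m)
    q_flat[order] = np.minimum(qmin, 1.0)
    q = np.full(p.shape, np.nan)
    q[tested] = q_flat

    sel = tested & ((q < fdr) if not keep_all else True)
    si, gi = np.nonzero(sel)
    out = pd.DataFrame(
        {
            "snp": geno.snp_ids[si],
            "chrom": geno.chrom[si],
            "pos": geno.pos[si],
            "gene": mean_expr.columns.to_numpy(object)[gi],
            "beta": beta[sel],
            "t": t[sel],
            "p": p[sel],
            "q": q[sel],
        }
    )
    out["environment"] = environment
    return out.reset_index(drop=True)


def map_gxe_eqtl(
    diff_expr: pd.DataFrame,
    geno: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """eQTL scan on the normal-minus-saline difference of accession means."""
    return map_eqtl(diff_expr, geno, covariates, fdr=fdr, environment="GxE")


def gene_snp_distance(
    records: pd.DataFrame, gene_positions: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """(same-chromosome flag, bp gap to the nearest gene-body edge; 0 inside)."""
    unknown = set(records["gene"]) - set(gene_positions.index)
    if unknown:
        raise KeyError(f"unknown gene ids: {sorted(unknown)[:10]}")
    gp = gene_positions.loc[records["gene"]]
    same = records["chrom"].to_numpy(str) == gp["chrom"].to_numpy(str)
    pos = records["pos"].to_numpy(np.int64)
    start = gp["start"].to_numpy(np.int64)
    end = gp["end"].to_numpy(np.int64)
    inside = (pos >= start) & (pos <= end)
    dist = np.where(inside, 0, np.minimum(np.abs(pos - start), np.abs(pos - end)))
    return same, dist


def annotate_cis_trans(
    records: pd.DataFrame, gene_positions: pd.DataFrame
) -> pd.DataFrame:
    """Add a ``class`` column in {cis, trans, unclassified}."""
    out = records.copy()
    if out.empty:
        out["class"] = pd.Series(dtype=object)
        return out
    same, dist = gene_snp_distance(out, gene_positions)
    cls = np.full(len(out), "unclassified", dtype=object)
    cls[same & (dist < CIS_MAX)] = "cis"
    cls[~same | (dist >= TRANS_MIN)] = "trans"
    out["class"] = cls
    return out


def lead_snps(records: pd.DataFrame, window: int = 100_000) -> pd.DataFrame:
    """Flag, per gene and per 100-kb genomic bin, the most significant SNP.

    Bins are anchored at position 1 of each chromosome; exact p ties break
    toward the smaller coordinate.
    """
    out = records.copy()
    if out.empty:
        out["lead"] = pd.Series(dtype=bool)
        return out
    out["_bin"] = (out["pos"].to_numpy(np.int64) - 1) // window
    out = out.sort_values(
        ["gene", "chrom", "_bin", "p", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    first = ~out.duplicated(subset=["gene", "chrom", "_bin"], keep="first")
    out["lead"] = first
    return out.drop(columns="_bin")
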