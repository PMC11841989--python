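"""Regulatory architecture and population-genetic selection inference.

Trans-eQTL hotspot detection (unique genes regulated by lead SNPs per 100-kb
bin), per-gene cis-trans mode classification (reinforcing vs compensating
from the per-individual sign of the product of cis and trans dosage-effect
pushes), a distance-matched LD permutation test, and folded-SFS / MAF /
nucleotide-diversity contrasts between eQTL classes and the genomic
background. Inbred accessions are treated as single haploid-equivalents for
MAF and pi (heterozygous calls, rare after filtering, count half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix


@dataclass
class ArchitectureCall:
    gene: str
    cis_beta: float
    mean_trans_beta: float
    frac_same: float
    frac_opposite: float
    n_informative: int
    mode: str  # reinforcing | compensating | unclassified


def detect_hotspots(
    lead_trans: pd.DataFrame, window: int = 100_000, min_genes: int = 30
) -> pd.DataFrame:
    """100-kb bins whose lead trans-eQTLs regulate > ``min_genes`` unique genes."""
    if lead_trans.empty:
        return pd.DataFrame(
            columns=["chrom", "bin_start", "bin_end", "n_genes", "snps"]
        )
    rec = lead_trans.copy()
    rec["_bin"] = (rec["pos"].to_numpy(np.int64) - 1) // window
    rows = []
    for (chrom, b), grp in rec.groupby(["chrom", "_bin"], sort=True):
        n_genes = grp["gene"].nunique()
        rows.append(
            {
                "chrom": chrom,
                "bin_start": int(b * window + 1),
                "bin_end": int((b + 1) * window),
                "n_genes": int(n_genes),
                "snps": ",".join(sorted(set(grp["snp"].astype(str)))),
            }
        )
    out = pd.DataFrame(rows)
    out = out[out["n_genes"] > min_genes].reset_index(drop=True)
    return out.sort_values("n_genes", ascending=False).reset_index(drop=True)


def classify_mode(
    gene: str,
    cis_records: pd.DataFrame,
    trans_records: pd.DataFrame,
    geno: GenotypeMatrix,
    threshold: float = 0.6,
) -> ArchitectureCall:
    """Reinforcing/compensating call for one gene with lead cis+trans eQTLs.

    Per individual, the cis push is beta_cis * (dosage - mean dosage) for the
    lead cis-eQTL; the trans push averages beta_t * (dosage - mean dosage)
    over all lead trans-eQTLs. Configurations are 'same' when the product of
    pushes is positive, 'opposite' when negative; the gene is reinforcing
    (compensating) when the same (opposite) fraction reaches ``threshold``.
    """
    if cis_records.empty or trans_records.empty:
        raise ValueError(f"gene {gene}: need at least one lead cis and trans record")
    cis = cis_records.sort_values(["p", "pos"]).iloc[0]
    dose = geno.dosage_imputed()
    xc = dose[:, geno.snp_index(cis["snp"])]
    cis_push = cis["beta"] * (xc - xc.mean())
    trans_push = np.zeros_like(cis_push)
    for _, tr in trans_records.iterrows():
        xt = dose[:, geno.snp_index(tr["snp"])]
        trans_push += tr["beta"] * (xt - xt.mean())
    trans_push /= len(trans_records)

    prod = cis_push * trans_push
    informative = prod != 0
    n_inf = int(informative.sum())
    if n_inf == 0:
        return ArchitectureCall(gene, float(cis["beta"]),
                                float(trans_records["beta"].mean()),
                                0.0, 0.0, 0, "unclassified")
    frac_same = float((prod > 0).sum() / n_inf)
    frac_opp = float((prod < 0).sum() / n_inf)
    if frac_same >= threshold:
        mode = "reinforcing"
    elif frac_opp >= threshold:
        mode = "compensating"
    else:
        mode = "unclassified"
    return ArchitectureCall(
        gene,
        float(cis["beta"]),
        float(trans_records["beta"].mean()),
        frac_same,
        frac_opp,
        n_inf,
        mode,
    )


def classify_modes(
    records: pd.DataFrame, geno: GenotypeMatrix, threshold: float = 0.6
) -> pd.DataFrame:
    """Mode calls for every gene carrying lead cis and lead trans records."""
    leads = records[records.get("lead", True) == True]  # noqa: E712
    calls = []
    for gene, grp in leads.groupby("gene", sort=True):
        cis = grp[grp["class"] == "cis"]
        trans = grp[grp["class"] == "trans"]
        if cis.empty or trans.empty:
            continue
        c = classify_mode(gene, cis, trans, geno, threshold)
        calls.append(vars(c))
    cols = ["gene", "cis_beta", "mean_trans_beta", "frac_same",
            "frac_opposite", "n_informative", "mode"]
    return pd.DataFrame(calls, columns=cols)


def prop_test_two_sample(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = True
) -> dict:
    """Two-sided two-sample proportion z-test with pooled variance and
    (optionally) Yates continuity correction; the corrected statistic is
    clamped at 0."""
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    diff = abs(p1 - p2)
    if continuity:
        diff = max(diff - 0.5 * (1 / n1 + 1 / n2), 0.0)
    z = diff / se if se > 0 else 0.0
    return {"z": float(z), "p": float(2 * stats.norm.sf(z))}


def summarize_modes(calls: pd.DataFrame) -> dict:
    """Counts of reinforcing vs compensating genes and the two-sided
    continuity-corrected proportion test of their fractions."""
    classified = calls[calls["mode"].isin(["reinforcing", "compensating"])]
    n = len(classified)
    if n == 0:
        raise ValueError("no classified genes")
    n_re = int((classified["mode"] == "reinforcing").sum())
    n_co = n - n_re
    test = prop_test_two_sample(n_re, n, n_co, n, continuity=True)
    return {
        "n_classified": n,
        "n_reinforcing": n_re,
        "n_compensating": n_co,
        "z": test["z"],
        "p": test["p"],
    }


def mode_expression_contrast(
    calls: pd.DataFrame, intervar: pd.Series
) -> dict:
    """One-sided Mann-Whitney test that inter-varietal expression variance is
    larger for reinforcing than for compensating genes."""
    re_genes = calls.loc[calls["mode"] == "reinforcing", "gene"]
    co_genes = calls.loc[calls["mode"] == "compensating", "gene"]
    x = intervar.reindex(re_genes).dropna()
    y = intervar.reindex(co_genes).dropna()
    if x.empty or y.empty:
        raise ValueError("both mode groups must be nonempty")
    u, p = stats.mannwhitneyu(x, y, alternative="greater")
    return {
        "U": float(u),
        "p": float(p),
        "mean_reinforcing": float(x.mean()),
        "mean_compensating": float(y.mean()),
    }


def _r2_matrix_cols(z: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    r = (z[:, i] * z[:, j]).mean(axis=0)
    return r**2


def ld_permutation_test(
    pairs: list,
    geno: GenotypeMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    distance_tol: float = 0.1,
) -> dict:
    """Distance-matched permutation test of mean r2 for observed SNP pairs.

    Null datasets keep the observed pair count: a cross-chromosome observed
    pair draws a random cross-chromosome pair; a same-chromosome pair draws a
    random pair whose separation lies within +-``distance_tol`` of the
    observed distance (the tolerance widens automatically, with a warning,
    when a stratum cannot be matched). The two-tailed p uses the +1
    permutation correction on each tail, capped at 1.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one observed pair")
    rng = np.random.default_rng(seed)
    dose = geno.dosage_imputed()
    sd = dose.std(axis=0)
    z = (dose - dose.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    n_snps = geno.n_snps
    snp_idx = {s: i for i, s in enumerate(geno.snp_ids)}
    chrom_of = geno.chrom
    chroms, chrom_codes = np.unique(chrom_of.astype(str), return_inverse=True)
    by_chrom = {c: np.flatnonzero(chrom_codes == ci) for ci, c in enumerate(chroms)}
    pos_by_chrom = {c: geno.pos[ix] for c, ix in by_chrom.items()}

    oi = np.asarray([snp_idx[a] for a, _ in pairs])
    oj = np.asarray([snp_idx[b] for _, b in pairs])
    obs_mean = float(_r2_matrix_cols(z, oi, oj).mean())

    cross = chrom_of[oi] != chrom_of[oj]
    dists = np.abs(geno.pos[oi] - geno.pos[oj])

    def draw_cross() -> tuple[int, int]:
        while True:
            a, b = rng.integers(0, n_snps, size=2)
            if chrom_of[a] != chrom_of[b]:
                return a, b

    def draw_same(d: int) -> tuple[int, int]:
        tol = distance_tol
        while True:
            for _ in range(200):
                c = chroms[rng.integers(0, len(chroms))]
                ix, ps = by_chrom[c], pos_by_chrom[c]
                a = rng.integers(0, len(ix))
                lo = np.searchsorted(ps, ps[a] + d * (1 - tol), side="left")
                hi = np.searchsorted(ps, ps[a] + d * (1 + tol), side="right")
                if hi > lo:
                    return ix[a], ix[lo + rng.integers(0, hi - lo)]
            tol *= 2.0
            warnings.warn(
                f"distance stratum {d} bp unmatched; widened tolerance to {tol:.2f}"
            )

    null = np.empty(n_perm)
    for it in range(n_perm):
        ai = np.empty(len(pairs), dtype=int)
        bi = np.empty(len(pairs), dtype=int)
        for k in range(len(pairs)):
            if cross[k]:
                ai[k], bi[k] = draw_cross()
            else:
                ai[k], bi[k] = draw_same(int(dists[k]))
        null[it] = _r2_matrix_cols(z, ai, bi).mean()

    ge = int((null >= obs_mean).sum())
    le = int((null <= obs_mean).sum())
    p = min(2.0 * (min(ge, le) + 1) / (n_perm + 1), 1.0)
    return {"observed_mean_r2": obs_mean, "null_mean_r2": float(null.mean()),
            "null": null, "p": float(p)}


def folded_sfs(maf: np.ndarray, n_bins: int = 25) -> pd.DataFrame:
    """Binned folded site-frequency spectrum on (0, 0.5]."""
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    counts, _ = np.histogram(maf, bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )


def maf_contrast(snp_sets: dict, geno: GenotypeMatrix, n_bins: int = 25) -> dict:
    """Per-set mean MAF, folded SFS, and pairwise Welch t-test p-values."""
    maf_all = geno.maf()
    snp_idx = {s: i for i, s in enumerate(geno.snp_ids)}
    values, sfs, means = {}, {}, {}
    for name, snps in snp_sets.items():
        ids = sorted(set(snps))
        vals = np.asarray([maf_all[snp_idx[s]] for s in ids if s in snp_idx])
        if len(vals) < 2:
            continue  # set too small to contrast
        values[name] = vals
        means[name] = float(vals.mean())
        sfs[name] = folded_sfs(vals, n_bins)
    names = sorted(values)
    tests = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            t, p = stats.ttest_ind(values[a], values[b], equal_var=False)
            tests[(a, b)] = {"t": float(t), "p": float(p)}
    return {"mean_maf": means, "sfs": sfs, "tests": tests, "values": values}


def site_pi(geno: GenotypeMatrix) -> np.ndarray:
    """Per-site nucleotide diversity 2p(1-p) n/(n-1) with n the number of
    non-missing haploid-equivalents (inbred accessions counted once)."""
    p = geno.allele_frequency()
    n = (geno.dosage != -1).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * p * (1.0 - p) * np.where(n > 1, n / (n - 1), np.nan)
    return pi


def pi_contrast(
    geno: GenotypeMatrix,
    cis_snps,
    flank: int = 50_000,
    block: int = 100_000,
) -> dict:
    """Mean pi in cis-eQTL flanking windows vs genome-wide background blocks.

    Each cis SNP gets a window of ``flank`` bp on both sides; the background
    is pi averaged over ``block``-bp tiles excluding every cis window.
    Windows or blocks without variant sites are excluded (count reported).
    """
    pi = site_pi(geno)
    snp_idx = {s: i for i, s in enumerate(geno.snp_ids)}
    cis_ids = sorted(set(cis_snps))
    window_means, empty_windows = [], 0
    cis_ranges: dict[str, list] = {}
    for s in cis_ids:
        i = snp_idx[s]
        c, p0 = str(geno.chrom[i]), int(geno.pos[i])
        lo, hi = p0 - flank, p0 + flank
        cis_ranges.setdefault(c, []).append((lo, hi))
        in_win = (geno.chrom == c) & (geno.pos >= lo) & (geno.pos <= hi)
        vals = pi[in_win]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            empty_windows += 1
        else:
            window_means.append(vals.mean())

    block_means, empty_blocks = [], 0
    for c in pd.unique(geno.chrom.astype(str)):
        on_c = geno.chrom == c
        pmax = int(geno.pos[on_c].max())
        ranges = cis_ranges.get(c, [])
        for b0 in range(1, pmax + 1, block):
            b1 = b0 + block - 1
            if any(lo <= b1 and hi >= b0 for lo, hi in ranges):
                continue
            in_b = on_c & (geno.pos >= b0) & (geno.pos <= b1)
            vals = pi[in_b]
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                empty_blocks += 1
            else:
                block_means.append(vals.mean())

    window_means = np.asarray(window_means)
    block_means = np.asarray(block_means)
    if len(window_means) >= 2 and len(block_means) >= 2:
        t, p = stats.ttest_ind(window_means, block_means, equal_var=False)
    else:
        t, p = float("nan"), float("nan")
    return {
        "window_pi_mean": float(window_means.mean()) if len(window_means) else float("nan"),
        "background_pi_mean": float(block_means.mean()) if len(block_means) else float("nan"),
        "t": float(t),
        "p": float(p),
        "n_windows": int(len(window_means)),
        "n_background_blocks": int(len(block_means)),
        "empty_windows": empty_windows,
        "empty_blocks": empty_blocks,
    }
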