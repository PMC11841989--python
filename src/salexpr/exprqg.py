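"""Quantitative genetics of expression and fecundity.

Two-way mixed ANOVA (environment fixed; genotype and genotype-x-environment
random) on a near-balanced accession x environment x replicate design, with
method-of-moments variance components from the expected mean squares and
broad-sense heritability

    H^2 = sigma2_G / (sigma2_G + sigma2_GE / e + sigma2_err / (r * e)),

where e and r are the number of environments and replicates per environment.
F-tests follow the classical mixed-model expectations: both main effects over
the interaction mean square, the interaction over the error mean square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

TERMS = ("G", "E", "GxE", "error")


@dataclass
class VarianceComponents:
    """One trait's ANOVA table plus derived genetic components."""

    table: pd.DataFrame  # index TERMS, columns SS/df/MS/F/p
    sigma2_g: float
    sigma2_ge: float
    sigma2_err: float
    e: int
    r: float

    @property
    def h2(self) -> float:
        return heritability(self)


def _design_indices(accession, environment):
    acc = np.asarray(accession, dtype=object)
    env = np.asarray(environment, dtype=object)
    acc_levels, ai = np.unique(acc.astype(str), return_inverse=True)
    env_levels, ei = np.unique(env.astype(str), return_inverse=True)
    g, e = len(acc_levels), len(env_levels)
    if g < 2:
        raise ValueError("need at least 2 accessions")
    if e < 2:
        raise ValueError("single environment: E and GxE terms are undefined")
    counts = np.zeros((g, e), dtype=np.int64)
    np.add.at(counts, (ai, ei), 1)
    if (counts == 0).any():
        i, j = np.argwhere(counts == 0)[0]
        raise ValueError(f"empty design cell: accession {acc_levels[i]}, "
                         f"environment {env_levels[j]}")
    if counts.min() < 2:
        raise ValueError("need at least 2 replicates in every cell")
    return ai, ei, g, e, counts


def partition_variance_matrix(
    values: np.ndarray, accession, environment
) -> pd.DataFrame:
    """Vectorized two-way ANOVA across the columns of ``values``.

    Sums of squares are computed from unweighted cell means (Type I on
    balanced data; mild imbalance handled by the harmonic-mean cell count).
    Returns one row per column with SS/MS/F/p per term, the method-of-moments
    components, and H^2.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and values.shape[1] > 1 and len(accession) != 1:
        values = values.T
    ai, ei, g, e, counts = _design_indices(accession, environment)
    n, n_traits = values.shape
    r_h = stats.hmean(counts.ravel())

    cell = ai * e + ei
    cell_sum = np.zeros((g * e, n_traits))
    np.add.at(cell_sum, cell, values)
    cell_mean = cell_sum / counts.reshape(-1, 1)
    cm = cell_mean.reshape(g, e, n_traits)
    acc_mean = cm.mean(axis=1)
    env_mean = cm.mean(axis=0)
    grand = cm.mean(axis=(0, 1))

    ss_g = e * r_h * ((acc_mean - grand) ** 2).sum(axis=0)
    ss_e = g * r_h * ((env_mean - grand) ** 2).sum(axis=0)
    inter = cm - acc_mean[:, None, :] - env_mean[None, :, :] + grand
    ss_gxe = r_h * (inter**2).sum(axis=(0, 1))
    ss_err = ((values - cell_mean[cell]) ** 2).sum(axis=0)

    df_g, df_e = g - 1, e - 1
    df_gxe = (g - 1) * (e - 1)
    df_err = n - g * e
    ms_g, ms_e = ss_g / df_g, ss_e / df_e
    ms_gxe, ms_err = ss_gxe / df_gxe, ss_err / df_err

    with np.errstate(divide="ignore", invalid="ignore"):
        f_g = ms_g / ms_gxe
        f_e = ms_e / ms_gxe
        f_gxe = ms_gxe / ms_err
    p_g = stats.f.sf(f_g, df_g, df_gxe)
    p_e = stats.f.sf(f_e, df_e, df_gxe)
    p_gxe = stats.f.sf(f_gxe, df_gxe, df_err)

    sigma2_err = ms_err
    sigma2_ge = (ms_gxe - ms_err) / r_h
    sigma2_g = (ms_g - ms_gxe) / (e * r_h)

    out = pd.DataFrame(
        {
            "SS_G": ss_g, "SS_E": ss_e, "SS_GxE": ss_gxe, "SS_err": ss_err,
            "df_G": df_g, "df_E": df_e, "df_GxE": df_gxe, "df_err": df_err,
            "F_G": f_g, "F_E": f_e, "F_GxE": f_gxe,
            "p_G": p_g, "p_E": p_e, "p_GxE": p_gxe,
            "sigma2_G": sigma2_g, "sigma2_GE": sigma2_ge, "sigma2_err": sigma2_err,
        }
    )
    out["H2"] = [
        heritability_from_components(a, b, c, e=e, r=r_h)
        for a, b, c in zip(sigma2_g, sigma2_ge, sigma2_err)
    ]
    return out


def partition_variance(values, accession, environment) -> VarianceComponents:
    """Two-way mixed ANOVA of a single trait (see module docstring)."""
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    row = partition_variance_matrix(values, accession, environment).iloc[0]
    _, _, g, e, counts = _design_indices(accession, environment)
    table = pd.DataFrame(
        {
            "SS": [row.SS_G, row.SS_E, row.SS_GxE, row.SS_err],
            "df": [row.df_G, row.df_E, row.df_GxE, row.df_err],
            "F": [row.F_G, row.F_E, row.F_GxE, np.nan],
            "p": [row.p_G, row.p_E, row.p_GxE, np.nan],
        },
        index=list(TERMS),
    )
    table["MS"] = table["SS"] / table["df"]
    return VarianceComponents(
        table=table[["SS", "df", "MS", "F", "p"]],
        sigma2_g=float(row.sigma2_G),
        sigma2_ge=float(row.sigma2_GE),
        sigma2_err=float(row.sigma2_err),
        e=e,
        r=float(stats.hmean(counts.ravel())),
    )


def heritability_from_components(
    sigma2_g: float, sigma2_ge: float, sigma2_err: float, e: int, r: float
) -> float:
    """H^2 with negative component estimates clamped to 0 first; NaN if all 0."""
    if e < 1 or r < 1:
        raise ValueError("e and r must be >= 1")
    sg = max(float(sigma2_g), 0.0)
    sge = max(float(sigma2_ge), 0.0)
    se = max(float(sigma2_err), 0.0)
    denom = sg + sge / e + se / (r * e)
    if denom == 0:
        return float("nan")
    return min(max(sg / denom, 0.0), 1.0)


def heritability(vc: VarianceComponents) -> float:
    return heritability_from_components(
        vc.sigma2_g, vc.sigma2_ge, vc.sigma2_err, e=vc.e, r=vc.r
    )


def transcriptome_anova(expr: ExpressionMatrix, fdr: float = 0.001) -> pd.DataFrame:
    """Per-transcript ANOVA with BH q-values per term at the given FDR."""
    out = partition_variance_matrix(expr.values, expr.accession, expr.environment)
    out.index = expr.transcript_ids
    for term in ("G", "E", "GxE"):
        p = out[f"p_{term}"].to_numpy()
        rej, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
        out[f"q_{term}"] = q
        out[f"sig_{term}"] = rej
    return out


def intervarietal_variance(expr: ExpressionMatrix, environment: str) -> pd.Series:
    """Population-wide variance between accession mean expression levels."""
    means = expr.accession_means(environment)
    if means.shape[0] < 2:
        raise ValueError("need at least 2 accessions in the environment")
    return means.var(axis=0, ddof=1)


def proportion_test_one_sample(k: int, n: int, p0: float = 0.5) -> dict:
    """Two-sided one-sample proportion test, chi-square WITHOUT continuity
    correction (z = (k/n - p0)/sqrt(p0 q0 / n))."""
    if n <= 0:
        raise ValueError("n must be positive")
    z = (k / n - p0) / np.sqrt(p0 * (1 - p0) / n)
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}


def fitness_environment_tests(fecundity, accession, environment) -> dict:
    """Paired accession-mean fecundity comparison between environments.

    Two-tailed paired t-test on accession means (saline - normal), the count
    of accessions with lower mean fecundity under salinity, and a two-sided
    one-sample proportion test of that count against 0.5.
    """
    df = pd.DataFrame(
        {
            "fecundity": np.asarray(fecundity, dtype=float),
            "accession": np.asarray(accession, dtype=object),
            "environment": np.asarray(environment, dtype=object),
        }
    )
    means = df.pivot_table(
        index="accession", columns="environment", values="fecundity"
    ).dropna()
    if not {"normal", "saline"} <= set(means.columns):
        raise ValueError("both environments required")
    if len(means) < 2:
        raise ValueError("need at least 2 paired accessions")
    t, p = stats.ttest_rel(means["saline"], means["normal"])
    n_lower = int((means["saline"] < means["normal"]).sum())
    prop = proportion_test_one_sample(n_lower, len(means))
    return {
        "n_pairs": int(len(means)),
        "paired_t": float(t),
        "paired_t_p": float(p),
        "n_lower": n_lower,
        "prop_test_z": prop["z"],
        "prop_test_p": prop["p"],
    }
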