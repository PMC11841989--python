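"""Regulatory decoherence: correlation change between environments.

Implements the correlation-by-individual-level-product approach: per-plant
products of within-environment z-scored (co-variate-adjusted) expression are
regressed on the environment indicator; because of the z-scoring, the
environment-wise mean of a pair's products equals the within-environment
Pearson correlation, so the test targets a change in correlation rather
than in means or variances. The per-pair environment test reduces to the
pooled-variance two-sample t (identical to the OLS Wald t on the indicator)
and is computed for all pairs via matrix cross-products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix


@dataclass
class CilpResult:
    pairs: pd.DataFrame  # t1, t2, r_normal, r_saline, t, p, q, significant
    counts: pd.Series  # per transcript: number of significant pairs
    transcripts: np.ndarray
    dropped: list  # transcripts dropped (constant within an environment)


def select_cilp_transcripts(
    table_normal: pd.DataFrame,
    table_saline: pd.DataFrame,
    expr: ExpressionMatrix,
    s_threshold: float = 0.1,
    detect_frac: float = 0.5,
) -> np.ndarray:
    """Transcripts with |S| > threshold in at least one environment and
    expression > 0 in at least ``detect_frac`` of individuals."""
    s_n = table_normal["S"].abs()
    s_s = table_saline["S"].abs()
    strong = set(s_n[s_n > s_threshold].index) | set(s_s[s_s > s_threshold].index)
    detected = (expr.values > 0).mean(axis=0) >= detect_frac
    out = np.asarray(
        [t for t, d in zip(expr.transcript_ids, detected) if d and t in strong],
        dtype=object,
    )
    if len(out) == 0:
        import warnings

        warnings.warn("decoherence transcript filter selected nothing")
    return out


def _residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return values - values.mean(axis=0)
    x = np.column_stack([np.ones(len(values)), covariates])
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    return values - x @ beta


def cilp(
    expr: ExpressionMatrix,
    transcripts: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    fdr: float = 0.05,
    min_per_env: int = 20,
    standardize: str = "within",
) -> CilpResult:
    """All-pairs product test of correlation change between environments.

    ``standardize="within"`` (default) z-scores residuals inside each
    environment; ``"global"`` z-scores across all plants (the reference
    method's original variant, which also reacts to mean/variance shifts).
    """
    if transcripts is not None:
        idx = {t: i for i, t in enumerate(expr.transcript_ids)}
        expr = expr.subset_transcripts(
            np.asarray([idx[t] for t in transcripts], dtype=int)
        )
    envs = ("normal", "saline")
    masks = [expr.env_mask(e) for e in envs]
    ns = [int(m.sum()) for m in masks]
    if min(ns) < min_per_env:
        raise ValueError(f"need at least {min_per_env} plants per environment")

    resid = _residualize(expr.values, covariates)
    z = np.empty_like(resid)
    dropped_mask = np.zeros(expr.n_transcripts, dtype=bool)
    if standardize == "global":
        sd = resid.std(axis=0)
        const = sd <= 1e-10
        dropped_mask |= const
        z = (resid - resid.mean(axis=0)) / np.where(const, 1.0, sd)
    else:
        for m in masks:
            mu = resid[m].mean(axis=0)
            sd = resid[m].std(axis=0)  # ddof=0: mean product == Pearson r
            const = sd <= 1e-10
            dropped_mask |= const
            z[m] = (resid[m] - mu) / np.where(const, 1.0, sd)
    dropped = list(expr.transcript_ids[dropped_mask])
    keep = ~dropped_mask
    z = z[:, keep]
    ids = expr.transcript_ids[keep]
    k = len(ids)
    if k < 2:
        raise ValueError("fewer than 2 usable transcripts")

    # per-environment sums of products and squared products via cross-products
    means, sse = [], []
    for m, n in zip(masks, ns):
        zg = z[m]
        s1 = zg.T @ zg
        s2 = (zg**2).T @ (zg**2)
        mu = s1 / n
        means.append(mu)
        sse.append(s2 - n * mu**2)
    n_tot = sum(ns)
    df = n_tot - 2
    pooled = (sse[0] + sse[1]) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mat = (means[1] - means[0]) / np.sqrt(
            pooled * (1.0 / ns[0] + 1.0 / ns[1])
        )
    iu = np.triu_indices(k, 1)
    t_vals = t_mat[iu]
    p_vals = 2 * stats.t.sf(np.abs(t_vals), df)
    rej, q_vals, _, _ = multipletests(p_vals, alpha=fdr, method="fdr_bh")

    pairs = pd.DataFrame(
        {
            "t1": ids[iu[0]],
            "t2": ids[iu[1]],
            "r_normal": means[0][iu],
            "r_saline": means[1][iu],
            "t": t_vals,
            "p": p_vals,
            "q": q_vals,
            "significant": rej,
        }
    )
    counts = pd.Series(0, index=ids, dtype=int)
    sig = pairs[pairs["significant"]]
    for col in ("t1", "t2"):
        vc = sig[col].value_counts()
        counts.loc[vc.index] += vc.to_numpy()
    return CilpResult(pairs=pairs, counts=counts, transcripts=ids, dropped=dropped)


def decoherence_hubs(result: CilpResult) -> tuple[np.ndarray, float]:
    """Transcripts with strictly more significant pairs than the median.

    The median is computed over transcripts with at least one significant
    pair; returns (hub ids, median).
    """
    active = result.counts[result.counts >= 1]
    if active.empty:
        return np.empty(0, dtype=object), float("nan")
    med = float(active.median())
    hubs = active[active > med].index.to_numpy(object)
    return hubs, med
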