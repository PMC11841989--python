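"""Phenotypic selection analysis on transcript abundance and organismal traits.

Linear (S) and quadratic (C) selection differentials come from per-transcript
regressions of relative fitness (fecundity / mean fecundity among plants with
non-zero fecundity) on expression with block as a fixed covariate; C is twice
the quadratic coefficient. Multivariate gradients (beta, gamma) come from a
joint regression on retained expression principal components or on
variance-standardized, correlation-pruned organismal traits. Transcripts are
classified as conditionally neutral (selection in one environment only, at
the stricter p<0.025 / p>0.05 rule) or antagonistically pleiotropic
(significant in both environments with opposite directions of S).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, FitnessTable


@dataclass
class RelativeFitness:
    """w = fecundity / mean fecundity among retained (non-zero) plants."""

    w: np.ndarray  # per retained plant
    retained: np.ndarray  # bool mask over the input order

    def __post_init__(self) -> None:
        if abs(self.w.mean() - 1.0) > 1e-10:
            raise AssertionError("mean relative fitness must equal 1")


@dataclass
class PcaResult:
    scores: np.ndarray  # plants x components
    loadings: np.ndarray  # transcripts x components
    var_frac: np.ndarray
    retained: np.ndarray  # bool, var_frac > threshold
    plant_ids: np.ndarray
    transcript_ids: np.ndarray


def relative_fitness(fecundity) -> RelativeFitness:
    fec = np.asarray(fecundity, dtype=float)
    retained = fec > 0
    if retained.sum() < 2:
        raise ValueError("need at least 2 plants with positive fecundity")
    w = fec[retained]
    return RelativeFitness(w=w / w.mean(), retained=retained)


def trim_outliers(values, k: float = 3.0) -> np.ndarray:
    """Mask (single pass) of values within k standard deviations of the mean."""
    x = np.asarray(values, dtype=float)
    if np.isfinite(x).sum() < 3:
        raise ValueError("need at least 3 finite values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(k):
        return np.ones_like(x, dtype=bool)
    return np.abs(x - x.mean()) <= k * sd


def _ols(X: np.ndarray, y: np.ndarray):
    """Coefficients with Wald t two-sided p-values; None if singular."""
    n, p = X.shape
    if n <= p:
        return None
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        return None
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - p
    s2 = resid @ resid / df
    se = np.sqrt(np.clip(np.diag(xtx_inv) * s2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = np.where(se > 0, 2 * stats.t.sf(np.abs(t), df), 1.0)
    return beta, se, t, pvals


def _block_dummies(block: np.ndarray) -> np.ndarray:
    levels = np.unique(block)
    return np.column_stack([(block == b).astype(float) for b in levels[1:]]) if (
        len(levels) > 1
    ) else np.empty((len(block), 0))


def selection_differentials(
    expr: ExpressionMatrix,
    fitness: FitnessTable,
    environment: str,
    min_n: int = 20,
    trim_k: float = 3.0,
    block_covariate: bool = True,
) -> pd.DataFrame:
    """Per-transcript S and C with raw, variance- and mean-standardized forms.

    Zero-fecundity plants are dropped before normalizing fitness; expression
    values more than ``trim_k`` SD from the transcript mean are removed; a
    transcript must be expressed (value > 0) in at least ``min_n`` retained
    plants to be tested. Bonferroni adjustment runs over the transcripts
    tested in this environment.
    """
    mask = expr.env_mask(environment)
    if mask.sum() == 0:
        raise ValueError(f"no plants in environment {environment!r}")
    fec = fitness.aligned_to(expr.plant_ids[mask])
    rf = relative_fitness(fec)
    sub = expr.subset_plants(mask).subset_plants(rf.retained)
    w = rf.w
    blocks = _block_dummies(sub.block) if block_covariate else np.empty((len(w), 0))

    rows = []
    for j, transcript in enumerate(sub.transcript_ids):
        x = sub.values[:, j]
        if (x > 0).sum() < min_n:
            rows.append({"transcript": transcript, "skipped": "min_n"})
            continue
        keep = trim_outliers(x, trim_k)
        xk, wk, bk = x[keep], w[keep], blocks[keep]
        mu, sd = xk.mean(), xk.std(ddof=1)
        intercept = np.ones(len(xk))
        lin = _ols(np.column_stack([intercept, xk, bk]), wk)
        quad = _ols(np.column_stack([intercept, xk, xk**2, bk]), wk)
        if lin is None or quad is None:
            rows.append({"transcript": transcript, "skipped": "singular"})
            continue
        s, p_s = lin[0][1], lin[3][1]
        c, p_c = 2.0 * quad[0][2], quad[3][2]
        rows.append(
            {
                "transcript": transcript,
                "n_used": int(keep.sum()),
                "S": s, "p_S": p_s, "se_S": lin[1][1],
                "C": c, "p_C": p_c, "se_C": 2.0 * quad[1][2],
                "mu_z": mu, "sigma_z": sd,
                "S_s": s * sd, "S_m": s * mu,
                "C_s": c * sd**2, "C_m": c * mu**2,
                "skipped": "",
            }
        )
    out = pd.DataFrame(rows).set_index("transcript")
    tested = out["skipped"] == ""
    n_tested = int(tested.sum())
    out.loc[tested, "p_S_bonferroni"] = np.minimum(
        out.loc[tested, "p_S"] * n_tested, 1.0
    )
    out.loc[tested, "p_C_bonferroni"] = np.minimum(
        out.loc[tested, "p_C"] * n_tested, 1.0
    )
    out["environment"] = environment
    return out


def classify_cn_ap(
    table_normal: pd.DataFrame,
    table_saline: pd.DataFrame,
    cn_p: float = 0.025,
    cn_other_p: float = 0.05,
    ap_p: float = 0.05,
) -> pd.Series:
    """CN/AP labels per transcript present in both environments' tables.

    AP: p < 0.05 in both environments and opposite sign of S (checked first).
    Concordant: significant in both with the same sign. CN: the stricter
    asymmetric rule (p < 0.025 in one environment, p > 0.05 in the other).
    """
    joined = table_normal[["S", "p_S"]].join(
        table_saline[["S", "p_S"]], how="inner", lsuffix="_n", rsuffix="_s"
    )
    labels = pd.Series("none", index=joined.index, dtype=object)
    missing = joined.isna().any(axis=1)
    pn, ps = joined["p_S_n"], joined["p_S_s"]
    sn, ss = joined["S_n"], joined["S_s"]
    both_sig = (pn < ap_p) & (ps < ap_p) & ~missing
    labels[both_sig & (np.sign(sn) * np.sign(ss) < 0)] = "AP"
    labels[both_sig & (np.sign(sn) * np.sign(ss) > 0)] = "concordant"
    free = labels == "none"
    labels[free & (pn < cn_p) & (ps > cn_other_p) & ~missing] = "CN_normal"
    free = labels == "none"
    labels[free & (ps < cn_p) & (pn > cn_other_p) & ~missing] = "CN_saline"
    labels.name = "trade_off_class"
    return labels


def expression_pca(
    expr: ExpressionMatrix, environment: str | None = None, min_var_frac: float = 0.005
) -> PcaResult:
    """Centered (not re-scaled) PCA of plant-level expression."""
    sub = expr if environment is None else expr.subset_plants(expr.env_mask(environment))
    x = sub.values
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 plants and 2 transcripts")
    centered = x - x.mean(axis=0)
    if not (centered.std(axis=0) > 0).any():
        raise ValueError("zero-variance expression matrix")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    var_frac = var / var.sum()
    return PcaResult(
        scores=u * s,
        loadings=vt.T,
        var_frac=var_frac,
        retained=var_frac > min_var_frac,
        plant_ids=sub.plant_ids,
        transcript_ids=sub.transcript_ids,
    )


def selection_gradients(scores: np.ndarray, w: np.ndarray) -> pd.DataFrame:
    """Linear (beta) and quadratic (gamma) gradients from joint regressions."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == len(w) - 0 and scores.ndim == 1:
        scores = scores[:, None]
    n, k = scores.shape
    if n <= k + 2:
        raise ValueError("need more plants than components + 2")
    intercept = np.ones(n)
    lin = _ols(np.column_stack([intercept, scores]), w)
    quad = _ols(np.column_stack([intercept, scores, scores**2]), w)
    if lin is None or quad is None:
        raise ValueError("collinear scores: gradient design is singular")
    return pd.DataFrame(
        {
            "beta": lin[0][1 : k + 1],
            "se_beta": lin[1][1 : k + 1],
            "p_beta": lin[3][1 : k + 1],
            "gamma": 2.0 * quad[0][k + 1 : 2 * k + 1],
            "se_gamma": 2.0 * quad[1][k + 1 : 2 * k + 1],
            "p_gamma": quad[3][k + 1 : 2 * k + 1],
        },
        index=[f"PC{i + 1}" for i in range(k)],
    )


def pc_direction(
    loadings: np.ndarray,
    transcript_ids: np.ndarray,
    s_table: pd.DataFrame,
    top_frac: float = 0.01,
) -> np.ndarray:
    """Assign a sign to each PC from its top-loading transcripts.

    Among the top ``top_frac`` transcripts by absolute loading, count sign
    agreement between the loading and the univariate S; the majority sets the
    direction (+1/-1); exact ties or no overlap give 0 (unresolved).
    """
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    s = s_table["S"] if "S" in s_table else s_table.iloc[:, 0]
    s = s.reindex(np.asarray(transcript_ids, dtype=object))
    n_top = max(int(np.ceil(top_frac * loadings.shape[0])), 1)
    signs = np.zeros(loadings.shape[1], dtype=int)
    for k in range(loadings.shape[1]):
        top = np.argsort(-np.abs(loadings[:, k]))[:n_top]
        sv = s.to_numpy()[top]
        lv = loadings[top, k]
        ok = np.isfinite(sv)
        if not ok.any():
            continue
        agree = int((np.sign(sv[ok]) * np.sign(lv[ok]) > 0).sum())
        disagree = int((np.sign(sv[ok]) * np.sign(lv[ok]) < 0).sum())
        signs[k] = 0 if agree == disagree else (1 if agree > disagree else -1)
    return signs


def prune_correlated(traits: pd.DataFrame, threshold: float = 0.6) -> list:
    """Greedy drop of the most-connected trait until all |r| < threshold."""
    kept = list(traits.columns)
    if len(kept) < 2:
        return kept
    while len(kept) > 1:
        corr = traits[kept].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if (corr.values < threshold).all():
            break
        kept.remove(corr.mean(axis=0).idxmax())
    if len(kept) == 1:
        warnings.warn("all traits mutually correlated above threshold; "
                      "kept the single best-connected trait")
    return kept


def trait_gradients(
    traits: pd.DataFrame, w: np.ndarray, cor_threshold: float = 0.6
) -> pd.DataFrame:
    """Variance-standardized gradients on correlation-pruned traits."""
    if traits.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    kept = prune_correlated(traits, cor_threshold)
    z = (traits[kept] - traits[kept].mean()) / traits[kept].std(ddof=1)
    out = selection_gradients(z.to_numpy(), np.asarray(w, dtype=float))
    out.index = kept
    return out


def go_selection(
    s_table: pd.DataFrame,
    term_map: dict,
    min_size: int = 20,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median |S| per term with a percentile-bootstrap 95% CI.

    A term is under significantly stronger selection than the transcriptome
    if the lower CI bound of its median |S| exceeds the transcriptome-wide
    median |S|.
    """
    rng = np.random.default_rng(seed)
    abs_s = s_table["S"].abs().dropna()
    global_median = float(abs_s.median())
    rows = []
    for term in sorted(term_map):
        members = abs_s.reindex(
            [t for t in term_map[term] if t in abs_s.index]
        ).dropna()
        if len(members) < min_size:
            continue
        vals = members.to_numpy()
        boots = np.median(
            vals[rng.integers(0, len(vals), size=(n_boot, len(vals)))], axis=1
        )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "term": term,
                "n": len(vals),
                "median_abs_S": float(np.median(vals)),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "global_median_abs_S": global_median,
                "significant": bool(lo > global_median),
            }
        )
    return pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame(
        columns=["n", "median_abs_S", "ci_low", "ci_high",
                 "global_median_abs_S", "significant"]
    )
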