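"""Additive genetic (co)variance of expression-PC scores and predicted
response to selection.

The genomic relationship matrix (GRM) is the cross-product of per-SNP
standardized dosages. Additive variances and covariances of accession-level
"eigengene" scores (replicate means of PC scores) are estimated by
Haseman-Elston regression of score cross-products on off-diagonal GRM
entries, the resulting G is bent to the nearest positive semi-definite
matrix if needed, and the multivariate breeder's equation Delta z = G beta
predicts the one-generation response, split into the direct (diagonal,
G_ii * beta_i) and indirect (off-diagonal) contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix


@dataclass
class GMatrixResult:
    g: np.ndarray  # k x k additive (co)variance of PC scores
    se: np.ndarray  # k x k standard errors of the HE slopes
    bent: bool  # True if eigenvalue clipping changed G


def grm(geno: GenotypeMatrix) -> np.ndarray:
    """GRM from unit-variance standardized dosages; mean diagonal is 1."""
    if geno.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    d = geno.dosage_imputed()
    sd = d.std(axis=0)  # ddof=0 so the mean diagonal is exactly 1
    poly = sd > 0
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    z = (d[:, poly] - d[:, poly].mean(axis=0)) / sd[poly]
    return z @ z.T / poly.sum()


def _he_pairs(k_mat: np.ndarray):
    iu = np.triu_indices_from(k_mat, k=1)
    return iu, k_mat[iu]


def estimate_g_matrix(
    pc_scores: np.ndarray, k_mat: np.ndarray, min_accessions: int = 10
) -> GMatrixResult:
    """Haseman-Elston G from accession-level scores and the GRM.

    Diagonal entries regress y_i * y_j (i < j) on K_ij; off-diagonals regress
    the symmetrized cross-trait products (y^a_i y^b_j + y^a_j y^b_i) / 2 on
    K_ij. Scores are mean-centered per trait. Any negative eigenvalues of the
    assembled matrix are clipped to zero (flagged as ``bent``).
    """
    y = np.atleast_2d(np.asarray(pc_scores, dtype=float))
    if y.ndim == 1:
        y = y[:, None]
    n, k = y.shape
    if n < min_accessions:
        raise ValueError(f"need at least {min_accessions} accessions")
    if k_mat.shape != (n, n):
        raise ValueError("GRM shape does not match scores")
    y = y - y.mean(axis=0)
    iu, x = _he_pairs(k_mat)
    design = np.column_stack([np.ones_like(x), x])
    xtx_inv = np.linalg.inv(design.T @ design)

    g = np.zeros((k, k))
    se = np.zeros((k, k))
    for a in range(k):
        for b in range(a, k):
            prod = 0.5 * (y[iu[0], a] * y[iu[1], b] + y[iu[1], a] * y[iu[0], b])
            beta = xtx_inv @ (design.T @ prod)
            resid = prod - design @ beta
            s2 = resid @ resid / (len(prod) - 2)
            g[a, b] = g[b, a] = beta[1]
            se[a, b] = se[b, a] = np.sqrt(s2 * xtx_inv[1, 1])

    vals, vecs = np.linalg.eigh(g)
    bent = bool((vals < 0).any())
    if bent:
        g = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        g = 0.5 * (g + g.T)
    return GMatrixResult(g=g, se=se, bent=bent)


def predict_response(g: np.ndarray, beta: np.ndarray) -> pd.DataFrame:
    """Multivariate breeder's equation Delta z = G beta.

    direct_i = G_ii * beta_i; indirect_i = Delta z_i - direct_i; a component
    is flagged constrained when direct and indirect responses have opposite
    (nonzero) signs.
    """
    g = np.asarray(g, dtype=float)
    beta = np.asarray(beta, dtype=float).ravel()
    if g.shape != (len(beta), len(beta)):
        raise ValueError("G and beta dimensions do not match")
    if not np.allclose(g, g.T, atol=1e-10):
        raise ValueError("G must be symmetric")
    delta_z = g @ beta
    direct = np.diag(g) * beta
    indirect = delta_z - direct
    flags = (np.sign(direct) * np.sign(indirect) < 0) & (direct != 0) & (indirect != 0)
    return pd.DataFrame(
        {
            "beta": beta,
            "delta_z": delta_z,
            "direct": direct,
            "indirect": indirect,
            "constrained": flags,
        },
        index=[f"PC{i + 1}" for i in range(len(beta))],
    )


def eigengene_scores(
    scores: np.ndarray, plant_accessions: np.ndarray, retained: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-accession means of replicate PC scores (the eigengene)."""
    cols = (
        np.flatnonzero(retained) if retained is not None else range(scores.shape[1])
    )
    df = pd.DataFrame({f"PC{int(c) + 1}": scores[:, c] for c in cols})
    df["__acc"] = np.asarray(plant_accessions, dtype=object)
    return df.groupby("__acc", sort=True).mean()
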