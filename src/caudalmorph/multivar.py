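"""Phylogenetic PCA and phylogenetic MANOVA.

The PCA eigendecomposes the evolutionary trait covariance
R = (X - 1a)' C^-1 (X - 1a) / (n - 1), with a the GLS (phylogenetic) mean
and C the Brownian among-species covariance; scores are the centred data
projected on the eigenvectors.  Components explaining at least 5% of total
variance are retained by default.

The MANOVA uses the Pillai-Bartlett trace of the ordinary (ahistorical)
between/within cross-products.  The ahistorical p-value comes from the
standard approximate-F transformation; the phylogenetic p-value compares
the observed trace with traces from multivariate Brownian simulations on
the tree (rate matrix = pooled within-group GLS covariance), keeping group
labels fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .morphodata import GroupFactor
from .phylo import Phylogeny, PhyloCovariance, lambda_transform, simulate_bm, tree_vcv

__all__ = [
    "PPCAResult",
    "ManovaResult",
    "phylo_pca",
    "select_components",
    "pillai_trace",
    "phylo_manova",
]


@dataclass(frozen=True)
class PPCAResult:
    eigenvalues: np.ndarray
    loadings: np.ndarray          # columns orthonormal
    scores: pd.DataFrame          # species x components
    percent_variance: np.ndarray
    phylo_mean: np.ndarray
    evolutionary_cov: np.ndarray


@dataclass(frozen=True)
class ManovaResult:
    pillai: float
    approx_F: float
    df1: int
    df2: int
    p_ahistorical: float
    p_phylogenetic: float
    n_sim: int
    seed: int


def phylo_pca(X: pd.DataFrame, tree: Phylogeny, *,
              cov: PhyloCovariance | None = None) -> PPCAResult:
    """Principal components of the evolutionary covariance matrix."""
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if X.shape[0] <= 2:
        raise ValueError("need more than 2 species")
    C = (cov if cov is not None else tree_vcv(tree)).reorder(list(X.index))
    Xv = X.to_numpy(dtype=float)
    n = Xv.shape[0]
    L = np.linalg.cholesky(C.C)
    ones_w = solve_triangular(L, np.ones(n), lower=True)
    Xw = solve_triangular(L, Xv, lower=True)
    a = (ones_w @ Xw) / (ones_w @ ones_w)          # phylogenetic mean
    Dw = Xw - np.outer(ones_w, a)
    R = (Dw.T @ Dw) / (n - 1)                       # evolutionary covariance
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    scores = (Xv - a) @ V
    pct = 100.0 * w / w.sum()
    cols = [f"PC{i + 1}" for i in range(V.shape[1])]
    return PPCAResult(eigenvalues=w, loadings=V,
                      scores=pd.DataFrame(scores, index=X.index, columns=cols),
                      percent_variance=pct, phylo_mean=a, evolutionary_cov=R)


def select_components(r: PPCAResult, min_percent: float = 5.0) -> list[int]:
    """Indices (0-based) of components explaining >= min_percent of variance."""
    return [int(i) for i in np.nonzero(r.percent_variance >= min_percent)[0]]


def _cross_products(Xv: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between-group (H) and within-group (E) SSCP matrices from one-hot Y."""
    ng = Y.sum(axis=0)
    means = (Y.T @ Xv) / ng[:, None]
    grand = Xv.mean(axis=0)
    Dm = means - grand
    H = (Dm * ng[:, None]).T @ Dm
    Rm = Xv - Y @ means
    E = Rm.T @ Rm
    return H, E


def pillai_trace(Xv: np.ndarray, Y: np.ndarray) -> float:
    """Pillai-Bartlett trace V = tr(H (H + E)^-1)."""
    H, E = _cross_products(Xv, Y)
    return float(np.trace(H @ np.linalg.inv(H + E)))


def _pillai_batch(Xs: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pillai trace for a stack of simulated datasets (r, n, p)."""
    ng = Y.sum(axis=0)
    means = np.einsum("gn,rnp->rgp", (Y / ng).T, Xs)
    grand = Xs.mean(axis=1, keepdims=True)
    Dm = means - grand
    H = np.einsum("rgp,g,rgq->rpq", Dm, ng, Dm)
    Rm = Xs - np.einsum("ng,rgp->rnp", Y, means)
    E = np.einsum("rnp,rnq->rpq", Rm, Rm)
    HE = H + E
    out = np.empty(Xs.shape[0])
    for r in range(Xs.shape[0]):
        out[r] = np.trace(np.linalg.solve(HE[r].T, H[r].T).T)
    return out


def _pillai_F(V: float, p: int, g: int, n: int) -> tuple[float, int, int, float]:
    """Approximate F for the Pillai trace and its ahistorical p-value."""
    q = g - 1
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (n - g - p - 1) / 2.0
    df1 = int(s * (2 * m + s + 1))
    df2 = int(s * (2 * nn + s + 1))
    if df2 <= 0 or V >= s:
        return np.nan, df1, df2, np.nan
    F = (2 * nn + s + 1) / (2 * m + s + 1) * (V / s) / (1 - V / s)
    pval = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, pval


def phylo_manova(X: pd.DataFrame, g: GroupFactor, tree: Phylogeny,
                 n_sim: int = 1000, seed: int = 0, *,
                 lam: float = 1.0) -> ManovaResult:
    """MANOVA with a Brownian-simulation null for the Pillai trace.

    ``lam`` rescales the tree covariance used by the null simulations
    (lam = 0 reduces the phylogenetic null to the ahistorical one on a
    unit-depth tree).
    """
    if n_sim < 99:
        raise ValueError("need n_sim >= 99")
    Y = g.indicator(X.index).to_numpy(dtype=float)
    n, p = X.shape
    G = Y.shape[1]
    if G < 2:
        raise ValueError("need at least 2 groups")
    if (Y.sum(axis=0) == n).any():
        raise ValueError("one group contains every species")
    Xv = X.to_numpy(dtype=float)
    V_obs = pillai_trace(Xv, Y)
    F, df1, df2, p_ahist = _pillai_F(V_obs, p, G, n)

    # pooled within-group evolutionary covariance as the BM rate matrix
    C = lambda_transform(tree_vcv(tree), lam).reorder(list(X.index))
    L = np.linalg.cholesky(C.C)
    Yw = solve_triangular(L, Y, lower=True)
    Xw = solve_triangular(L, Xv, lower=True)
    B, *_ = np.linalg.lstsq(Yw, Xw, rcond=None)
    Rw = Xw - Yw @ B
    rate = (Rw.T @ Rw) / max(n - G, 1)
    sims = simulate_bm(tree, rate, lam, seed, n_reps=n_sim, cov=C)
    V_sim = _pillai_batch(sims, Y)
    p_phylo = (np.sum(V_sim >= V_obs - 1e-12) + 1) / (n_sim + 1)
    return ManovaResult(pillai=V_obs, approx_F=F, df1=df1, df2=df2,
                        p_ahistorical=p_ahist, p_phylogenetic=float(p_phylo),
                        n_sim=n_sim, seed=seed)
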