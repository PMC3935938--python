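"""Phylogenetic flexible discriminant analysis.

Both the trait matrix and the one-hot class-indicator matrix are whitened
by the inverse Cholesky factor of the lambda-rescaled phylogenetic
covariance C(lambda); a linear discriminant is then fitted to the whitened
data via optimal scoring (regression of scored class indicators on the
predictors, followed by a generalized eigendecomposition of the fitted
cross-products).  With lambda = 0 on a unit-depth tree the whitening is the
identity and the procedure collapses to ordinary linear discriminant
analysis.  Classification uses the optimal-scoring/LDA correspondence:
weighted distances to class centroids in discriminant space, with weights
1 / (alpha^2 (1 - alpha^2)) per axis and uniform class priors.

The optimal lambda maximizes the summed per-column GLS ML log-likelihood of
the traits given the class-indicator design under C(lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar

from .morphodata import GroupFactor
from .phylo import Phylogeny, lambda_transform, tree_vcv

__all__ = ["PFDAResult", "pfda_optimal_lambda", "pfda_fit_predict"]


@dataclass(frozen=True)
class PFDAResult:
    lambda_used: float
    scores: pd.DataFrame           # species x discriminant axes
    predicted: pd.Series           # species -> predicted class
    confusion: pd.DataFrame        # true (rows) x predicted (cols)
    misclassification_rate: float
    eigenvalues: np.ndarray        # alpha^2 per axis
    class_centroids: pd.DataFrame  # class x axes


def _design_loglik(Xv: np.ndarray, W: np.ndarray, C: np.ndarray) -> float:
    """Summed per-column ML GLS log-likelihood of X on design W under C."""
    n, p = Xv.shape
    L = np.linalg.cholesky(C)
    Ww = solve_triangular(L, W, lower=True)
    Xw = solve_triangular(L, Xv, lower=True)
    B, *_ = np.linalg.lstsq(Ww, Xw, rcond=None)
    Rw = Xw - Ww @ B
    sigma2 = np.einsum("ij,ij->j", Rw, Rw) / n
    if np.any(sigma2 <= 0):
        return np.inf
    logdetC = 2.0 * np.sum(np.log(np.diag(L)))
    return float(np.sum(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdetC + n)))


def pfda_optimal_lambda(X: pd.DataFrame, g: GroupFactor, tree: Phylogeny) -> float:
    """Lambda in [0, 1] maximizing the GLS likelihood of traits given groups."""
    Y = g.indicator(X.index).to_numpy(dtype=float)
    if Y.shape[1] < 2:
        raise ValueError("need at least 2 groups")
    Xv = X.to_numpy(dtype=float)
    cov = tree_vcv(tree).reorder(list(X.index))

    def neg(lam: float) -> float:
        return -_design_loglik(Xv, Y, lambda_transform(cov, lam).C)

    res = minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    cands = [(float(res.x), -neg(res.x)), (0.0, -neg(0.0)), (1.0, -neg(1.0))]
    return max(cands, key=lambda c: c[1])[0]


def pfda_fit_predict(X: pd.DataFrame, g: GroupFactor, tree: Phylogeny,
                     lam: float | None = None) -> PFDAResult:
    """Fit the discriminant and classify every training species.

    ``lam`` defaults to the optimum from :func:`pfda_optimal_lambda`.
    Misclassification is resubstitution (training-set) error, the quantity
    reported for the study's 51 taxa.
    """
    if lam is None:
        lam = pfda_optimal_lambda(X, g, tree)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    classes = sorted(g.mapping.loc[X.index].unique())
    G = len(classes)
    if G < 2:
        raise ValueError("need at least 2 groups")
    Y = g.indicator(X.index)[classes].to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if p >= n - G:
        raise ValueError(
            f"{p} predictors for {n} species and {G} groups is ill-posed; "
            "reduce dimensionality first (e.g. phylo_pca + select_components)")

    C = lambda_transform(tree_vcv(tree), lam).reorder(list(X.index))
    L = np.linalg.cholesky(C.C)
    Yw = solve_triangular(L, Y, lower=True)
    W = solve_triangular(L, np.column_stack([np.ones(n), Xv]), lower=True)

    # optimal scoring: regress whitened indicators on whitened [1, X]
    B, *_ = np.linalg.lstsq(W, Yw, rcond=None)
    Yhat = W @ B
    A = Yhat.T @ Yhat        # = Yw' Yhat, cross-products of fitted values
    Bm = Yw.T @ Yw
    if np.linalg.cond(Bm) > 1e10:
        raise np.linalg.LinAlgError(
            "singular within-class structure; check for empty groups")
    # deflate the trivial constant score (theta = 1 fits exactly through
    # the intercept): restrict to the Bm-orthogonal complement of 1
    ones = np.ones(G)
    b1 = Bm @ ones
    Q, _ = np.linalg.qr(np.column_stack([b1, np.eye(G)[:, : G - 1]]))
    K = Q[:, 1:]
    from scipy.linalg import eigh

    alpha2, Vr = eigh(K.T @ A @ K, K.T @ Bm @ K)
    order = np.argsort(alpha2)[::-1]
    n_axes = min(G - 1, p)
    alpha2 = np.clip(alpha2[order][:n_axes], 0.0, 1.0 - 1e-12)
    Theta = K @ Vr[:, order][:, :n_axes]
    # normalize scores: theta' (Bm/n) theta = 1
    norms = np.sqrt(np.einsum("ij,jk,ki->i", Theta.T, Bm / n, Theta))
    Theta = Theta / norms

    # discriminant directions come from the whitened (GLS) regression, but
    # species are scored and classified on their own trait values: the
    # whitened rows are phylogenetic mixtures and do not represent any one
    # species' morphology
    Beta = np.linalg.lstsq(W, Yw @ Theta, rcond=None)[0]   # (p+1, axes)
    eta = np.column_stack([np.ones(n), Xv]) @ Beta          # raw-space scores
    centroids = (Y.T @ eta) / Y.sum(axis=0)[:, None]        # class means
    w_axis = 1.0 / np.maximum(alpha2 * (1.0 - alpha2), 1e-12)

    d2 = ((eta[:, None, :] - centroids[None, :, :]) ** 2 * w_axis).sum(axis=2)
    pred_idx = d2.argmin(axis=1)
    predicted = pd.Series([classes[i] for i in pred_idx], index=X.index,
                          name="predicted")
    truth = g.mapping.loc[X.index]
    confusion = pd.crosstab(truth, predicted).reindex(
        index=classes, columns=classes, fill_value=0)
    mis = float((predicted != truth).mean())
    axes = [f"DA{i + 1}" for i in range(n_axes)]
    return PFDAResult(
        lambda_used=float(lam),
        scores=pd.DataFrame(eta, index=X.index, columns=axes),
        predicted=predicted,
        confusion=confusion,
        misclassification_rate=mis,
        eigenvalues=alpha2,
        class_centroids=pd.DataFrame(centroids, index=classes, columns=axes),
    )
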