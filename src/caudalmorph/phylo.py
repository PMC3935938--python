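"""Trees and the shared phylogenetic linear-algebra layer.

Everything downstream (signal tests, phylogenetic PCA/MANOVA, pFDA) consumes
a :class:`Phylogeny` plus the among-species covariance matrix it induces
under Brownian motion, optionally rescaled by Pagel's lambda.  All joins
between trees and trait tables are by species label, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "GLSFit",
    "read_newick",
    "tree_vcv",
    "lambda_transform",
    "simulate_bm",
    "gls_fit",
]

#: covariance matrices worse-conditioned than this are refused outright
#: rather than silently ridge-regularized
MAX_CONDITION = 1e12


@dataclass(frozen=True)
class Phylogeny:
    """A rooted tree with branch lengths, stored as a parent array.

    Nodes are indexed 0..n_nodes-1 with tips first (in ``tips`` order) and
    the root last; ``parent[i]`` is -1 for the root.  Polytomies and
    zero-length branches are allowed.
    """

    tips: tuple[str, ...]
    parent: np.ndarray          # (n_nodes,) int, -1 at root
    edge_length: np.ndarray     # (n_nodes,) float, 0.0 at root
    newick: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if len(self.tips) < 2:
            raise ValueError("a phylogeny needs at least 2 tips")
        if len(set(self.tips)) != len(self.tips):
            dupes = sorted({t for t in self.tips if list(self.tips).count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if np.any(self.edge_length[:-1] < 0) or not np.all(np.isfinite(self.edge_length)):
            raise ValueError("branch lengths must be finite and >= 0")

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths, computed by walking parent pointers."""
        depths = np.zeros(self.n_nodes)
        # root is last; children always have lower index than ... not
        # guaranteed, so walk each node up to the root explicitly
        for i in range(self.n_nodes):
            d, j = 0.0, i
            while self.parent[j] != -1:
                d += self.edge_length[j]
                j = self.parent[j]
            depths[i] = d
        return depths

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p != -1:
                kids[p].append(i)
        return kids

    def to_newick(self) -> str:
        if self.newick:
            return self.newick
        kids = self.children()

        def render(i: int) -> str:
            if i < self.n_tips:
                return f"{self.tips[i]}:{self.edge_length[i]:.10g}"
            inner = ",".join(render(c) for c in kids[i])
            if self.parent[i] == -1:
                return f"({inner})"
            return f"({inner}):{self.edge_length[i]:.10g}"

        return render(self.n_nodes - 1) + ";"


@dataclass(frozen=True)
class PhyloCovariance:
    """Among-species covariance: shared root-to-MRCA path lengths."""

    C: np.ndarray
    tip_order: tuple[str, ...]

    def __post_init__(self) -> None:
        C = self.C
        if C.shape != (len(self.tip_order),) * 2:
            raise ValueError("C shape does not match tip_order")
        if not np.allclose(C, C.T):
            raise ValueError("C must be symmetric")

    @property
    def n(self) -> int:
        return len(self.tip_order)

    def reorder(self, labels) -> "PhyloCovariance":
        """Return the submatrix for ``labels``, in that order."""
        idx = {t: i for i, t in enumerate(self.tip_order)}
        missing = [s for s in labels if s not in idx]
        if missing:
            raise KeyError(f"species not in tree: {missing}")
        sel = np.array([idx[s] for s in labels])
        return PhyloCovariance(self.C[np.ix_(sel, sel)], tuple(labels))


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Tip labels and branch lengths are preserved exactly; unlabeled internal
    nodes are fine.  Duplicate tips, missing branch lengths, and malformed
    strings raise ``ValueError``.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises a zoo of error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(tree, newick=text.strip())


def _from_dendropy(tree: dendropy.Tree, newick: str = "") -> Phylogeny:
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
    if any(lab is None for lab in labels):
        raise ValueError("unlabeled tip in tree")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")

    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    # tips first, internals in reverse preorder so the root ends up last
    order = leaves + internals[::-1]
    index = {id(nd): i for i, nd in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=int)
    elen = np.zeros(n)
    for nd in order:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise ValueError(f"missing branch length above node {nd}")
            elen[i] = float(nd.edge.length)
        elif nd.edge.length:  # root edge, fold into nothing
            elen[i] = 0.0
    return Phylogeny(tuple(labels), parent, elen, newick=newick)


def tree_vcv(tree: Phylogeny) -> PhyloCovariance:
    """Brownian-motion covariance: C[i,j] = depth of MRCA(tip i, tip j)."""
    n = tree.n_tips
    depths = tree.node_depths()
    C = np.zeros((n, n))
    C[np.diag_indices(n)] = depths[:n]
    kids = tree.children()
    # postorder over internals: tip sets of children meet at this node
    tipsets: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    for node in sorted(range(n, tree.n_nodes), key=lambda i: -_depth_rank(tree, i)):
        groups = [tipsets[c] for c in kids[node]]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                C[np.ix_(groups[gi], groups[gj])] = depths[node]
                C[np.ix_(groups[gj], groups[gi])] = depths[node]
        tipsets[node] = np.concatenate(groups)
    return PhyloCovariance(C, tree.tips)


def _depth_rank(tree: Phylogeny, i: int) -> int:
    """Number of ancestors of node i (topological depth)."""
    d, j = 0, i
    while tree.parent[j] != -1:
        d += 1
        j = tree.parent[j]
    return d


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda rescaling: off-diagonals times lambda, diagonal kept.

    lambda = 1 leaves the Brownian covariance untouched; lambda = 0 turns
    the tree into a star phylogeny (independent tips).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = cov.C * lam
    np.fill_diagonal(C, np.diag(cov.C))
    return PhyloCovariance(C, cov.tip_order)


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish factor A with A @ A.T = M, tolerant of PSD rank
    deficiency (eigenvalue fallback when Cholesky fails)."""
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("matrix is not positive semi-definite")
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)


def simulate_bm(tree: Phylogeny, rate_matrix: np.ndarray, lam: float,
                seed: int, n_reps: int = 1, *,
                ancestral: float = 0.0,
                cov: PhyloCovariance | None = None) -> pd.DataFrame | np.ndarray:
    """Simulate multivariate Brownian motion on a lambda-rescaled tree.

    Tip values are one draw from a matrix-normal with among-species
    covariance ``lambda_transform(tree_vcv(tree), lam)`` and among-trait
    covariance ``rate_matrix``.  With ``n_reps == 1`` a species x trait
    DataFrame is returned; otherwise a (n_reps, n_tips, p) array.
    """
    rate_matrix = np.atleast_2d(np.asarray(rate_matrix, dtype=float))
    p = rate_matrix.shape[0]
    if rate_matrix.shape != (p, p):
        raise ValueError("rate matrix must be square")
    B = _psd_factor(rate_matrix)
    Cm = cov if cov is not None else lambda_transform(tree_vcv(tree), lam)
    A = _psd_factor(Cm.C)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_reps, Cm.n, p))
    X = ancestral + np.einsum("ij,rjk,lk->ril", A, Z, B)
    if n_reps == 1:
        return pd.DataFrame(X[0], index=list(Cm.tip_order))
    return X


@dataclass(frozen=True)
class GLSFit:
    beta: np.ndarray
    residuals: np.ndarray
    log_lik: float
    sigma2: float


def _check_condition(C: np.ndarray) -> None:
    w = np.linalg.eigvalsh(C)
    if w[0] <= 0 or w[-1] / w[0] > MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"phylogenetic covariance is singular or too ill-conditioned "
            f"(condition number > {MAX_CONDITION:.0e}); no silent ridging is applied")


def gls_fit(y: np.ndarray, X: np.ndarray, cov: PhyloCovariance | np.ndarray,
            *, check: bool = True) -> GLSFit:
    """Generalized least squares under a phylogenetic covariance.

    beta = (X' C^-1 X)^-1 X' C^-1 y; sigma2 is the ML (1/n) estimate; the
    returned log-likelihood is the full ML Gaussian log-likelihood including
    constants, so values are comparable across lambda transforms.
    """
    C = cov.C if isinstance(cov, PhyloCovariance) else np.asarray(cov, float)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size or C.shape[0] != y.size:
        raise ValueError("dimension mismatch between y, X and C")
    if check:
        _check_condition(C)
    L = np.linalg.cholesky(C)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > MAX_CONDITION:
        raise np.linalg.LinAlgError("singular design: X' C^-1 X not invertible")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = y - X @ beta
    rw = yw - Xw @ beta
    n = y.size
    sigma2 = float(rw @ rw) / n
    logdetC = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2 <= 0:
        # perfect fit: the Gaussian likelihood is unbounded; report +inf
        log_lik = np.inf
    else:
        log_lik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdetC + n)
    return GLSFit(beta=beta, residuals=resid, log_lik=float(log_lik), sigma2=sigma2)


def align_to_cov(X: pd.DataFrame, cov: PhyloCovariance) -> tuple[np.ndarray, PhyloCovariance]:
    """Align a species x trait table with a covariance by label.

    Returns the trait values in the table's row order and the covariance
    reordered to match.  Raises KeyError naming any species absent from the
    tree.
    """
    sub = cov.reorder(list(X.index))
    return X.to_numpy(dtype=float), sub
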