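"""Phylogenetic generalized least squares with maximum-likelihood Pagel's lambda.

Under Brownian trait evolution on a rooted tree, the covariance of tip
values is proportional to the matrix C of shared root-to-ancestor path
lengths: C[i,j] is the depth of the most recent common ancestor of tips i
and j, and C[i,i] the root-to-tip distance.  Pagel's lambda multiplies the
off-diagonal (shared-history) entries by a factor in [0, 1], interpolating
between a star phylogeny (lambda = 0, ordinary least squares) and pure
Brownian covariance (lambda = 1).

``pgls_regress`` profiles lambda over [0, 1] (coarse grid then bounded
refinement), fits GLS conditional on each lambda with the ML variance
sigma^2 = r' V^-1 r / n, and reports the slope with a t-test on n - 2
degrees of freedom conditional on the ML lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloCovariance",
    "PGLSFit",
    "phylo_covariance",
    "pagel_transform",
    "gls_fit",
    "PGLS",
    "pgls_regress",
]


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian-motion tip covariance (shared path lengths from the root)."""

    taxa: tuple[str, ...]
    C: np.ndarray

    def __post_init__(self) -> None:
        if self.C.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("covariance shape does not match taxa")


@dataclass(frozen=True)
class PGLSFit:
    slope: float
    intercept: float
    lam: float
    sigma2: float
    loglik: float
    slope_p: float
    n: int
    slope_se: float = float("nan")
    degenerate: bool = False


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            edge = node.edge.length if node.edge.length is not None else 0.0
            if edge < 0:
                raise ValueError("negative branch length in tree")
            depths[node] = depths[node.parent_node] + edge
    return depths


def phylo_covariance(tree: dendropy.Tree, taxa: Sequence[str]) -> PhyloCovariance:
    """Build the Brownian covariance C for the given taxa from a rooted tree.

    C[i,j] = depth of MRCA(i, j) measured from the root; C[i,i] = root-to-tip
    distance of taxon i.  Raises if a taxon is missing from the tree.
    """
    taxa = tuple(taxa)
    index = {name: i for i, name in enumerate(taxa)}
    if len(index) != len(taxa):
        raise ValueError("duplicate taxa in request")
    depths = _node_depths(tree)
    n = len(taxa)
    C = np.zeros((n, n))
    seen = set()
    # tips_below[node] = indices of requested taxa in that subtree
    tips_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else None
            if label in index:
                i = index[label]
                seen.add(label)
                C[i, i] = depths[node]
                tips_below[node] = [i]
            else:
                tips_below[node] = []
        else:
            groups = [tips_below[c] for c in node.child_nodes()]
            d = depths[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = C[j, i] = d
            tips_below[node] = [i for grp in groups for i in grp]
    missing = [t for t in taxa if t not in seen]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    return PhyloCovariance(taxa=taxa, C=C)


def pagel_transform(cov: PhyloCovariance | np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal (shared-history) covariance entries by lambda."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    C = cov.C if isinstance(cov, PhyloCovariance) else np.asarray(cov, dtype=float)
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def gls_fit(
    y: np.ndarray, x: np.ndarray, V: np.ndarray
) -> tuple[float, float, float, float, np.ndarray]:
    """Generalized least squares of y on [1, x] with error covariance sigma^2 V.

    Returns (intercept, slope, sigma2_ml, loglik, cov_beta_unscaled) where
    cov_beta_unscaled = (X' V^-1 X)^-1 (multiply by sigma^2 for the
    coefficient covariance).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least three observations")
    X = np.column_stack([np.ones(n), x])
    try:
        cf = cho_factor(V)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance matrix is not positive definite") from err
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    if np.linalg.cond(XtViX) > 1e12:
        raise ValueError("design is collinear")
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ (X.T @ Vi_y)
    r = y - X @ beta
    sigma2 = float(r @ cho_solve(cf, r) / n)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    if sigma2 > 0:
        loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    else:
        loglik = np.inf  # degenerate exact fit
    return float(beta[0]), float(beta[1]), sigma2, float(loglik), cov_beta


class PGLS(BaseEstimator):
    """PGLS regression estimator bound to a tree (or precomputed covariance).

    Parameters
    ----------
    tree:
        Rooted dendropy tree with branch lengths.
    taxa:
        Taxon order of the x/y vectors passed to ``fit``; defaults to the
        tree's leaf order.
    lam:
        ``"ml"`` (default) profiles Pagel's lambda over [0, 1]; a float fixes
        it.

    Attributes after ``fit``: ``slope_``, ``intercept_``, ``lambda_``,
    ``sigma2_``, ``loglik_``, ``slope_p_``, ``slope_se_``, ``degenerate_``.
    """

    def __init__(self, tree=None, taxa: Sequence[str] | None = None, lam="ml"):
        self.tree = tree
        self.taxa = taxa
        self.lam = lam

    def _covariance(self) -> PhyloCovariance:
        taxa = self.taxa
        if taxa is None:
            taxa = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        return phylo_covariance(self.tree, taxa)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "PGLS":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cov = self._covariance()
        n = x.size
        if y.size != n or len(cov.taxa) != n:
            raise ValueError("x, y and taxa must have matching lengths")
        if n < 4 and self.lam == "ml":
            raise ValueError("need at least four taxa to profile lambda")

        def ll_at(lam: float) -> float:
            V = pagel_transform(cov, lam)
            return gls_fit(y, x, V)[3]

        if self.lam == "ml":
            grid = np.linspace(0.0, 1.0, 101)
            lls = np.array([ll_at(l) for l in grid])
            k = int(np.argmax(lls))
            if np.isinf(lls[k]):
                lam_hat = float(grid[k])
            else:
                lo = grid[max(k - 1, 0)]
                hi = grid[min(k + 1, len(grid) - 1)]
                res = optimize.minimize_scalar(
                    lambda l: -ll_at(l),
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": 1e-6},
                )
                lam_hat = float(res.x) if -res.fun >= lls[k] else float(grid[k])
        else:
            lam_hat = float(self.lam)
        V = pagel_transform(cov, lam_hat)
        intercept, slope, sigma2, loglik, cov_beta = gls_fit(y, x, V)
        scale = float(np.var(y)) if np.var(y) > 0 else 1.0
        degenerate = sigma2 <= 1e-14 * scale
        if degenerate:
            logger.warning("PGLS residual variance is (numerically) zero")
            se = 0.0
            p = np.finfo(float).tiny
            t = np.inf
        else:
            sigma2_unbiased = sigma2 * n / (n - 2)
            se = float(np.sqrt(sigma2_unbiased * cov_beta[1, 1]))
            t = slope / se if se > 0 else np.inf
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            p = min(max(p, np.finfo(float).tiny), 1.0)
        self.slope_ = slope
        self.intercept_ = intercept
        self.lambda_ = lam_hat
        self.sigma2_ = sigma2
        self.loglik_ = loglik
        self.slope_p_ = p
        self.slope_se_ = se
        self.degenerate_ = degenerate
        self.n_ = n
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept_ + self.slope_ * np.asarray(x, dtype=float)

    @property
    def result_(self) -> PGLSFit:
        return PGLSFit(
            slope=self.slope_,
            intercept=self.intercept_,
            lam=self.lambda_,
            sigma2=self.sigma2_,
            loglik=self.loglik_,
            slope_p=self.slope_p_,
            n=self.n_,
            slope_se=self.slope_se_,
            degenerate=self.degenerate_,
        )


def pgls_regress(
    x: np.ndarray,
    y: np.ndarray,
    tree: dendropy.Tree,
    taxa: Sequence[str] | None = None,
) -> PGLSFit:
    """Functional wrapper: ML-lambda PGLS of y on x over the given tree."""
    est = PGLS(tree=tree, taxa=taxa, lam="ml").fit(x, y)
    return est.result_
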