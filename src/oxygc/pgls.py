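"""Phylogenetic generalized least squares with Pagel's lambda.

Under Brownian trait evolution on a rooted tree, the covariance between two
tips equals the branch length shared on their root-to-tip paths (the depth
of their most recent common ancestor). Regressions across species therefore
have correlated residuals; GLS with this covariance yields slope and
intercept estimates corrected for shared ancestry. Pagel's λ scales the
off-diagonal covariances: λ = 1 is the pure Brownian structure, λ = 0
recovers ordinary least squares (phylogenetic independence).

The oxygen-requirement predictor follows the ordinal coding of the source
analysis: the more oxygen-preferring group of a contrast is coded 3, the
less 2, and organisms outside the contrast are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)


class DegenerateDesignError(ValueError):
    """Constant predictor or otherwise rank-deficient design matrix."""


class EmptyGroupError(ValueError):
    """A contrast group matched no organism."""


@dataclass
class PhyloCovariance:
    """Brownian trait covariance implied by a rooted tree."""

    labels: Sequence[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.labels)
        if self.C.shape != (n, n):
            raise ValueError("covariance shape does not match label count")

    def subset(self, labels: Sequence[str]) -> "PhyloCovariance":
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = [pos[l] for l in labels]
        return PhyloCovariance(list(labels), self.C[np.ix_(idx, idx)])


@dataclass(frozen=True)
class PGLSResult:
    slope: float
    intercept: float
    se_slope: float
    t: float
    p_two_tailed: float
    lambda_hat: float
    n: int
    loglik: float


def brownian_covariance(tree: dendropy.Tree, jitter: float = 1e-8) -> PhyloCovariance:
    """Covariance matrix C with C[i,j] = depth of MRCA(i, j), C[i,i] = tip depth.

    The tree must be rooted (no silent midpoint rooting) with non-negative
    branch lengths and at least 3 tips. Tips on zero-length terminal
    branches get ``jitter`` added to their variance so that C(λ) stays
    positive definite; each addition is logged.
    """
    if not tree.is_rooted:
        raise ValueError("tree must be rooted for a Brownian covariance")
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("need at least 3 tips")
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(labels)
    C = np.zeros((n, n))

    depth: Dict[int, float] = {}
    below: Dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        e = node.edge.length or 0.0
        if e < 0:
            raise ValueError("negative branch length")
        parent = node.parent_node
        depth[id(node)] = e + (depth[id(parent)] if parent is not None else 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = np.array([i])
            C[i, i] = depth[id(node)]
            if (node.edge.length or 0.0) == 0.0:
                logger.info("zero-length terminal branch at %s: +%g jitter", labels[i], jitter)
                C[i, i] += jitter
        else:
            kids = [below[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    C[np.ix_(kids[a], kids[b])] = d
                    C[np.ix_(kids[b], kids[a])] = d
            below[id(node)] = np.concatenate(kids)
    return PhyloCovariance(labels, C)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Scale off-diagonal covariances by λ ∈ [0, 1]; diagonal untouched."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = cov.C * lam
    np.fill_diagonal(C, np.diag(cov.C))
    return PhyloCovariance(list(cov.labels), C)


def _gls_pieces(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Cholesky-whitened GLS: returns beta, rss, logdetV, XtViX_inv."""
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise np.linalg.LinAlgError(
            f"covariance not positive definite (condition number {cond:.3g})"
        ) from exc
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    beta = linalg.solve(XtX, Xw.T @ yw, assume_a="pos")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    XtX_inv = linalg.inv(XtX)
    return beta, rss, logdetV, XtX_inv


def _loglik(lam: float, y, X, cov: PhyloCovariance, reml: bool) -> float:
    n, p = X.shape
    V = lambda_transform(cov, lam).C
    beta, rss, logdetV, XtX_inv = _gls_pieces(y, X, V)
    if reml:
        df = n - p
        s2 = rss / df
        sign, logdetXtX = np.linalg.slogdet(np.linalg.inv(XtX_inv))
        return -0.5 * (
            df * math.log(2 * math.pi * s2) + logdetV + logdetXtX + df
        )
    s2 = rss / n
    return -0.5 * (n * math.log(2 * math.pi * s2) + logdetV + n)


def pgls_fit(
    y: Sequence[float],
    x: Sequence[float],
    cov: PhyloCovariance,
    lambda_mode: Union[str, float] = "ml",
    reml: bool = False,
) -> PGLSResult:
    """GLS regression of y on [1, x] under the λ-scaled Brownian covariance.

    ``lambda_mode`` is ``"ml"`` (λ̂ maximises the log-likelihood over [0, 1]
    by bounded scalar search, tolerance 1e-6) or a fixed λ value. Inference
    on the slope uses a t distribution with n − 2 degrees of freedom and
    σ̂² = RSS/(n − 2).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if not (n == len(x) == len(cov.labels)):
        raise ValueError("y, x and covariance labels must align")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("predictor is constant")
    X = np.column_stack([np.ones(n), x])

    if lambda_mode == "ml":
        res = optimize.minimize_scalar(
            lambda lam: -_loglik(lam, y, X, cov, reml),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        # the bounded search never evaluates exactly at the ends; snap when
        # a boundary value beats the interior optimum
        lam_hat = float(res.x)
        cands = [(lam_hat, -res.fun)] + [
            (b, _loglik(b, y, X, cov, reml)) for b in (0.0, 1.0)
        ]
        lam_hat, ll = max(cands, key=lambda c: c[1])
    else:
        lam_hat = float(lambda_mode)
        if not 0.0 <= lam_hat <= 1.0:
            raise ValueError("fixed lambda must lie in [0, 1]")
        ll = _loglik(lam_hat, y, X, cov, reml)

    V = lambda_transform(cov, lam_hat).C
    beta, rss, _, XtX_inv = _gls_pieces(y, X, V)
    s2 = rss / (n - 2)
    se = np.sqrt(s2 * np.diag(XtX_inv))
    t = beta[1] / se[1]
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return PGLSResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        se_slope=float(se[1]),
        t=float(t),
        p_two_tailed=float(p),
        lambda_hat=lam_hat,
        n=n,
        loglik=float(ll),
    )


# ---------------------------------------------------------------------------
# Oxygen-requirement coding
# ---------------------------------------------------------------------------

def _canon(state: str) -> str:
    return state.strip().lower().replace("_", " ")

#: the seven contrasts of the source analysis: (name, coded-3 states, coded-2 states)
CONTRASTS: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]] = {
    "aerobes+obligate_aerobes vs anaerobes+obligate_anaerobes": (
        ("aerobe", "obligate aerobe"),
        ("anaerobe", "obligate anaerobe"),
    ),
    "aerobes vs anaerobes": (("aerobe",), ("anaerobe",)),
    "obligate_aerobes vs obligate_anaerobes": (
        ("obligate aerobe",),
        ("obligate anaerobe",),
    ),
    "obligate_aerobes vs anaerobes": (("obligate aerobe",), ("anaerobe",)),
    "obligate_aerobes vs aerobes": (("obligate aerobe",), ("aerobe",)),
    "aerobes vs obligate_anaerobes": (("aerobe",), ("obligate anaerobe",)),
    "anaerobes vs obligate_anaerobes": (("anaerobe",), ("obligate anaerobe",)),
}


def encode_oxygen(
    states: Mapping[str, str], contrast: str
) -> Tuple[List[str], np.ndarray]:
    """Ordinal 3/2 codes for one named contrast.

    Returns (organism ids, codes): organisms in the more oxygen-preferring
    group get 3, the less 2; organisms in neither group are dropped.
    """
    try:
        hi, lo = CONTRASTS[contrast]
    except KeyError:
        raise KeyError(
            f"unknown contrast {contrast!r}; valid: {sorted(CONTRASTS)}"
        ) from None
    ids, codes = [], []
    for oid in states:
        s = _canon(states[oid])
        if s in hi:
            ids.append(oid)
            codes.append(3.0)
        elif s in lo:
            ids.append(oid)
            codes.append(2.0)
    arr = np.array(codes)
    if not np.any(arr == 3.0) or not np.any(arr == 2.0):
        raise EmptyGroupError(f"contrast {contrast!r} has an empty group")
    return ids, arr


def log_transform_gc(gc: float, base: str = "e") -> float:
    """Natural (or base-10) log of GC content on the percent scale."""
    if not 0.0 < gc <= 1.0:
        raise ValueError(f"GC fraction must lie in (0, 1], got {gc}")
    v = 100.0 * gc
    return math.log10(v) if base == "10" else math.log(v)
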