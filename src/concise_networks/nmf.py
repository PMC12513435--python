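"""Convex NMF state-node discovery.

A center node's target dynamics ``X`` (column-stochastic, one column
per predecessor) is approximated by ``r`` state nodes.  State node
``alpha`` has an in-distribution ``Xin[i, alpha]`` — the probability a
trajectory arriving from predecessor ``i`` uses it — and an
out-distribution ``Xout[k, alpha]`` over successors, so the implied
dynamics are ``Xhat = Xout @ Xin.T``.

We search for ``Xhat = X W G.T`` with ``W, G >= 0`` (convex NMF): each
reconstructed out-column is a convex combination of observed columns of
``X``, so state nodes represent plausible behavioral modes rather than
arbitrary nonnegative directions.  The Frobenius loss

    || X - X W G.T ||_F^2

is minimized by multiplicative updates; factors are initialized from a
smoothed k-means clustering of the columns of ``X``.  After
convergence the transition matrices are extracted via the diagonal
matrix ``D_W`` of column sums of ``W``::

    Xout = X W D_W^{-1}        (exactly column-stochastic)
    Xin  = G D_W               (rows then normalized to sum 1)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .dynamics import TargetDynamics, matrix_flow_overlap

logger = logging.getLogger(__name__)

__all__ = [
    "FactorPair",
    "StateSplit",
    "init_factors",
    "multiplicative_step",
    "fit_factorization",
    "split_node",
    "select_rank",
    "rank_sweep",
]

EPS = 1e-12  # denominator guard in multiplicative updates
MAX_ITER = 2000
CONVERGENCE_WINDOW = 10
CONVERGENCE_TOL = 1e-4
SMOOTHING = 0.2  # off-cluster entry in the k-means initialization of G


@dataclass
class FactorPair:
    """Nonnegative factors of the convex factorization X ~ X W G.T."""

    W: np.ndarray  # |i| x r
    G: np.ndarray  # |i| x r
    loss: float

    @property
    def rank(self) -> int:
        return self.W.shape[1]


@dataclass
class StateSplit:
    """A rank-r split of one center node into state nodes."""

    center: str | None
    rank: int
    Xin: np.ndarray  # |i| x r, row-stochastic
    Xout: np.ndarray  # |k| x r, column-stochastic
    overlap: float
    loss: float
    predecessors: tuple[str, ...] | None = None
    successors: tuple[str, ...] | None = None
    factors: FactorPair | None = None  # converged (W, G), kept for warm starts

    def __post_init__(self) -> None:
        if not np.allclose(self.Xin.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of Xin must sum to 1")
        if not np.allclose(self.Xout.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("columns of Xout must sum to 1")

    @property
    def Xhat(self) -> np.ndarray:
        """Implied dynamics Xout @ Xin.T (column-stochastic)."""
        return self.Xout @ self.Xin.T


def _frobenius_loss(X: np.ndarray, W: np.ndarray, G: np.ndarray) -> float:
    resid = X - X @ W @ G.T
    return float(np.sum(resid * resid))


def init_factors(X: np.ndarray, r: int, seed: int, smoothing: float = SMOOTHING) -> FactorPair:
    """Smoothed k-means initialization.

    Columns of ``X`` are clustered into ``r`` groups (Lloyd's algorithm
    with k-means++ seeding, 10 restarts); ``G[i, a]`` is 1 when column
    ``i`` falls in cluster ``a`` and ``smoothing`` (default 0.2)
    otherwise, and ``W`` is the row-normalized version of ``G``.
    ``smoothing = 0`` gives the hard cluster-indicator start, whose
    exact zeros are invariant under the multiplicative updates.
    """
    n_cols = X.shape[1]
    if not 1 <= r <= n_cols:
        raise ValueError(f"rank must be in [1, {n_cols}], got {r}")
    if r == 1:
        labels = np.zeros(n_cols, dtype=int)
    else:
        km = KMeans(n_clusters=r, n_init=10, random_state=seed)
        labels = km.fit_predict(X.T)
    G = np.full((n_cols, r), float(smoothing))
    G[np.arange(n_cols), labels] = 1.0
    W = G / G.sum(axis=1, keepdims=True)
    return FactorPair(W=W, G=G, loss=_frobenius_loss(X, W, G))


def _update(XtX: np.ndarray, W: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    XtXW = XtX @ W
    G = G * XtXW / (G @ (W.T @ XtXW) + EPS)
    XtXG = XtX @ G
    W = W * XtXG / (XtX @ W @ (G.T @ G) + EPS)
    return W, G


def multiplicative_step(X: np.ndarray, f: FactorPair) -> FactorPair:
    """One multiplicative update of G then W (loss nonincreasing)."""
    W, G = _update(X.T @ X, f.W.copy(), f.G.copy())
    if not (np.isfinite(W).all() and np.isfinite(G).all()):
        raise FloatingPointError("non-finite factor entries after multiplicative update")
    return FactorPair(W=W, G=G, loss=_frobenius_loss(X, W, G))


def _run_to_convergence(
    X: np.ndarray,
    f: FactorPair,
    max_iter: int = MAX_ITER,
    tol: float = CONVERGENCE_TOL,
    window: int = CONVERGENCE_WINDOW,
) -> FactorPair:
    XtX = X.T @ X
    W, G = f.W.copy(), f.G.copy()
    history = [_frobenius_loss(X, W, G)]
    for _ in range(max_iter):
        W, G = _update(XtX, W, G)
        loss = _frobenius_loss(X, W, G)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite loss during multiplicative updates")
        history.append(loss)
        if len(history) > window:
            ref = history[-window - 1]
            if ref <= 0 or (ref - loss) < tol * ref:
                break
    return FactorPair(W=W, G=G, loss=history[-1])


def _extract_split(
    X: np.ndarray, f: FactorPair, n: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    W, G = f.W, f.G
    Dw = W.sum(axis=0)
    Xout = (X @ W) / Dw
    Xin = G * Dw
    rowsums = Xin.sum(axis=1)
    degenerate = rowsums <= 0
    if np.any(degenerate):
        Xin[degenerate] = 1.0 / f.rank
        rowsums = Xin.sum(axis=1)
    Xin = Xin / rowsums[:, None]
    overlap = matrix_flow_overlap(X, Xout @ Xin.T, n)
    return Xin, Xout, overlap


def fit_factorization(
    X: np.ndarray,
    r: int,
    n_restarts: int = 10,
    seed: int = 0,
    n: np.ndarray | None = None,
    extra_inits: Sequence[FactorPair] = (),
    max_iter: int = MAX_ITER,
) -> StateSplit:
    """Best-of-restarts convex NMF at rank ``r``.

    Runs multiplicative updates from ``n_restarts`` smoothed k-means
    initializations with distinct sub-seeds, one hard (unsmoothed)
    k-means indicator start — which preserves its exact zeros under
    the updates and recovers duplicated-column structure exactly —
    plus any ``extra_inits`` (e.g. a padded lower-rank solution), and
    keeps the lowest-loss candidate.  ``n`` weights the columns in the
    reported flow overlap; uniform weights are used when it is omitted.
    """
    if r < 1:
        raise ValueError("rank must be at least 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be at least 1")
    if n is None:
        n = np.ones(X.shape[1])
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_restarts + 1)
    pool = [init_factors(X, r, int(s)) for s in sub_seeds[:-1]]
    pool.append(init_factors(X, r, int(sub_seeds[-1]), smoothing=0.0))
    best: FactorPair | None = None
    for f0 in pool + list(extra_inits):
        f = _run_to_convergence(X, f0, max_iter=max_iter)
        if best is None or f.loss < best.loss:
            best = f
    assert best is not None
    dead = best.W.sum(axis=0) <= EPS
    if np.any(dead):
        logger.warning(
            "dropping %d state node(s) with zero incoming weight; refitting at rank %d",
            int(dead.sum()), r - int(dead.sum()),
        )
        return fit_factorization(
            X, r - int(dead.sum()), n_restarts=n_restarts, seed=seed, n=n, max_iter=max_iter
        )
    Xin, Xout, overlap = _extract_split(X, best, n)
    return StateSplit(
        center=None, rank=r, Xin=Xin, Xout=Xout, overlap=overlap, loss=best.loss,
        factors=best,
    )


def _rank1_split(dyn: TargetDynamics) -> StateSplit:
    """Analytic single-state solution: the flow-weighted mean column.

    With one state node every predecessor maps to it, and the optimal
    out-distribution under flow weighting is ``sum_i (n_i / sum n) X[:, i]``,
    which reduces exactly to the first-order MLE ``M1`` at ``mu = 0``.
    """
    weights = dyn.n / dyn.n.sum()
    xout = (dyn.X @ weights)[:, None]
    xin = np.ones((dyn.X.shape[1], 1))
    overlap = matrix_flow_overlap(dyn.X, xout @ xin.T, dyn.n)
    loss = float(np.sum((dyn.X - xout) ** 2))
    return StateSplit(
        center=dyn.center,
        rank=1,
        Xin=xin,
        Xout=xout,
        overlap=overlap,
        loss=loss,
        predecessors=dyn.predecessors,
        successors=dyn.successors,
        factors=FactorPair(W=weights[:, None], G=xin.copy(), loss=loss),
    )


def split_node(
    dyn: TargetDynamics,
    r: int,
    n_restarts: int = 10,
    seed: int = 0,
    extra_inits: Sequence[FactorPair] = (),
) -> StateSplit:
    """Split a center node into ``r`` state nodes.

    ``r = 1`` uses the closed-form first-order solution; ``r >= 2``
    fits the convex factorization.
    """
    if r == 1:
        return _rank1_split(dyn)
    split = fit_factorization(
        dyn.X, r, n_restarts=n_restarts, seed=seed, n=dyn.n, extra_inits=extra_inits
    )
    return replace(
        split, center=dyn.center, predecessors=dyn.predecessors, successors=dyn.successors
    )


def _padded_init(X: np.ndarray, prev: StateSplit, r: int, seed: int, scale: float = 0.01):
    """Pad the previous rank's solution with one extra k-means column.

    Column-normalizing the converged ``W`` and taking ``G = Xin``
    reproduces the previous split's implied dynamics exactly (``D_W``
    becomes the identity), so the warm start begins at the previous
    rank's solution; the extra column is scaled down so it perturbs it
    only slightly.
    """
    assert prev.factors is not None
    fresh = init_factors(X, r, seed)
    W_prev = prev.factors.W / prev.factors.W.sum(axis=0, keepdims=True).clip(min=EPS)
    W = np.hstack([W_prev, scale * fresh.W[:, :1]])
    G = np.hstack([prev.Xin, scale * fresh.G[:, :1]])
    W = np.clip(W, EPS, None)
    G = np.clip(G, EPS, None)
    return FactorPair(W=W, G=G, loss=_frobenius_loss(X, W, G))


def rank_sweep(
    dyn: TargetDynamics,
    r_values: Sequence[int],
    n_restarts: int = 10,
    seed: int = 0,
):
    """Yield splits for increasing ranks, warm-starting consecutive ranks.

    For each rank after the first, the restart pool is augmented with
    the previous rank's solution padded by one extra k-means column,
    which stabilizes the sweep and keeps best-of-restarts overlap
    nondecreasing across consecutive ranks.
    """
    rng = np.random.default_rng(seed)
    prev: StateSplit | None = None
    prev_r: int | None = None
    for r in r_values:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        extra: list[FactorPair] = []
        if prev is not None and prev_r is not None and r == prev_r + 1 and r >= 2:
            extra.append(_padded_init(dyn.X, prev, r, sub_seed))
        split = split_node(dyn, r, n_restarts=n_restarts, seed=sub_seed, extra_inits=extra)
        yield split
        prev, prev_r = split, r


def select_rank(
    dyn: TargetDynamics,
    threshold: float,
    r_max: int,
    n_restarts: int = 10,
    seed: int = 0,
) -> StateSplit:
    """Smallest rank whose flow overlap reaches ``threshold``.

    Fits ``r = 1, 2, ...`` and returns the first split with overlap at
    least ``threshold``; if none reaches it by ``r_max`` the
    ``r_max`` split is returned with a warning.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if r_max > dyn.X.shape[1]:
        raise ValueError("r_max cannot exceed the number of predecessors")
    last: StateSplit | None = None
    for split in rank_sweep(dyn, range(1, r_max + 1), n_restarts=n_restarts, seed=seed):
        last = split
        if split.overlap >= threshold:
            return split
    assert last is not None
    logger.warning(
        "center %s: flow overlap %.3f below threshold %.3f at r_max=%d",
        dyn.center, last.overlap, threshold, r_max,
    )
    return last
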