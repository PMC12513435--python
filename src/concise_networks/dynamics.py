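"""Regularized second-order target dynamics.

The maximum-likelihood second-order transition matrix ``M2`` (column
``i`` is the out-distribution of trajectories arriving at the center
from predecessor ``i``) overfits undersampled predecessors.  We place a
Dirichlet prior with parameters ``M1`` (the memoryless first-order
out-distribution) and strength ``mu`` on each column; the posterior
mean

    X[k, i] = (A[k, i] + mu * M1[k]) / (n_i + mu)

interpolates between memory (``mu -> 0`` gives ``M2``) and the
memoryless model (``mu -> inf`` gives ``M1``), with the pull toward
``M1`` strongest for predecessors with few observations.  When no
domain knowledge informs ``mu`` we maximize the leave-one-out
cross-validated likelihood of the observed transitions, which has a
closed form.

Model quality is measured by *flow overlap*: the shared probability
mass ``sum_k min(p_k, q_k)`` between two distributions (equivalently
one minus their total-variation distance), extended to transition
matrices as the ``n_i``-weighted mean overlap of corresponding columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .corpus import TrigramCounts

logger = logging.getLogger(__name__)

__all__ = [
    "TargetDynamics",
    "mle_second_order",
    "mle_first_order",
    "posterior_dynamics",
    "loo_objective",
    "select_mu",
    "flow_overlap",
    "matrix_flow_overlap",
]

#: log-grid bounds for the mu search, as multiples of the mean per-predecessor count
MU_MIN_FACTOR = 1e-3
MU_MAX_FACTOR = 1e6
MU_GRID_SIZE = 200


@dataclass
class TargetDynamics:
    """Regularized second-order dynamics through one center node."""

    center: str
    predecessors: tuple[str, ...]
    successors: tuple[str, ...]
    M1: np.ndarray  # first-order out-distribution, length |k|
    M2: np.ndarray  # column-stochastic MLE, |k| x |i|
    X: np.ndarray  # column-stochastic posterior mean, |k| x |i|
    n: np.ndarray  # per-predecessor counts n_i, length |i|
    mu: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("prior strength mu must be nonnegative")
        if np.any(self.n <= 0):
            raise ValueError("every stored predecessor must have positive counts")
        for name, mat in (("M2", self.M2), ("X", self.X)):
            if not np.allclose(mat.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError(f"columns of {name} must sum to 1")
        if not np.isclose(self.M1.sum(), 1.0, atol=1e-9):
            raise ValueError("M1 must sum to 1")


def mle_second_order(counts: TrigramCounts) -> np.ndarray:
    """Column-normalize the count matrix A into transition rates."""
    colsums = counts.A.sum(axis=0)
    if np.any(colsums <= 0):
        raise ValueError("every predecessor column must have a positive sum")
    return counts.A / colsums


def mle_first_order(counts: TrigramCounts) -> np.ndarray:
    """Memoryless out-distribution: row sums of A over the total."""
    total = counts.A.sum()
    if total <= 0:
        raise ValueError("count matrix has zero total")
    return counts.A.sum(axis=1) / total


def posterior_dynamics(counts: TrigramCounts, mu: float | str = "auto") -> TargetDynamics:
    """Posterior-mean target dynamics under the Dirichlet(mu * M1) prior.

    ``mu`` may be a nonnegative scalar or ``"auto"`` to select it by
    leave-one-out cross-validation.
    """
    if isinstance(mu, str):
        if mu != "auto":
            raise ValueError(f"mu must be a scalar or 'auto', got {mu!r}")
        mu = select_mu(counts)
    if mu < 0:
        raise ValueError("prior strength mu must be nonnegative")
    M1 = mle_first_order(counts)
    M2 = mle_second_order(counts)
    n = counts.A.sum(axis=0)
    X = (counts.A + mu * M1[:, None]) / (n + mu)
    return TargetDynamics(
        center=counts.center,
        predecessors=counts.predecessors,
        successors=counts.successors,
        M1=M1,
        M2=M2,
        X=X,
        n=n,
        mu=float(mu),
    )


def _loo_terms(counts: TrigramCounts) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arrays (a, m1, ni) over the nonzero entries of A."""
    A = counts.A
    M1 = mle_first_order(counts)
    n = A.sum(axis=0)
    rows, cols = np.nonzero(A)
    return A[rows, cols], M1[rows], n[cols]


def loo_objective(counts: TrigramCounts, mu: float) -> float:
    """Leave-one-out log-likelihood of all observed transitions.

    Each observed trigram is scored by the posterior predictive of a
    model trained on all other transitions:

        sum_{k,i: A_ki > 0} A_ki * log( (A_ki - 1 + mu*M1_k) / (n_i - 1 + mu) )
    """
    a, m1, ni = _loo_terms(counts)
    num = a - 1.0 + mu * m1
    den = ni - 1.0 + mu
    if np.any(num <= 0) or np.any(den <= 0):
        raise ValueError(
            "nonpositive leave-one-out likelihood argument; mu must be positive "
            "when singleton counts are present"
        )
    return float(np.sum(a * (np.log(num) - np.log(den))))


def select_mu(
    counts: TrigramCounts,
    grid_size: int = MU_GRID_SIZE,
    min_factor: float = MU_MIN_FACTOR,
    max_factor: float = MU_MAX_FACTOR,
) -> float:
    """Maximize the leave-one-out objective over a log grid of mu.

    The grid spans ``[min_factor, max_factor]`` times the mean
    per-predecessor count and is followed by a bounded scalar
    maximization on the bracketing interval.  A maximum on the boundary
    is returned as the cap value with a warning: the lower cap signals
    a "no regularization" regime (strong memory), the upper cap a
    "memoryless" regime (identical predecessors).
    """
    a, m1, ni = _loo_terms(counts)
    nbar = float(counts.A.sum(axis=0).mean())
    lo, hi = min_factor * nbar, max_factor * nbar
    grid = np.geomspace(lo, hi, grid_size)

    def objective(mu: float) -> float:
        return float(np.sum(a * (np.log(a - 1.0 + mu * m1) - np.log(ni - 1.0 + mu))))

    values = np.array([objective(mu) for mu in grid])
    best = int(np.argmax(values))
    if best == 0:
        logger.warning(
            "center %s: LOO objective maximized at the lower mu cap %.3g "
            "(no-regularization regime)", counts.center, lo,
        )
        return float(lo)
    if best == grid_size - 1:
        logger.warning(
            "center %s: LOO objective maximized at the upper mu cap %.3g "
            "(memoryless regime)", counts.center, hi,
        )
        return float(hi)
    res = minimize_scalar(
        lambda t: -objective(float(np.exp(t))),
        bounds=(np.log(grid[best - 1]), np.log(grid[best + 1])),
        method="bounded",
        options={"xatol": 1e-10},
    )
    mu_star = float(np.exp(res.x))
    # keep the grid maximizer if the refinement did not improve on it
    if objective(mu_star) < values[best]:
        mu_star = float(grid[best])
    return mu_star


def flow_overlap(p: np.ndarray, q: np.ndarray) -> float:
    """Shared probability mass between two distributions: sum_i min(p_i, q_i)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    for name, vec in (("p", p), ("q", q)):
        if not np.isclose(vec.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} must sum to 1 (got {vec.sum():.8f})")
    return float(np.minimum(p, q).sum())


def matrix_flow_overlap(X: np.ndarray, Xhat: np.ndarray, n: np.ndarray) -> float:
    """Flow-weighted mean column overlap between two transition matrices.

    Columns are weighted by the per-predecessor counts ``n``, so the
    result is the fraction of total flow through the node that the
    approximation captures.
    """
    X = np.asarray(X, dtype=float)
    Xhat = np.asarray(Xhat, dtype=float)
    n = np.asarray(n, dtype=float)
    if X.shape != Xhat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xhat.shape}")
    if n.shape != (X.shape[1],):
        raise ValueError("n must have one entry per column")
    if np.any(n < 0) or n.sum() <= 0:
        raise ValueError("n must be nonnegative with positive sum")
    return float(np.sum(n * np.minimum(X, Xhat).sum(axis=0)) / n.sum())
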