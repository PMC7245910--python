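"""Choosing the design-row permutation to hit a target correlation.

The permutable design block's rows are reordered so that its columns have
(approximately) a requested Pearson correlation with latent factors
estimated from the count matrix.  The pipeline is:

1. estimate surrogate factors by truncated SVD of the row-centered
   ``log2(Y + 0.5)`` matrix (:func:`estimate_surrogates`);
2. shrink the requested correlation matrix until the implied joint normal
   covariance is positive semi-definite (:func:`repair_target_correlation`);
3. draw a latent target ``U`` from the conditional normal given the
   surrogates (:func:`draw_latent_target`);
4. permute the design rows to sit as close to ``U`` as possible
   (:func:`match_rows`).

:func:`estimate_realized_correlation` Monte-Carlo-estimates the correlation
the pipeline actually achieves for a given (design, target) pair, which for
non-normal designs can differ from the request.
"""

from __future__ import annotations

import warnings
from typing import Union

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .types import (
    CountMatrix,
    Permutation,
    SurrogateMatrix,
    TargetCorrelation,
)

__all__ = [
    "estimate_surrogates",
    "surrogate_correlation",
    "repair_target_correlation",
    "draw_latent_target",
    "match_rows",
    "estimate_realized_correlation",
]

SeedLike = Union[int, None, np.random.SeedSequence]

#: feasibility slack on the smallest eigenvalue of the Schur complement
SCHUR_TOL = -1e-8
#: geometric shrink factor applied per repair iteration
SHRINK_FACTOR = 0.95
MAX_SHRINK_ITER = 500


def estimate_surrogates(y: CountMatrix, k: int) -> SurrogateMatrix:
    """Estimate ``k`` latent factors by truncated SVD.

    Takes the top-``k`` right singular vectors of the row-centered
    ``log2(Y + 0.5)`` matrix.  Each column is sign-fixed (largest-magnitude
    entry positive) and standardized to mean 0, unit variance.
    """
    g, n = y.shape
    if not 1 <= k < min(g, n):
        raise ValueError(f"k must satisfy 1 <= k < min(G, N) = {min(g, n)}")
    logs = np.log2(y.values + 0.5)
    centered = logs - logs.mean(axis=1, keepdims=True)
    if not np.any(np.abs(centered) > 1e-12):
        raise ValueError(
            "count matrix has no within-gene variation; cannot estimate "
            "surrogate factors"
        )
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[k - 1] <= 1e-12 * svals[0]:
        raise ValueError(
            f"matrix rank is below k={k}; reduce the number of surrogates"
        )
    z = vt[:k].T.copy()
    for j in range(k):
        if z[np.argmax(np.abs(z[:, j])), j] < 0:
            z[:, j] = -z[:, j]
    col_mean = z.mean(axis=0)
    col_sd = z.std(axis=0, ddof=1)
    z = (z - col_mean) / col_sd
    return SurrogateMatrix(z=z, column_mean=col_mean, column_sd=col_sd)


def surrogate_correlation(z: SurrogateMatrix) -> np.ndarray:
    """Sample correlation matrix of the surrogate columns (K x K)."""
    if z.n_factors == 1:
        return np.ones((1, 1))
    return np.atleast_2d(np.corrcoef(z.z, rowvar=False))


def _corr_inverse(s: np.ndarray) -> np.ndarray:
    """Inverse of a correlation matrix, ridge-regularized if singular."""
    s = np.atleast_2d(np.asarray(s, dtype=float))
    if s.shape[0] != s.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    try:
        cond = np.linalg.cond(s)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "surrogate correlation matrix is singular; using a "
            "ridge-regularized inverse",
            RuntimeWarning,
            stacklevel=3,
        )
        s = s + 1e-8 * np.eye(s.shape[0])
    return np.linalg.inv(s)


def _schur_min_eig(r: np.ndarray, s_inv: np.ndarray) -> float:
    p3 = r.shape[0]
    schur = np.eye(p3) - r @ s_inv @ r.T
    return float(np.linalg.eigvalsh(schur).min())


def repair_target_correlation(
    r: TargetCorrelation, z_cor: np.ndarray
) -> TargetCorrelation:
    """Shrink an infeasible target correlation until it is feasible.

    Multiplies the whole matrix by ``SHRINK_FACTOR`` until the Schur
    complement ``I - R S^-1 R^T`` of the implied joint covariance has
    smallest eigenvalue above ``SCHUR_TOL``.  A feasible input is returned
    unchanged.
    """
    s_inv = _corr_inverse(z_cor)
    if r.shape[1] != s_inv.shape[0]:
        raise ValueError(
            f"target has {r.shape[1]} factor columns but the surrogate "
            f"correlation is {s_inv.shape[0]} x {s_inv.shape[0]}"
        )
    if _schur_min_eig(r.r, s_inv) >= SCHUR_TOL:
        return r
    shrunk = r.r.copy()
    for _ in range(MAX_SHRINK_ITER):
        shrunk = shrunk * SHRINK_FACTOR
        if _schur_min_eig(shrunk, s_inv) >= SCHUR_TOL:
            return TargetCorrelation(shrunk)
    raise RuntimeError(
        "failed to reach a feasible target correlation after "
        f"{MAX_SHRINK_ITER} shrink iterations"
    )


def draw_latent_target(
    z: SurrogateMatrix, r: TargetCorrelation, seed: SeedLike = None
) -> np.ndarray:
    """Draw the latent matching target ``U`` (N x P3).

    Row ``n`` is drawn from ``Normal(R S^-1 z_n, I - R S^-1 R^T)`` with
    ``S`` the sample correlation of the surrogates, so that ``(u_n, z_n)``
    is jointly normal with unit marginal variances and cross-correlation
    ``R``.  Raises if ``r`` is infeasible — repair it first.
    """
    p3, k = r.shape
    if k != z.n_factors:
        raise ValueError(
            f"target has {k} factor columns, surrogates have {z.n_factors}"
        )
    s_inv = _corr_inverse(surrogate_correlation(z))
    cov = np.eye(p3) - r.r @ s_inv @ r.r.T
    min_eig = float(np.linalg.eigvalsh(cov).min())
    if min_eig < SCHUR_TOL:
        raise ValueError(
            "target correlation is infeasible for these surrogates "
            f"(min Schur eigenvalue {min_eig:.3g}); apply "
            "repair_target_correlation first"
        )
    eigval, eigvec = np.linalg.eigh(cov)
    scale = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    mean = z.z @ s_inv @ r.r.T
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    noise = rng.standard_normal((z.n_samples, p3))
    return mean + noise @ scale.T


def _match_greedy(cost: np.ndarray) -> np.ndarray:
    n = cost.shape[0]
    work = cost.copy()
    pi = np.full(n, -1, dtype=np.int64)
    for _ in range(n):
        # np.argmin returns the first (lexicographically smallest) minimizer,
        # which is the documented tie-break
        flat = np.argmin(work)
        i, j = divmod(int(flat), n)
        pi[i] = j
        work[i, :] = np.inf
        work[:, j] = np.inf
    return pi


def _match_gale_shapley(cost: np.ndarray) -> np.ndarray:
    """Stable matching with target rows proposing, preferences by distance."""
    n = cost.shape[0]
    # ranks[j, i] = how much design row j likes target row i (lower = better)
    pref = np.argsort(cost, axis=1, kind="stable")
    rank_for_design = np.argsort(cost.T, axis=1, kind="stable")
    ranks = np.empty((n, n), dtype=np.int64)
    for j in range(n):
        ranks[j, rank_for_design[j]] = np.arange(n)
    next_choice = np.zeros(n, dtype=np.int64)
    engaged_to = np.full(n, -1, dtype=np.int64)  # design j -> target i
    free = list(range(n - 1, -1, -1))
    while free:
        i = free.pop()
        j = int(pref[i, next_choice[i]])
        next_choice[i] += 1
        current = engaged_to[j]
        if current == -1:
            engaged_to[j] = i
        elif ranks[j, i] < ranks[j, current]:
            engaged_to[j] = i
            free.append(int(current))
        else:
            free.append(i)
    pi = np.empty(n, dtype=np.int64)
    pi[engaged_to] = np.arange(n)
    return pi


def match_rows(x3: np.ndarray, u: np.ndarray,
               method: str = "hungarian") -> Permutation:
    """Pair each row of the target ``u`` with a distinct row of ``x3``.

    Returns the permutation ``pi`` such that ``x3[pi[n]]`` is the design row
    assigned to target row ``n``.  ``hungarian`` minimizes the total squared
    Euclidean distance exactly; ``greedy`` repeatedly pairs the closest
    remaining (target, design) rows; ``gale_shapley`` computes a stable
    matching under distance-ranked preferences.
    """
    x3 = np.atleast_2d(np.asarray(x3, dtype=float))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if x3.ndim == 2 and x3.shape[0] == 1 and u.shape[0] != 1:
        x3 = x3.T
    if x3.shape != u.shape:
        raise ValueError(f"shape mismatch: x3 {x3.shape} vs u {u.shape}")
    cost = cdist(u, x3, metric="sqeuclidean")
    if method == "hungarian":
        row_ind, col_ind = linear_sum_assignment(cost)
        pi = np.empty(cost.shape[0], dtype=np.int64)
        pi[row_ind] = col_ind
    elif method == "greedy":
        pi = _match_greedy(cost)
    elif method == "gale_shapley":
        pi = _match_gale_shapley(cost)
    else:
        raise ValueError(
            f"unknown matching method {method!r}; choose from hungarian, "
            "greedy, gale_shapley"
        )
    return Permutation(pi)


def _column_cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlations between all column pairs of a and b."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    return (a.T @ b) / np.outer(na, nb)


def estimate_realized_correlation(
    x3: np.ndarray,
    z: SurrogateMatrix,
    r: TargetCorrelation,
    n_mc: int = 100,
    seed: SeedLike = None,
    match_method: str = "hungarian",
) -> np.ndarray:
    """Monte-Carlo estimate of the correlation the pipeline actually yields.

    Averages, over ``n_mc`` independent (latent-target draw, row matching)
    replications, the empirical Pearson correlations between the columns of
    the permuted design and the surrogate columns.  For designs far from
    normal this can differ substantially from the requested target.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    x3 = np.atleast_2d(np.asarray(x3, dtype=float))
    if x3.shape[0] == 1 and z.n_samples != 1:
        x3 = x3.T
    repaired = repair_target_correlation(r, surrogate_correlation(z))
    master = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = master.spawn(n_mc)
    total = np.zeros(r.shape)
    for child in children:
        u = draw_latent_target(z, repaired, seed=child)
        perm = match_rows(x3, u, method=match_method)
        total += _column_cross_correlation(perm.apply(x3), z.z)
    return total / n_mc
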