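"""Binomial thinning of count matrices.

The central object is the non-positive log2 thinning matrix ``Q``: entry
``(g, n)`` of the output is a Binomial(y_gn, 2**q_gn) draw.  Because a
binomial subsample of a Poisson (or negative binomial) count stays in the
family, thinning shifts the log2-mean of the data by exactly ``Q`` while
keeping every other source of variation in the source matrix intact.

``Q`` is built from two signal blocks: a fixed block ``(X2, B2)`` and a
permutable block ``(X3, B3)`` whose design rows are reordered by a
permutation before use.  The row-wise maximum is subtracted from each row so
probabilities stay in (0, 1] while discarding as few counts as possible.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Callable, Optional, Union

import numpy as np

from .effects import EffectSpec, draw_coefficients, normal_sampler
from .targeting import (
    draw_latent_target,
    estimate_surrogates,
    match_rows,
    repair_target_correlation,
    surrogate_correlation,
)
from .types import (
    CountMatrix,
    DesignBlock,
    Permutation,
    TargetCorrelation,
    ThinLogMatrix,
    ThinningResult,
)

__all__ = [
    "build_thin_log",
    "binomial_thin",
    "thin_diff",
    "thin_2group",
    "thin_lib",
    "thin_gene",
    "thin_all",
]

_log = logging.getLogger("countthin")

SeedLike = Union[int, None, np.random.SeedSequence]


def _as_seedseq(seed: SeedLike) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _binomial_matrix(values: np.ndarray, prob: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    # Column-major draw order: all thinning entry points funnel through this
    # helper, so equal (Q, seed) pairs give bit-identical output regardless
    # of which public function produced them.
    out = rng.binomial(values.T, prob.T).T
    return np.ascontiguousarray(out, dtype=np.int64)


def build_thin_log(fixed: DesignBlock, permuted: DesignBlock,
                   perm: Permutation) -> ThinLogMatrix:
    """Assemble the log2 thinning matrix from the two signal blocks.

    Computes ``B2 @ X2.T + B3 @ (PiX3).T``, where ``PiX3`` is the permuted
    design (row ``n`` is ``X3[perm.pi[n]]``), then subtracts each row's
    maximum so that every entry is non-positive and each row attains zero.
    The subtracted offsets are returned as ``e`` (they shift the per-gene
    intercepts of the thinned data).
    """
    if fixed.n_genes != permuted.n_genes:
        raise ValueError(
            f"blocks disagree on G: {fixed.n_genes} vs {permuted.n_genes}"
        )
    if fixed.n_samples != permuted.n_samples:
        raise ValueError(
            f"blocks disagree on N: {fixed.n_samples} vs {permuted.n_samples}"
        )
    n = fixed.n_samples
    g = fixed.n_genes
    if len(perm) != n:
        raise ValueError(f"permutation length {len(perm)} != N = {n}")

    raw = np.zeros((g, n))
    if fixed.n_covariates:
        raw += fixed.coef @ fixed.design.T
    if permuted.n_covariates:
        raw += permuted.coef @ perm.apply(permuted.design).T
    e = raw.max(axis=1)
    q = raw - e[:, None]
    # guard against rounding pushing the row max above zero
    np.minimum(q, 0.0, out=q)
    return ThinLogMatrix(q=q, e=e)


def binomial_thin(y: CountMatrix, thin_log: ThinLogMatrix,
                  seed: SeedLike = None) -> CountMatrix:
    """Subsample each count ``y_gn`` as Binomial(y_gn, 2**q_gn)."""
    if thin_log.shape != y.shape:
        raise ValueError(
            f"thin_log shape {thin_log.shape} != counts shape {y.shape}"
        )
    rng = np.random.default_rng(_as_seedseq(seed))
    thinned = _binomial_matrix(y.values, thin_log.probabilities, rng)
    return y.with_values(thinned)


def _resolve_blocks(y: CountMatrix, fixed: Optional[DesignBlock],
                    permuted: Optional[DesignBlock]):
    g, n = y.shape
    if fixed is None:
        fixed = DesignBlock.empty(g, n)
    if permuted is None:
        permuted = DesignBlock.empty(g, n)
    for name, block in (("fixed", fixed), ("permuted", permuted)):
        if block.n_genes != g:
            raise ValueError(
                f"{name} block has {block.n_genes} gene rows, counts have {g}"
            )
        if block.n_samples != n:
            raise ValueError(
                f"{name} block has {block.n_samples} sample rows, "
                f"counts have {n}"
            )
    return fixed, permuted


def thin_diff(
    y: CountMatrix,
    fixed: Optional[DesignBlock] = None,
    permuted: Optional[DesignBlock] = None,
    *,
    target_cor: Optional[TargetCorrelation] = None,
    match_method: str = "hungarian",
    permutation: Optional[Permutation] = None,
    custom_q: Optional[np.ndarray] = None,
    seed: SeedLike = None,
) -> ThinningResult:
    """Thin a count matrix to inject an arbitrary log2-linear signal.

    Orchestrates the full pipeline: choose the permutation of the permutable
    design rows (uniformly at random, targeted at a desired correlation with
    latent factors via ``target_cor``, or fixed via ``permutation``), build
    the thinning matrix, and binomially subsample the counts.

    ``custom_q`` bypasses the design blocks entirely: the supplied
    non-positive G x N matrix is used as-is, which permits arbitrary
    (including non-linear) signals on the log2 scale.  In that case the
    result is identical to ``binomial_thin`` on that matrix with the same
    seed.

    Randomness is split deterministically from the master seed: one child
    stream chooses the permutation (or the latent-target draw), a second
    performs the binomial thinning.
    """
    g, n = y.shape
    if custom_q is not None:
        if fixed is not None or permuted is not None or target_cor is not None:
            raise ValueError("custom_q cannot be combined with design blocks")
        thin_log = ThinLogMatrix(q=np.asarray(custom_q, dtype=float))
        if thin_log.shape != (g, n):
            raise ValueError(
                f"custom_q shape {thin_log.shape} != counts shape {(g, n)}"
            )
        counts = binomial_thin(y, thin_log, seed=seed)
        empty_fixed, empty_perm = _resolve_blocks(y, None, None)
        return ThinningResult(
            counts=counts,
            thin_log=thin_log,
            permutation=Permutation.identity(n),
            design_fixed=empty_fixed.design,
            coef_fixed=empty_fixed.coef,
            design_perm_applied=empty_perm.design,
            coef_perm=empty_perm.coef,
            seed=seed,
        )

    fixed, permuted = _resolve_blocks(y, fixed, permuted)
    master = _as_seedseq(seed)
    perm_ss, thin_ss = master.spawn(2)

    if permutation is not None:
        if len(permutation) != n:
            raise ValueError("supplied permutation has wrong length")
        perm = permutation
    elif target_cor is not None and permuted.n_covariates > 0:
        if target_cor.shape[0] != permuted.n_covariates:
            raise ValueError(
                f"target correlation has {target_cor.shape[0]} rows but the "
                f"permutable block has {permuted.n_covariates} covariates"
            )
        k = target_cor.shape[1]
        z = estimate_surrogates(y, k)
        repaired = repair_target_correlation(target_cor, surrogate_correlation(z))
        if not np.array_equal(repaired.r, target_cor.r):
            _log.info("target correlation shrunk to satisfy feasibility")
        u = draw_latent_target(z, repaired, seed=perm_ss)
        perm = match_rows(permuted.design, u, method=match_method)
    else:
        rng = np.random.default_rng(perm_ss)
        perm = Permutation(rng.permutation(n))

    thin_log = build_thin_log(fixed, permuted, perm)
    counts = binomial_thin(y, thin_log, seed=thin_ss)
    discarded = 1.0 - counts.values.sum() / max(y.values.sum(), 1)
    _log.info(
        "thinned %d x %d counts; fraction of reads discarded: %.4f",
        g, n, discarded,
    )
    return ThinningResult(
        counts=counts,
        thin_log=thin_log,
        permutation=perm,
        design_fixed=fixed.design,
        coef_fixed=fixed.coef,
        design_perm_applied=perm.apply(permuted.design),
        coef_perm=permuted.coef,
        seed=seed,
    )


def thin_2group(
    y: CountMatrix,
    prop_null: float,
    coef_sampler: Optional[Callable] = None,
    group_prop: float = 0.5,
    alpha: float = 0.0,
    seed: SeedLike = None,
) -> ThinningResult:
    """Two-group differential-expression benchmark generator.

    Builds a single binary indicator with exactly ``floor(group_prop * N)``
    samples in group 1 (chosen by permutation), draws per-gene log2
    fold-changes for ``ceil((1 - prop_null) * G)`` randomly chosen non-null
    genes as ``s_g**alpha`` times a sampler draw (``s_g`` the per-gene
    standard deviation of ``log2(Y + 0.5)``), and delegates to
    :func:`thin_diff` with a uniformly random permutation.

    ``alpha = 0`` means the sampler specifies the effects directly;
    ``alpha = 1`` scales effects with each gene's log-count spread.
    """
    if not 0.0 <= prop_null <= 1.0:
        raise ValueError(f"prop_null must be in [0, 1], got {prop_null}")
    if not 0.0 < group_prop < 1.0:
        raise ValueError(f"group_prop must be in (0, 1), got {group_prop}")
    if coef_sampler is None:
        coef_sampler = normal_sampler(0.0, 0.8)

    g, n = y.shape
    master = _as_seedseq(seed)
    coef_ss, group_ss, diff_ss = master.spawn(3)

    spec = EffectSpec(sampler=coef_sampler, alpha=alpha, prop_null=prop_null)
    coef, _null_mask = draw_coefficients(spec, y, p=1, seed=coef_ss)

    n_group1 = math.floor(group_prop * n)
    rng = np.random.default_rng(group_ss)
    x = np.zeros((n, 1))
    x[rng.permutation(n)[:n_group1], 0] = 1.0

    return thin_diff(
        y,
        permuted=DesignBlock(design=x, coef=coef),
        seed=diff_ss,
    )


def _thin_uniform(y: CountMatrix, q: np.ndarray, seed: SeedLike) -> CountMatrix:
    thin_log = ThinLogMatrix(q=q)
    return binomial_thin(y, thin_log, seed=seed)


def thin_lib(y: CountMatrix, log2_factors: np.ndarray,
             seed: SeedLike = None) -> CountMatrix:
    """Thin each sample (column) uniformly across genes.

    ``log2_factors`` is an N-vector of non-positive log2 library scale
    factors; column ``n`` keeps each read with probability
    ``2**log2_factors[n]``, emulating heterogeneous sequencing depth.
    """
    factors = np.asarray(log2_factors, dtype=float)
    if factors.shape != (y.n_samples,):
        raise ValueError(
            f"expected {y.n_samples} factors, got shape {factors.shape}"
        )
    q = np.broadcast_to(factors, y.shape).copy()
    return _thin_uniform(y, q, seed)


def thin_gene(y: CountMatrix, log2_factors: np.ndarray,
              seed: SeedLike = None) -> CountMatrix:
    """Row-wise analogue of :func:`thin_lib`: thin each gene uniformly."""
    factors = np.asarray(log2_factors, dtype=float)
    if factors.shape != (y.n_genes,):
        raise ValueError(
            f"expected {y.n_genes} factors, got shape {factors.shape}"
        )
    q = np.broadcast_to(factors[:, None], y.shape).copy()
    return _thin_uniform(y, q, seed)


def thin_all(y: CountMatrix, log2_factor: float,
             seed: SeedLike = None) -> CountMatrix:
    """Uniformly reduce the sequencing depth of the whole matrix.

    Equivalent to :func:`thin_lib` with a constant factor vector (and the
    same seed yields the same counts).
    """
    factor = float(log2_factor)
    if not np.isfinite(factor):
        raise ValueError("log2_factor must be finite")
    return thin_lib(y, np.full(y.n_samples, factor), seed=seed)
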