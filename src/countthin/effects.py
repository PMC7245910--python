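"""Effect-size generation and signal-strength summaries.

Coefficients are log2 fold-changes.  A caller-supplied sampler provides the
raw effect distribution; effects can additionally be scaled by each gene's
log-count standard deviation raised to a power ``alpha`` (``alpha = 0``:
effects specified directly; ``alpha = 1``: effects scale with the gene's
spread, the classic p-value-prior convention).

The proportion of variance explained (PVE) summary measures, per gene, how
much of the variance of the thinned log2 counts the injected signal
accounts for.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .types import CountMatrix

__all__ = [
    "EffectSpec",
    "normal_sampler",
    "point_mass_sampler",
    "draw_coefficients",
    "signal_variance",
    "compute_pve",
    "median_pve",
]

_log = logging.getLogger("countthin")

SeedLike = Union[int, None, np.random.SeedSequence]


@dataclass(frozen=True)
class EffectSpec:
    """How to draw per-gene log2 effects.

    ``sampler(rng, size)`` must return an array of the requested shape.
    """

    sampler: Callable
    alpha: float = 0.0
    prop_null: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.prop_null <= 1.0):
            raise ValueError(
                f"prop_null must be in [0, 1], got {self.prop_null}"
            )
        if not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite")


def normal_sampler(mean: float = 0.0, sd: float = 0.8) -> Callable:
    """Gaussian effect sampler (the usual benchmark choice)."""
    def sample(rng: np.random.Generator, size):
        return rng.normal(mean, sd, size=size)
    return sample


def point_mass_sampler(value: float) -> Callable:
    """Degenerate sampler: every effect equals ``value``."""
    def sample(rng: np.random.Generator, size):
        return np.full(size, float(value))
    return sample


def row_log2_sd(y: CountMatrix) -> np.ndarray:
    """Per-gene sample standard deviation of ``log2(Y + 0.5)`` (ddof=1)."""
    return np.log2(y.values + 0.5).std(axis=1, ddof=1)


def draw_coefficients(
    spec: EffectSpec, y: CountMatrix, p: int = 1, seed: SeedLike = None
) -> tuple:
    """Draw a G x p coefficient matrix and its null mask.

    Exactly ``ceil((1 - prop_null) * G)`` genes are selected uniformly at
    random as non-null; each of their coefficients is
    ``s_g**alpha * draw``, where ``s_g`` is the gene's sample standard
    deviation of ``log2(Y + 0.5)``.  Null genes get zero in every column.

    Genes with ``s_g == 0`` (constant rows) are forced null when
    ``alpha != 0`` to avoid ``0**alpha`` artifacts; a warning is logged.

    Returns ``(coef, null_mask)`` where ``null_mask[g]`` is True for null
    genes.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    g = y.n_genes
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    n_signal = math.ceil((1.0 - spec.prop_null) * g)
    null_mask = np.ones(g, dtype=bool)
    if n_signal > 0:
        signal_idx = rng.choice(g, size=n_signal, replace=False)
        null_mask[signal_idx] = False

    if spec.alpha != 0.0:
        s = row_log2_sd(y)
        # exact constancy check on the raw counts; the log-scale sd of a
        # constant row can be a nonzero rounding artifact
        constant = np.all(y.values == y.values[:, :1], axis=1)
        s[constant] = 0.0
        forced = (~null_mask) & constant
        if forced.any():
            _log.warning(
                "%d constant gene(s) forced null: s_g = 0 with alpha != 0",
                int(forced.sum()),
            )
            null_mask[forced] = True
        scale = np.where(null_mask, 0.0, s) ** spec.alpha
        scale[null_mask] = 0.0
    else:
        scale = (~null_mask).astype(float)

    coef = np.zeros((g, p))
    active = ~null_mask
    if active.any():
        draws = np.asarray(spec.sampler(rng, (int(active.sum()), p)), dtype=float)
        if draws.shape != (int(active.sum()), p):
            raise ValueError(
                f"sampler returned shape {draws.shape}, expected "
                f"{(int(active.sum()), p)}"
            )
        if not np.all(np.isfinite(draws)):
            raise ValueError("sampler returned non-finite effect values")
        coef[active] = scale[active, None] * draws
    return coef, null_mask


def signal_variance(x: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-gene empirical variance of the injected signal ``x * b_g``.

    Equals ``b**2 * var(x)`` with the n-1 denominator.  This is the PVE
    numerator, exposed separately because it is exact arithmetic (no
    randomness) and scales as ``b**2``.
    """
    x = np.asarray(x, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return b**2 * x.var(ddof=1)


def compute_pve(y_thinned: CountMatrix, x: np.ndarray,
                b: np.ndarray) -> np.ndarray:
    """Per-gene proportion of variance explained by the injected signal.

    ``V(x * b_g) / V(log2(y_g + 0.5))`` with empirical (n-1) variances,
    where ``x`` is the realized (already permuted) design column.  Null
    genes (``b_g == 0``) get PVE 0 by convention.  A constant thinned row
    with a non-null coefficient yields NaN (undefined), not an error.
    """
    x = np.asarray(x, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if x.shape[0] != y_thinned.n_samples:
        raise ValueError(
            f"x has {x.shape[0]} entries, counts have {y_thinned.n_samples} "
            "samples"
        )
    if b.shape[0] != y_thinned.n_genes:
        raise ValueError(
            f"b has {b.shape[0]} entries, counts have {y_thinned.n_genes} "
            "genes"
        )
    num = signal_variance(x, b)
    denom = np.log2(y_thinned.values + 0.5).var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pve = num / denom
    pve[b == 0.0] = 0.0
    pve[(b != 0.0) & (denom == 0.0)] = np.nan
    return pve


def median_pve(pve: np.ndarray, null_mask: np.ndarray) -> float:
    """Median PVE over non-null genes, ignoring undefined (NaN) entries.

    Returns NaN when every gene is null or every non-null PVE is undefined.
    """
    pve = np.asarray(pve, dtype=float).ravel()
    null_mask = np.asarray(null_mask, dtype=bool).ravel()
    if pve.shape != null_mask.shape:
        raise ValueError("pve and null_mask must have the same length")
    vals = pve[~null_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(np.median(vals))
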