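"""Core value types shared across the package.

All matrices follow the genes-by-samples convention: a count matrix has one
row per gene and one column per sample.  Design matrices are
samples-by-covariates and coefficient matrices are genes-by-covariates, both
on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CountMatrix",
    "DesignBlock",
    "ThinLogMatrix",
    "Permutation",
    "TargetCorrelation",
    "SurrogateMatrix",
    "ThinningResult",
]


def _as_2d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class CountMatrix:
    """A genes x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    values
        Integer array of shape ``(G, N)``.  Floats are accepted if every
        entry is integral.
    gene_ids
        ``G`` unique row labels.  Generated as ``gene_0001, ...`` if omitted.
    sample_ids
        ``N`` unique column labels.  Generated as ``sample_001, ...`` if
        omitted.
    """

    values: np.ndarray
    gene_ids: tuple = field(default=None)
    sample_ids: tuple = field(default=None)

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"counts must be 2-D, got ndim={arr.ndim}")
        g, n = arr.shape
        if g < 1 or n < 2:
            raise ValueError(f"need G >= 1 and N >= 2, got G={g}, N={n}")

        gene_ids = self.gene_ids
        sample_ids = self.sample_ids
        if gene_ids is None:
            width = len(str(g))
            gene_ids = tuple(f"gene_{i + 1:0{max(width, 4)}d}" for i in range(g))
        else:
            gene_ids = tuple(str(x) for x in gene_ids)
        if sample_ids is None:
            width = len(str(n))
            sample_ids = tuple(f"sample_{j + 1:0{max(width, 3)}d}" for j in range(n))
        else:
            sample_ids = tuple(str(x) for x in sample_ids)
        if len(gene_ids) != g:
            raise ValueError(f"{len(gene_ids)} gene ids for {g} rows")
        if len(sample_ids) != n:
            raise ValueError(f"{len(sample_ids)} sample ids for {n} columns")
        if len(set(gene_ids)) != g:
            raise ValueError("gene ids are not unique")
        if len(set(sample_ids)) != n:
            raise ValueError("sample ids are not unique")

        if not np.issubdtype(arr.dtype, np.integer):
            farr = np.asarray(arr, dtype=float)
            bad = ~np.isfinite(farr) | (farr != np.floor(farr))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    "non-integer count at gene "
                    f"'{gene_ids[i]}', sample '{sample_ids[j]}': {arr[i, j]!r}"
                )
            arr = farr.astype(np.int64)
        neg = arr < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(
                "negative count at gene "
                f"'{gene_ids[i]}', sample '{sample_ids[j]}': {arr[i, j]}"
            )
        arr = np.ascontiguousarray(arr, dtype=np.int64)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "CountMatrix":
        """New matrix with the same labels and different counts."""
        return CountMatrix(values, self.gene_ids, self.sample_ids)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class DesignBlock:
    """A (design, coefficient) pair on the log2 scale.

    ``design`` is samples x covariates (N x P); ``coef`` is genes x
    covariates (G x P).  ``P`` may be zero, representing an absent block.
    """

    design: np.ndarray
    coef: np.ndarray

    def __post_init__(self):
        design = _as_2d_float(self.design, "design")
        coef = _as_2d_float(self.coef, "coef")
        if design.shape[1] != coef.shape[1]:
            raise ValueError(
                f"design has {design.shape[1]} columns but coef has "
                f"{coef.shape[1]}"
            )
        design.setflags(write=False)
        coef.setflags(write=False)
        object.__setattr__(self, "design", design)
        object.__setattr__(self, "coef", coef)

    @classmethod
    def empty(cls, n_genes: int, n_samples: int) -> "DesignBlock":
        """A zero-covariate block contributing nothing to the signal."""
        return cls(np.zeros((n_samples, 0)), np.zeros((n_genes, 0)))

    @property
    def n_covariates(self) -> int:
        return self.design.shape[1]

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def n_genes(self) -> int:
        return self.coef.shape[0]


@dataclass(frozen=True)
class ThinLogMatrix:
    """Log2 thinning factors: entrywise binomial probability is ``2**q``.

    ``q`` must be non-positive and finite; ``e`` records the per-row offset
    that was subtracted to enforce this (zero for user-supplied matrices).
    """

    q: np.ndarray
    e: np.ndarray = None

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 2:
            raise ValueError("q must be 2-D")
        if np.isnan(q).any():
            raise ValueError("q contains NaN")
        if np.isneginf(q).any():
            raise ValueError(
                "q contains -inf; use a large negative value to approximate "
                "zero thinning probability"
            )
        if (q > 0).any():
            i, j = np.argwhere(q > 0)[0]
            raise ValueError(
                f"q must be non-positive; q[{i}, {j}] = {q[i, j]} implies a "
                "binomial probability > 1"
            )
        e = self.e
        e = np.zeros(q.shape[0]) if e is None else np.asarray(e, dtype=float)
        if e.shape != (q.shape[0],):
            raise ValueError(f"e must have shape ({q.shape[0]},)")
        if not np.all(np.isfinite(e)):
            raise ValueError("e contains non-finite entries")
        q = np.ascontiguousarray(q)
        q.setflags(write=False)
        e = np.ascontiguousarray(e)
        e.setflags(write=False)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "e", e)

    @property
    def shape(self) -> tuple:
        return self.q.shape

    @property
    def probabilities(self) -> np.ndarray:
        return np.exp2(self.q)


@dataclass(frozen=True)
class Permutation:
    """A bijection of ``{0..N-1}``.

    Convention: applying the permutation to a design ``X`` yields the matrix
    whose row ``n`` is ``X[pi[n]]``.
    """

    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=np.int64)
        if pi.ndim != 1:
            raise ValueError("pi must be a vector")
        n = pi.shape[0]
        if not np.array_equal(np.sort(pi), np.arange(n)):
            raise ValueError("pi is not a permutation of 0..N-1")
        pi = np.ascontiguousarray(pi)
        pi.setflags(write=False)
        object.__setattr__(self, "pi", pi)

    @classmethod
    def identity(cls, n: int) -> "Permutation":
        return cls(np.arange(n))

    def __len__(self) -> int:
        return self.pi.shape[0]

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Reorder the rows of ``x``: output row n is ``x[pi[n]]``."""
        return np.asarray(x)[self.pi]


@dataclass(frozen=True)
class TargetCorrelation:
    """Desired Pearson correlations between permuted design columns and
    latent factors: shape (P3, K), entries in [-1, 1]."""

    r: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2:
            raise ValueError("target correlation must be a 2-D matrix")
        if not np.all(np.isfinite(r)):
            raise ValueError("target correlation contains non-finite entries")
        if (np.abs(r) > 1).any():
            raise ValueError("target correlations must lie in [-1, 1]")
        r = np.ascontiguousarray(r)
        r.setflags(write=False)
        object.__setattr__(self, "r", r)

    @property
    def shape(self) -> tuple:
        return self.r.shape


@dataclass(frozen=True)
class SurrogateMatrix:
    """Estimated latent factors, one column per factor, standardized to
    mean 0 / unit variance.  ``column_mean`` and ``column_sd`` record the
    pre-standardization moments."""

    z: np.ndarray
    column_mean: np.ndarray
    column_sd: np.ndarray

    def __post_init__(self):
        z = _as_2d_float(self.z, "z")
        if z.shape[1] < 1:
            raise ValueError("need at least one surrogate column")
        cm = np.asarray(self.column_mean, dtype=float)
        cs = np.asarray(self.column_sd, dtype=float)
        if cm.shape != (z.shape[1],) or cs.shape != (z.shape[1],):
            raise ValueError("column moments must have one entry per factor")
        z.setflags(write=False)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "column_mean", cm)
        object.__setattr__(self, "column_sd", cs)

    @property
    def n_samples(self) -> int:
        return self.z.shape[0]

    @property
    def n_factors(self) -> int:
        return self.z.shape[1]


@dataclass(frozen=True)
class ThinningResult:
    """Everything produced by a thinning run: the thinned counts plus the
    provenance needed to reproduce or analyze them."""

    counts: CountMatrix
    thin_log: ThinLogMatrix
    permutation: Permutation
    design_fixed: np.ndarray
    coef_fixed: np.ndarray
    design_perm_applied: np.ndarray
    coef_perm: np.ndarray
    seed: object = None

    def __post_init__(self):
        g, n = self.counts.shape
        if self.thin_log.shape != (g, n):
            raise ValueError("thin_log shape does not match counts")
        if len(self.permutation) != n:
            raise ValueError("permutation length does not match sample count")
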