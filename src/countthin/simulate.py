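"""Synthetic base count matrices.

Generates genes x samples count matrices whose log2-mean decomposes as an
intercept plus an optional low-rank factor term plus unstructured noise:

    theta = mu 1' + A Z' + Omega,      counts ~ family(mean = 2**theta)

with Poisson, negative binomial (mean/size parameterization, variance
``mu + mu**2 / size``) or zero-inflated negative binomial observation
families.  The true ``theta`` is returned alongside the counts so recovery
can be asserted in tests.  The noise term defaults to i.i.d. Gaussian but a
fully custom matrix may be supplied.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .types import CountMatrix, DesignBlock

__all__ = ["BaseModelSpec", "simulate_base_counts", "make_fixture"]

_log = logging.getLogger("countthin")

SeedLike = Union[int, None, np.random.SeedSequence]

#: log2-mean cap; 2**30 ~ 1e9 reads per cell is already implausibly deep
THETA_CAP = 30.0

FAMILIES = ("poisson", "nb", "zinb")


@dataclass(frozen=True)
class BaseModelSpec:
    """Parameters of the synthetic base model.

    ``mu`` is the G-vector of log2 intercepts (a scalar is broadcast).
    ``factor_loadings`` (G x K) and ``factor_scores`` (N x K) give the
    low-rank term; both or neither must be provided.  ``omega_sd`` scales
    i.i.d. Gaussian log2 noise; alternatively pass an explicit G x N
    ``omega`` matrix.  ``nb_dispersion`` is the negative binomial size
    parameter (scalar or per-gene); ``zero_inflation`` the structural-zero
    probability for the zinb family.
    """

    n_genes: int
    n_samples: int
    mu: Union[float, np.ndarray] = 5.0
    factor_loadings: Optional[np.ndarray] = None
    factor_scores: Optional[np.ndarray] = None
    omega_sd: float = 0.0
    omega: Optional[np.ndarray] = None
    family: str = "poisson"
    nb_dispersion: Union[float, np.ndarray] = 1.0
    zero_inflation: float = 0.0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValueError("need n_genes >= 1 and n_samples >= 2")
        if self.family not in FAMILIES:
            raise ValueError(
                f"family must be one of {FAMILIES}, got {self.family!r}"
            )
        if (self.factor_loadings is None) != (self.factor_scores is None):
            raise ValueError(
                "factor_loadings and factor_scores must be given together"
            )
        if self.factor_loadings is not None:
            a = np.asarray(self.factor_loadings, dtype=float)
            z = np.asarray(self.factor_scores, dtype=float)
            if a.ndim != 2 or z.ndim != 2 or a.shape[1] != z.shape[1]:
                raise ValueError("factor blocks must be G x K and N x K")
            if a.shape[0] != self.n_genes or z.shape[0] != self.n_samples:
                raise ValueError("factor block dimensions do not match G, N")
        if self.omega_sd < 0:
            raise ValueError("omega_sd must be >= 0")
        if np.any(np.asarray(self.nb_dispersion, dtype=float) <= 0):
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0, 1)")


def simulate_base_counts(
    spec: BaseModelSpec, seed: SeedLike = None
) -> tuple:
    """Draw a count matrix from the base model.

    Returns ``(counts, theta)`` where ``theta`` is the realized G x N
    log2-mean matrix (after noise, capped at ``THETA_CAP``).
    """
    g, n = spec.n_genes, spec.n_samples
    master = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    noise_ss, count_ss = master.spawn(2)

    mu = np.broadcast_to(np.asarray(spec.mu, dtype=float), (g,))
    theta = np.tile(mu[:, None], (1, n))
    if spec.factor_loadings is not None:
        a = np.asarray(spec.factor_loadings, dtype=float)
        z = np.asarray(spec.factor_scores, dtype=float)
        theta = theta + a @ z.T
    if spec.omega is not None:
        omega = np.asarray(spec.omega, dtype=float)
        if omega.shape != (g, n):
            raise ValueError(f"omega must have shape {(g, n)}")
        theta = theta + omega
    elif spec.omega_sd > 0:
        rng_noise = np.random.default_rng(noise_ss)
        theta = theta + rng_noise.normal(0.0, spec.omega_sd, size=(g, n))

    if np.any(theta > THETA_CAP):
        warnings.warn(
            f"capping {int((theta > THETA_CAP).sum())} log2-mean entries at "
            f"{THETA_CAP}",
            RuntimeWarning,
            stacklevel=2,
        )
        theta = np.minimum(theta, THETA_CAP)

    mean = np.exp2(theta)
    rng = np.random.default_rng(count_ss)
    if spec.family == "poisson":
        counts = rng.poisson(mean)
    else:
        size = np.broadcast_to(
            np.asarray(spec.nb_dispersion, dtype=float), (g,)
        )[:, None]
        prob = size / (size + mean)
        counts = rng.negative_binomial(size, prob)
        if spec.family == "zinb":
            keep = rng.random((g, n)) >= spec.zero_inflation
            counts = counts * keep
    return CountMatrix(counts.astype(np.int64)), theta


def _write_tsv_matrix(path: Path, arr: np.ndarray, row_ids, col_ids,
                      index_label: str) -> None:
    import pandas as pd

    pd.DataFrame(arr, index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", index_label=index_label
    )


def make_fixture(name: str, seed: SeedLike = None,
                 out_dir: Union[str, Path, None] = None) -> dict:
    """Build a small self-contained test dataset.

    ``two_group_small``: 500 x 20 Poisson counts plus a balanced binary
    design column.  ``factor_rank1``: counts with a known rank-1 factor
    term (loadings and scores written out for recovery tests).
    ``null_only``: 100 x 10 Poisson counts with an all-zero design.

    Returns a dict of in-memory objects; when ``out_dir`` is given the
    bundle is also written as TSV files plus a ``meta.json`` and the dict
    gains a ``"paths"`` entry.
    """
    master = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    mu_ss, base_ss, design_ss = master.spawn(3)
    rng = np.random.default_rng(mu_ss)

    if name == "two_group_small":
        g, n = 500, 20
        spec = BaseModelSpec(
            n_genes=g, n_samples=n,
            mu=np.log2(rng.uniform(20.0, 400.0, size=g)),
            omega_sd=0.4, family="poisson",
        )
        counts, theta = simulate_base_counts(spec, seed=base_ss)
        x = np.zeros((n, 1))
        drng = np.random.default_rng(design_ss)
        x[drng.permutation(n)[: n // 2], 0] = 1.0
        bundle = {"counts": counts, "theta": theta, "design": x}
    elif name == "factor_rank1":
        g, n = 200, 40
        drng = np.random.default_rng(design_ss)
        loadings = drng.normal(0.0, 0.7, size=(g, 1))
        scores = drng.normal(0.0, 1.0, size=(n, 1))
        spec = BaseModelSpec(
            n_genes=g, n_samples=n,
            mu=np.log2(rng.uniform(50.0, 500.0, size=g)),
            factor_loadings=loadings, factor_scores=scores,
            omega_sd=0.2, family="poisson",
        )
        counts, theta = simulate_base_counts(spec, seed=base_ss)
        bundle = {
            "counts": counts, "theta": theta,
            "loadings": loadings, "scores": scores,
        }
    elif name == "null_only":
        g, n = 100, 10
        spec = BaseModelSpec(
            n_genes=g, n_samples=n,
            mu=np.log2(rng.uniform(20.0, 200.0, size=g)),
            family="poisson",
        )
        counts, theta = simulate_base_counts(spec, seed=base_ss)
        bundle = {
            "counts": counts, "theta": theta,
            "design": np.zeros((n, 1)),
        }
    else:
        raise ValueError(
            f"unknown fixture {name!r}; choose from two_group_small, "
            "factor_rank1, null_only"
        )

    if out_dir is not None:
        from .io import write_counts

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"counts": out / "counts.tsv"}
        write_counts(bundle["counts"], paths["counts"])
        counts = bundle["counts"]
        for key in ("design", "loadings"):
            if key in bundle:
                paths[key] = out / f"{key}.tsv"
                _write_tsv_matrix(
                    paths[key], bundle[key],
                    counts.sample_ids if key == "design" else counts.gene_ids,
                    [f"{key[0]}{j + 1}" for j in range(bundle[key].shape[1])],
                    "sample" if key == "design" else "gene",
                )
        if "scores" in bundle:
            paths["scores"] = out / "scores.tsv"
            _write_tsv_matrix(
                paths["scores"], bundle["scores"], counts.sample_ids,
                [f"z{j + 1}" for j in range(bundle["scores"].shape[1])],
                "sample",
            )
        meta = {
            "fixture": name,
            "n_genes": counts.n_genes,
            "n_samples": counts.n_samples,
            "files": {k: str(v.name) for k, v in paths.items()},
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
        bundle["paths"] = {k: str(v) for k, v in paths.items()}
    return bundle
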