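import numpy as np
import pytest

from countthin import CountMatrix, SurrogateMatrix


def poisson_counts(n_genes, n_samples, seed, mean=100.0):
    rng = np.random.default_rng(seed)
    vals = rng.poisson(mean, size=(n_genes, n_samples))
    return CountMatrix(vals)


def standardized_surrogates(z_raw):
    """Wrap raw factor draws as a standardized SurrogateMatrix."""
    z_raw = np.atleast_2d(np.asarray(z_raw, dtype=float))
    if z_raw.shape[0] == 1:
        z_raw = z_raw.T
    mean = z_raw.mean(axis=0)
    sd = z_raw.std(axis=0, ddof=1)
    return SurrogateMatrix(z=(z_raw - mean) / sd, column_mean=mean,
                           column_sd=sd)


@pytest.fixture
def small_counts():
    return poisson_counts(30, 8, seed=1776, mean=50.0)


@pytest.fixture
def medium_counts():
    return poisson_counts(200, 40, seed=42, mean=120.0)
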