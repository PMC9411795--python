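"""Shared fixtures and independent oracles for the test suite."""

from math import comb

import numpy as np
import pytest

from fishmet.synthetic import GeneratorConfig


def _binomial_pmf(k: int, n: int, p: float) -> float:
    if k < 0 or k > n:
        return 0.0
    return comb(n, k) * p ** k * (1.0 - p) ** (n - k)


def natural_abundance_oracle(true_fractions, n, p):
    """Independent forward model: sum over species of binomial mass shifts.

    Written from the definition (each M+i species gains j extra mass units
    with probability Binomial(n-i, p) at j), without any matrix algebra, to
    cross-check the packaged correction matrix.
    """
    true_fractions = np.asarray(true_fractions, dtype=float)
    out = np.zeros(n + 1)
    for i in range(n + 1):
        for j in range(i, n + 1):
            out[j] += true_fractions[i] * _binomial_pmf(j - i, n - i, p)
    return out


def convolve_oracle(a, b):
    """Plain double-loop convolution of two distributions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.zeros(a.size + b.size - 1)
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            out[i + j] += ai * bj
    return out


@pytest.fixture
def nat_abundance_oracle():
    return natural_abundance_oracle


@pytest.fixture
def convolution_oracle():
    return convolve_oracle


@pytest.fixture
def default_config():
    return GeneratorConfig(seed=11)


@pytest.fixture
def noiseless_config():
    return GeneratorConfig(seed=11, noise_cv=0.0, feature_noise_cv=0.0)


@pytest.fixture
def small_config():
    """Reduced problem sizes for integration tests."""
    return GeneratorConfig(
        seed=7, grid_dims=(24, 48), n_endogenous_features=40,
        n_contaminant_features=10,
        perturbed_counts={"brain": 5, "eye": 5, "fin": 5, "heart": 6,
                          "intestine": 12, "kidney": 8, "liver": 3, "muscle": 10},
    )
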