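"""Shared fixtures and independent brute-force oracles.

The oracles materialize the full n x m* dummy matrix and solve dense linear
systems directly; they are deliberately naive and independent of the
package's blockwise / closed-form code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from serrblup import GenotypeMatrix, finalize_coding


def random_genotypes(rng: np.random.Generator, n: int, m: int) -> GenotypeMatrix:
    """Random finalized inbred genotypes, guaranteed >= 1 polymorphic marker."""
    while True:
        doses = 2 * (rng.random((n, m)) < rng.uniform(0.2, 0.8, m)).astype(np.int8)
        if (doses.std(axis=0) > 0).any():
            break
    g = GenotypeMatrix([f"L{i}" for i in range(n)], [f"M{j}" for j in range(m)],
                       doses)
    return finalize_coding(g)


def brute_dummy_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Explicit n x m* indicator matrix over all pairs j <= k, combos
    (00, 02, 20, 22), in the package's column order."""
    X = g.haplotypes()
    n, m = X.shape
    cols = []
    for j in range(m):
        for k in range(j, m):
            for a, b in ((0, 0), (0, 1), (1, 0), (1, 1)):
                cols.append(((X[:, j] == a) & (X[:, k] == b)).astype(float))
    return np.column_stack(cols)


def brute_err_kernel(g: GenotypeMatrix):
    """Kernel, normalizer and (centered design, p*) from the dummy matrix."""
    Ms = brute_dummy_matrix(g)
    p = Ms.mean(axis=0)
    denom = float(np.sum(p * (1 - p)))
    Mc = Ms - p
    return (Mc @ Mc.T) / denom, denom, Mc, p


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_genotypes(rng):
    return random_genotypes(rng, 8, 5)
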