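"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive the statistics from first principles (exact
rational arithmetic, naive double sums) and stay independent of the package
implementations they check.
"""

from fractions import Fraction

import numpy as np


def di_exact(minority, reference) -> Fraction:
    """Dissimilarity index by the definition, in exact rational arithmetic."""
    xs = [Fraction(int(v)) for v in minority]
    ys = [Fraction(int(v)) for v in reference]
    X, Y = sum(xs), sum(ys)
    return Fraction(1, 2) * sum(abs(x / X - y / Y) for x, y in zip(xs, ys))


def moran_naive(values, weights_dense) -> float:
    """Global Moran's I by the literal double summation."""
    z = np.asarray(values, dtype=float)
    w = np.asarray(weights_dense, dtype=float)
    n = len(z)
    zc = z - z.mean()
    s0 = w.sum()
    num = sum(w[i, j] * zc[i] * zc[j] for i in range(n) for j in range(n))
    return (n / s0) * num / (zc ** 2).sum()


def dense_weights(spatial_weights) -> np.ndarray:
    """Expand neighbour-list weights to a dense matrix for the naive oracle."""
    n = spatial_weights.n
    w = np.zeros((n, n))
    for i in range(n):
        for j, wij in zip(spatial_weights.neighbors[i],
                          spatial_weights.weights[i]):
            w[i, j] = wij
    return w
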