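"""Numba kernels for the O(N^2) template-matching entropies.

Both kernels are exact quadratic template counts; they only reorganise the
work (sorting by the first template coordinate so that non-candidate pairs
are skipped, pair symmetry, early exit on the Chebyshev distance).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _apen_phi(x: np.ndarray, m: int, r: float) -> float:
    """mean_i log(C_i^m) with self-matches included (ApEn convention)."""
    n = x.size - m + 1
    if n <= 0:
        return np.nan
    order = np.argsort(x[:n])
    counts = np.ones(n)  # self-matches
    for a_ in range(n):
        i = order[a_]
        xi0 = x[i]
        for b_ in range(a_ + 1, n):
            j = order[b_]
            if x[j] - xi0 > r:  # sorted: no later j can match on dim 0
                break
            match = True
            for k in range(1, m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                counts[i] += 1.0
                counts[j] += 1.0
    total = 0.0
    for i in range(n):
        total += np.log(counts[i] / n)
    return total / n


@njit(cache=True)
def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[float, float]:
    """(B, A): numbers of m- and (m+1)-template matches, i < j (no self)."""
    n = x.size - m  # number of templates when the (m+1)-th sample must exist
    b = 0.0
    a = 0.0
    order = np.argsort(x[:n])
    for a_ in range(n):
        i = order[a_]
        xi0 = x[i]
        for b_ in range(a_ + 1, n):
            j = order[b_]
            if x[j] - xi0 > r:
                break
            match = True
            for k in range(1, m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1.0
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1.0
    return b, a


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    x = np.ascontiguousarray(x, dtype=np.float64)
    if r is None:
        r = 0.2 * x.std()
    if x.size < m + 2 or r <= 0:
        return np.nan
    return _apen_phi(x, m, r) - _apen_phi(x, m + 1, r)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    x = np.ascontiguousarray(x, dtype=np.float64)
    if r is None:
        r = 0.2 * x.std()
    if x.size < m + 2 or r <= 0:
        return np.nan
    b, a = _sampen_counts(x, m, r)
    if b == 0 or a == 0:
        return np.nan
    return -np.log(a / b)
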