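"""Numba pair-counting kernels for the entropy estimators.

All kernels evaluate templates of dimension m and m+1 over the same
index set i = 0..n-1 with n = N - m*t, which is what guarantees
ApEn >= 0 and matches the pair-count definitions of SampEn.  Chebyshev
(max-norm) distance throughout, with early abort inside the component
loop.  Correctness is pinned to naive O(N^2) oracles in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _match_counts(x: np.ndarray, order: np.ndarray, m: int, t: int, r: float):
    """Per-template match counts at dimensions m and m+1, self included.

    ``order`` sorts templates by their first component, so for each
    template only the window of candidates whose first component lies
    within r needs the remaining components checked — identical counts
    to the all-pairs scan, typically a small fraction of the work.
    """
    n = x.size - m * t
    count_m = np.ones(n, dtype=np.int64)
    count_m1 = np.ones(n, dtype=np.int64)
    for a_pos in range(n):
        i = order[a_pos]
        for b_pos in range(a_pos + 1, n):
            j = order[b_pos]
            if x[j] - x[i] > r:
                break
            d = 0.0
            for k in range(1, m):
                diff = abs(x[i + k * t] - x[j + k * t])
                if diff > d:
                    d = diff
                if d > r:
                    break
            if d <= r:
                count_m[i] += 1
                count_m[j] += 1
                if abs(x[i + m * t] - x[j + m * t]) <= r:
                    count_m1[i] += 1
                    count_m1[j] += 1
    return count_m, count_m1


def _sorted_template_order(x: np.ndarray, m: int, t: int) -> np.ndarray:
    n = x.size - m * t
    return np.argsort(x[:n], kind="stable").astype(np.int64)


def apen_phis(x: np.ndarray, m: int, t: int, r: float):
    """Return (phi_m, phi_m1): mean log match fractions, self-match included."""
    n = x.size - m * t
    count_m, count_m1 = _match_counts(x, _sorted_template_order(x, m, t), m, t, r)
    phi_m = float(np.mean(np.log(count_m / n)))
    phi_m1 = float(np.mean(np.log(count_m1 / n)))
    return phi_m, phi_m1


def sampen_counts(x: np.ndarray, m: int, t: int, r: float):
    """Return (A, B): template pairs (i < j) within r at dimension m+1 and m."""
    count_m, count_m1 = _match_counts(x, _sorted_template_order(x, m, t), m, t, r)
    # per-template counts include the self-match and count each pair twice
    b = int((count_m.sum() - count_m.size) // 2)
    a = int((count_m1.sum() - count_m1.size) // 2)
    return a, b


@njit(cache=True, fastmath=True)
def _fuzzy_total(u: np.ndarray, r: float, power: float) -> float:
    """Sum of exp(-(d/r)**power) over unordered row pairs of ``u`` (Chebyshev d)."""
    n, m = u.shape
    total = 0.0
    square = power == 2.0
    for i in range(n):
        row_sum = 0.0
        for j in range(i + 1, n):
            d = 0.0
            for k in range(m):
                diff = abs(u[i, k] - u[j, k])
                if diff > d:
                    d = diff
            ratio = d / r
            arg = ratio * ratio if square else ratio ** power
            row_sum += np.exp(-arg)
        total += row_sum
    return total


def fuzzy_phi(x: np.ndarray, n_templates: int, m: int, t: int, r: float, power: float):
    """Mean pairwise exponential similarity at dimension m, self-pairs excluded.

    Templates are baseline-removed (each template's own mean subtracted)
    before the Chebyshev distance; similarity is exp(-(d/r)**power).
    ``n_templates`` fixes the shared template index set for both dimensions.
    """
    idx = np.arange(n_templates)[:, None] + np.arange(m)[None, :] * t
    u = x[idx]
    u -= u.mean(axis=1, keepdims=True)
    total = _fuzzy_total(np.ascontiguousarray(u), r, power)
    n_pairs = n_templates * (n_templates - 1) / 2.0
    return total / n_pairs
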