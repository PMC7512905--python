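"""Independent brute-force oracles used to pin the fast implementations.

Everything here is written directly from the defining formulas with full
O(N^2) pairwise distance matrices — no code shared with the package's
kernels.
"""

from __future__ import annotations

import numpy as np


def embed(x: np.ndarray, m: int, t: int, n_templates: int) -> np.ndarray:
    """Delay-embedding matrix with a fixed number of rows."""
    return np.stack([x[i : i + (m - 1) * t + 1 : t] for i in range(n_templates)])


def chebyshev_matrix(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.abs(u[:, None, :] - v[None, :, :]).max(axis=2)


def apen_naive(x: np.ndarray, m: int, t: int, r: float) -> float:
    """ApEn with self-matches, both dimensions over the same N - m*t templates."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size - m * t
    phis = []
    for dim in (m, m + 1):
        u = embed(x, dim, t, n)
        counts = (chebyshev_matrix(u, u) <= r).sum(axis=1)
        phis.append(np.mean(np.log(counts / n)))
    return float(phis[0] - phis[1])


def sampen_naive(x: np.ndarray, m: int, t: int, r: float) -> float:
    """SampEn from explicit pair counts, self-matches excluded."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size - m * t
    counts = []
    for dim in (m, m + 1):
        u = embed(x, dim, t, n)
        d = chebyshev_matrix(u, u)
        within = (d <= r).sum() - n  # drop the diagonal self-matches
        counts.append(within // 2)
    a, b = counts[1], counts[0]
    return float(-np.log(a / b))


def coarse_grain_naive(x: np.ndarray, tau: int) -> list:
    """Composite coarse-graining by explicit block loops."""
    x = np.asarray(x, dtype=np.float64)
    out = []
    for k in range(1, tau + 1):
        series = []
        j = 1
        while (j - 1) * tau + k - 1 + tau <= x.size:
            start = (j - 1) * tau + k - 1
            series.append(x[start : start + tau].mean())
            j += 1
        out.append(np.array(series))
    return out


def cmpmse_naive(x: np.ndarray, m: int, t: int, r: float, tau: int) -> float:
    """Mean of naive SampEn over the composite coarse-grained series.

    Series with zero template matches (undefined SampEn) are skipped,
    mirroring the estimator's recoverable-error policy.
    """
    values = []
    for y in coarse_grain_naive(x, tau):
        try:
            with np.errstate(divide="raise", invalid="raise"):
                values.append(sampen_naive(y, m, t, r))
        except FloatingPointError:
            continue
    return float(np.mean(values))


def fuzzyen_naive(x: np.ndarray, m: int, t: int, r: float, power: float = 2.0) -> float:
    """FuzzyEn: baseline-removed templates, exp(-(d/r)**power) similarity."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size - m * t
    phis = []
    for dim in (m, m + 1):
        u = embed(x, dim, t, n)
        u = u - u.mean(axis=1, keepdims=True)
        d = chebyshev_matrix(u, u)
        sim = np.exp(-((d / r) ** power))
        phi = (sim.sum() - n) / (n * (n - 1))  # exclude self-pairs
        phis.append(phi)
    return float(np.log(phis[0]) - np.log(phis[1]))


def lda_scores_naive(X: np.ndarray, y: np.ndarray, X_new: np.ndarray) -> np.ndarray:
    """Pooled-covariance Gaussian discriminant scores, equal priors."""
    X = np.asarray(X, dtype=np.float64)
    classes = np.unique(y)
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    scatter = sum(
        (X[y == c] - mu).T @ (X[y == c] - mu) for c, mu in zip(classes, means)
    )
    cov = scatter / (X.shape[0] - classes.size)
    inv = np.linalg.inv(cov)
    scores = np.empty((X_new.shape[0], classes.size))
    for k, mu in enumerate(means):
        scores[:, k] = X_new @ inv @ mu - 0.5 * mu @ inv @ mu
    return scores


def polyfit_normal_equations(x: np.ndarray, degree: int) -> np.ndarray:
    """Least-squares polynomial trend via explicit normal equations."""
    t = np.arange(x.size, dtype=np.float64)
    design = np.vander(t, degree + 1, increasing=True)
    coeffs = np.linalg.solve(design.T @ design, design.T @ x)
    return design @ coeffs
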