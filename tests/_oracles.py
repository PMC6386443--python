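"""Independent loop-based oracles for counting and feature formulas.

These are deliberately naive transcriptions of the printed definitions —
explicit Python loops, scalar math, no shared code with the package — so
they can serve as an independent reference for the vectorized
implementations.
"""

import math

import numpy as np


def oracle_counts(qimage, vectors, n_levels, mask=None, symmetrize=False):
    """Brute-force pair enumeration over all positions and displacements."""
    q = np.asarray(qimage)
    x = np.zeros((n_levels, n_levels), dtype=int)
    for vec in vectors:
        for pos in np.ndindex(*q.shape):
            npos = tuple(p + d for p, d in zip(pos, vec))
            if any(c < 0 or c >= s for c, s in zip(npos, q.shape)):
                continue
            if mask is not None and not (mask[pos] and mask[npos]):
                continue
            x[q[pos] - 1, q[npos] - 1] += 1
    if symmetrize:
        x = x + x.T
    return x


def oracle_features(matrix, n, variant, symmetric=None):
    """All 20 texture features from a stored (normalized) GLCM matrix.

    ``matrix`` is the stored N x N array (PMF values for ``original``,
    density values for ``invariant``); level ``(i, j)`` lives at
    ``matrix[i-1, j-1]``.
    """
    P = np.asarray(matrix, dtype=float)
    if symmetric is None:
        symmetric = np.allclose(P, P.T)

    def p(i, j):
        return P[i - 1, j - 1]

    if variant == "original":
        D, Dij, Ds = 1.0, 1.0, 1.0
        idx = lambda i: float(i)
        ksum = lambda k: float(k)
        kdiff = lambda k: float(k)
    else:
        D, Dij, Ds = 1.0 / n, 1.0 / n**2, 1.0 / (2 * n - 1)
        idx = lambda i: i / n
        ksum = lambda k: 2.0 * (k - 1) / (2 * n - 1)
        kdiff = lambda k: (k + 1.0) / n

    rng1 = range(1, n + 1)
    px = {i: sum(p(i, j) for j in rng1) * D for i in rng1}
    py = {j: sum(p(i, j) for i in rng1) * D for j in rng1}
    mu_x = sum(idx(i) * px[i] * D for i in rng1)
    mu_y = sum(idx(j) * py[j] * D for j in rng1)
    var_x = sum((idx(i) - mu_x) ** 2 * px[i] * D for i in rng1)
    var_y = sum((idx(j) - mu_y) ** 2 * py[j] * D for j in rng1)
    pxy_sum = {
        k: sum(p(i, j) for i in rng1 for j in rng1 if i + j == k) * D
        for k in range(2, 2 * n + 1)
    }
    pxy_diff = {
        k: sum(p(i, j) for i in rng1 for j in rng1 if abs(i - j) == k) * D
        for k in range(0, n)
    }
    mu_sum = sum(ksum(k) * pxy_sum[k] * Ds for k in pxy_sum)
    mu_diff = sum(kdiff(k) * pxy_diff[k] * D for k in pxy_diff)

    def xlogx(v):
        return v * math.log(v) if v > 0 else 0.0

    hx = -sum(xlogx(px[i]) for i in rng1) * D
    hy = -sum(xlogx(py[j]) for j in rng1) * D
    hxy = -sum(xlogx(p(i, j)) for i in rng1 for j in rng1) * Dij
    hxy1 = -sum(
        p(i, j) * math.log(px[i] * py[j])
        for i in rng1
        for j in rng1
        if p(i, j) > 0 and px[i] * py[j] > 0
    ) * Dij
    hxy2 = -sum(xlogx(px[i] * py[j]) for i in rng1 for j in rng1) * Dij

    mu = mu_x if symmetric else 0.5 * (mu_x + mu_y)
    sx, sy = math.sqrt(var_x), math.sqrt(var_y)

    q_mat = np.zeros((n, n))
    for i in rng1:
        for j in rng1:
            acc = 0.0
            for k in rng1:
                if px[i] > 0 and py[k] > 0:
                    acc += p(i, k) * p(j, k) / (px[i] * py[k])
            q_mat[i - 1, j - 1] = acc * Dij

    feats = {
        "autocorrelation": sum(idx(i) * idx(j) * p(i, j) for i in rng1 for j in rng1) * Dij,
        "cluster_prominence": sum(
            (idx(i) + idx(j) - 2 * mu) ** 3 * p(i, j) for i in rng1 for j in rng1
        ) * Dij,
        "cluster_shade": sum(
            (idx(i) + idx(j) - 2 * mu) ** 4 * p(i, j) for i in rng1 for j in rng1
        ) * Dij,
        "contrast": sum((idx(i) - idx(j)) ** 2 * p(i, j) for i in rng1 for j in rng1) * Dij,
        "correlation": sum(
            ((idx(i) - mu_x) / sx) * ((idx(j) - mu_y) / sy) * p(i, j)
            for i in rng1
            for j in rng1
        ) * Dij,
        "difference_entropy": -sum(xlogx(pxy_diff[k]) for k in pxy_diff) * D,
        "difference_variance": sum(
            (kdiff(k) - mu_diff) ** 2 * pxy_diff[k] for k in pxy_diff
        ) * D,
        "dissimilarity": sum(abs(idx(i) - idx(j)) * p(i, j) for i in rng1 for j in rng1) * Dij,
        "energy": sum(p(i, j) ** 2 for i in rng1 for j in rng1) * Dij,
        "entropy": -sum(xlogx(p(i, j)) for i in rng1 for j in rng1) * Dij,
        "homogeneity": sum(
            p(i, j) / (1.0 + (idx(i) - idx(j)) ** 2) for i in rng1 for j in rng1
        ) * Dij,
        "information_measure_of_correlation_1": (hxy - hxy1) / max(hx, hy),
        "information_measure_of_correlation_2": 1.0 - math.exp(-2.0 * (hxy2 - hxy)),
        "inverse_difference": sum(
            p(i, j) / (1.0 + abs(idx(i) - idx(j))) for i in rng1 for j in rng1
        ) * Dij,
        "maximum_probability": max(p(i, j) for i in rng1 for j in rng1),
        "sum_average": sum(ksum(k) * pxy_sum[k] for k in pxy_sum) * Ds,
        "sum_entropy": -sum(xlogx(pxy_sum[k]) for k in pxy_sum) * Ds,
        "sum_of_squares": sum(
            (idx(i) - mu) ** 2 * p(i, j) for i in rng1 for j in rng1
        ) * Dij,
        "sum_variance": sum(
            (ksum(k) - mu_sum) ** 2 * pxy_sum[k] for k in pxy_sum
        ) * Ds,
        "maximal_correlation_coefficient": float(np.sort(np.linalg.eigvals(q_mat).real)[::-1][1]),
    }
    return feats, q_mat
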