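"""Haralick texture features in original and gray-level-invariant form.

Every feature is a functional of the normalized GLCM.  In the ``original``
formulation the GLCM is a probability mass function over gray-level pairs
``(i, j)`` with ``i, j = 1..N`` and features are plain sums.  In the
``invariant`` formulation the GLCM is a discretized density on the unit
square: indices are mapped to ``i/N, j/N`` in ``(0, 1]``, every sum is
multiplied by the cell differential (``delta = 1/N`` for marginal sums,
``delta_ij = 1/N**2`` for joint sums, ``delta_xplusy = 1/(2N-1)`` for the
sum-marginal), and the matrix itself carries a factor ``N**2``.  The sums
then approximate integrals of the underlying pair density, so the feature
values converge as ``N`` grows instead of drifting with the quantization.

Consequences of the density view worth keeping in mind:

* the entropy-family features become differential entropies and can be
  negative (invariant Entropy equals original Entropy minus ``2 ln N``);
* Maximum probability becomes a maximum probability *density* (the density
  at the mode) and is the one feature that does not converge for noisy
  data;
* Correlation is identical in both formulations, since the index and
  matrix rescalings cancel.

All logarithms are natural, with the convention ``0 * log 0 = 0``.

Note on naming: here Cluster prominence carries the cube and Cluster shade
the 4th power.  Much of the wider literature swaps these two exponents;
the convention used here is kept fixed and documented rather than guessed
per source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .glcm import GLCMDistribution

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_FEATURE_NAMES",
    "MarginalStats",
    "FeatureVector",
    "marginal_stats",
    "compute_feature",
    "compute_all",
    "q_matrix",
    "maximal_correlation_coefficient",
]

#: All feature names, in canonical table order.  The maximal correlation
#: coefficient is last and excluded from the default set because it is
#: numerically unstable on sparse GLCMs.
FEATURE_NAMES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "contrast",
    "correlation",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "information_measure_of_correlation_1",
    "information_measure_of_correlation_2",
    "inverse_difference",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_of_squares",
    "sum_variance",
    "maximal_correlation_coefficient",
)

DEFAULT_FEATURE_NAMES = FEATURE_NAMES[:-1]


def _xlogx(p: np.ndarray) -> np.ndarray:
    """Elementwise ``p * log(p)`` with ``0 log 0 = 0``."""
    out = np.zeros_like(p, dtype=float)
    pos = p > 0
    out[pos] = p[pos] * np.log(p[pos])
    return out


@dataclass(frozen=True)
class MarginalStats:
    """Marginal distributions, moments and entropies of a normalized GLCM.

    For the invariant variant the marginals are themselves densities:
    ``p_x`` integrates to 1 against ``delta = 1/N`` and the means/variances
    are taken over the rescaled support ``i/N in (0, 1]``.  The
    sum-marginal ``p_xplusy`` has length ``2N-1`` (indexed ``k = 2..2N``)
    and the difference-marginal ``p_xminusy`` length ``N`` (``k = 0..N-1``).
    """

    variant: str
    n_levels: int
    p_x: np.ndarray
    p_y: np.ndarray
    mu_x: float
    mu_y: float
    var_x: float
    var_y: float
    p_xplusy: np.ndarray
    p_xminusy: np.ndarray
    mu_xplusy: float
    mu_xminusy: float
    hx: float
    hy: float
    hxy: float
    hxy1: float
    hxy2: float


@dataclass(frozen=True)
class FeatureVector:
    """Named feature values for one GLCM and one normalization variant."""

    variant: str
    n_levels: int
    values: Dict[str, float]


def marginal_stats(glcm: GLCMDistribution) -> MarginalStats:
    """Compute all marginal quantities needed by the texture features."""
    p = glcm.matrix
    n = glcm.n_levels
    k_sum = np.arange(2, 2 * n + 1)          # support of the sum marginal
    k_diff = np.arange(0, n)                 # support of the difference marginal
    i_idx = np.arange(1, n + 1, dtype=float)

    # raw marginals of the stored matrix (PMF-scaled sums along axes)
    row_sum = p.sum(axis=1)
    col_sum = p.sum(axis=0)
    ii, jj = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
    sum_groups = np.bincount((ii + jj).ravel() - 2, weights=p.ravel(), minlength=2 * n - 1)
    diff_groups = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=n)

    if glcm.variant == "original":
        p_x, p_y = row_sum, col_sum
        mu_x = float(np.sum(i_idx * p_x))
        mu_y = float(np.sum(i_idx * p_y))
        var_x = float(np.sum((i_idx - mu_x) ** 2 * p_x))
        var_y = float(np.sum((i_idx - mu_y) ** 2 * p_y))
        p_xplusy = sum_groups
        p_xminusy = diff_groups
        mu_xplusy = float(np.sum(k_sum * p_xplusy))
        mu_xminusy = float(np.sum(k_diff * p_xminusy))
        hx = -float(np.sum(_xlogx(p_x)))
        hy = -float(np.sum(_xlogx(p_y)))
        hxy = -float(np.sum(_xlogx(p)))
        prod = np.outer(p_x, p_y)
        with np.errstate(divide="ignore"):
            logprod = np.where(prod > 0, np.log(np.where(prod > 0, prod, 1.0)), 0.0)
        hxy1 = -float(np.sum(np.where(p > 0, p * logprod, 0.0)))
        hxy2 = -float(np.sum(_xlogx(prod)))
    else:
        d = glcm.delta
        d_ij = glcm.delta_ij
        d_sum = glcm.delta_xplusy
        p_x = row_sum * d
        p_y = col_sum * d
        mu_x = float(np.sum((i_idx / n) * p_x * d))
        mu_y = float(np.sum((i_idx / n) * p_y * d))
        var_x = float(np.sum((i_idx / n - mu_x) ** 2 * p_x * d))
        var_y = float(np.sum((i_idx / n - mu_y) ** 2 * p_y * d))
        p_xplusy = sum_groups * d
        p_xminusy = diff_groups * d
        mu_xplusy = float(np.sum((2.0 * (k_sum - 1) / (2 * n - 1)) * p_xplusy * d_sum))
        mu_xminusy = float(np.sum(((k_diff + 1.0) / n) * p_xminusy * d))
        hx = -float(np.sum(_xlogx(p_x))) * d
        hy = -float(np.sum(_xlogx(p_y))) * d
        hxy = -float(np.sum(_xlogx(p))) * d_ij
        prod = np.outer(p_x, p_y)
        with np.errstate(divide="ignore"):
            logprod = np.where(prod > 0, np.log(np.where(prod > 0, prod, 1.0)), 0.0)
        hxy1 = -float(np.sum(np.where(p > 0, p * logprod, 0.0))) * d_ij
        hxy2 = -float(np.sum(_xlogx(prod))) * d_ij

    return MarginalStats(
        variant=glcm.variant,
        n_levels=n,
        p_x=p_x,
        p_y=p_y,
        mu_x=mu_x,
        mu_y=mu_y,
        var_x=var_x,
        var_y=var_y,
        p_xplusy=p_xplusy,
        p_xminusy=p_xminusy,
        mu_xplusy=mu_xplusy,
        mu_xminusy=mu_xminusy,
        hx=hx,
        hy=hy,
        hxy=hxy,
        hxy1=hxy1,
        hxy2=hxy2,
    )


def _shared_mu(glcm: GLCMDistribution, ms: MarginalStats) -> float:
    # symmetric GLCMs have identical marginals; otherwise average the two means
    if glcm.is_symmetric:
        return ms.mu_x
    return 0.5 * (ms.mu_x + ms.mu_y)


def q_matrix(glcm: GLCMDistribution) -> np.ndarray:
    """The Q matrix whose second eigenvalue is the maximal correlation coefficient.

    ``Q(i,j) = sum_k p(i,k) p(j,k) / (p_x(i) p_y(k))`` in the original
    formulation; the invariant formulation uses the density and its
    marginals and carries the differential ``delta_ij``.  Terms whose
    marginal is zero (unvisited gray-levels) contribute zero.
    """
    ms = marginal_stats(glcm)
    p = glcm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(ms.p_x[:, None] > 0, p / ms.p_x[:, None], 0.0)
        c = np.where(ms.p_y[None, :] > 0, p / ms.p_y[None, :], 0.0)
    q = a @ c.T
    if glcm.variant == "invariant":
        q *= glcm.delta_ij
    return q


def maximal_correlation_coefficient(glcm: GLCMDistribution, sqrt: bool = False) -> float:
    """Second-largest eigenvalue (by real part) of the Q matrix.

    With ``sqrt=True`` the square root of the eigenvalue is returned
    instead (the older convention); the plain eigenvalue is the default.
    """
    q = q_matrix(glcm)
    try:
        eig = np.linalg.eigvals(q)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("eigendecomposition of the Q matrix did not converge") from exc
    second = float(np.sort(eig.real)[::-1][1])
    if sqrt:
        return math.sqrt(max(second, 0.0))
    return second


def _feature_value(glcm: GLCMDistribution, ms: MarginalStats, name: str) -> float:
    p = glcm.matrix
    n = glcm.n_levels
    inv = glcm.variant == "invariant"
    ii, jj = np.meshgrid(
        np.arange(1, n + 1, dtype=float), np.arange(1, n + 1, dtype=float), indexing="ij"
    )
    if inv:
        xi, xj = ii / n, jj / n
        w = glcm.delta_ij          # joint-sum differential
        wm = glcm.delta            # marginal-sum differential
        ws = glcm.delta_xplusy     # sum-marginal differential
        k_sum = 2.0 * (np.arange(2, 2 * n + 1) - 1) / (2 * n - 1)
        k_diff = (np.arange(0, n) + 1.0) / n
    else:
        xi, xj = ii, jj
        w = wm = ws = 1.0
        k_sum = np.arange(2, 2 * n + 1, dtype=float)
        k_diff = np.arange(0, n, dtype=float)

    if name == "autocorrelation":
        return float(np.sum(xi * xj * p) * w)
    if name == "cluster_prominence":
        mu = _shared_mu(glcm, ms)
        return float(np.sum((xi + xj - 2 * mu) ** 3 * p) * w)
    if name == "cluster_shade":
        mu = _shared_mu(glcm, ms)
        return float(np.sum((xi + xj - 2 * mu) ** 4 * p) * w)
    if name == "contrast":
        return float(np.sum((xi - xj) ** 2 * p) * w)
    if name == "correlation":
        if ms.var_x <= 0 or ms.var_y <= 0:
            raise ValueError(
                "correlation is undefined: zero marginal variance (degenerate GLCM)"
            )
        sx, sy = math.sqrt(ms.var_x), math.sqrt(ms.var_y)
        return float(np.sum(((xi - ms.mu_x) / sx) * ((xj - ms.mu_y) / sy) * p) * w)
    if name == "difference_entropy":
        return float(-np.sum(_xlogx(ms.p_xminusy)) * wm)
    if name == "difference_variance":
        return float(np.sum((k_diff - ms.mu_xminusy) ** 2 * ms.p_xminusy) * wm)
    if name == "dissimilarity":
        return float(np.sum(np.abs(xi - xj) * p) * w)
    if name == "energy":
        return float(np.sum(p**2) * w)
    if name == "entropy":
        return float(-np.sum(_xlogx(p)) * w)
    if name == "homogeneity":
        return float(np.sum(p / (1.0 + (xi - xj) ** 2)) * w)
    if name == "information_measure_of_correlation_1":
        denom = max(ms.hx, ms.hy)
        if abs(denom) < 1e-12:
            raise ValueError(
                "information measure of correlation 1 is undefined: "
                "max(HX, HY) is zero (uniform or degenerate marginals)"
            )
        return (ms.hxy - ms.hxy1) / denom
    if name == "information_measure_of_correlation_2":
        return 1.0 - math.exp(-2.0 * (ms.hxy2 - ms.hxy))
    if name == "inverse_difference":
        return float(np.sum(p / (1.0 + np.abs(xi - xj))) * w)
    if name == "maximum_probability":
        return float(p.max())
    if name == "sum_average":
        return float(np.sum(k_sum * ms.p_xplusy) * ws)
    if name == "sum_entropy":
        return float(-np.sum(_xlogx(ms.p_xplusy)) * ws)
    if name == "sum_of_squares":
        mu = _shared_mu(glcm, ms)
        return float(np.sum((xi - mu) ** 2 * p) * w)
    if name == "sum_variance":
        return float(np.sum((k_sum - ms.mu_xplusy) ** 2 * ms.p_xplusy) * ws)
    if name == "maximal_correlation_coefficient":
        return maximal_correlation_coefficient(glcm)
    raise KeyError(
        f"unknown feature {name!r}; valid names: {', '.join(FEATURE_NAMES)}"
    )


def compute_feature(glcm: GLCMDistribution, name: str) -> float:
    """Evaluate a single named texture feature on a normalized GLCM."""
    ms = marginal_stats(glcm)
    return _feature_value(glcm, ms, name)


def compute_all(glcm: GLCMDistribution, include_mcc: bool = False) -> FeatureVector:
    """Evaluate all texture features on a normalized GLCM.

    Returns the 19 default features in canonical order; the maximal
    correlation coefficient is appended only when ``include_mcc`` is true.
    """
    ms = marginal_stats(glcm)
    names = FEATURE_NAMES if include_mcc else DEFAULT_FEATURE_NAMES
    values: Dict[str, float] = {}
    for name in names:
        try:
            values[name] = _feature_value(glcm, ms, name)
        except ValueError as exc:
            raise ValueError(f"{name}: {exc}") from exc
    return FeatureVector(variant=glcm.variant, n_levels=glcm.n_levels, values=values)
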