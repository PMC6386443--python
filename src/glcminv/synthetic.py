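"""Synthetic GLCMs and textured images with known statistical structure.

Two generators cover the two levels of the pipeline:

* :func:`gaussian_glcm` builds a GLCM directly by discretizing a bivariate
  Gaussian density on the unit square -- useful for visualizing and
  testing the PMF-vs-density normalizations without any image at all.
* :func:`gaussian_random_field` and :func:`two_class_sample` produce
  continuous-valued textured images whose spatial correlation (and hence
  GLCM structure) is controlled by a single correlation-length parameter.
  Because the images are continuous, any quantization can be applied
  downstream, which is exactly what the invariance experiments need.

Gaussian random fields are a deliberately simple texture model: they are
stationary, have Gaussian marginals and are fully described by their
covariance. Real tissue textures are none of these things, so passing the
classification experiments on these fields demonstrates quantization
invariance of the features, not biological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage
from scipy.stats import multivariate_normal

from .glcm import CooccurrenceCounts, GLCMDistribution, OffsetSet

__all__ = [
    "GaussianGlcmSpec",
    "TextureParams",
    "TextureSampleSet",
    "gaussian_glcm",
    "gaussian_random_field",
    "two_class_sample",
]


@dataclass(frozen=True)
class GaussianGlcmSpec:
    """A bivariate Gaussian density on the unit square, discretized to N levels."""

    n_levels: int
    mean: Tuple[float, float] = (0.5, 0.5)
    cov: Tuple[Tuple[float, float], Tuple[float, float]] = ((0.02, 0.0), (0.0, 0.02))
    total_counts: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (2, 2) or not np.allclose(c, c.T):
            raise ValueError("cov must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(c) <= 0):
            raise ValueError("cov must be positive definite")
        if self.total_counts is not None and self.total_counts < 1:
            raise ValueError("total_counts must be a positive integer")


def gaussian_glcm(spec: GaussianGlcmSpec, variant: str = "invariant") -> GLCMDistribution:
    """Discretize a bivariate Gaussian density at cell centers into a GLCM.

    The density is evaluated at ``((i - 1/2)/N, (j - 1/2)/N)`` for
    ``i, j = 1..N`` and normalized either as a PMF (entries sum to 1) or as
    a density (Riemann sum with cell area ``1/N**2`` equals 1).  When
    ``spec.total_counts`` is given, the density is first converted to
    integer counts of that approximate total, emulating a finite sample.
    """
    if variant not in ("original", "invariant"):
        raise ValueError(f"variant must be 'original' or 'invariant', got {variant!r}")
    n = spec.n_levels
    centers = (np.arange(1, n + 1) - 0.5) / n
    gi, gj = np.meshgrid(centers, centers, indexing="ij")
    pts = np.stack([gi.ravel(), gj.ravel()], axis=1)
    dens = multivariate_normal(mean=spec.mean, cov=np.asarray(spec.cov)).pdf(pts)
    weights = dens.reshape(n, n)
    if spec.total_counts is not None:
        counts = np.rint(weights / weights.sum() * spec.total_counts).astype(np.int64)
        if counts.sum() == 0:
            raise ValueError("total_counts too small: all cells rounded to zero")
        weights = counts.astype(float)
    total = weights.sum()
    if variant == "original":
        return GLCMDistribution(matrix=weights / total, n_levels=n, variant="original")
    return GLCMDistribution(matrix=weights * (n * n / total), n_levels=n, variant="invariant")


def gaussian_random_field(
    shape: Sequence[int],
    correlation_length: float,
    seed: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """Stationary Gaussian random field with mean 0 and unit variance.

    White Gaussian noise is smoothed with an isotropic Gaussian kernel of
    standard deviation ``correlation_length`` pixels (periodic boundaries)
    and rescaled so the stationary variance is exactly 1.  The resulting
    autocorrelation is Gaussian with standard deviation
    ``correlation_length * sqrt(2)``.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError(f"shape must be positive, got {shape}")
    if correlation_length <= 0:
        raise ValueError(f"correlation_length must be positive, got {correlation_length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=correlation_length, mode="wrap")
    # exact output std for periodic convolution: l2 norm of the effective kernel
    delta = np.zeros(shape)
    delta[tuple(0 for _ in shape)] = 1.0
    kernel = ndimage.gaussian_filter(delta, sigma=correlation_length, mode="wrap")
    scale = float(np.sqrt(np.sum(kernel**2)))
    return smooth / scale


@dataclass(frozen=True)
class TextureParams:
    """Generating parameters for one texture class."""

    correlation_length: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class TextureSampleSet:
    """Seeded, labeled synthetic images for the classification harness.

    Images are continuous-valued so any number of gray-levels in 8..256
    can be applied downstream.  Labels are 0 for class A and 1 for
    class B.
    """

    images: Tuple[np.ndarray, ...]
    labels: np.ndarray
    params: Tuple[TextureParams, TextureParams]
    seed: int


def two_class_sample(
    n_per_class: int,
    params_a: TextureParams,
    params_b: TextureParams,
    image_shape: Sequence[int] = (64, 64),
    seed: int = 0,
) -> TextureSampleSet:
    """Generate a two-class population of Gaussian-random-field textures.

    Each image is an independent field with its class's correlation
    length plus white Gaussian noise of its class's ``noise_sd``.
    Per-image seeds are derived deterministically from the master seed by
    counter, so the whole set is bit-reproducible.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    images: List[np.ndarray] = []
    labels: List[int] = []
    for label, params in enumerate((params_a, params_b)):
        for k in range(n_per_class):
            rng = np.random.default_rng(np.random.SeedSequence([seed, label, k]))
            img = gaussian_random_field(image_shape, params.correlation_length, rng)
            if params.noise_sd > 0:
                img = img + params.noise_sd * rng.standard_normal(tuple(image_shape))
            images.append(img)
            labels.append(label)
    return TextureSampleSet(
        images=tuple(images),
        labels=np.asarray(labels, dtype=int),
        params=(params_a, params_b),
        seed=seed,
    )
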