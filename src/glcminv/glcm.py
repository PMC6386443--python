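"""Quantization and gray-level co-occurrence matrices.

The texture pipeline starts by mapping a continuous-valued image on an
intensity range ``[a, b]`` to ``N`` discrete gray-levels ``1..N`` (an affine
quantization).  Pairs of quantized gray-levels observed at fixed pixel
displacements are then counted into an ``N x N`` co-occurrence matrix ``X``.

Two normalizations of ``X`` are supported:

* ``original`` -- the classical probability *mass* function
  ``P = X / sum(X)``, whose entries sum to 1.
* ``invariant`` -- the matrix reinterpreted as a discretized probability
  *density* on the unit square, ``P~ = X / (sum(X) * delta_ij)`` with cell
  area ``delta_ij = 1/N**2``, so that the Riemann sum
  ``sum(P~) * delta_ij = 1``.  Features computed from the density converge
  to fixed values as ``N`` grows, making them comparable across
  quantizations.

Gray-levels are 1-based (``1..N``) in the API, matching the usual texture
literature; matrices are stored 0-based, so ``matrix[i-1, j-1]`` holds the
count for the gray-level pair ``(i, j)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "QuantizationSpec",
    "OffsetSet",
    "CooccurrenceCounts",
    "GLCMDistribution",
    "quantize",
    "dither",
    "standard_offsets",
    "cooccurrence_counts",
    "normalize_pmf",
    "normalize_density",
    "glcm_from_image",
]


@dataclass(frozen=True)
class QuantizationSpec:
    """Affine quantization of intensities on ``[lower, upper]`` to ``1..n_levels``.

    Values are binned into ``n_levels`` equal-width half-open bins
    ``[a + (l-1)w, a + l*w)`` with ``w = (b-a)/N``; the value ``b`` itself is
    assigned to level ``N``.  With ``clip=True`` (default) out-of-range
    intensities are clipped to the first/last level; with ``clip=False``
    they raise an error.
    """

    n_levels: int
    lower: float
    upper: float
    clip: bool = True

    def __post_init__(self) -> None:
        if int(self.n_levels) != self.n_levels or self.n_levels < 2:
            raise ValueError(f"n_levels must be an integer >= 2, got {self.n_levels}")
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("quantization limits must be finite")
        if not self.upper > self.lower:
            raise ValueError(
                f"upper must be strictly greater than lower, got [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class OffsetSet:
    """A set of integer displacement vectors defining pixel neighborhoods.

    Offsets are (row, column[, slice]) displacements on the stored array;
    a displacement ``(0, 1)`` pairs each pixel with its right neighbor.
    When ``semi_invariant`` is true the set contains exactly one of each
    ``+d / -d`` pair and the resulting co-occurrence matrix is symmetrized
    by adding its transpose, which is equivalent to counting both
    directions.
    """

    dims: int
    vectors: Tuple[Tuple[int, ...], ...]
    semi_invariant: bool = False

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError(f"dims must be 2 or 3, got {self.dims}")
        vecs = tuple(tuple(int(c) for c in v) for v in self.vectors)
        object.__setattr__(self, "vectors", vecs)
        if not vecs:
            raise ValueError("offset set must contain at least one vector")
        seen = set()
        for v in vecs:
            if len(v) != self.dims:
                raise ValueError(f"offset {v} does not have {self.dims} components")
            if all(c == 0 for c in v):
                raise ValueError("zero displacement vector is not allowed")
            if v in seen:
                raise ValueError(f"duplicate displacement vector {v}")
            seen.add(v)
        if self.semi_invariant:
            for v in vecs:
                neg = tuple(-c for c in v)
                if neg in seen:
                    raise ValueError(
                        f"semi-invariant set contains both {v} and {neg}"
                    )

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass(frozen=True)
class CooccurrenceCounts:
    """Integer co-occurrence counts with their offset provenance."""

    matrix: np.ndarray
    n_levels: int
    offsets: OffsetSet
    symmetric: bool

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (self.n_levels, self.n_levels):
            raise ValueError(
                f"matrix shape {m.shape} does not match n_levels={self.n_levels}"
            )
        if np.any(m < 0):
            raise ValueError("co-occurrence counts must be non-negative")
        object.__setattr__(self, "matrix", m.astype(np.int64, copy=False))
        if self.symmetric and not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("matrix flagged symmetric but is not equal to its transpose")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass(frozen=True)
class GLCMDistribution:
    """A normalized GLCM, either a PMF (``original``) or a density (``invariant``).

    ``delta``, ``delta_ij`` and ``delta_xplusy`` are the cell widths/areas
    (``1/N``, ``1/N**2``, ``1/(2N-1)``) used as differentials in the
    Riemann sums of the invariant features.
    """

    matrix: np.ndarray
    n_levels: int
    variant: str

    def __post_init__(self) -> None:
        if self.variant not in ("original", "invariant"):
            raise ValueError(f"variant must be 'original' or 'invariant', got {self.variant!r}")
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.n_levels, self.n_levels):
            raise ValueError(
                f"matrix shape {m.shape} does not match n_levels={self.n_levels}"
            )
        if np.any(m < 0):
            raise ValueError("normalized GLCM entries must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def delta(self) -> float:
        return 1.0 / self.n_levels

    @property
    def delta_ij(self) -> float:
        return 1.0 / self.n_levels**2

    @property
    def delta_xplusy(self) -> float:
        return 1.0 / (2 * self.n_levels - 1)

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.matrix, self.matrix.T, rtol=1e-10, atol=1e-12))


def quantize(image: np.ndarray, spec: QuantizationSpec) -> np.ndarray:
    """Quantize a continuous-valued image to integer gray-levels ``1..N``.

    A value ``v`` maps to ``floor((v - a) / (b - a) * N) + 1``, with ``v = b``
    mapping to ``N``.  Values outside ``[a, b]`` are clipped to levels 1 or
    ``N`` when ``spec.clip`` is true, and raise otherwise.
    """
    arr = np.asarray(image, dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = tuple(int(c) for c in np.argwhere(bad)[0])
        raise ValueError(f"non-finite pixel value at index {idx}")
    if not spec.clip:
        out = (arr < spec.lower) | (arr > spec.upper)
        if out.any():
            idx = tuple(int(c) for c in np.argwhere(out)[0])
            raise ValueError(
                f"pixel value {arr[idx]} at index {idx} outside "
                f"[{spec.lower}, {spec.upper}] and clip=False"
            )
    n = spec.n_levels
    scaled = (arr - spec.lower) / (spec.upper - spec.lower) * n
    q = np.floor(scaled).astype(np.int64) + 1
    # handles both v == b (floor(N)+1 -> N) and out-of-range clipping
    np.clip(q, 1, n, out=q)
    return q


def dither(image: np.ndarray, amplitude: float = 1.0, seed: int | None = None) -> np.ndarray:
    """Add i.i.d. uniform noise on ``[-amplitude/2, +amplitude/2]``.

    Dithering decorrelates quantization error for integer-valued inputs;
    an amplitude of 1.0 (the default) matches a unit native gray-level
    step.
    """
    if amplitude < 0:
        raise ValueError(f"amplitude must be non-negative, got {amplitude}")
    arr = np.asarray(image, dtype=float)
    if amplitude == 0:
        return arr.copy()
    rng = np.random.default_rng(seed)
    return arr + rng.uniform(-amplitude / 2.0, amplitude / 2.0, size=arr.shape)


def standard_offsets(dims: int, semi_invariant: bool = False) -> OffsetSet:
    """Displacement vectors to all immediate neighbors in 2D or 3D.

    Full sets pair each pixel with all 8 (2D) or 26 (3D) immediate
    neighbors.  Semi-invariant sets keep exactly one of each opposite
    pair -- 4 (2D) or 13 (3D) vectors -- relying on transpose
    symmetrization to recover the opposite directions.
    """
    if dims not in (2, 3):
        raise ValueError(f"dims must be 2 or 3, got {dims}")
    all_vecs = [
        v for v in itertools.product((-1, 0, 1), repeat=dims) if any(c != 0 for c in v)
    ]
    if semi_invariant:
        # keep the lexicographically positive member of each +/- pair
        all_vecs = [v for v in all_vecs if v > tuple(-c for c in v)]
    return OffsetSet(dims=dims, vectors=tuple(all_vecs), semi_invariant=semi_invariant)


def cooccurrence_counts(
    qimage: np.ndarray,
    offsets: OffsetSet,
    n_levels: int,
    mask: Optional[np.ndarray] = None,
) -> CooccurrenceCounts:
    """Accumulate gray-level pair counts over all offsets.

    For each displacement and each position where both the reference pixel
    and its displaced neighbor lie inside the array (and inside the mask,
    if one is given), the count for the observed gray-level pair is
    incremented.  Counts from all offsets are summed.  When the offset set
    is semi-invariant the summed matrix is symmetrized by adding its
    transpose, which is exactly equivalent to also counting the opposite
    displacements.
    """
    q = np.asarray(qimage)
    if q.ndim != offsets.dims:
        raise ValueError(f"image has {q.ndim} dimensions but offsets are {offsets.dims}D")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != q.shape:
            raise ValueError(f"mask shape {mask.shape} does not match image shape {q.shape}")
        inside = q[mask]
    else:
        inside = q.reshape(-1)
    if inside.size:
        lo, hi = int(inside.min()), int(inside.max())
        if lo < 1 or hi > n_levels:
            raise ValueError(
                f"quantized values must lie in [1, {n_levels}], found range [{lo}, {hi}]"
            )

    n = int(n_levels)
    x = np.zeros((n, n), dtype=np.int64)
    for vec in offsets.vectors:
        src = []
        dst = []
        for axis, d in enumerate(vec):
            size = q.shape[axis]
            if abs(d) >= size:
                src = None
                break
            if d >= 0:
                src.append(slice(0, size - d))
                dst.append(slice(d, size))
            else:
                src.append(slice(-d, size))
                dst.append(slice(0, size + d))
        if src is None:
            continue
        i = q[tuple(src)]
        j = q[tuple(dst)]
        if mask is not None:
            valid = mask[tuple(src)] & mask[tuple(dst)]
            i = i[valid]
            j = j[valid]
        else:
            i = i.reshape(-1)
            j = j.reshape(-1)
        if i.size:
            flat = (i.astype(np.int64) - 1) * n + (j.astype(np.int64) - 1)
            x += np.bincount(flat, minlength=n * n).reshape(n, n)

    symmetric = False
    if offsets.semi_invariant:
        x = x + x.T
        symmetric = True
    if x.sum() == 0:
        raise ValueError(
            "degenerate ROI: no valid pixel pairs (empty mask or image smaller than offsets)"
        )
    return CooccurrenceCounts(matrix=x, n_levels=n, offsets=offsets, symmetric=symmetric)


def normalize_pmf(counts: CooccurrenceCounts) -> GLCMDistribution:
    """Normalize counts to a probability mass function (entries sum to 1)."""
    total = counts.total
    if total <= 0:
        raise ValueError("cannot normalize a co-occurrence matrix with zero total count")
    return GLCMDistribution(
        matrix=counts.matrix / float(total),
        n_levels=counts.n_levels,
        variant="original",
    )


def normalize_density(counts: CooccurrenceCounts) -> GLCMDistribution:
    """Normalize counts to a discretized density on the unit square.

    Each cell is ascribed area ``1/N**2``; the result satisfies the Riemann
    sum ``sum(P~) / N**2 = 1`` and equals the PMF scaled by ``N**2``.
    """
    total = counts.total
    if total <= 0:
        raise ValueError("cannot normalize a co-occurrence matrix with zero total count")
    n = counts.n_levels
    return GLCMDistribution(
        matrix=counts.matrix * (n * n / float(total)),
        n_levels=n,
        variant="invariant",
    )


def glcm_from_image(
    image: np.ndarray,
    spec: QuantizationSpec,
    offsets: Optional[OffsetSet] = None,
    mask: Optional[np.ndarray] = None,
    variant: str = "invariant",
) -> GLCMDistribution:
    """Quantize an image and return its normalized GLCM in one call.

    Defaults to the semi-direction-invariant immediate-neighbor offsets
    for the image's dimensionality and the invariant (density)
    normalization.
    """
    arr = np.asarray(image)
    if offsets is None:
        offsets = standard_offsets(arr.ndim, semi_invariant=True)
    q = quantize(arr, spec)
    counts = cooccurrence_counts(q, offsets, spec.n_levels, mask=mask)
    if variant == "original":
        return normalize_pmf(counts)
    if variant == "invariant":
        return normalize_density(counts)
    raise ValueError(f"variant must be 'original' or 'invariant', got {variant!r}")
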