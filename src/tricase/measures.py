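"""Vector similarity and distance kernels for case retrieval.

The module provides the five classical kernels used as baselines in
case-based reasoning (cosine, Euclidean, Manhattan, Chebyshev, Hamming)
and the triangular similarity measure (TSM).

TSM scores the dissimilarity of two non-zero vectors ``OA`` and ``OB`` by
the area of the triangle they span, weighted by a magnitude-difference
coefficient.  With ``θ`` the included angle, the closed form is::

    tsm(a, b) = (ED(a, b) + | |a| - |b| |)^2 * (sin²θ + 0.001) * |a| * |b| / 4

where ``ED`` is the Euclidean distance.  The first factor is the squared
side of the coefficient triangle (Euclidean distance plus magnitude gap),
the ``sin²θ + 0.001`` term is the product of the two SAS sine factors with
an additive floor so that collinear-but-unequal vectors still receive a
positive dissimilarity, and ``|a||b|/4`` carries the triangle areas'
magnitudes.  The measure is zero exactly when ``a == b``; it separates
collinear vectors of different length (where cosine is blind) and
equidistant vectors at different angles (where Euclidean distance is
blind).

Raw dissimilarities are converted to percent similarity with the inverse
exponential ``exp(-raw)``, mapping [0, ∞) onto (0, 1] with identity at
100 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MEASURES",
    "SIN2_FLOOR",
    "AngleMeasure",
    "DegenerateVectorError",
    "DimensionMismatchError",
    "magnitude",
    "cosine_similarity",
    "euclidean_distance",
    "manhattan_distance",
    "chebyshev_distance",
    "hamming_distance",
    "included_angle",
    "triangle_area",
    "coefficient_side",
    "magnitude_coefficient",
    "tsm_raw",
    "to_percent",
    "dissimilarity",
    "similarity_percent",
    "batch_dissimilarity",
]

#: Measure tokens accepted throughout the package.
MEASURES = ("tsm", "euclidean", "manhattan", "chebyshev", "cosine")

#: Additive floor on sin²θ in the TSM closed form. Keeps the score positive
#: for collinear vectors of different magnitude (sin θ = 0 there).
SIN2_FLOOR = 0.001


class DimensionMismatchError(ValueError):
    """Operands have different lengths, or a vector is empty."""


class DegenerateVectorError(ValueError):
    """A zero-magnitude vector was passed to an angle-dependent measure."""


def _as_vector(v: Sequence[float]) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise DimensionMismatchError(
            f"expected a non-empty 1-d vector, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"vector contains non-finite components: {arr!r}")
    return arr


def _as_pair(a: Sequence[float], b: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    av, bv = _as_vector(a), _as_vector(b)
    if av.shape != bv.shape:
        raise DimensionMismatchError(
            f"dimension mismatch: {av.size} vs {bv.size}"
        )
    return av, bv


def magnitude(v: Sequence[float]) -> float:
    """Euclidean norm ``sqrt(Σ vᵢ²)`` of a vector."""
    return float(np.linalg.norm(_as_vector(v)))


def _require_nonzero(av: np.ndarray, bv: np.ndarray) -> tuple[float, float]:
    na, nb = float(np.linalg.norm(av)), float(np.linalg.norm(bv))
    if na == 0.0 or nb == 0.0:
        raise DegenerateVectorError(
            "zero-magnitude vector: the included angle is undefined"
        )
    return na, nb


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """cos θ between two non-zero vectors, clamped into [-1, 1].

    The denominator is computed as ``sqrt((a·a)(b·b))`` rather than as a
    product of two norms: for exactly scaled (collinear) operands the
    quotient then rounds to ±1 exactly.
    """
    av, bv = _as_pair(a, b)
    _require_nonzero(av, bv)
    denom = math.sqrt(float(av @ av) * float(bv @ bv))
    return float(np.clip(float(av @ bv) / denom, -1.0, 1.0))


def euclidean_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Straight-line distance ``sqrt(Σ (aᵢ - bᵢ)²)``."""
    av, bv = _as_pair(a, b)
    return float(np.linalg.norm(av - bv))


def manhattan_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """City-block distance ``Σ |aᵢ - bᵢ|``."""
    av, bv = _as_pair(a, b)
    return float(np.abs(av - bv).sum())


def chebyshev_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Greatest per-coordinate difference ``max |aᵢ - bᵢ|``."""
    av, bv = _as_pair(a, b)
    return float(np.abs(av - bv).max())


def hamming_distance(a: Sequence, b: Sequence) -> int:
    """Number of positions at which two equal-length token sequences differ."""
    if len(a) == 0:
        raise DimensionMismatchError("empty sequence")
    if len(a) != len(b):
        raise DimensionMismatchError(
            f"length mismatch: {len(a)} vs {len(b)}"
        )
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass(frozen=True)
class AngleMeasure:
    """Included angle between two vectors.

    ``sin_value`` is derived as ``sqrt(1 - cos²)`` (non-negative since
    θ ∈ [0, π]), which is numerically better behaved than
    ``sin(arccos(cos))`` near the endpoints.
    """

    cos_value: float
    sin_value: float
    theta: float


def included_angle(a: Sequence[float], b: Sequence[float]) -> AngleMeasure:
    """Angle θ ∈ [0, π] between two non-zero vectors."""
    c = cosine_similarity(a, b)
    s = math.sqrt(max(0.0, 1.0 - c * c))
    return AngleMeasure(cos_value=c, sin_value=s, theta=math.acos(c))


def triangle_area(a: Sequence[float], b: Sequence[float]) -> float:
    """Area of the triangle spanned by the two vectors (SAS formula).

    ``|a| * |b| * sin θ / 2``; zero exactly when the vectors are collinear.
    """
    av, bv = _as_pair(a, b)
    na, nb = _require_nonzero(av, bv)
    return na * nb * included_angle(av, bv).sin_value / 2.0


def coefficient_side(a: Sequence[float], b: Sequence[float]) -> float:
    """Side length of the magnitude-coefficient triangle.

    Euclidean distance plus the absolute magnitude difference; zero exactly
    when the two vectors coincide.
    """
    av, bv = _as_pair(a, b)
    return euclidean_distance(av, bv) + abs(
        float(np.linalg.norm(av)) - float(np.linalg.norm(bv))
    )


def magnitude_coefficient(a: Sequence[float], b: Sequence[float]) -> float:
    """Area of the coefficient triangle: ``side² * sin θ / 2``.

    The coefficient triangle is isosceles with both legs equal to
    :func:`coefficient_side` and apex angle θ, so its SAS area is
    ``side * side * sin θ / 2``.
    """
    av, bv = _as_pair(a, b)
    _require_nonzero(av, bv)
    side = coefficient_side(av, bv)
    return side * side * included_angle(av, bv).sin_value / 2.0


def tsm_raw(a: Sequence[float], b: Sequence[float]) -> float:
    """Triangular-similarity dissimilarity (closed form).

    ``(ED + |Δmag|)² * (sin²θ + 0.001) * |a| * |b| / 4``.  Symmetric,
    non-negative, and zero exactly when ``a == b``.
    """
    av, bv = _as_pair(a, b)
    na, nb = _require_nonzero(av, bv)
    side = euclidean_distance(av, bv) + abs(na - nb)
    sin2 = max(0.0, 1.0 - cosine_similarity(av, bv) ** 2)
    return side * side * (sin2 + SIN2_FLOOR) * na * nb / 4.0


def to_percent(dissim: float) -> float:
    """Inverse-exponential conversion ``exp(-d)`` of a raw dissimilarity.

    Maps [0, ∞) monotonically onto (0, 1]; exactly 1 (100 %) iff ``d == 0``.
    """
    if dissim < 0:
        raise ValueError(f"dissimilarity must be non-negative, got {dissim}")
    return math.exp(-dissim)


def dissimilarity(
    a: Sequence[float],
    b: Sequence[float],
    measure: str,
    cosine_dialect: str = "shifted",
) -> float:
    """Raw dissimilarity of ``a`` and ``b`` under a named measure.

    For the angle measure, ``cosine_dialect="shifted"`` (default) uses
    ``1 - cos θ`` so that more-similar pairs get a smaller dissimilarity and
    hence a larger percent.  ``"paper"`` feeds ``cos θ`` itself into the
    inverse exponential, which inverts the ranking direction; it is kept
    only as a dialect for comparison and raises on negative cosines, since
    the percent contract requires a non-negative input.
    """
    if measure == "tsm":
        return tsm_raw(a, b)
    if measure == "euclidean":
        return euclidean_distance(a, b)
    if measure == "manhattan":
        return manhattan_distance(a, b)
    if measure == "chebyshev":
        return chebyshev_distance(a, b)
    if measure == "cosine":
        av, bv = _as_pair(a, b)
        c = cosine_similarity(av, bv)
        if np.array_equal(av, bv):
            c = 1.0  # identical vectors: zero angle, exactly
        if cosine_dialect == "shifted":
            return max(0.0, 1.0 - c)
        if cosine_dialect == "paper":
            if c < 0:
                raise ValueError(
                    "paper cosine dialect undefined for negative cosines"
                )
            return c
        raise ValueError(f"unknown cosine dialect: {cosine_dialect!r}")
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")


def similarity_percent(
    a: Sequence[float],
    b: Sequence[float],
    measure: str,
    cosine_dialect: str = "shifted",
) -> float:
    """Percent similarity ``exp(-dissimilarity)`` under a named measure."""
    return to_percent(dissimilarity(a, b, measure, cosine_dialect))


def batch_dissimilarity(
    query: Sequence[float],
    candidates: np.ndarray,
    measure: str,
    cosine_dialect: str = "shifted",
) -> np.ndarray:
    """Vectorised raw dissimilarity of one query against a candidate matrix.

    ``candidates`` is an ``(m, n)`` array of row vectors.  Returns an
    ``(m,)`` array equal, element-wise, to calling :func:`dissimilarity`
    per row (the scalar path is the oracle in the test suite).
    """
    q = _as_vector(query)
    c = np.asarray(candidates, dtype=float)
    if c.ndim != 2 or c.shape[1] != q.size:
        raise DimensionMismatchError(
            f"candidate matrix shape {c.shape} incompatible with query of size {q.size}"
        )
    diff = c - q
    if measure == "euclidean":
        return np.linalg.norm(diff, axis=1)
    if measure == "manhattan":
        return np.abs(diff).sum(axis=1)
    if measure == "chebyshev":
        return np.abs(diff).max(axis=1)

    nq = float(np.linalg.norm(q))
    nc = np.linalg.norm(c, axis=1)
    if nq == 0.0 or np.any(nc == 0.0):
        raise DegenerateVectorError(
            "zero-magnitude vector: the included angle is undefined"
        )
    # sqrt of the squared-norm product keeps collinear rows at exactly ±1
    cos = np.clip((c @ q) / np.sqrt((c * c).sum(axis=1) * float(q @ q)), -1.0, 1.0)
    cos[np.all(c == q, axis=1)] = 1.0  # identical vectors: zero angle, exactly
    if measure == "cosine":
        if cosine_dialect == "shifted":
            return np.maximum(0.0, 1.0 - cos)
        if cosine_dialect == "paper":
            if np.any(cos < 0):
                raise ValueError(
                    "paper cosine dialect undefined for negative cosines"
                )
            return cos
        raise ValueError(f"unknown cosine dialect: {cosine_dialect!r}")
    if measure == "tsm":
        ed = np.linalg.norm(diff, axis=1)
        side = ed + np.abs(nc - nq)
        sin2 = np.maximum(0.0, 1.0 - cos * cos)
        return side * side * (sin2 + SIN2_FLOOR) * nc * nq / 4.0
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
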