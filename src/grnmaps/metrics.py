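"""Statistics on parameter-to-phenotype maps.

Slopes are ordinary least squares of T2 on T1 over the viable map points,
log-compressed as ``S_a = sgn(S) * ln(1 + |S|)`` so that steep positive and
negative responses remain comparable. Map pairs are classified by the angular
sector of their (transformed) slope pair. Map dissimilarity is the paired
Euclidean distance; map complexity is the residual sum of squares around the
line ``y = S x`` after min-max rescaling both traits to the unit interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as _scipy_stats

INSENSITIVITY_THRESHOLD = 0.01  # on the raw slope
SECTOR_HALF_WIDTH = math.pi / 12


@dataclass
class MapStats:
    raw_slope: float | None
    transformed_slope: float | None
    complexity: float | None
    degenerate: bool = False


@dataclass(frozen=True)
class PairClassification:
    label: str  # correlated | anticorrelated | uncorrelated | insensitive_first | insensitive_second

    LABELS = ("correlated", "anticorrelated", "uncorrelated", "insensitive_first", "insensitive_second")


def _viable_points(map_or_points) -> np.ndarray:
    """Accept a PhenotypeMap or a raw (n, 2+) point array."""
    if hasattr(map_or_points, "viable_points"):
        return np.asarray(map_or_points.viable_points(), dtype=float)
    return np.asarray(map_or_points, dtype=float)


def fit_slope(map_or_points) -> float:
    """OLS slope of T2 on T1 over viable points.

    Raises ``ValueError`` (degenerate map) with < 2 points or zero T1 variance.
    """
    pts = _viable_points(map_or_points)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("slope needs at least 2 viable points")
    x, y = pts[:, 0], pts[:, 1]
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0:
        raise ValueError("degenerate map: zero variance in T1")
    return float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)


def transform_slope(s: float) -> float:
    """``S_a = sgn(S) * ln(1 + |S|)``; odd and strictly monotone."""
    return float(np.sign(s) * np.log1p(abs(s)))


def inverse_transform_slope(s_a: float) -> float:
    return float(np.sign(s_a) * np.expm1(abs(s_a)))


def _angular_distance(theta: float, target: float) -> float:
    """Distance between angles modulo pi (slopes are line directions)."""
    d = (theta - target) % math.pi
    return min(d, math.pi - d)


def classify_pair(
    s_a_first: float,
    s_a_second: float,
    insensitivity_threshold: float = INSENSITIVITY_THRESHOLD,
) -> PairClassification:
    """Sector classification of a (transformed) slope pair.

    Insensitivity (|S| <= 0.01 on the raw scale) takes precedence; otherwise
    the pair is correlated when the direction of (S_a_second, S_a_first) lies
    within pi/12 of the diagonal (mod pi), anticorrelated within pi/12 of the
    antidiagonal, and uncorrelated elsewhere.
    """
    raw_first = abs(inverse_transform_slope(s_a_first))
    raw_second = abs(inverse_transform_slope(s_a_second))
    if raw_first <= insensitivity_threshold:
        return PairClassification("insensitive_first")
    if raw_second <= insensitivity_threshold:
        return PairClassification("insensitive_second")
    theta = math.atan2(s_a_first, s_a_second)
    if _angular_distance(theta, math.pi / 4) <= SECTOR_HALF_WIDTH:
        return PairClassification("correlated")
    if _angular_distance(theta, -math.pi / 4) <= SECTOR_HALF_WIDTH:
        return PairClassification("anticorrelated")
    return PairClassification("uncorrelated")


def euclidean_distance(map_a, map_b) -> float:
    """Root summed squared trait differences over grid-paired points."""
    a = _viable_points(map_a)
    b = _viable_points(map_b)
    if a.shape != b.shape:
        raise ValueError("maps must have the same number of paired points")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def rescale_unit(points: np.ndarray) -> np.ndarray:
    """Min-max rescale each trait column to [0, 1].

    Raises ``ValueError`` for a zero-range (constant) trait.
    """
    pts = np.asarray(points, dtype=float)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = hi - lo
    if (span <= 0).any():
        raise ValueError("degenerate map: zero-range trait cannot be rescaled")
    return (pts - lo) / span


def complexity(map_or_points) -> float:
    """Non-linearity: residual sum around ``y = S x`` on unit-rescaled points.

    Invariant to affine rescaling of the raw trait units; zero iff the
    rescaled points fall exactly on the fitted line through the origin.
    """
    pts = _viable_points(map_or_points)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("complexity needs at least 2 viable points")
    scaled = rescale_unit(pts[:, :2])
    x, y = scaled[:, 0], scaled[:, 1]
    s = fit_slope(scaled)
    return float(np.sum((y - x * s) ** 2))


def map_stats(map_or_points) -> MapStats:
    """Slope, transformed slope and complexity with degeneracy handling."""
    try:
        s = fit_slope(map_or_points)
        c = complexity(map_or_points)
    except ValueError:
        return MapStats(None, None, None, degenerate=True)
    return MapStats(raw_slope=s, transformed_slope=transform_slope(s), complexity=c)


def pearson(xs, ys) -> float:
    """Product-moment correlation; undefined for n < 3 or zero variance."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 3:
        raise ValueError("pearson needs >= 3 paired values")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    return float(_scipy_stats.pearsonr(xs, ys).statistic)


def composite_slope(points: np.ndarray) -> float:
    """Method-1: average sub-traits into two composites, then OLS slope.

    With an odd number of traits the first ``ceil(N_t/2)`` go to the first
    composite.
    """
    pts = np.asarray(points, dtype=float)
    n_t = pts.shape[1]
    half = (n_t + 1) // 2
    t1 = pts[:, :half].mean(axis=1)
    t2 = pts[:, half:].mean(axis=1)
    return fit_slope(np.column_stack([t1, t2]))


def averaged_slope(points: np.ndarray) -> float:
    """Method-2: mean pairwise OLS slope over unordered trait pairs i < j."""
    pts = np.asarray(points, dtype=float)
    n_t = pts.shape[1]
    slopes = [
        fit_slope(np.column_stack([pts[:, i], pts[:, j]]))
        for i, j in combinations(range(n_t), 2)
    ]
    return float(np.mean(slopes))


def multitrait_euclidean(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Method-3: trait-dimension-normalized Euclidean distance between maps."""
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have the same number of paired points")
    n_t = a.shape[1]
    return float(np.sqrt(np.sum((a - b) ** 2 / n_t)))


def multitrait_stats(points_a, points_b=None, method: str = "composite"):
    """Dispatch the three multi-trait comparison methods."""
    if method == "composite":
        return composite_slope(points_a)
    if method == "averaged_slopes":
        return averaged_slope(points_a)
    if method == "euclidean":
        if points_b is None:
            raise ValueError("euclidean method compares two maps")
        return multitrait_euclidean(points_a, points_b)
    raise ValueError(f"unknown multi-trait method {method!r}")
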