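"""Averaging corresponding loops into a mean contour with dispersion.

Thirty trial loops per area (10 subjects x 3 trials) are averaged point
by point.  Correspondence is established against a reference loop (the
loop of median perimeter): for every reference vertex index i, the
nearest vertex of each other loop is matched to it.  The mean point
P̄_i over the matched set defines the averaged contour; per-coordinate
Student-t confidence half-widths (δx, δy) quantify inter-trial spread.

Each area is then summarised by four *control points* — the extreme
mean points in x and y — whose positional uncertainty is summarised by
the confidence diagonal

    Δ = 2 · sqrt(δx² + δy²)

the distance between the two opposite corners (x±δx, y±δy) of the
confidence box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .errors import ConfigError, DataQualityError
from .extraction import ResampledLoop

__all__ = [
    "MeanContour",
    "ControlPoint",
    "correspond_loops",
    "mean_contour",
    "control_points",
    "delta_interval",
    "bbox_metrics",
    "mean_delta",
    "round_half_away",
    "ContourAverager",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (406.5 -> 407)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class MeanContour:
    """Averaged contour: mean points plus per-point confidence half-widths."""

    mean_points: np.ndarray  # (m, 2)
    dx: np.ndarray  # (m,) confidence half-width of the mean, x
    dy: np.ndarray  # (m,) confidence half-width of the mean, y
    n: int
    p: float
    area: object = None

    def __post_init__(self) -> None:
        self.mean_points = np.asarray(self.mean_points, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        m = len(self.mean_points)
        if self.dx.shape != (m,) or self.dy.shape != (m,):
            raise ConfigError("dx/dy must have one entry per mean point")
        if np.any(self.dx < 0) or np.any(self.dy < 0):
            raise ConfigError("confidence half-widths must be >= 0")
        if self.n < 2:
            raise ConfigError("a mean contour requires n >= 2 loops")
        if not 0 < self.p < 1:
            raise ConfigError("confidence level p must lie in (0, 1)")


@dataclass(frozen=True)
class ControlPoint:
    """An extreme point of a mean contour with its uncertainty summary."""

    point_id: str
    x: float
    y: float
    dx: float
    dy: float
    delta: float
    n: int
    p: float

    @property
    def delta_mm(self) -> int:
        """Δ rounded to the nearest millimetre (half away from zero)."""
        return round_half_away(self.delta)

    def as_dict(self) -> dict:
        return {
            "id": self.point_id,
            "x": self.x,
            "y": self.y,
            "dx": self.dx,
            "dy": self.dy,
            "delta": self.delta_mm,
            "n": self.n,
            "p": self.p,
        }


def delta_interval(dx: float, dy: float) -> float:
    """Confidence diagonal Δ = 2·sqrt(δx² + δy²) (mm, unrounded).

    This is the closed form of the distance between the opposite corners
    (x−δx, y−δy) and (x+δx, y+δy) of a control point's confidence box.
    """
    if dx < 0 or dy < 0:
        raise ConfigError("confidence half-widths must be >= 0")
    return 2.0 * math.hypot(dx, dy)


def _loop_key(loop: ResampledLoop) -> tuple:
    return (str(getattr(loop, "subject_id", "")), str(getattr(loop, "trial_id", "")))


def correspond_loops(
    loops: Sequence[ResampledLoop],
) -> tuple[int, np.ndarray]:
    """Match every loop to a common reference loop, vertex by vertex.

    The reference is the loop of median perimeter rank (ties broken by
    the lower subject/trial label).  Returns ``(ref_index, matched)``
    where ``matched[j, i]`` is the vertex of loop j nearest to reference
    vertex i (``matched[ref]`` is the reference itself).
    """
    if len(loops) < 2:
        raise DataQualityError("need >= 2 loops to correspond")
    m = len(loops[0].vertices)
    areas = {str(getattr(lp, "area", None)) for lp in loops}
    if len(areas) > 1:
        raise DataQualityError(f"loops of mixed areas cannot be averaged: {areas}")
    for lp in loops:
        if len(lp.vertices) != m:
            raise DataQualityError("all loops must have the same vertex count")
    order = sorted(
        range(len(loops)), key=lambda j: (loops[j].perimeter, _loop_key(loops[j]), j)
    )
    ref = order[(len(loops) - 1) // 2]
    ref_pts = loops[ref].vertices
    matched = np.empty((len(loops), m, 2), dtype=float)
    for j, lp in enumerate(loops):
        if j == ref:
            matched[j] = ref_pts
            continue
        _, idx = cKDTree(lp.vertices).query(ref_pts)
        matched[j] = lp.vertices[idx]
    return ref, matched


def mean_contour(
    loops: Sequence[ResampledLoop], p: float = 0.05
) -> MeanContour:
    """Coordinate-wise mean of corresponding points with t half-widths.

    ``p`` is the two-sided significance level: half-widths are
    ``t_{1-p/2, n-1} · s / sqrt(n)`` per coordinate, i.e. 95% confidence
    intervals of the mean for the default p = 0.05.
    """
    if len(loops) < 2:
        raise DataQualityError("dispersion needs at least 2 loops")
    if not 0 < p < 1:
        raise ConfigError("p must lie in (0, 1)")
    _, matched = correspond_loops(loops)
    n = matched.shape[0]
    mean = matched.mean(axis=0)
    sd = matched.std(axis=0, ddof=1)
    tq = stats.t.ppf(1.0 - p / 2.0, df=n - 1)
    half = tq * sd / math.sqrt(n)
    area = getattr(loops[0], "area", None)
    return MeanContour(
        mean_points=mean, dx=half[:, 0], dy=half[:, 1], n=n, p=p, area=area
    )


def control_points(contour: MeanContour) -> list[ControlPoint]:
    """The four extreme mean points: max x, min x, max y, min y.

    Labels A1..A4 follow that fixed order; ties resolve to the first
    vertex index.  Each point carries its own per-point half-widths and
    the confidence diagonal Δ.
    """
    pts = contour.mean_points
    idx = [
        int(np.argmax(pts[:, 0])),
        int(np.argmin(pts[:, 0])),
        int(np.argmax(pts[:, 1])),
        int(np.argmin(pts[:, 1])),
    ]
    out = []
    for label, i in zip(("A1", "A2", "A3", "A4"), idx):
        dx, dy = float(contour.dx[i]), float(contour.dy[i])
        out.append(
            ControlPoint(
                point_id=label,
                x=float(pts[i, 0]),
                y=float(pts[i, 1]),
                dx=dx,
                dy=dy,
                delta=delta_interval(dx, dy),
                n=contour.n,
                p=contour.p,
            )
        )
    return out


def bbox_metrics(points: Sequence[ControlPoint]) -> tuple[float, float]:
    """(length, height): x- and y-extent of a set of control points, mm."""
    xs = [cp.x for cp in points]
    ys = [cp.y for cp in points]
    return (max(xs) - min(xs), max(ys) - min(ys))


def mean_delta(points: Sequence[ControlPoint]) -> int:
    """Arithmetic mean of the rounded Δ values, rounded to the nearest mm."""
    if not points:
        raise ConfigError("mean_delta needs at least one control point")
    return round_half_away(
        sum(cp.delta_mm for cp in points) / len(points)
    )


class ContourAverager(BaseEstimator):
    """Fit an averaged contour to a set of corresponding loops.

    Parameters
    ----------
    p : float
        Two-sided significance level of the per-point confidence
        intervals (0.05 -> 95%).

    Attributes (after :meth:`fit`)
    ------------------------------
    mean_contour_ : MeanContour
    control_points_ : list of ControlPoint
    reference_index_ : int
    """

    def __init__(self, p: float = 0.05):
        self.p = p

    def fit(self, X: Sequence[ResampledLoop], y=None):
        self.reference_index_, _ = correspond_loops(X)
        self.mean_contour_ = mean_contour(X, p=self.p)
        self.control_points_ = control_points(self.mean_contour_)
        return self

    def bbox(self) -> tuple[float, float]:
        return bbox_metrics(self.control_points_)

    def mean_delta(self) -> int:
        return mean_delta(self.control_points_)
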