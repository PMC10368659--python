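"""Closed-boundary extraction: alpha shape, canonical form, resampling.

A trial's point cloud is reduced to a single simple, counter-clockwise
boundary loop via the alpha-shape construction (Delaunay triangulation
with large-circumradius triangles removed), then resampled to a fixed
number of arc-length-uniform vertices so that loops from different
trials can be put into correspondence.

Alpha convention
----------------
The dimensionless ``alpha`` is interpreted as the *inverse* circumradius
threshold in units of the cloud's RMS radius about its centroid:
triangles with circumradius above ``rms_radius / alpha`` are removed.
``alpha -> 0`` therefore keeps every triangle and returns the convex
hull; larger alpha carves deeper concavities.  A raw millimetre
threshold can be supplied instead via ``radius_override``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import LinearRing, Polygon
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, DataQualityError, DegenerateAlphaError
from .simulate import PointCloud

__all__ = [
    "Loop",
    "ResampledLoop",
    "alpha_boundary",
    "auto_alpha",
    "canonicalize",
    "resample_loop",
    "AlphaContourExtractor",
    "DEFAULT_ALPHA_BAND",
]

DEFAULT_ALPHA_BAND = (0.7, 0.9)
DEFAULT_MIN_ENCLOSURE = 0.95


@dataclass
class Loop:
    """A simple closed polyline (implicitly closed, CCW when canonical)."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise DataQualityError("a loop needs an (n>=3, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise DataQualityError("loop vertices must be finite")
        self.vertices = v

    @property
    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def is_simple(self) -> bool:
        try:
            return bool(LinearRing(self.vertices).is_simple)
        except Exception:  # degenerate ring
            return False


@dataclass
class ResampledLoop(Loop):
    """Canonical loop resampled to ``n`` arc-length-uniform vertices.

    Vertex ``i`` is the loop's point index used for cross-trial
    correspondence; index 0 is the canonical start (max x, tie max y).
    """

    subject_id: str = ""
    trial_id: str = ""
    area: Any = None
    alpha_used: float | None = None


def _as_points(cloud: PointCloud | np.ndarray) -> np.ndarray:
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DataQualityError("expected an (n, 2) point array")
    if len(pts) < 3:
        raise DataQualityError("need >= 3 points for boundary extraction")
    if not np.all(np.isfinite(pts)):
        raise DataQualityError("point cloud contains non-finite coordinates")
    return pts


def _circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    area2 = np.abs(cross)  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def _triangle_components(keep_idx: np.ndarray, neighbors: np.ndarray) -> list[np.ndarray]:
    """Connected components (edge adjacency) of the kept triangles."""
    keep_set = {int(i): k for k, i in enumerate(keep_idx)}
    n = len(keep_idx)
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            k = stack.pop()
            comp.append(k)
            for nb in neighbors[keep_idx[k]]:
                j = keep_set.get(int(nb))
                if j is not None and not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(keep_idx[np.asarray(comp)])
    return comps


def _boundary_loops(pts: np.ndarray, simplices: np.ndarray) -> list[np.ndarray]:
    """Vertex-index loops bounding a set of triangles.

    Boundary edges appear in exactly one triangle; they are chained by
    walking directed edges (each triangle contributes its edges CCW, so
    boundary edges form consistent directed cycles).
    """
    # orient every triangle CCW so directed boundary edges chain head->tail
    a, b, c = simplices[:, 0], simplices[:, 1], simplices[:, 2]
    cross = (pts[b, 0] - pts[a, 0]) * (pts[c, 1] - pts[a, 1]) - (
        pts[b, 1] - pts[a, 1]
    ) * (pts[c, 0] - pts[a, 0])
    tris = simplices.copy()
    flip = cross < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    edges: dict[tuple[int, int], int] = {}
    for t in tris:
        for i in range(3):
            e = (int(t[i]), int(t[(i + 1) % 3]))
            key = (min(e), max(e))
            edges[key] = edges.get(key, 0) + 1
    boundary = set()
    directed: dict[int, list[int]] = {}
    for t in tris:
        for i in range(3):
            u, v = int(t[i]), int(t[(i + 1) % 3])
            if edges[(min(u, v), max(u, v))] == 1:
                boundary.add((u, v))
                directed.setdefault(u, []).append(v)
    loops = []
    visited: set[tuple[int, int]] = set()
    for e0 in sorted(boundary):
        if e0 in visited:
            continue
        u, v = e0
        loop = [u]
        while True:
            visited.add((u, v))
            loop.append(v)
            nxts = [w for w in directed.get(v, []) if (v, w) not in visited]
            if not nxts:
                break
            # prefer the continuation that keeps the boundary to the left
            u, v = v, nxts[0]
            if v == loop[0]:
                visited.add((u, v))
                loop.append(v)
                break
        if len(loop) > 3 and loop[0] == loop[-1]:
            loops.append(np.asarray(loop[:-1], dtype=int))
    return loops


def _extract_once(
    pts: np.ndarray, tri: Delaunay, radii: np.ndarray, r_thresh: float
) -> Loop | None:
    keep = np.flatnonzero(radii <= r_thresh)
    if len(keep) == 0:
        return None
    comps = _triangle_components(keep, tri.neighbors)
    # largest component by total triangle area
    def comp_area(idx: np.ndarray) -> float:
        s = tri.simplices[idx]
        a, b, c = pts[s[:, 0]], pts[s[:, 1]], pts[s[:, 2]]
        return float(
            0.5
            * np.abs(
                (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
            ).sum()
        )

    comps.sort(key=comp_area, reverse=True)
    loops = _boundary_loops(pts, tri.simplices[comps[0]])
    if not loops:
        return None
    # outermost ring: the one enclosing the largest absolute area
    best, best_area = None, -1.0
    for idx in loops:
        lp = Loop(pts[idx])
        if abs(lp.signed_area) > best_area:
            best, best_area = lp, abs(lp.signed_area)
    if best is None or not best.is_simple():
        return None
    return best


def alpha_boundary(
    cloud: PointCloud | np.ndarray,
    alpha: float,
    *,
    radius_override: float | None = None,
    min_enclosure: float = DEFAULT_MIN_ENCLOSURE,
    max_relax_steps: int = 10,
) -> Loop:
    """Outer alpha-shape boundary of a 2-D point cloud, as a canonical loop.

    Triangles of the Delaunay triangulation whose circumradius exceeds
    ``rms_radius / alpha`` (or ``radius_override`` mm) are removed; the
    outer boundary of the largest remaining component is returned.  If the
    boundary fails to enclose at least ``min_enclosure`` of the points
    (fragmented or over-carved complex), alpha is relaxed in 10% steps, up
    to ``max_relax_steps`` times.  Interior rings (holes) are discarded.
    """
    pts = _as_points(cloud)
    if radius_override is None and not alpha > 0:
        raise ConfigError("alpha must be > 0")
    pts_u = np.unique(pts, axis=0)
    if len(pts_u) < 3:
        raise DataQualityError("fewer than 3 distinct points")
    try:
        tri = Delaunay(pts_u)
    except QhullError as exc:
        raise DataQualityError(f"degenerate (collinear?) point cloud: {exc}") from exc
    radii = _circumradii(pts_u, tri.simplices)
    rms = float(np.sqrt(np.mean(np.sum((pts_u - pts_u.mean(axis=0)) ** 2, axis=1))))
    if radius_override is not None:
        r_thresh = float(radius_override)
    elif rms == 0.0:
        raise DataQualityError("zero-extent point cloud")
    else:
        r_thresh = rms / alpha

    for _ in range(max_relax_steps + 1):
        loop = _extract_once(pts_u, tri, radii, r_thresh)
        if loop is not None:
            poly = Polygon(loop.vertices)
            if poly.is_valid and poly.area > 0:
                # tiny buffer so boundary vertices count as enclosed
                fat = poly.buffer(1e-6 * max(rms, 1.0))
                inside = shapely.contains_xy(fat, pts_u[:, 0], pts_u[:, 1])
                if inside.mean() >= min_enclosure:
                    return canonicalize(loop)
        r_thresh *= 1.1  # relax: more permissive threshold
    raise DegenerateAlphaError(
        "no simple boundary enclosing the required point fraction was found"
    )


def auto_alpha(
    cloud: PointCloud | np.ndarray,
    band: tuple[float, float] = DEFAULT_ALPHA_BAND,
    *,
    spacing_ref: float = 0.2,
) -> float:
    """Choose alpha within ``band`` from the cloud's point density.

    The density statistic is the median nearest-neighbour distance in
    units of the cloud RMS radius; sparser clouds map monotonically to
    the more permissive (smaller) end of the band.  Deterministic.
    """
    pts = _as_points(cloud)
    lo, hi = band
    if not 0 < lo <= hi:
        raise ConfigError("alpha band must satisfy 0 < lo <= hi")
    rms = float(np.sqrt(np.mean(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1))))
    if rms == 0:
        return hi
    d, _ = cKDTree(pts).query(pts, k=2)
    rho = float(np.median(d[:, 1])) / rms
    frac = min(rho / spacing_ref, 1.0)
    return float(hi - (hi - lo) * frac)


def canonicalize(loop: Loop) -> Loop:
    """Canonical form: CCW orientation, start at max-x vertex (tie: max y)."""
    if not loop.is_simple():
        raise DataQualityError("loop is self-intersecting")
    v = loop.vertices
    if loop.signed_area < 0:
        v = v[::-1]
    elif loop.signed_area == 0:
        raise DataQualityError("loop has zero enclosed area")
    start = np.lexsort((v[:, 1], v[:, 0]))[-1]  # max x, tie max y
    v = np.roll(v, -start, axis=0)
    out = Loop(v.copy())
    if isinstance(loop, ResampledLoop):
        return ResampledLoop(
            v.copy(),
            subject_id=loop.subject_id,
            trial_id=loop.trial_id,
            area=loop.area,
            alpha_used=loop.alpha_used,
        )
    return out


def resample_loop(loop: Loop, n: int = 100) -> ResampledLoop:
    """Resample a canonical loop to ``n`` arc-length-uniform vertices.

    Vertex 0 coincides with the canonical start; consecutive vertices are
    separated by perimeter/n of arc length along the source polyline.
    """
    if n < 3:
        raise ConfigError("n must be >= 3")
    loop = canonicalize(loop)
    closed = np.vstack([loop.vertices, loop.vertices[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise DataQualityError("zero-perimeter loop")
    targets = np.arange(n) * total / n
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    meta = {}
    if isinstance(loop, ResampledLoop):
        meta = dict(
            subject_id=loop.subject_id,
            trial_id=loop.trial_id,
            area=loop.area,
            alpha_used=loop.alpha_used,
        )
    return ResampledLoop(np.column_stack([x, y]), **meta)


class AlphaContourExtractor(BaseEstimator, TransformerMixin):
    """Point cloud -> canonical 100-point boundary loop, sklearn style.

    Parameters
    ----------
    alpha : float or None
        Alpha value; ``None`` selects one from ``alpha_band`` by cloud
        density (see :func:`auto_alpha`).
    alpha_band : (float, float)
        Admissible alpha range for automatic selection.
    radius_override : float or None
        Raw circumradius threshold in mm, bypassing the normalized alpha.
    n_points : int
        Number of arc-length-uniform vertices of the output loop.
    min_enclosure : float
        Minimum fraction of cloud points the boundary must enclose.
    """

    def __init__(
        self,
        alpha: float | None = None,
        alpha_band: tuple[float, float] = DEFAULT_ALPHA_BAND,
        radius_override: float | None = None,
        n_points: int = 100,
        min_enclosure: float = DEFAULT_MIN_ENCLOSURE,
    ):
        self.alpha = alpha
        self.alpha_band = alpha_band
        self.radius_override = radius_override
        self.n_points = n_points
        self.min_enclosure = min_enclosure

    def fit(self, X, y=None):
        pts = _as_points(X)
        if self.alpha is not None:
            self.alpha_ = float(self.alpha)
        else:
            self.alpha_ = auto_alpha(pts, self.alpha_band)
        return self

    def transform(self, X) -> np.ndarray:
        """Return the (n_points, 2) resampled boundary of cloud ``X``."""
        if not hasattr(self, "alpha_"):
            raise DataQualityError("extractor is not fitted")
        loop = alpha_boundary(
            X,
            self.alpha_,
            radius_override=self.radius_override,
            min_enclosure=self.min_enclosure,
        )
        res = resample_loop(loop, self.n_points)
        if isinstance(X, PointCloud):
            res.subject_id = X.subject_id
            res.trial_id = X.trial_id
            res.area = X.area
        res.alpha_used = self.alpha_
        self.loop_ = res
        return res.vertices

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X).transform(X)


def extract_resampled(
    cloud: PointCloud | np.ndarray,
    alpha: float | None = None,
    n_points: int = 100,
    **kwargs,
) -> ResampledLoop:
    """One-call convenience: cloud -> canonical resampled loop."""
    ext = AlphaContourExtractor(alpha=alpha, n_points=n_points, **kwargs)
    ext.fit_transform(cloud)
    return ext.loop_
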