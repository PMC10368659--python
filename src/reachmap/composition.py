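"""Overlay of averaged reach areas on the wheelchair's geometric features.

The wheelchair is described by horizontal levels (lower/upper frame FDL,
FUL; armrest ARL; seat SL; shoulder SH ± δSH), the backrest plane SBV
(a vertical line) and the rear-wheel spinning disc WB (a full disc about
the wheel axis — hands must avoid the whole swept region).  The averaged
AoC/AoA/AoR envelopes are nested, so the final map carves them into
three disjoint bands by priority (shorter chains claim shared territory)
and removes the obstacles:

    band(AoC) = AoC − WB − AoP
    band(AoA) = AoA − AoC − WB − AoP
    band(AoR) = AoR − AoA − AoC − WB − AoP

all clipped to y >= FDL.  Everything is in millimetres, wheel-axis frame.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union
from sklearn.base import BaseEstimator

from .averaging import MeanContour
from .errors import ConfigError, DataQualityError
from .simulate import AreaKind

__all__ = [
    "WheelchairGeometry",
    "ZonePolygon",
    "ReachMap",
    "geometry_from_config",
    "subtract_regions",
    "compose_map",
    "export_map_points",
    "anthropometric_checks",
    "ReachMapComposer",
]

#: vertex-snapping tolerance for boolean robustness (mm)
SNAP_TOL = 1e-6
#: wheel-disc discretization step (degrees)
WB_STEP_DEG = 1.0


@dataclass(frozen=True)
class WheelchairGeometry:
    """Parametric features of the human–wheelchair system (mm levels).

    Defaults describe a cross-frame semi-active wheelchair with a
    50th-percentile occupant: FDL = −30, FUL = 170, ARL = 420, SL = 190,
    SH = 730 ± 30, backrest plane at x = 80, wheel radius 300 about the
    origin.
    """

    fdl: float = -30.0
    ful: float = 170.0
    arl: float = 420.0
    sl: float = 190.0
    sh: float = 730.0
    sh_halfwidth: float = 30.0
    sbv_x: float = 80.0
    wheel_radius: float = 300.0
    wheel_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.fdl < self.ful < self.arl:
            raise ConfigError("levels must satisfy FDL < FUL < ARL")
        if not self.sl < self.sh:
            raise ConfigError("seat level must lie below shoulder level")
        if not self.wheel_radius > 0:
            raise ConfigError("wheel radius must be > 0")
        if self.sh_halfwidth < 0:
            raise ConfigError("SH half-width must be >= 0")

    def wheel_disc(self) -> Polygon:
        """The rear-wheel spinning region as a 1°-discretized disc."""
        t = np.radians(np.arange(0.0, 360.0, WB_STEP_DEG))
        cx, cy = self.wheel_center
        ring = np.column_stack(
            [cx + self.wheel_radius * np.sin(t), cy + self.wheel_radius * np.cos(t)]
        )
        return Polygon(ring)

    def translate(self, dx: float, dy: float) -> "WheelchairGeometry":
        """The same chair, rigidly shifted (all levels, planes and wheel)."""
        return dataclasses.replace(
            self,
            fdl=self.fdl + dy,
            ful=self.ful + dy,
            arl=self.arl + dy,
            sl=self.sl + dy,
            sh=self.sh + dy,
            sbv_x=self.sbv_x + dx,
            wheel_center=(self.wheel_center[0] + dx, self.wheel_center[1] + dy),
        )

    def as_dict(self) -> dict:
        return {
            "FDL": self.fdl,
            "FUL": self.ful,
            "ARL": self.arl,
            "SL": self.sl,
            "SH": self.sh,
            "SH_halfwidth": self.sh_halfwidth,
            "SBV_x": self.sbv_x,
            "WB_radius": self.wheel_radius,
            "WB_center": list(self.wheel_center),
        }


_CONFIG_KEYS = {
    "fdl": "fdl",
    "ful": "ful",
    "arl": "arl",
    "sl": "sl",
    "sh": "sh",
    "sh_halfwidth": "sh_halfwidth",
    "sbv_x": "sbv_x",
    "wheel_radius": "wheel_radius",
    "wheel_center": "wheel_center",
}


def geometry_from_config(config: Mapping | None = None) -> WheelchairGeometry:
    """Build a geometry from a (possibly partial) config mapping.

    Keys are case-insensitive feature names (``fdl``/``FDL`` ...);
    omitted features keep their defaults.  Ordering violations raise
    :class:`ConfigError`.
    """
    cfg = {}
    for key, value in (config or {}).items():
        k = str(key).lower()
        if k not in _CONFIG_KEYS:
            raise ConfigError(f"unknown geometry key: {key!r}")
        if k == "wheel_center":
            value = tuple(float(v) for v in value)
        else:
            value = float(value)
        cfg[_CONFIG_KEYS[k]] = value
    return WheelchairGeometry(**cfg)


@dataclass
class ZonePolygon:
    """One composed map zone: outer ring, optional holes, annotations."""

    label: str
    ring: np.ndarray
    holes: list[np.ndarray] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def polygon(self) -> Polygon:
        if len(self.ring) < 3:
            return Polygon()
        return Polygon(self.ring, [h for h in self.holes if len(h) >= 3])

    @property
    def area(self) -> float:
        return self.polygon.area

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "ring": np.asarray(self.ring, dtype=float).tolist(),
            "holes": [np.asarray(h, dtype=float).tolist() for h in self.holes],
            "notes": list(self.notes),
        }


@dataclass
class ReachMap:
    """The composed accessory-mounting map: disjoint zones + geometry."""

    zones: list[ZonePolygon]
    geometry: WheelchairGeometry
    provenance: dict | None = None

    def zone(self, label: str) -> ZonePolygon:
        for z in self.zones:
            if z.label == label:
                return z
        raise KeyError(label)

    def to_json(self) -> str:
        return json.dumps(
            {
                "zones": [z.as_dict() for z in self.zones],
                "geometry": self.geometry.as_dict(),
                "provenance": self.provenance,
            },
            indent=1,
        )


def _clean(geom) -> Polygon | MultiPolygon:
    geom = shapely.set_precision(geom, SNAP_TOL)
    if not geom.is_valid:
        geom = shapely.make_valid(geom)
    return geom


def _largest_part(geom, label: str = "") -> Polygon:
    if geom.is_empty:
        return Polygon()
    if isinstance(geom, Polygon):
        return geom
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    if not polys:
        return Polygon()
    if len(polys) > 1:
        warnings.warn(
            f"zone {label or '?'} fragmented into {len(polys)} parts; "
            "keeping the largest",
            stacklevel=3,
        )
    return max(polys, key=lambda g: g.area)


def _to_polygon(obj) -> Polygon:
    if isinstance(obj, Polygon):
        return _largest_part(_clean(obj))
    if isinstance(obj, ZonePolygon):
        return _largest_part(_clean(obj.polygon), obj.label)
    if isinstance(obj, MeanContour):
        return _largest_part(_clean(Polygon(obj.mean_points)))
    arr = np.asarray(getattr(obj, "vertices", obj), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise DataQualityError("cannot interpret object as a polygon")
    return _largest_part(_clean(Polygon(arr)))


def _zone_from_polygon(label: str, poly: Polygon) -> ZonePolygon:
    if poly.is_empty:
        return ZonePolygon(label=label, ring=np.empty((0, 2)))
    return ZonePolygon(
        label=label,
        ring=np.asarray(poly.exterior.coords[:-1], dtype=float),
        holes=[np.asarray(h.coords[:-1], dtype=float) for h in poly.interiors],
    )


def subtract_regions(
    area_polygon: ZonePolygon | Polygon | np.ndarray,
    obstacles: Sequence[ZonePolygon | Polygon | np.ndarray],
) -> ZonePolygon:
    """Boolean difference of an area and a list of obstacle regions.

    If the difference fragments into several parts the largest is kept
    (with a warning).  An empty result is allowed and returned as an
    empty zone of zero area.
    """
    label = area_polygon.label if isinstance(area_polygon, ZonePolygon) else "zone"
    poly = _to_polygon(area_polygon)
    if obstacles:
        blob = unary_union([_to_polygon(o) for o in obstacles])
        poly = _largest_part(_clean(poly.difference(blob)), label)
    return _zone_from_polygon(label, poly)


def compose_map(
    mean_contours: Mapping[AreaKind | str, MeanContour | np.ndarray],
    geometry: WheelchairGeometry | None = None,
    provenance: dict | None = None,
) -> ReachMap:
    """Compose the final map from the four averaged areas.

    Requires AoC, AoA, AoR and AoP contours.  Removes the wheel disc and
    the propulsion area from every reach zone, resolves overlaps by
    priority AoC > AoA > AoR and clips below the lower frame level FDL.
    Zones overlapping the armrest strip (FUL..ARL) are annotated as
    removable-support territory.
    """
    geometry = geometry if geometry is not None else WheelchairGeometry()
    contours = {AreaKind.coerce(k): v for k, v in mean_contours.items()}
    missing = [a.value for a in AreaKind if a not in contours]
    if missing:
        raise DataQualityError(f"missing areas for composition: {missing}")

    polys = {a: _to_polygon(c) for a, c in contours.items()}
    wb = geometry.wheel_disc()
    bounds = unary_union(list(polys.values()) + [wb]).bounds
    pad = 10.0 * max(1.0, geometry.wheel_radius)
    above_fdl = box(bounds[0] - pad, geometry.fdl, bounds[2] + pad, bounds[3] + pad)

    obstacles = {
        AreaKind.AoC: [wb, polys[AreaKind.AoP]],
        AreaKind.AoA: [wb, polys[AreaKind.AoP], polys[AreaKind.AoC]],
        AreaKind.AoR: [
            wb,
            polys[AreaKind.AoP],
            polys[AreaKind.AoA],
            polys[AreaKind.AoC],
        ],
    }
    armrest_strip = box(bounds[0] - pad, geometry.ful, bounds[2] + pad, geometry.arl)
    zones = []
    for area in (AreaKind.AoC, AreaKind.AoA, AreaKind.AoR):
        base = _clean(polys[area].intersection(above_fdl))
        zone = subtract_regions(
            ZonePolygon(label=area.value, ring=np.empty((0, 2)))
            if base.is_empty
            else _zone_from_polygon(area.value, _largest_part(base, area.value)),
            obstacles[area],
        )
        if not zone.polygon.is_empty and zone.polygon.intersects(armrest_strip):
            zone.notes.append("removable-support: overlaps armrest strip (FUL..ARL)")
        zones.append(zone)
    return ReachMap(zones=zones, geometry=geometry, provenance=provenance)


def export_map_points(
    reach_map: ReachMap, n_points: int = 20, *, max_area_loss: float = 0.02
) -> pd.DataFrame:
    """Compact labelled vertex list for approximate re-plotting.

    Each zone's outer ring is decimated (Douglas–Peucker) toward a total
    of about ``n_points`` vertices across zones, never letting a zone's
    polygon area drift more than ``max_area_loss`` (relative).  Returns a
    DataFrame with columns zone, point_index, x_mm, y_mm.
    """
    live = [z for z in reach_map.zones if z.area > 0]
    rows = []
    counter = 0
    if live:
        per = [z.polygon.exterior.length for z in live]
        total_perim = sum(per)
        for z, zp in zip(live, per):
            target = max(4, int(round(n_points * zp / total_perim)))
            ring = _simplify_ring(z.polygon, target, max_area_loss)
            for x, y in ring:
                rows.append(
                    {"zone": z.label, "point_index": counter, "x_mm": x, "y_mm": y}
                )
                counter += 1
    return pd.DataFrame(rows, columns=["zone", "point_index", "x_mm", "y_mm"])


def _simplify_ring(poly: Polygon, target: int, max_area_loss: float) -> np.ndarray:
    """Smallest Douglas–Peucker tolerance meeting the vertex budget.

    Binary search over tolerance; among tolerances whose simplification
    keeps the polygon area within ``max_area_loss``, pick the smallest
    one with at most ``target`` vertices.  If the budget and the area
    bound conflict, the area bound wins (more vertices are kept).
    """
    ref_area = poly.area
    full = np.asarray(poly.exterior.coords[:-1], dtype=float)
    if len(full) <= target:
        return full
    lo, hi = 0.0, poly.exterior.length
    best = None
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        simp = poly.simplify(mid, preserve_topology=True)
        area_ok = (
            not simp.is_empty and abs(simp.area - ref_area) <= max_area_loss * ref_area
        )
        n = len(simp.exterior.coords) - 1 if area_ok else None
        if area_ok and n <= target:
            best = np.asarray(simp.exterior.coords[:-1], dtype=float)
            hi = mid  # try to keep more detail within the budget
        elif area_ok:
            lo = mid  # too many vertices: coarsen
        else:
            hi = mid  # area destroyed: refine
    if best is None:
        best = full  # budget unreachable within the area bound
    return best


def anthropometric_checks(
    contours: Mapping[AreaKind | str, MeanContour | np.ndarray] | None = None,
    geometry: WheelchairGeometry | None = None,
    *,
    landmarks: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Compare reach landmarks with 50th-percentile limb lengths.

    Reports ``arm_forearm_reach_mm`` — |min x| of the extended-arm
    landmark (AoA forward extreme) — and ``forearm_reach_mm`` — |min x|
    of the forearm landmark (AoC forward extreme) plus the backrest
    offset SBV.  Landmark x values may be given directly via
    ``landmarks={'arm_forearm_x': ..., 'forearm_x': ...}`` instead of
    contours.
    """
    geometry = geometry if geometry is not None else WheelchairGeometry()
    if landmarks is not None:
        aoa_x = float(landmarks["arm_forearm_x"])
        aoc_x = float(landmarks["forearm_x"])
    else:
        if contours is None:
            raise ConfigError("provide contours or landmarks")
        cs = {AreaKind.coerce(k): v for k, v in contours.items()}
        for need in (AreaKind.AoA, AreaKind.AoC):
            if need not in cs:
                raise DataQualityError(f"{need.value} contour required")

        def min_x(c) -> float:
            pts = c.mean_points if isinstance(c, MeanContour) else np.asarray(c)
            return float(np.min(pts[:, 0]))

        aoa_x = min_x(cs[AreaKind.AoA])
        aoc_x = min_x(cs[AreaKind.AoC])
    return {
        "arm_forearm_reach_mm": abs(aoa_x),
        "forearm_reach_mm": abs(aoc_x) + geometry.sbv_x,
    }


class ReachMapComposer(BaseEstimator):
    """Compose per-area mean contours into the final map, sklearn style.

    Parameters
    ----------
    geometry_config : mapping or None
        Overrides for the wheelchair geometry (see
        :func:`geometry_from_config`).

    Attributes (after :meth:`fit`)
    ------------------------------
    geometry_ : WheelchairGeometry
    map_ : ReachMap
    """

    def __init__(self, geometry_config: Mapping | None = None):
        self.geometry_config = geometry_config

    def fit(self, X: Mapping, y=None):
        self.geometry_ = geometry_from_config(self.geometry_config)
        self.map_ = compose_map(X, self.geometry_)
        return self

    def transform(self, X: Mapping) -> ReachMap:
        if not hasattr(self, "geometry_"):
            self.fit(X)
        return self.map_
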