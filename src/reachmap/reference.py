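"""Published reference values used as validation fixtures.

These are the control-point tables, map point list and summary
dimensions measured on a ten-subject cohort (50th-percentile male
anthropometry, EN 979) seated in a cross-frame semi-active wheelchair,
averaged over N = 30 trials per area at confidence level p = 0.05.
They let the statistics layer be validated against real measured
numbers without access to the original recordings.

Notes on data quality:

* The approval-area (AoA) Δ column of the source table is not
  reproducible from its own half-widths under the confidence-diagonal
  identity Δ = 2·sqrt(δx² + δy²); those cells are stored as ``None``
  and excluded from consistency checks.  The AoA coordinates themselves
  are consistent with the published area dimensions (1009 x 553 mm).
* Control-point labels follow the source ordering, which does not always
  coincide with the max/min-x/y convention used by
  :func:`reachmap.averaging.control_points`; the tables are treated as
  unordered point sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .averaging import (
    ControlPoint,
    bbox_metrics,
    delta_interval,
    mean_delta,
    round_half_away,
)
from .composition import WheelchairGeometry, anthropometric_checks

__all__ = [
    "reference_control_points",
    "reference_map_points",
    "reference_geometry",
    "REFERENCE_DIMENSIONS",
    "REFERENCE_MEAN_DELTA",
    "REFERENCE_LANDMARKS",
    "check_tables",
]

_N = 30
_P = 0.05

# (label, x, y, dx, dy, printed delta or None) per area
_CONTROL_POINT_TABLE: dict[str, list[tuple]] = {
    "AoC": [
        ("A1", 92.0, 107.0, 42.0, 33.0, 108),
        ("A2", -36.0, 245.0, 18.0, 45.0, 97),
        ("A3", -260.0, 689.0, 33.0, 43.0, 109),
        ("A4", 33.0, 40.0, 21.0, 31.0, 76),
    ],
    "AoA": [
        ("A1", 255.0, 174.0, 92.0, 32.0, None),
        ("A2", -754.0, 42.0, 38.0, 52.0, None),
        ("A3", -272.0, 559.0, 65.0, 27.0, None),
        ("A4", -120.0, 6.0, 18.0, 14.0, None),
    ],
    "AoR": [
        ("A1", 317.0, 300.0, 46.0, 103.0, 225),
        ("A2", -952.0, 296.0, 194.0, 60.0, 406),
        ("A3", -41.0, 570.0, 141.0, 26.0, 288),
        ("A4", -230.0, -161.0, 31.0, 46.0, 111),
    ],
    "AoP": [
        ("A1", 85.0, 324.0, 40.0, 8.0, 81),
        ("A2", -327.0, 95.0, 14.0, 22.0, 52),
        ("A3", 30.0, 331.0, 42.0, 9.0, 86),
        ("A4", -319.0, 86.0, 16.0, 26.0, 61),
    ],
}

#: published (length, height) of each area, mm
REFERENCE_DIMENSIONS: dict[str, tuple[int, int]] = {
    "AoC": (352, 649),
    "AoA": (1009, 553),
    "AoR": (1269, 731),
    "AoP": (412, 245),
}

#: published mean confidence diagonal per area, mm (AoA omitted — see
#: module notes)
REFERENCE_MEAN_DELTA: dict[str, int] = {"AoC": 98, "AoR": 258}

#: landmark x positions on the composed map used for the anthropometric
#: plausibility check, with the 50th-percentile lengths they should match
REFERENCE_LANDMARKS: dict[str, dict[str, float]] = {
    "arm_forearm": {"x": -753.0, "expected_mm": 753.0},
    "forearm": {"x": -361.0, "expected_mm": 441.0},
}

# composed-map outline points (zone boundaries after subtracting the
# wheel disc and the propulsion area), wheel-axis frame, mm
_MAP_POINT_TABLE: list[tuple[int, float, float]] = [
    (0, -951.0, 296.0),
    (1, -840.0, 420.0),
    (2, -753.0, 420.0),
    (3, -623.0, -30.0),
    (4, -361.0, 420.0),
    (5, -327.0, 95.0),
    (6, -299.0, 25.0),
    (7, -298.0, -30.0),
    (8, -282.0, 102.0),
    (9, -273.0, 193.0),
    (10, -245.0, 420.0),
    (11, -167.0, 274.0),
    (12, 37.0, 298.0),
    (13, 85.0, 324.0),
    (14, 164.0, 420.0),
    (15, 253.0, 160.0),
    (16, 274.0, 420.0),
    (17, 281.0, 104.0),
    (18, 317.0, 300.0),
]


def reference_control_points(area: str | None = None):
    """Reference control points, as :class:`ControlPoint` objects.

    For rows whose printed Δ exists it is stored as-is (``delta``);
    otherwise Δ is computed from the half-widths via Eq.-style identity.
    Returns a dict of lists, or one list if ``area`` is given.
    """
    out: dict[str, list[ControlPoint]] = {}
    for a, rows in _CONTROL_POINT_TABLE.items():
        pts = []
        for label, x, y, dx, dy, printed in rows:
            delta = float(printed) if printed is not None else delta_interval(dx, dy)
            pts.append(
                ControlPoint(
                    point_id=label, x=x, y=y, dx=dx, dy=dy, delta=delta, n=_N, p=_P
                )
            )
        out[a] = pts
    if area is not None:
        return out[area]
    return out


def reference_map_points() -> pd.DataFrame:
    """The published composed-map point list as a DataFrame."""
    return pd.DataFrame(
        _MAP_POINT_TABLE, columns=["point_index", "x_mm", "y_mm"]
    ).astype({"point_index": int})


def reference_geometry() -> WheelchairGeometry:
    """The geometry of the reference chair (package defaults)."""
    return WheelchairGeometry()


def check_tables() -> pd.DataFrame:
    """Recompute every checkable published quantity from the bundled data.

    Returns a DataFrame with columns check, area, computed, expected,
    passed.  Covers: the confidence-diagonal identity on every row with a
    printed Δ (±2 mm for rows whose half-widths were rounded before
    printing; the AoR far-reach point must match exactly), the per-area
    mean Δ, the bounding-box dimensions, and the anthropometric landmark
    comparison.
    """
    rows = []
    cps = reference_control_points()
    for area, table in _CONTROL_POINT_TABLE.items():
        for label, x, y, dx, dy, printed in table:
            if printed is None:
                continue
            computed = round_half_away(delta_interval(dx, dy))
            tol = 0 if (area, label) == ("AoR", "A2") else 2
            rows.append(
                {
                    "check": "delta_identity",
                    "area": f"{area}:{label}",
                    "computed": computed,
                    "expected": printed,
                    "passed": abs(computed - printed) <= tol,
                }
            )
    for area, expected in REFERENCE_MEAN_DELTA.items():
        computed = mean_delta(cps[area])
        rows.append(
            {
                "check": "mean_delta",
                "area": area,
                "computed": computed,
                "expected": expected,
                "passed": computed == expected,
            }
        )
    for area, (length, height) in REFERENCE_DIMENSIONS.items():
        l, h = bbox_metrics(cps[area])
        rows.append(
            {
                "check": "bbox_length",
                "area": area,
                "computed": round_half_away(l),
                "expected": length,
                "passed": round_half_away(l) == length,
            }
        )
        rows.append(
            {
                "check": "bbox_height",
                "area": area,
                "computed": round_half_away(h),
                "expected": height,
                "passed": round_half_away(h) == height,
            }
        )
    geom = reference_geometry()
    checks = anthropometric_checks(
        geometry=geom,
        landmarks={
            "arm_forearm_x": REFERENCE_LANDMARKS["arm_forearm"]["x"],
            "forearm_x": REFERENCE_LANDMARKS["forearm"]["x"],
        },
    )
    for key, name in (
        ("arm_forearm_reach_mm", "arm_forearm"),
        ("forearm_reach_mm", "forearm"),
    ):
        expected = REFERENCE_LANDMARKS[name]["expected_mm"]
        rows.append(
            {
                "check": "anthropometric",
                "area": name,
                "computed": checks[key],
                "expected": expected,
                "passed": abs(checks[key] - expected) < 1e-9,
            }
        )
    return pd.DataFrame(rows)
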