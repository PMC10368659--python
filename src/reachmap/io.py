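"""Plain-text trajectory and contour formats.

Trajectory CSV columns: ``frame,t,marker_id,x_mm,y_mm`` with marker_id 0
for the stationary wheel-axis reference and 1 for the hand marker.
Contour CSV columns: ``point_index,x_mm,y_mm``.  Comma-separated, '.'
decimal, UTF-8, one header line.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import DataQualityError, FormatError
from .simulate import AreaKind, PointCloud

if TYPE_CHECKING:  # pragma: no cover
    from .extraction import ResampledLoop

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_contour",
    "write_contour",
    "TRAJECTORY_COLUMNS",
    "CONTOUR_COLUMNS",
]

TRAJECTORY_COLUMNS = ["frame", "t", "marker_id", "x_mm", "y_mm"]
CONTOUR_COLUMNS = ["point_index", "x_mm", "y_mm"]

#: hook for external video -> trajectory converters: register a callable
#: ``name -> (video_path, out_csv_path) -> None`` here.  Declared as an
#: extension point only; no adapter ships with the package.
TRAJECTORY_ADAPTERS: dict = {}

#: maximum allowed excursion of the reference marker about its mean (mm)
DEFAULT_ID0_TOLERANCE = 2.0


def read_trajectory(
    path: str | os.PathLike,
    *,
    id0_tolerance: float = DEFAULT_ID0_TOLERANCE,
    area: AreaKind | str | None = None,
) -> PointCloud:
    """Read one trial and return hand samples in the wheel-axis frame.

    If reference-marker (ID0) rows are present, the hand (ID1) samples are
    re-expressed relative to the *mean* ID0 position — the camera is
    rigidly mounted, so per-frame subtraction would double detection
    jitter.  ID0 excursions beyond ``id0_tolerance`` raise
    :class:`DataQualityError`.
    """
    try:
        df = pd.read_csv(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse trajectory file {path}: {exc}") from exc
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    xy = df[["x_mm", "y_mm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise DataQualityError(f"{path}: non-finite coordinates")
    ids = df["marker_id"].to_numpy()
    if not np.isin(ids, (0, 1)).all():
        raise FormatError(f"{path}: marker_id must be 0 or 1")
    ref = xy[ids == 0]
    hand = xy[ids == 1]
    if len(hand) < 3:
        raise DataQualityError(f"{path}: need >= 3 hand-marker samples, got {len(hand)}")
    if len(ref):
        mean_ref = ref.mean(axis=0)
        drift = np.linalg.norm(ref - mean_ref, axis=1).max()
        if drift > id0_tolerance:
            raise DataQualityError(
                f"{path}: reference marker drifts {drift:.2f} mm "
                f"(tolerance {id0_tolerance} mm)"
            )
        hand = hand - mean_ref
    return PointCloud(
        hand, area=None if area is None else AreaKind.coerce(area)
    )


def write_trajectory(
    cloud: PointCloud,
    path: str | os.PathLike,
    *,
    fps: float = 240.0,
    reference: tuple[float, float] | None = None,
) -> None:
    """Write a point cloud as a trajectory CSV (one ID1 row per sample).

    If ``reference`` is given, its coordinates are added to every sample
    and one ID0 row per frame is emitted at the reference position, so a
    read round-trips back to the wheel-axis frame.
    """
    n = len(cloud.points)
    frames = np.arange(n)
    t = frames / fps
    pts = cloud.points
    rows = []
    if reference is not None:
        pts = pts + np.asarray(reference, dtype=float)
        rows.append(
            pd.DataFrame(
                {
                    "frame": frames,
                    "t": t,
                    "marker_id": 0,
                    "x_mm": reference[0],
                    "y_mm": reference[1],
                }
            )
        )
    rows.append(
        pd.DataFrame(
            {"frame": frames, "t": t, "marker_id": 1, "x_mm": pts[:, 0], "y_mm": pts[:, 1]}
        )
    )
    out = pd.concat(rows).sort_values(["frame", "marker_id"], kind="stable")
    out.to_csv(path, index=False, float_format="%.6f")


def write_contour(loop: "ResampledLoop", path: str | os.PathLike) -> None:
    """Write a canonical resampled loop as a contour CSV."""
    verts = np.asarray(loop.vertices, dtype=float)
    if len(verts) < 3:
        raise DataQualityError("cannot write a loop with fewer than 3 vertices")
    pd.DataFrame(
        {
            "point_index": np.arange(len(verts)),
            "x_mm": verts[:, 0],
            "y_mm": verts[:, 1],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_contour(path: str | os.PathLike) -> "ResampledLoop":
    """Read a contour CSV back into a resampled loop (index order kept)."""
    from .extraction import ResampledLoop

    try:
        df = pd.read_csv(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse contour file {path}: {exc}") from exc
    missing = [c for c in CONTOUR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.sort_values("point_index", kind="stable")
    verts = df[["x_mm", "y_mm"]].to_numpy(dtype=float)
    if len(verts) < 3:
        raise DataQualityError(f"{path}: contour needs >= 3 points")
    if not np.all(np.isfinite(verts)):
        raise DataQualityError(f"{path}: non-finite coordinates")
    return ResampledLoop(vertices=verts)
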