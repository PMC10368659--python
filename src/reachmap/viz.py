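"""Matplotlib rendering of reach maps and contours (SVG-friendly)."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .composition import ReachMap

__all__ = ["plot_map"]

_ZONE_COLORS = {"AoC": "#2a9d8f", "AoA": "#e9c46a", "AoR": "#e76f51"}


def plot_map(reach_map: ReachMap, path: str | os.PathLike | None = None):
    """Draw the composed map: levels as lines, wheel disc, filled zones.

    Returns the matplotlib figure; also saves it if ``path`` is given
    (format from the extension, e.g. ``.svg``).
    """
    geom = reach_map.geometry
    fig, ax = plt.subplots(figsize=(8, 5))
    for level, name in (
        (geom.fdl, "FDL"),
        (geom.ful, "FUL"),
        (geom.arl, "ARL"),
        (geom.sl, "SL"),
        (geom.sh, "SH"),
    ):
        ax.axhline(level, color="0.6", lw=0.8, zorder=1)
        ax.annotate(name, (0.99, level), xycoords=("axes fraction", "data"),
                    fontsize=7, color="0.4", va="bottom", ha="right")
    ax.axvline(geom.sbv_x, color="0.6", lw=0.8, zorder=1)
    t = np.linspace(0, 2 * np.pi, 361)
    cx, cy = geom.wheel_center
    ax.plot(cx + geom.wheel_radius * np.sin(t), cy + geom.wheel_radius * np.cos(t),
            color="0.3", lw=1.0, zorder=2)
    for zone in reach_map.zones:
        if zone.area <= 0:
            continue
        ring = np.vstack([zone.ring, zone.ring[:1]])
        color = _ZONE_COLORS.get(zone.label, "#888888")
        ax.fill(ring[:, 0], ring[:, 1], color=color, alpha=0.45,
                label=zone.label, zorder=3)
        ax.plot(ring[:, 0], ring[:, 1], color=color, lw=1.2, zorder=4)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm, rear positive)")
    ax.set_ylabel("y (mm)")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
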