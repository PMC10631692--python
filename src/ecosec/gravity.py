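"""Gravity-center migration of security grades between epochs.

The center of gravity of a security grade is the area-weighted mean of its
patch (or cell) centroids, x = sum(c_i x_i)/sum(c_i).  Epoch-to-epoch
displacement is summarized by the transfer distance

    d = c * sqrt(dX^2 + dY^2),  c = 111.11 km/degree for geographic input
                                (c = 1 when coordinates are already km)

and a compass bearing.  The operative bearing is the standard atan2 compass
angle measured clockwise from north, mapped to 8-wind labels; the raw
arctangent value arctg(dY/dX) is reported alongside for comparison with the
older quadrant-offset convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEG_TO_KM",
    "GravityPoint",
    "GravityShift",
    "security_centroid",
    "transfer_distance",
    "transfer_angle",
    "compass_label",
]

# crude equirectangular conversion, km per degree
DEG_TO_KM = 111.11

_WINDS = ("north", "northeast", "east", "southeast",
          "south", "southwest", "west", "northwest")


@dataclass(frozen=True)
class GravityPoint:
    """Area-weighted centroid of one security grade in one epoch."""

    x: float
    y: float
    total_weight: float
    in_degrees: bool = False
    grade: str = ""
    epoch: str = ""


@dataclass(frozen=True)
class GravityShift:
    """Displacement of a grade's gravity center between two epochs."""

    dx_km: float
    dy_km: float
    distance_km: float
    bearing_deg: float | None  # clockwise from north; None if no movement
    direction: str | None
    raw_arctg_deg: float | None  # arctg(dY/dX), the older convention's core
    grade: str = ""
    period: str = ""


def security_centroid(
    xs,
    ys,
    weights,
    in_degrees: bool = False,
    grade: str = "",
    epoch: str = "",
) -> GravityPoint | None:
    """Weighted mean of patch centroids; weights are patch areas.

    Returns None for an empty grade (no contributing patches) rather than
    a fictitious zero point.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    w = np.asarray(weights, dtype=float)
    if xs.size == 0:
        return None
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    return GravityPoint(float(xs @ w / total), float(ys @ w / total),
                        float(total), in_degrees, grade, epoch)


def transfer_distance(p_m: GravityPoint, p_n: GravityPoint) -> float:
    """Transfer distance in km between two gravity centers.

    Degree coordinates are converted with the equirectangular constant
    111.11 km/degree; km coordinates are used as-is.
    """
    if p_m.in_degrees != p_n.in_degrees:
        raise ValueError("cannot mix degree and km gravity points")
    c = DEG_TO_KM if p_m.in_degrees else 1.0
    return c * math.hypot(p_n.x - p_m.x, p_n.y - p_m.y)


def compass_label(bearing_deg: float) -> str:
    """8-wind label for a compass bearing (clockwise from north)."""
    sector = int(((bearing_deg % 360.0) + 22.5) // 45.0) % 8
    return _WINDS[sector]


def transfer_angle(p_m: GravityPoint, p_n: GravityPoint,
                   grade: str = "", period: str = "") -> GravityShift:
    """Displacement, distance, compass bearing and label between epochs."""
    if p_m.in_degrees != p_n.in_degrees:
        raise ValueError("cannot mix degree and km gravity points")
    c = DEG_TO_KM if p_m.in_degrees else 1.0
    dx = c * (p_n.x - p_m.x)
    dy = c * (p_n.y - p_m.y)
    dist = math.hypot(dx, dy)
    if dist == 0.0:
        return GravityShift(dx, dy, 0.0, None, None, None, grade, period)
    bearing = math.degrees(math.atan2(dx, dy)) % 360.0
    raw = math.degrees(math.atan2(dy, dx)) if dx != 0 else math.copysign(90.0, dy)
    if dx != 0:
        raw = math.degrees(math.atan(dy / dx))
    return GravityShift(dx, dy, dist, bearing, compass_label(bearing), raw,
                        grade, period)
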