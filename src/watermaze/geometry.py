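"""Planar geometry helpers shared by the simulator and cue-weighting code.

Frame convention: x east, y north; bearings/yaw in degrees measured
counter-clockwise from +y (north).
"""

from __future__ import annotations

import numpy as np

Point = tuple[float, float]


def wrap_angle(deg):
    """Wrap an angle (or array) to the half-open interval (-180, 180]."""
    out = -((-np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0)
    return out if out.ndim else float(out)


def bearing(vec) -> float:
    """Bearing of a 2-D vector in degrees CCW from +y, in [0, 360)."""
    v = np.asarray(vec, dtype=float)
    if np.allclose(v, 0):
        raise ValueError("bearing of the zero vector is undefined")
    return float(np.degrees(np.arctan2(-v[0], v[1])) % 360.0)


def unit_from_bearing(deg: float) -> np.ndarray:
    """Unit vector at a given bearing (inverse of :func:`bearing`)."""
    r = np.radians(deg)
    return np.array([-np.sin(r), np.cos(r)])


def rotate_about(point, centre, angle_deg: float) -> np.ndarray:
    """Rotate ``point`` about ``centre`` by ``angle_deg`` CCW."""
    r = np.radians(angle_deg)
    c, s = np.cos(r), np.sin(r)
    d = np.asarray(point, dtype=float) - np.asarray(centre, dtype=float)
    return np.asarray(centre, dtype=float) + np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


def dist(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))
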