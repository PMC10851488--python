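"""Shared independent oracles and line builders for the test suite."""

from __future__ import annotations

import numpy as np

from maccurv import SegLine


def solve_circle_radius(p1, p2, p3) -> float:
    """Independent circumradius oracle: solve the 3-point circle equations.

    Subtracting the circle equation |p - c|^2 = R^2 pairwise gives a linear
    2x2 system for the centre c; the radius is the distance to any point.
    Deliberately a different algorithm from the product/area formula used by
    the implementation.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    A = 2.0 * np.array([p2 - p1, p3 - p1])
    b = np.array(
        [p2 @ p2 - p1 @ p1, p3 @ p3 - p1 @ p1]
    )
    centre = np.linalg.solve(A, b)
    return float(np.hypot(*(p1 - centre)))


def circle_line(
    rho: float,
    *,
    px_h: float = 0.014,
    n_cols: int = 643,
    depth_offset: float = 0.5,
    lateral_offset: float = 0.0,
    concave_down: bool = True,
    eye_id: str = "circle",
    scan_angle_deg: float = 0.0,
) -> SegLine:
    """Sample an exact circular arc of radius ``rho`` as a SegLine."""
    x = np.arange(n_cols) * px_h
    t = x - x[-1] / 2.0 - lateral_offset
    assert np.all(np.abs(t) < rho), "scan wider than the circle"
    bowl = np.sqrt(rho**2 - t**2) - rho
    depth = depth_offset + (bowl if concave_down else -bowl)
    return SegLine(
        depth_mm=depth, px_h=px_h, eye_id=eye_id, scan_angle_deg=scan_angle_deg
    )
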