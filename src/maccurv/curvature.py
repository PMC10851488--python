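"""Sliding three-point arc radii along an RPE segmentation line.

At every column *a* inside the region of interest, an arc is constructed
through the line point at *a* and the two line points one chord offset to
each side (default 1.4 mm = 100 columns at 0.014 mm/px, so the full chord
spans 2.8 mm).  The arc radius is the circumradius of the three points in
physical mm coordinates; the smallest radius in a scan is the per-scan
minimum r.  Radii are never computed in pixel units — the anisotropic pixel
pitch is absorbed by the mm conversion, which is exactly the device's
"1:1 aspect correction" expressed as a coordinate transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .seg_io import SegLine

#: Triangle areas below this (mm^2) are treated as collinear and map to the
#: infinite-radius sentinel instead of dividing by a vanishing area.
COLLINEAR_AREA_TOL = 1e-12

#: Sentinel for a locally straight (collinear) arc: an infinite radius.
INF_RADIUS = float("inf")


@dataclass(frozen=True)
class CurvatureProfile:
    """Per-column arc radii over the ROI of one scan.

    ``radius_mm`` has one entry per line column: NaN outside the ROI,
    ``inf`` where the three points were collinear, a positive radius
    elsewhere.  ``r_min_mm``/``r_min_col`` give the per-scan minimum r
    (first column on ties); ``all_collinear`` flags a perfectly straight
    line whose minimum is undefined (sentinel ``inf``).
    """

    radius_mm: np.ndarray
    roi: tuple[int, int]  # inclusive column bounds
    r_min_mm: float
    r_min_col: int | None
    chord_offset_cols: int
    chord_offset_mm: float
    px_h: float
    eye_id: str = ""
    scan_angle_deg: float = 0.0
    all_collinear: bool = False

    @property
    def roi_radii(self) -> np.ndarray:
        return self.radius_mm[self.roi[0]:self.roi[1] + 1]


def circumradius(
    p1: Sequence[float],
    p2: Sequence[float],
    p3: Sequence[float],
    *,
    area_tol: float = COLLINEAR_AREA_TOL,
) -> float:
    """Radius of the circle through three points (mm).

    Uses R = |p1p2| |p2p3| |p1p3| / (4 A) with A the triangle area from the
    cross product.  Collinear points (area below ``area_tol``) return the
    infinite-radius sentinel; coincident points raise ValidationError.
    """
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    c = np.asarray(p3, dtype=float)
    d_ab = float(np.hypot(*(b - a)))
    d_bc = float(np.hypot(*(c - b)))
    d_ac = float(np.hypot(*(c - a)))
    if min(d_ab, d_bc, d_ac) == 0.0:
        raise ValidationError("coincident points have no unique circumcircle")
    cross = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
    area = 0.5 * abs(cross)
    if area < area_tol:
        return INF_RADIUS
    return d_ab * d_bc * d_ac / (4.0 * area)


def roi_bounds(line: SegLine, margin_cols: int) -> tuple[int, int]:
    """Inclusive ROI column bounds after excluding ``margin_cols`` per side."""
    if margin_cols < 0:
        raise ValidationError("margin_cols must be non-negative")
    if line.n_cols <= 2 * margin_cols:
        raise ValidationError(
            f"line with {line.n_cols} columns leaves no ROI after excluding "
            f"{margin_cols} columns on each side"
        )
    return margin_cols, line.n_cols - 1 - margin_cols


def curvature_profile(
    line: SegLine,
    chord_offset_mm: float = 1.4,
    *,
    roi_margin_cols: int | None = None,
    area_tol: float = COLLINEAR_AREA_TOL,
) -> CurvatureProfile:
    """Compute the sliding three-point arc-radius profile of a gap-free line.

    For each ROI column *a*, endpoints sit ``chord_offset_cols =
    round(chord_offset_mm / px_h)`` columns to either side (offsets are
    column counts — lateral distance, not arc length).  The ROI margin
    defaults to the chord offset and is never smaller than it, so both
    endpoints always exist.  Collinear triples carry the ``inf`` sentinel
    and are excluded from the minimum; a fully straight line yields a
    flagged profile with ``r_min_mm = inf``.
    """
    if not line.is_gap_free:
        raise ValidationError(
            "line has missing columns; run interpolate_gaps first"
        )
    if chord_offset_mm <= 0:
        raise ValidationError("chord_offset_mm must be positive")
    off = int(round(chord_offset_mm / line.px_h))
    if off < 2:
        raise ValidationError(
            f"chord offset {chord_offset_mm} mm is {off} columns at "
            f"px_h={line.px_h}; need >= 2"
        )
    margin = off if roi_margin_cols is None else max(int(roi_margin_cols), off)
    first, last = roi_bounds(line, margin)

    x = line.x_mm
    z = line.depth_mm
    a = np.arange(first, last + 1)
    b, c = a - off, a + off
    pax, paz = x[a], z[a]
    pbx, pbz = x[b], z[b]
    pcx, pcz = x[c], z[c]
    d_ab = np.hypot(pax - pbx, paz - pbz)
    d_ac = np.hypot(pcx - pax, pcz - paz)
    d_bc = np.hypot(pcx - pbx, pcz - pbz)
    cross = (pax - pbx) * (pcz - pbz) - (pcx - pbx) * (paz - pbz)
    area = 0.5 * np.abs(cross)
    with np.errstate(divide="ignore"):
        radii = np.where(
            area < area_tol, INF_RADIUS, d_ab * d_ac * d_bc / (4.0 * area)
        )

    full = np.full(line.n_cols, np.nan)
    full[first:last + 1] = radii
    finite = np.isfinite(radii)
    if finite.any():
        i = int(np.argmin(np.where(finite, radii, np.inf)))
        r_min, r_col, flagged = float(radii[i]), first + i, False
    else:
        r_min, r_col, flagged = INF_RADIUS, None, True
    return CurvatureProfile(
        radius_mm=full,
        roi=(first, last),
        r_min_mm=r_min,
        r_min_col=r_col,
        chord_offset_cols=off,
        chord_offset_mm=chord_offset_mm,
        px_h=line.px_h,
        eye_id=line.eye_id,
        scan_angle_deg=line.scan_angle_deg,
        all_collinear=flagged,
    )


def write_profile_csv(profile: CurvatureProfile, path: str | Path) -> None:
    """Export a profile as ``col,x_mm,radius_mm`` (``inf`` for collinear)."""
    path = Path(path)
    first, last = profile.roi
    rows = [
        f"# chord_offset_mm={profile.chord_offset_mm!r}",
        f"# roi_first_col={first}",
        f"# roi_last_col={last}",
        f"# r_min_mm={profile.r_min_mm!r}",
        f"# r_min_col={profile.r_min_col}",
        "col,x_mm,radius_mm",
    ]
    x0 = 0.0
    for col in range(first, last + 1):
        r = profile.radius_mm[col]
        r_str = "inf" if np.isinf(r) else f"{r:.6f}"
        rows.append(f"{col},{x0 + col * profile.px_h:.6f},{r_str}")
    path.write_text("\n".join(rows) + "\n")
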