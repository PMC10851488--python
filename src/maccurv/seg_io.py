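"""B-scan and RPE segmentation-line I/O, detection and correction.

The retinal pigment epithelium (RPE) appears on an OCT B-scan as the
posterior hyperreflective band; its segmentation line, one depth sample per
image column, traces the posterior eye-wall contour.  This module reads
grayscale B-scan rasters, detects that line, reads/writes line files, applies
manual corrections, and fills gaps, always expressing depth in physical
millimetres (depth = (row + 0.5) * px_v, increasing downward from the image
top).  Working in mm makes the device's 2:1 vertical display stretch a pure
coordinate statement rather than a resampling step.

File formats
------------
SegLine CSV::

    # px_h_mm=0.014
    # scan_angle_deg=0.0
    # eye_id=E01
    # source=machine
    col,depth_mm
    0,1.234567
    1,
    ...

(an empty depth field marks a missing column).  SegLine JSON is an object
with keys ``eye_id``, ``scan_angle_deg``, ``px_h_mm``, ``source`` and
``depth_mm`` (array, ``null`` = missing).  Correction overlays are JSON
arrays of ``{col_start, col_end, depths_mm}`` with 0-based half-open spans.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter1d, median_filter

from .errors import (
    ConfigurationError,
    DetectionError,
    FormatError,
    RejectionError,
    ValidationError,
)

#: Lines with more than this fraction of missing columns are rejected.
MAX_MISSING_FRACTION = 0.20

#: Minimum raster width: ROI margins of 100 columns on each side plus at
#: least one measurable column.
MIN_BSCAN_COLS = 301


class SegSource(str, Enum):
    """Provenance of a segmentation line."""

    MACHINE = "machine"      # supplied by the OCT device / external file
    DETECTED = "detected"    # produced by :func:`detect_rpe_line`
    CORRECTED = "corrected"  # manually corrected via an overlay


@dataclass(frozen=True)
class BScanImage:
    """A grayscale OCT B-scan with physical pixel pitches.

    Rows are depth (increasing downward), columns are lateral position.
    ``px_v`` is the axial pitch of the *stored* raster; if the raster was
    stored with the device's vertical display stretch applied,
    ``display_stretch`` records the integer duplication factor so the native
    sampling can be recovered exactly.
    """

    pixels: np.ndarray
    px_h: float  # lateral pitch, mm/pixel
    px_v: float  # axial pitch of the stored raster, mm/pixel
    scan_angle_deg: float = 0.0
    eye_id: str = ""
    scan_len_mm: float | None = None
    display_stretch: int = 1

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if pix.ndim != 2:
            raise FormatError(f"B-scan must be 2-D grayscale, got shape {pix.shape}")
        if pix.shape[0] < 2 or pix.shape[1] < MIN_BSCAN_COLS:
            raise ValidationError(
                f"B-scan raster {pix.shape} too small: need >= 2 rows and "
                f">= {MIN_BSCAN_COLS} columns"
            )
        if not (self.px_h > 0 and self.px_v > 0):
            raise ConfigurationError("pixel pitches must be positive")
        if self.display_stretch < 1:
            raise ConfigurationError("display_stretch must be >= 1")
        if self.scan_len_mm is None:
            object.__setattr__(self, "scan_len_mm", pix.shape[1] * self.px_h)
        else:
            nominal = pix.shape[1] * self.px_h
            if not math.isclose(self.scan_len_mm, nominal, rel_tol=0.02):
                raise ValidationError(
                    f"scan_len_mm={self.scan_len_mm} inconsistent with "
                    f"{pix.shape[1]} columns x {self.px_h} mm/px = {nominal:.3f} mm"
                )
        object.__setattr__(self, "pixels", pix)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class SegLine:
    """One RPE segmentation line in physical coordinates.

    ``depth_mm`` holds one depth per column; NaN marks a missing column
    (vessel shadow, dropout).  Lateral positions are uniformly spaced:
    ``x_mm[i] = x0_mm + i * px_h``.
    """

    depth_mm: np.ndarray
    px_h: float
    source: SegSource = SegSource.MACHINE
    eye_id: str = ""
    scan_angle_deg: float = 0.0
    x0_mm: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_mm, dtype=float)
        if d.ndim != 1 or d.size < 3:
            raise ValidationError("depth_mm must be a 1-D array with >= 3 columns")
        if not self.px_h > 0:
            raise ConfigurationError("px_h must be positive")
        finite_or_nan = np.isfinite(d) | np.isnan(d)
        if not finite_or_nan.all():
            raise ValidationError("depth_mm contains non-finite, non-NaN values")
        object.__setattr__(self, "px_h", float(self.px_h))
        object.__setattr__(self, "scan_angle_deg", float(self.scan_angle_deg))
        object.__setattr__(self, "x0_mm", float(self.x0_mm))
        frac = float(np.isnan(d).mean())
        if frac > MAX_MISSING_FRACTION:
            raise RejectionError(
                f"{frac:.0%} of columns missing exceeds the "
                f"{MAX_MISSING_FRACTION:.0%} cap (scan angle "
                f"{self.scan_angle_deg}, eye {self.eye_id!r})"
            )
        object.__setattr__(self, "depth_mm", d)

    @property
    def n_cols(self) -> int:
        return self.depth_mm.size

    @property
    def x_mm(self) -> np.ndarray:
        return self.x0_mm + np.arange(self.n_cols) * self.px_h

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.depth_mm).mean())

    @property
    def is_gap_free(self) -> bool:
        return not np.isnan(self.depth_mm).any()


@dataclass(frozen=True)
class CorrectionSpan:
    """Replacement depths over a 0-based half-open column interval."""

    col_start: int
    col_end: int
    depths_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.col_end <= self.col_start or self.col_start < 0:
            raise ValidationError(
                f"invalid span [{self.col_start}, {self.col_end})"
            )
        if len(self.depths_mm) != self.col_end - self.col_start:
            raise ValidationError(
                f"span [{self.col_start}, {self.col_end}) expects "
                f"{self.col_end - self.col_start} depths, got {len(self.depths_mm)}"
            )
        object.__setattr__(self, "depths_mm", tuple(float(v) for v in self.depths_mm))


@dataclass(frozen=True)
class CorrectionOverlay:
    """A set of non-overlapping manual-correction spans."""

    spans: tuple[CorrectionSpan, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        spans = tuple(sorted(self.spans, key=lambda s: s.col_start))
        for a, b in zip(spans, spans[1:]):
            if b.col_start < a.col_end:
                raise ValidationError(
                    f"overlapping correction spans [{a.col_start},{a.col_end}) "
                    f"and [{b.col_start},{b.col_end})"
                )
        object.__setattr__(self, "spans", spans)

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionOverlay":
        raw = json.loads(Path(path).read_text())
        if not isinstance(raw, list):
            raise FormatError("correction overlay JSON must be an array of spans")
        return cls(
            spans=tuple(
                CorrectionSpan(int(s["col_start"]), int(s["col_end"]),
                               tuple(s["depths_mm"]))
                for s in raw
            )
        )


# ---------------------------------------------------------------------------
# image I/O

def read_bscan(path: str | Path, meta: Mapping[str, object]) -> BScanImage:
    """Read an 8/16-bit grayscale TIFF or PNG as a :class:`BScanImage`.

    ``meta`` must supply ``px_h`` and ``px_v`` (mm/pixel); pitches are never
    inferred from image size.  Optional keys: ``scan_angle_deg``, ``eye_id``,
    ``scan_len_mm``, ``display_stretch``.  Intensities are normalised to
    [0, 1] by the dtype full scale.
    """
    path = Path(path)
    for key in ("px_h", "px_v"):
        if key not in meta:
            raise ConfigurationError(
                f"metadata for {path.name} lacks required pixel pitch {key!r}"
            )
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # corrupt / unreadable file
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: expected single-channel grayscale, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        scale = 1.0
    else:
        raise FormatError(f"{path.name}: unsupported dtype {arr.dtype}")
    return BScanImage(
        pixels=arr.astype(float) / scale,
        px_h=float(meta["px_h"]),
        px_v=float(meta["px_v"]),
        scan_angle_deg=float(meta.get("scan_angle_deg", 0.0)),
        eye_id=str(meta.get("eye_id", path.stem)),
        scan_len_mm=(float(meta["scan_len_mm"]) if "scan_len_mm" in meta else None),
        display_stretch=int(meta.get("display_stretch", 1)),
    )


def write_bscan(img: BScanImage, path: str | Path) -> None:
    """Write a B-scan as 16-bit grayscale TIFF or PNG (by suffix)."""
    path = Path(path)
    arr = np.clip(img.pixels, 0.0, 1.0)
    arr16 = np.round(arr * 65535.0).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr16)
    else:
        iio.imwrite(path, arr16)


# ---------------------------------------------------------------------------
# RPE detection

def _collapse_display_stretch(pixels: np.ndarray, factor: int) -> np.ndarray:
    """Undo an integer row-duplication display stretch exactly.

    Averaging each group of ``factor`` rows is the exact floating-point
    inverse of ``np.repeat`` duplication, so a stretched raster reduces
    bit-for-bit to its native-sampling original.
    """
    n_rows = pixels.shape[0]
    if n_rows % factor:
        raise FormatError(
            f"row count {n_rows} not divisible by display_stretch={factor}"
        )
    return pixels.reshape(n_rows // factor, factor, -1).mean(axis=1)


def detect_rpe_line(
    img: BScanImage,
    *,
    smooth_halfwidth: int = 5,
    min_contrast: float = 0.3,
    column_smooth_sigma_px: float = 2.0,
    centroid_frac: float = 0.2,
) -> SegLine:
    """Detect the RPE segmentation line on a B-scan.

    Per column, the candidate band is the deepest local intensity maximum
    (after a small axial Gaussian smoothing) whose smoothed peak exceeds
    ``min_contrast``; its depth is the intensity-weighted centroid of the
    contiguous region around the peak above ``centroid_frac`` of the peak,
    converted to mm at the native axial pitch.  Columns with no qualifying
    band are marked missing.  The depth series is then median-filtered with
    half-width ``smooth_halfwidth`` columns (missing columns stay missing).

    Raises :class:`DetectionError` if more than 20% of columns fail.
    """
    pix = img.pixels
    px_v = img.px_v
    if img.display_stretch > 1:
        pix = _collapse_display_stretch(pix, img.display_stretch)
        px_v = img.px_v * img.display_stretch

    sm = gaussian_filter1d(pix, sigma=column_smooth_sigma_px, axis=0, mode="nearest")
    n_rows, n_cols = sm.shape

    # deepest qualifying interior local maximum per column
    interior = sm[1:-1]
    is_max = (interior >= sm[:-2]) & (interior >= sm[2:]) & (interior >= min_contrast)
    row_idx = np.arange(1, n_rows - 1)[:, None]
    peak_row = np.where(is_max, row_idx, -1).max(axis=0)  # -1 = no band

    depth = np.full(n_cols, np.nan)
    for j in range(n_cols):
        p = peak_row[j]
        if p < 0:
            continue
        v = sm[:, j]
        cut = centroid_frac * v[p]
        lo = p
        while lo > 0 and v[lo - 1] >= cut:
            lo -= 1
        hi = p
        while hi < n_rows - 1 and v[hi + 1] >= cut:
            hi += 1
        w = np.clip(v[lo:hi + 1], 0.0, None)
        rows = np.arange(lo, hi + 1)
        depth[j] = (float(np.sum(w * rows)) / float(np.sum(w)) + 0.5) * px_v

    missing = np.isnan(depth)
    frac = float(missing.mean())
    if frac > MAX_MISSING_FRACTION:
        raise DetectionError(
            f"RPE detection failed on {frac:.0%} of columns (eye "
            f"{img.eye_id!r}, angle {img.scan_angle_deg})"
        )
    if smooth_halfwidth > 0 and not missing.all():
        # fill gaps before filtering so NaNs cannot contaminate neighbours,
        # then restore them: the filter must not invent missing columns.
        # 'nearest' edge padding keeps the median exact on monotone slopes.
        filled = depth
        if missing.any():
            idx = np.arange(n_cols)
            filled = depth.copy()
            filled[missing] = np.interp(idx[missing], idx[~missing], depth[~missing])
        depth = median_filter(
            filled, size=2 * smooth_halfwidth + 1, mode="nearest"
        )
        depth[missing] = np.nan
    return SegLine(
        depth_mm=depth,
        px_h=img.px_h,
        source=SegSource.DETECTED,
        eye_id=img.eye_id,
        scan_angle_deg=img.scan_angle_deg,
    )


# ---------------------------------------------------------------------------
# line file I/O

def write_segline(line: SegLine, path: str | Path) -> None:
    """Write a SegLine as CSV (6-decimal depths) or JSON (lossless), by suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = {
            "eye_id": line.eye_id,
            "scan_angle_deg": line.scan_angle_deg,
            "px_h_mm": line.px_h,
            "source": line.source.value,
            "depth_mm": [None if np.isnan(v) else float(v) for v in line.depth_mm],
        }
        path.write_text(json.dumps(obj))
        return
    rows = [
        f"# px_h_mm={line.px_h!r}",
        f"# scan_angle_deg={line.scan_angle_deg!r}",
        f"# eye_id={line.eye_id}",
        f"# source={line.source.value}",
        "col,depth_mm",
    ]
    for i, v in enumerate(line.depth_mm):
        rows.append(f"{i}," if np.isnan(v) else f"{i},{v:.6f}")
    path.write_text("\n".join(rows) + "\n")


def load_segline(path: str | Path) -> SegLine:
    """Load a SegLine from its CSV or JSON dialect.

    Raises :class:`FormatError` for malformed files (including non-uniform
    column spacing) and :class:`RejectionError` when more than 20% of the
    depths are missing.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            obj = json.loads(path.read_text())
            depth = np.array(
                [np.nan if v is None else float(v) for v in obj["depth_mm"]]
            )
            return SegLine(
                depth_mm=depth,
                px_h=float(obj["px_h_mm"]),
                source=SegSource(obj.get("source", "machine")),
                eye_id=str(obj.get("eye_id", "")),
                scan_angle_deg=float(obj.get("scan_angle_deg", 0.0)),
            )
        except (KeyError, TypeError, json.JSONDecodeError) as exc:
            raise FormatError(f"malformed SegLine JSON {path}: {exc}") from exc

    header: dict[str, str] = {}
    cols: list[int] = []
    depths: list[float] = []
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    body_started = False
    for raw in lines:
        raw = raw.strip()
        if not raw:
            continue
        if raw.startswith("#"):
            key, _, val = raw.lstrip("# ").partition("=")
            header[key.strip()] = val.strip()
            continue
        if not body_started:
            if raw.lower().replace(" ", "") != "col,depth_mm":
                raise FormatError(f"{path}: expected 'col,depth_mm' header row")
            body_started = True
            continue
        parts = raw.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}: malformed row {raw!r}")
        try:
            cols.append(int(parts[0]))
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer column index {parts[0]!r}") from exc
        depths.append(np.nan if parts[1] == "" else float(parts[1]))
    if "px_h_mm" not in header:
        raise FormatError(f"{path}: missing '# px_h_mm=' header")
    if not cols:
        raise FormatError(f"{path}: no data rows")
    cols_arr = np.asarray(cols)
    if not np.array_equal(cols_arr, np.arange(cols_arr[0], cols_arr[0] + len(cols))):
        raise FormatError(f"{path}: non-uniform column spacing")
    return SegLine(
        depth_mm=np.asarray(depths),
        px_h=float(header["px_h_mm"]),
        source=SegSource(header.get("source", "machine")),
        eye_id=header.get("eye_id", ""),
        scan_angle_deg=float(header.get("scan_angle_deg", 0.0)),
    )


# ---------------------------------------------------------------------------
# corrections and gaps

def apply_corrections(line: SegLine, overlay: CorrectionOverlay) -> SegLine:
    """Replace depths inside each overlay span; marks the line ``corrected``.

    An empty overlay returns the line unchanged (same source).
    """
    if not overlay.spans:
        return line
    for s in overlay.spans:
        if s.col_end > line.n_cols:
            raise ValidationError(
                f"correction span [{s.col_start},{s.col_end}) exceeds "
                f"{line.n_cols} columns"
            )
    depth = line.depth_mm.copy()
    for s in overlay.spans:
        depth[s.col_start:s.col_end] = s.depths_mm
    return replace(line, depth_mm=depth, source=SegSource.CORRECTED)


def interpolate_gaps(line: SegLine) -> SegLine:
    """Fill missing columns by linear interpolation between valid neighbours.

    Leading/trailing gaps are filled by nearest-value extension.  The input
    must satisfy the <= 20% missing invariant (enforced by SegLine itself);
    the result is gap-free.  Column count and lateral geometry are unchanged.
    """
    missing = np.isnan(line.depth_mm)
    if not missing.any():
        return line
    valid = ~missing
    idx = np.arange(line.n_cols)
    depth = line.depth_mm.copy()
    depth[missing] = np.interp(idx[missing], idx[valid], line.depth_mm[valid])
    return replace(line, depth_mm=depth)
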