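"""Macular curvature (MC) index: aggregation and classification.

Each radial scan contributes its minimum three-point arc radius r (mm); the
mean over the eye's scans is R (mm), and the MC index is 337.5/R — the same
keratometric convention that converts a corneal radius in mm to diopters, so
an MC index of 40 corresponds to a radius of 8.44 mm, the curvature of a
40-diopter cornea.  Eyes whose steepest posterior-wall curvature exceeds
that reference (index above 40) are consistent with posterior staphyloma.

The classifier exposes the empirical gray zone between the highest index
observed without staphyloma (37.5) and the lowest with definite staphyloma
(42.7) rather than pretending the 40 cutoff is sharp; indices inside the
band are reported as indeterminate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import PipelineConfig
from .curvature import CurvatureProfile, curvature_profile
from .errors import AggregationError, ConfigurationError, ValidationError
from .seg_io import SegLine, interpolate_gaps

#: Keratometric conversion constant (mm of radius <-> diopter-like index).
#: Fixed, not configurable, so indices stay comparable across studies.
KERATOMETRIC_CONSTANT = 337.5


class Classification(str, Enum):
    NO_STAPHYLOMA_CONSISTENT = "no_staphyloma_consistent"
    INDETERMINATE = "indeterminate"
    STAPHYLOMA_CONSISTENT = "staphyloma_consistent"


@dataclass(frozen=True)
class EyeScanSet:
    """The ordered radial scan set of one eye (nominally 12 scans)."""

    eye_id: str
    scans: tuple[tuple[float, CurvatureProfile], ...]
    expected_count: int = 12

    def __post_init__(self) -> None:
        if len(self.scans) < 1:
            raise ValidationError(f"eye {self.eye_id!r} has no scans")
        angles = [a % 180.0 for a, _ in self.scans]
        if len(angles) != len({round(a, 6) for a in angles}):
            raise ValidationError(
                f"eye {self.eye_id!r} has duplicate scan angles modulo 180"
            )
        object.__setattr__(self, "scans", tuple(self.scans))

    @property
    def usable(self) -> tuple[tuple[float, CurvatureProfile], ...]:
        """Scans not flagged all-collinear (those carry no finite minimum)."""
        return tuple((a, p) for a, p in self.scans if not p.all_collinear)


@dataclass(frozen=True)
class MCResult:
    eye_id: str
    R_mm: float
    mc_index: float
    n_scans_used: int
    classification: Classification
    per_scan: tuple[tuple[float, float, int | None], ...]  # (angle, r_mm, r_min_col)
    warnings: tuple[str, ...] = ()
    config_hash: str = ""

    def to_dict(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "R_mm": self.R_mm,
            "mc_index": self.mc_index,
            "classification": self.classification.value,
            "n_scans_used": self.n_scans_used,
            "per_scan": [
                {"angle_deg": a, "r_mm": r, "r_min_col": c}
                for a, r, c in self.per_scan
            ],
            "warnings": list(self.warnings),
            "config_hash": self.config_hash,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def aggregate_R(
    scan_set: EyeScanSet, *, method: str = "mean"
) -> tuple[float, int, list[str]]:
    """Aggregate per-scan minimum radii into the eye radius R (mm).

    Returns ``(R_mm, n_used, warnings)``.  The published construction is the
    unweighted arithmetic mean; ``method="median"`` is a robustness option.
    Flagged (all-collinear) scans are excluded; zero usable scans raise
    :class:`AggregationError`.
    """
    usable = scan_set.usable
    if not usable:
        raise AggregationError(
            f"eye {scan_set.eye_id!r}: no usable scans (all flagged collinear)"
        )
    r_values = np.array([p.r_min_mm for _, p in usable])
    warnings: list[str] = []
    n_flagged = len(scan_set.scans) - len(usable)
    if n_flagged:
        warnings.append(f"{n_flagged} scan(s) flagged collinear and excluded")
    if len(usable) < scan_set.expected_count:
        warnings.append(
            f"only {len(usable)} of {scan_set.expected_count} expected scans used"
        )
    if method == "mean":
        R = float(np.mean(r_values))
    elif method == "median":
        R = float(np.median(r_values))
    else:
        raise ConfigurationError(f"unknown aggregation method {method!r}")
    return R, len(usable), warnings


def compute_mc(R_mm: float) -> float:
    """MC index = 337.5 / R, for R in mm."""
    if not R_mm > 0:
        raise ValidationError(f"R must be positive, got {R_mm}")
    return KERATOMETRIC_CONSTANT / R_mm


def classify(
    mc: float,
    *,
    reference: float = 40.0,
    band: tuple[float, float] | None = (37.5, 42.7),
) -> Classification:
    """Classify an MC index against the staphyloma reference.

    With the gray-zone ``band`` enabled (default), indices above the band are
    staphyloma-consistent, below it no-staphyloma-consistent, inside it
    indeterminate.  With ``band=None``, a strict comparison to ``reference``
    is used (> reference -> staphyloma-consistent).
    """
    if band is not None:
        lo, hi = band
        if lo > hi:
            raise ConfigurationError(f"malformed band: low {lo} > high {hi}")
        if mc > hi:
            return Classification.STAPHYLOMA_CONSISTENT
        if mc < lo:
            return Classification.NO_STAPHYLOMA_CONSISTENT
        return Classification.INDETERMINATE
    return (
        Classification.STAPHYLOMA_CONSISTENT
        if mc > reference
        else Classification.NO_STAPHYLOMA_CONSISTENT
    )


def process_eye(
    lines: Sequence[SegLine], cfg: PipelineConfig | None = None
) -> MCResult:
    """Full per-eye pipeline: gap fill, curvature, aggregate, index, classify.

    All lines must share ``eye_id`` and lateral pitch.  Per-scan diagnostics
    (angle, r, column of the minimum) and any warnings (dropped scans,
    flagged collinear scans) are carried on the result.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if not lines:
        raise ValidationError("process_eye needs at least one segmentation line")
    eye_id = lines[0].eye_id
    px_h = lines[0].px_h
    for ln in lines:
        if ln.eye_id != eye_id:
            raise ValidationError(
                f"mixed eye_ids {eye_id!r} and {ln.eye_id!r} in one scan set"
            )
        if ln.px_h != px_h:
            raise ValidationError(
                f"mixed lateral pitches in eye {eye_id!r} "
                f"(scan angle {ln.scan_angle_deg})"
            )
    profiles = []
    for ln in lines:
        try:
            filled = interpolate_gaps(ln)
            prof = curvature_profile(
                filled,
                cfg.chord_offset_mm,
                roi_margin_cols=cfg.roi_margin_cols,
            )
        except ValidationError as exc:
            raise ValidationError(
                f"eye {eye_id!r}, scan angle {ln.scan_angle_deg}: {exc}"
            ) from exc
        profiles.append((ln.scan_angle_deg, prof))
    scan_set = EyeScanSet(
        eye_id=eye_id, scans=tuple(profiles), expected_count=cfg.expected_scans
    )
    R, n_used, warnings = aggregate_R(scan_set, method=cfg.aggregate)
    mc = compute_mc(R)
    cls = classify(mc, reference=cfg.mc_reference, band=cfg.indeterminate_band)
    per_scan = tuple(
        (a, p.r_min_mm, p.r_min_col) for a, p in scan_set.scans
    )
    return MCResult(
        eye_id=eye_id,
        R_mm=R,
        mc_index=mc,
        n_scans_used=n_used,
        classification=cls,
        per_scan=per_scan,
        warnings=tuple(warnings),
        config_hash=cfg.config_hash(),
    )
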