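"""Synthetic ocular phantoms with analytically known curvature.

A phantom eye is a spherical posterior pole of radius ``rho_mm`` with an
optional Gaussian outpouching (the staphyloma surrogate) of depth amplitude
``bump_A_mm`` and width ``bump_sigma_mm``.  Depth increases downward, the
posterior wall is deepest at the scan centre, and the outpouching deepens it
further, so the sphere and bump curvatures add: along a scan through the
bump apex the depth profile is

    z(t) = z0 + sqrt(rho^2 - t^2) - sqrt(rho^2 - (w/2)^2)
              + A_eff * exp(-(t - t_par)^2 / (2 sigma^2))

with apex curvature 1/rho + A/sigma^2, i.e. a closed-form target apex
radius (1/rho + A/sigma^2)^-1 against which every pipeline stage can be
validated without clinical data.

The bump lives on the 2-D retina at ``(bump_x_mm, bump_y_mm)``; a radial
scan at angle theta through the fovea sees it at in-scan offset
``t_par = bx cos(theta) + by sin(theta)`` with effective amplitude
``A exp(-d_perp^2 / (2 sigma^2))``, so off-centre bumps exercise the
12-scan averaging nontrivially while centred bumps make every scan
identical.

Rendered B-scans place a Gaussian-profile bright band (the RPE surrogate)
on the line, optionally store the raster with the device-style 2x vertical
display stretch (rows duplicated, pitch halved), and add seeded Gaussian
intensity noise.  Everything stochastic is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .curvature import circumradius
from .errors import ValidationError
from .mc_index import Classification, classify, compute_mc
from .seg_io import BScanImage, SegLine, SegSource, write_bscan, write_segline

#: FWHM -> sigma for the rendered band profile.
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic eye."""

    eye_id: str = "phantom"
    rho_mm: float = 12.0            # posterior-pole sphere radius
    bump_A_mm: float = 0.0          # outpouching depth amplitude (0 = none)
    bump_sigma_mm: float = 1.5      # outpouching Gaussian width
    bump_x_mm: float = 0.0          # bump apex position on the retina
    bump_y_mm: float = 0.0
    n_scans: int = 12
    n_cols: int = 643
    px_h: float = 0.014             # mm/px lateral
    px_v: float = 0.0026            # mm/px axial (native, pre-stretch)
    display_stretch: int = 2        # device-style vertical display elongation
    depth_offset_mm: float = 0.3    # depth of the wall at the scan edges
    band_thickness_mm: float = 0.05  # FWHM of the rendered RPE band
    band_amplitude: float = 0.8
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_h <= 0 or self.px_v <= 0:
            raise ValidationError("pixel pitches must be positive")
        half_width = (self.n_cols - 1) * self.px_h / 2.0
        if not self.rho_mm > half_width:
            raise ValidationError(
                f"rho_mm={self.rho_mm} must exceed the scan half-width "
                f"{half_width:.2f} mm"
            )
        if self.bump_A_mm < 0:
            raise ValidationError("bump_A_mm must be >= 0")
        if self.bump_A_mm > 0 and not self.bump_sigma_mm > 0:
            raise ValidationError("bump_sigma_mm must be positive when bump_A_mm > 0")
        if self.n_scans < 1 or self.n_cols < 5:
            raise ValidationError("need n_scans >= 1 and n_cols >= 5")
        # reject bumps so steep the wall stops being a graph z(x)
        max_slope = (
            half_width / math.sqrt(self.rho_mm**2 - half_width**2)
            + (self.bump_A_mm / self.bump_sigma_mm * math.exp(-0.5)
               if self.bump_A_mm > 0 else 0.0)
        )
        if max_slope > 5.0:
            raise ValidationError(
                f"bump parameters give wall slope {max_slope:.1f}; "
                "not a valid depth graph"
            )

    @property
    def scan_angles_deg(self) -> np.ndarray:
        return np.arange(self.n_scans) * (180.0 / self.n_scans)


def apex_radius_mm(spec: PhantomSpec) -> float:
    """Analytic radius of curvature at the bump apex: (1/rho + A/sigma^2)^-1."""
    if spec.bump_A_mm == 0:
        return spec.rho_mm
    return 1.0 / (1.0 / spec.rho_mm + spec.bump_A_mm / spec.bump_sigma_mm**2)


def expected_class(spec: PhantomSpec) -> Classification:
    """Ground-truth classification from the analytic apex radius."""
    return classify(compute_mc(apex_radius_mm(spec)))


def _depth_profile(spec: PhantomSpec, scan_angle_deg: float, t: np.ndarray) -> np.ndarray:
    half_width = (spec.n_cols - 1) * spec.px_h / 2.0
    z = (
        spec.depth_offset_mm
        + np.sqrt(spec.rho_mm**2 - t**2)
        - math.sqrt(spec.rho_mm**2 - half_width**2)
    )
    if spec.bump_A_mm > 0:
        th = math.radians(scan_angle_deg)
        t_par = spec.bump_x_mm * math.cos(th) + spec.bump_y_mm * math.sin(th)
        d_perp = -spec.bump_x_mm * math.sin(th) + spec.bump_y_mm * math.cos(th)
        a_eff = spec.bump_A_mm * math.exp(-d_perp**2 / (2.0 * spec.bump_sigma_mm**2))
        z = z + a_eff * np.exp(-((t - t_par) ** 2) / (2.0 * spec.bump_sigma_mm**2))
    return z


def phantom_line(spec: PhantomSpec, scan_angle_deg: float = 0.0) -> SegLine:
    """Sample the phantom wall along one radial scan as a gap-free SegLine."""
    x = np.arange(spec.n_cols) * spec.px_h
    t = x - x[-1] / 2.0
    return SegLine(
        depth_mm=_depth_profile(spec, scan_angle_deg, t),
        px_h=spec.px_h,
        source=SegSource.MACHINE,
        eye_id=spec.eye_id,
        scan_angle_deg=scan_angle_deg,
    )


def continuous_min_arc_radius(
    spec: PhantomSpec,
    scan_angle_deg: float = 0.0,
    *,
    chord_offset_mm: float = 1.4,
    roi_margin_mm: float = 1.4,
    n_grid: int = 4001,
) -> float:
    """Brute-force three-point oracle on the continuous phantom curve.

    Evaluates the same finite-chord construction — centre point plus
    endpoints ``chord_offset_mm`` to each side — at full floating precision
    on a dense grid of centre positions, and returns the minimum radius.
    Deliberately independent of :func:`maccurv.curvature.curvature_profile`
    (no column raster, scalar circumradius per grid point).
    """
    half_width = (spec.n_cols - 1) * spec.px_h / 2.0
    margin = max(roi_margin_mm, chord_offset_mm)
    a = np.linspace(-half_width + margin, half_width - margin, n_grid)
    best = math.inf
    for t0 in a:
        ts = np.array([t0 - chord_offset_mm, t0, t0 + chord_offset_mm])
        zs = _depth_profile(spec, scan_angle_deg, ts)
        r = circumradius((ts[0], zs[0]), (ts[1], zs[1]), (ts[2], zs[2]))
        if r < best:
            best = r
    return best


def render_bscan(
    line: SegLine,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
) -> BScanImage:
    """Render a B-scan image of a segmentation line.

    A Gaussian bright band of FWHM ``band_thickness_mm`` and peak
    ``band_amplitude`` is centred on the line (pixel-centre depth
    convention, depth = (row + 0.5) * px_v); zero-mean Gaussian noise of
    sigma ``noise_sigma`` is added and the image clipped to [0, 1].  With
    ``display_stretch`` > 1 the stored raster has each row duplicated that
    many times at the correspondingly finer stored pitch, emulating the
    device's 2:1 presentation; metadata records the stretch so detection
    can undo it exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sigma_b = spec.band_thickness_mm / _FWHM
    z = line.depth_mm
    if np.isnan(z).any():
        raise ValidationError("cannot render a line with missing columns")
    n_rows = int(math.ceil((z.max() + 4.0 * sigma_b + 0.05) / spec.px_v))
    d = (np.arange(n_rows) + 0.5) * spec.px_v
    img = spec.band_amplitude * np.exp(
        -((d[:, None] - z[None, :]) ** 2) / (2.0 * sigma_b**2)
    )
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    px_v_stored = spec.px_v
    stretch = int(spec.display_stretch)
    if stretch > 1:
        img = np.repeat(img, stretch, axis=0)
        px_v_stored = spec.px_v / stretch
    return BScanImage(
        pixels=img,
        px_h=spec.px_h,
        px_v=px_v_stored,
        scan_angle_deg=line.scan_angle_deg,
        eye_id=line.eye_id,
        display_stretch=stretch,
    )


def phantom_cohort(
    specs: Sequence[PhantomSpec],
    out_dir: str | Path,
    *,
    write_images: bool = False,
    line_format: str = "csv",
) -> pd.DataFrame:
    """Write a cohort of phantom eyes plus its ground-truth table.

    Per eye, one SegLine file per radial scan (``<eye>_scan<k>.csv`` or
    ``.json``) and optionally rendered TIFF images; ``truth.csv`` records
    the generating geometry, the analytic apex radius and the expected
    classification.  Output is a pure function of the specs (and their
    seeds).  Returns the truth table.
    """
    if len({s.eye_id for s in specs}) != len(specs):
        raise ValidationError("duplicate eye_ids in phantom cohort")
    if line_format not in ("csv", "json"):
        raise ValidationError(f"unknown line format {line_format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        for k, angle in enumerate(spec.scan_angles_deg):
            line = phantom_line(spec, angle)
            write_segline(line, out_dir / f"{spec.eye_id}_scan{k:02d}.{line_format}")
            if write_images:
                img = render_bscan(line, spec, rng)
                write_bscan(img, out_dir / f"{spec.eye_id}_scan{k:02d}.tiff")
        rows.append(
            {
                "eye_id": spec.eye_id,
                "rho_mm": spec.rho_mm,
                "bump_A_mm": spec.bump_A_mm,
                "bump_sigma_mm": spec.bump_sigma_mm,
                "apex_radius_mm": apex_radius_mm(spec),
                "expected_class": expected_class(spec).value,
            }
        )
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "truth.csv", index=False, float_format="%.6f")
    return truth


def demo_cohort_specs(
    n_no_staphyloma: int = 20,
    n_staphyloma: int = 20,
    seed: int = 0,
    **overrides,
) -> list[PhantomSpec]:
    """Randomised demo cohort spanning both sides of the MC-40 reference.

    No-staphyloma eyes are plain spheres with rho in [9.5, 13] mm (MC index
    25.9–35.5, all below the gray zone).  Staphyloma eyes carry a centred
    (fovea-apex) outpouching tuned to an analytic apex radius in
    [4.8, 7.0] mm (apex MC index 48.2–70.3), with width sigma in
    [1.8, 2.6] mm.  Each eye gets its own derived seed.
    """
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    for i in range(n_no_staphyloma):
        specs.append(
            PhantomSpec(
                eye_id=f"NS{i:02d}",
                rho_mm=float(rng.uniform(9.5, 13.0)),
                bump_A_mm=0.0,
                seed=int(rng.integers(2**31)),
                **overrides,
            )
        )
    for i in range(n_staphyloma):
        rho = float(rng.uniform(10.5, 12.5))
        sigma = float(rng.uniform(1.8, 2.6))
        apex = float(rng.uniform(4.8, 7.0))
        A = sigma**2 * (1.0 / apex - 1.0 / rho)
        specs.append(
            PhantomSpec(
                eye_id=f"ST{i:02d}",
                rho_mm=rho,
                bump_A_mm=A,
                bump_sigma_mm=sigma,
                seed=int(rng.integers(2**31)),
                **overrides,
            )
        )
    return specs
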