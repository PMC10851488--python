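# Methods

## The measurement model

A posterior staphyloma is a local outpouching of the posterior eye wall:
its defining geometric signature is a region whose radius of curvature is
smaller than that of the surrounding wall. On an OCT B-scan the wall is
traced by the RPE segmentation line, so the package reduces "how steep is
the steepest part of the posterior pole?" to a one-dimensional curve
problem, solved per radial scan and aggregated per eye.

All geometry is computed in physical millimetres. A raster column *i* at
depth row *j* maps to (x, z) = (x₀ + i·px_h, (j + 0.5)·px_v) with depth
increasing downward from the image top. OCT devices commonly display
B-scans stretched two-fold vertically; since the stretch is integer row
duplication, carrying the true pitches and working in mm makes the "1:1
aspect correction" an exact no-op rather than a resample (verified
bit-for-bit in the test suite).

### Three-point arc radius

At each region-of-interest column *a*, endpoints *b* and *c* sit
`chord_offset_cols = round(chord_offset_mm / px_h)` columns to either side
(offsets are column counts, i.e. lateral distance, not arc length). The
arc radius is the circumradius of the three points,
R = |ab||bc||ac| / (4·area). Triangle areas below 1e−12 mm² are treated as
collinear and mapped to an infinite-radius sentinel — this guards the
division without turning genuinely flat anatomy into spurious minima.
Collinear columns are excluded from the per-scan minimum; a fully straight
line yields a flagged profile rather than a number. Ties for the minimum
break to the smallest column index, for determinism.

Two readings of the chord construction are possible: endpoints 1.4 mm
*from the centre column* (full chord 2.8 mm) or 1.4 mm *from each other*.
The package implements the first as the default (`chord_offset_mm = 1.4`),
matching the 100-pixels-per-side construction; the knob accepts any value
so the second reading can be run as a sensitivity analysis.

The ROI excludes 100 columns per side by default and is never narrower
than the chord offset, so both endpoints always exist for every evaluated
column.

### Aggregation and classification

Per scan, the minimum defined radius is r (mm); per eye, R is the
unweighted arithmetic mean of r over the usable scans — exactly the
published construction; a median option exists for robustness studies and
is deliberately not the default. Fewer than the expected 12 usable scans
aggregates with a warning rather than rejecting: dropped scans are an
auditing concern, not a hard failure. Zero usable scans is an error.

MC index = 337.5/R. The constant is the keratometric convention converting
a corneal radius in mm to diopters and is intentionally not configurable,
so indices stay comparable across studies; MC 40 ↔ R = 8.44 mm (337.5/40
= 8.4375, printed to two decimals).

Classification defaults to a gray zone [37.5, 42.7] — the empirical
extremes observed clinically between eyes without and with definite
staphyloma — rather than pretending the 40 cutoff is sharp: above the band
is `staphyloma_consistent`, below is `no_staphyloma_consistent`, inside is
`indeterminate`. Disabling the band (`--no-band`) gives a strict
comparison against the single reference.

## RPE detection

The device's own segmentation is not reimplemented; when only raw images
are available, a simple detector stands in and is validated purely against
rendered phantoms. Per column, intensities are smoothed axially (Gaussian,
σ = 2 px), the candidate band is the *deepest* local maximum above the
contrast threshold (default 0.3 of full scale) — the RPE is the posterior
hyperreflective band, so depth breaks ties against inner retinal layers —
and its depth is the intensity-weighted centroid of the contiguous region
above 20% of the peak. The depth series is then median-filtered
(half-width 5 columns, edge-replicating, exact on monotone slopes);
columns with no qualifying band stay missing and are never invented by the
filter. Detection fails if more than 20% of columns are missing.

If the image metadata records a display stretch, the duplicated row groups
are collapsed by averaging before detection. Averaging duplicated rows is
the exact floating-point inverse of the duplication, so stretched and
native rasters produce bit-identical lines and downstream profiles.

Gap policy: up to 20% missing columns are filled by linear interpolation
(nearest-value extension at the ends); beyond that the line is rejected,
so fabricated geometry can never dominate the minimum-radius search.
Manual corrections are applied as explicit column-span overlays recorded
in the output provenance (`source = corrected`).

## The phantom generator

The synthetic eye is a spherical posterior pole of radius ρ (default
12 mm, a typical emmetropic posterior-pole radius) with an optional
Gaussian outpouching of depth amplitude A and width σ. Along a scan
through the apex:

    z(t) = z₀ + sqrt(ρ² − t²) − sqrt(ρ² − (w/2)²) + A·exp(−(t − t∥)²/(2σ²))

The wall is deepest at the scan centre and the outpouching deepens it
further, so the sphere and bump curvatures add and the apex radius of
curvature is (1/ρ + A/σ²)⁻¹ in closed form. (The sign convention matters:
an outpouching must curve *with* the wall, not against it — this is what
makes the analytic apex target valid.) The bump lives on the 2-D retina at
(bump_x, bump_y); a radial scan at angle θ sees effective amplitude
A·exp(−d⊥²/(2σ²)) at in-scan offset t∥, so off-centre bumps make the
12-scan averaging nontrivial while centred bumps (the typical fovea-apex
staphyloma) make all scans identical.

Rendered B-scans place a Gaussian bright band (FWHM 0.05 mm, peak 0.8 —
an RPE-like band a few pixels thick at the default 0.0026 mm axial pitch)
on the line, add seeded zero-mean Gaussian intensity noise, clip to
[0, 1], and optionally store the raster with the 2× display stretch. All
stochastic output is a pure function of (spec, seed).

Defaults mirror the published acquisition geometry: 12 radial scans,
643 columns at 0.014 mm/px (9.0 mm scan length, 1.4 mm = 100 px), axial
pitch 0.0026 mm/px. The axial pitch and raster height of the clinical
device are not public; 0.0026 mm/px is a representative swept-source OCT
value and is metadata, never inferred, in real use.

**Finite-chord bias.** The three-point radius over a 2.8 mm chord on a
non-circular curve differs systematically from the osculating (apex)
radius — for a bump narrower than the chord the measured minimum can be
~30% larger than the analytic apex value. All phantom tolerances are
therefore defined against a brute-force three-point oracle evaluated on
the *continuous* curve (dense centre grid, full precision, independent
scalar solver), not against the osculating value. The demo cohorts place
staphyloma-eye apex radii in [4.8, 7.0] mm and plain spheres in
[9.5, 13] mm so that ground-truth classes sit clearly outside the
[337.5/42.7, 337.5/37.5] ≈ [7.90, 9.00] mm gray zone even after the
finite-chord bias.

### What the phantoms do and do not show

Phantoms exercise the full numerical chain — detection, mm conversion,
chord construction, minimum search, aggregation, classification — against
exact ground truth. They do not emulate speckle statistics, choroidal or
scleral layers, vessel shadows, motion artefacts, or segmentation
ambiguity at the staphyloma edge; passing on phantoms therefore validates
the geometry and the software contract, not clinical detection
performance on real OCT.

## Numerical and design choices

- Pixel pitches are required metadata and never inferred from image size;
  the only built-in default is the lateral 0.014 mm/px implied by the
  100 px = 1.4 mm construction, exposed in configuration.
- Collinearity tolerance 1e−12 mm²; circumradius via the product/area
  formula (chords here are millimetres, sagittae tens of microns, so the
  formula is far from its ill-conditioned regime); an independent
  linear-system circle solver is the test oracle.
- No smoothing or spline refit of the line before curvature: the
  construction is deliberately the raw three-point arc.
- Scan sizes in the test and acceptance suites (643-column lines, 40-eye
  cohorts, single noisy renders at σ = 0.1) were chosen as the smallest
  sets that exercise every contract with comfortable statistical margin;
  the whole suite runs in a few seconds.

## Known limitations

- The detector is a phantom-validated stand-in, not a replacement for
  device segmentation of pathological retinas.
- Only graph-representable walls (single depth per column) are modelled;
  extreme staphylomas with overhanging contours are out of scope, as are
  staphyloma subtype localisation and 3-D surface curvature across scans.
- The gray-zone defaults are empirical values from a single clinical
  cohort; they are configuration, not biology.
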