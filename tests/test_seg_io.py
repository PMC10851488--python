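"""B-scan / segmentation-line I/O, RPE detection, corrections and gaps."""

import numpy as np
import pytest
import tifffile
import imageio.v3 as iio

from maccurv import (
    BScanImage,
    ConfigurationError,
    CorrectionOverlay,
    CorrectionSpan,
    DetectionError,
    FormatError,
    PhantomSpec,
    RejectionError,
    SegLine,
    SegSource,
    ValidationError,
    apply_corrections,
    detect_rpe_line,
    interpolate_gaps,
    load_segline,
    phantom_line,
    read_bscan,
    render_bscan,
    write_segline,
)
from util import circle_line


META = {"px_h": 0.014, "px_v": 0.0026, "scan_angle_deg": 15.0, "eye_id": "E01"}


class TestReadBScan:
    def test_16bit_tiff_is_normalised(self, tmp_path, rng):
        arr = rng.integers(0, 65536, size=(64, 643), dtype=np.uint16)
        arr[10, 5] = 65535
        path = tmp_path / "scan.tiff"
        tifffile.imwrite(path, arr)
        img = read_bscan(path, META)
        assert img.n_cols == 643
        assert img.pixels.max() == 1.0 and img.pixels.min() >= 0.0
        assert img.scan_len_mm == pytest.approx(9.002)
        assert img.eye_id == "E01" and img.scan_angle_deg == 15.0

    def test_8bit_png_roundtrip(self, tmp_path, rng):
        arr = rng.integers(0, 256, size=(64, 320), dtype=np.uint8)
        path = tmp_path / "scan.png"
        iio.imwrite(path, arr)
        img = read_bscan(path, META)
        assert img.pixels.shape == (64, 320)
        assert img.pixels.max() <= 1.0

    def test_missing_pitch_metadata_is_a_configuration_error(self, tmp_path, rng):
        path = tmp_path / "scan.tiff"
        tifffile.imwrite(path, rng.integers(0, 255, (64, 320)).astype(np.uint8))
        with pytest.raises(ConfigurationError):
            read_bscan(path, {"px_h": 0.014})

    def test_rgb_image_is_a_format_error(self, tmp_path, rng):
        path = tmp_path / "scan.png"
        iio.imwrite(path, rng.integers(0, 255, (64, 320, 3)).astype(np.uint8))
        with pytest.raises(FormatError):
            read_bscan(path, META)

    def test_inconsistent_scan_length_rejected(self, tmp_path, rng):
        path = tmp_path / "scan.tiff"
        tifffile.imwrite(path, rng.integers(0, 255, (64, 643)).astype(np.uint8))
        with pytest.raises(ValidationError):
            read_bscan(path, {**META, "scan_len_mm": 12.0})


class TestSegLineFiles:
    @pytest.fixture
    def line_with_gaps(self):
        depth = circle_line(11.0, eye_id="E02").depth_mm.copy()
        depth[[7, 8, 9, 200, 641]] = np.nan
        return SegLine(
            depth_mm=depth, px_h=0.014, eye_id="E02", scan_angle_deg=30.0,
            source=SegSource.MACHINE,
        )

    def test_json_roundtrip_is_lossless(self, tmp_path, line_with_gaps):
        path = tmp_path / "line.json"
        write_segline(line_with_gaps, path)
        back = load_segline(path)
        np.testing.assert_array_equal(back.depth_mm, line_with_gaps.depth_mm)
        assert back.px_h == line_with_gaps.px_h
        assert (back.eye_id, back.scan_angle_deg, back.source) == (
            "E02", 30.0, SegSource.MACHINE,
        )

    def test_csv_roundtrip_to_six_decimals(self, tmp_path, line_with_gaps):
        path = tmp_path / "line.csv"
        write_segline(line_with_gaps, path)
        back = load_segline(path)
        assert back.n_cols == line_with_gaps.n_cols
        np.testing.assert_array_equal(
            np.isnan(back.depth_mm), np.isnan(line_with_gaps.depth_mm)
        )
        ok = ~np.isnan(back.depth_mm)
        np.testing.assert_allclose(
            back.depth_mm[ok], line_with_gaps.depth_mm[ok], atol=5e-7
        )
        assert back.px_h == line_with_gaps.px_h

    def test_too_many_missing_rejected(self, tmp_path):
        rows = ["# px_h_mm=0.014", "col,depth_mm"]
        rows += [f"{i},{'' if i < 200 else '1.0'}" for i in range(643)]
        path = tmp_path / "gappy.csv"
        path.write_text("\n".join(rows))
        with pytest.raises(RejectionError):
            load_segline(path)  # 200/643 = 31% missing

    def test_non_uniform_columns_are_a_format_error(self, tmp_path):
        rows = ["# px_h_mm=0.014", "col,depth_mm", "0,1.0", "1,1.0", "3,1.0"]
        path = tmp_path / "bad.csv"
        path.write_text("\n".join(rows))
        with pytest.raises(FormatError):
            load_segline(path)

    def test_missing_pitch_header_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("col,depth_mm\n0,1.0\n1,1.0\n2,1.0\n")
        with pytest.raises(FormatError):
            load_segline(path)


class TestCorrections:
    def test_empty_overlay_is_identity(self):
        line = circle_line(11.0)
        out = apply_corrections(line, CorrectionOverlay())
        np.testing.assert_array_equal(out.depth_mm, line.depth_mm)
        assert out.source == line.source

    def test_span_replaces_exactly_those_columns(self):
        line = circle_line(11.0)
        repl = tuple(np.linspace(1.0, 1.09, 10))
        overlay = CorrectionOverlay(spans=(CorrectionSpan(100, 110, repl),))
        out = apply_corrections(line, overlay)
        assert out.source == SegSource.CORRECTED
        np.testing.assert_array_equal(out.depth_mm[100:110], repl)
        changed = out.depth_mm != line.depth_mm
        assert np.flatnonzero(changed).tolist() == list(range(100, 110))
        np.testing.assert_array_equal(out.x_mm, line.x_mm)

    def test_out_of_range_span_rejected(self):
        line = circle_line(11.0)  # 643 columns
        overlay = CorrectionOverlay(
            spans=(CorrectionSpan(640, 650, tuple([1.0] * 10)),)
        )
        with pytest.raises(ValidationError):
            apply_corrections(line, overlay)

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValidationError):
            CorrectionOverlay(
                spans=(
                    CorrectionSpan(0, 5, (1.0,) * 5),
                    CorrectionSpan(3, 8, (1.0,) * 5),
                )
            )

    def test_span_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            CorrectionSpan(0, 5, (1.0, 2.0))

    def test_overlay_json_loading(self, tmp_path):
        path = tmp_path / "fix.corrections.json"
        path.write_text('[{"col_start": 2, "col_end": 4, "depths_mm": [1.5, 1.6]}]')
        overlay = CorrectionOverlay.from_json(path)
        assert overlay.spans[0].depths_mm == (1.5, 1.6)


class TestInterpolateGaps:
    def test_linear_fill_between_neighbours(self):
        depth = np.array([1.00, np.nan, np.nan, np.nan, 1.04, 1.05])
        line = SegLine(depth_mm=np.r_[np.full(20, 1.0), depth], px_h=0.01)
        out = interpolate_gaps(line)
        np.testing.assert_allclose(out.depth_mm[21:24], [1.01, 1.02, 1.03])
        assert out.is_gap_free

    def test_leading_gap_extends_nearest_value(self):
        depth = np.r_[[np.nan, np.nan], np.full(20, 0.5)]
        out = interpolate_gaps(SegLine(depth_mm=depth, px_h=0.01))
        np.testing.assert_array_equal(out.depth_mm[:2], [0.5, 0.5])

    def test_gap_free_line_unchanged(self):
        line = circle_line(11.0)
        out = interpolate_gaps(line)
        assert out is line

    def test_geometry_preserved(self):
        depth = circle_line(11.0).depth_mm.copy()
        depth[50:60] = np.nan
        line = SegLine(depth_mm=depth, px_h=0.014)
        out = interpolate_gaps(line)
        assert out.n_cols == line.n_cols
        np.testing.assert_array_equal(out.x_mm, line.x_mm)

    def test_rejects_more_than_20pct_missing_at_construction(self):
        depth = np.full(100, 1.0)
        depth[:21] = np.nan
        with pytest.raises(RejectionError):
            SegLine(depth_mm=depth, px_h=0.01)


class TestDetectRpeLine:
    def test_noiseless_render_recovered_within_half_pixel(self):
        spec = PhantomSpec(eye_id="P", rho_mm=10.0, bump_A_mm=0.3,
                           bump_sigma_mm=1.5, display_stretch=1)
        line = phantom_line(spec)
        det = detect_rpe_line(render_bscan(line, spec))
        assert det.source == SegSource.DETECTED
        assert det.is_gap_free
        err = np.abs(det.depth_mm - line.depth_mm)
        assert err.max() <= spec.px_v / 2

    def test_all_zero_image_fails_detection(self):
        img = BScanImage(pixels=np.zeros((50, 320)), px_h=0.014, px_v=0.0026)
        with pytest.raises(DetectionError):
            detect_rpe_line(img)

    def test_deepest_band_wins_over_shallower_inner_layers(self):
        # two bright bands: the detector must lock onto the deeper (RPE-like)
        n_rows, n_cols = 200, 320
        rows = np.arange(n_rows)[:, None]
        img_arr = (
            0.9 * np.exp(-((rows - 60.0) ** 2) / 18.0)
            + 0.7 * np.exp(-((rows - 140.0) ** 2) / 18.0)
            + np.zeros((1, n_cols))
        )
        img = BScanImage(pixels=img_arr, px_h=0.014, px_v=0.0026)
        det = detect_rpe_line(img)
        np.testing.assert_allclose(det.depth_mm, (140 + 0.5) * 0.0026, atol=0.0026)
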