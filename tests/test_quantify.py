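"""Specimen measurement, group summaries, ΔC, and the batch pipeline."""

import math

import numpy as np
import pandas as pd
import pytest

from cvchroma.colorspace import ConversionOptions, D65_WHITE_XY
from cvchroma.imaging import ImageRecord, ROISpec
from cvchroma.quantify import (
    compare_groups,
    measure_specimen,
    run_experiment,
    summarize_group,
)
from cvchroma.synthetic import SyntheticExperiment, SyntheticSpec, generate_experiment

FULL = ROISpec.rectangle(0, 10, 0, 10)


def _measure(pixels, mode, **kw):
    img = ImageRecord(pixels=np.asarray(pixels, dtype=np.uint8))
    h, w = img.shape
    return measure_specimen(img, ROISpec.rectangle(0, h, 0, w), mode=mode, **kw)


class TestMeasureSpecimen:
    @pytest.mark.parametrize("mode", ["mean-then-convert", "per-pixel"])
    def test_gray_maps_to_white_point(self, constant_image, mode):
        m = measure_specimen(constant_image((128, 128, 128)), FULL, mode=mode)
        np.testing.assert_allclose((m.x, m.y), D65_WHITE_XY, atol=1e-9)

    def test_modes_agree_on_constant_field(self, constant_image):
        img = constant_image((180, 40, 160))
        a = measure_specimen(img, FULL, mode="mean-then-convert")
        b = measure_specimen(img, FULL, mode="per-pixel")
        assert a.x == pytest.approx(b.x, abs=1e-12)
        assert a.y == pytest.approx(b.y, abs=1e-12)

    def test_modes_differ_on_two_colour_fixture(self):
        """Averaging before vs after the nonlinear projection must differ,
        and each route must match a scalar hand-rolled oracle."""

        def srgb_dec(c):
            return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4

        def to_xy(r, g, b):
            R, G, B = srgb_dec(r / 255), srgb_dec(g / 255), srgb_dec(b / 255)
            X = 0.4124 * R + 0.3576 * G + 0.1805 * B
            Y = 0.2126 * R + 0.7152 * G + 0.0722 * B
            Z = 0.0193 * R + 0.1192 * G + 0.9505 * B
            s = X + Y + Z
            return X / s, Y / s

        pixels = [[[255, 0, 0], [0, 0, 255]]]
        mean_mode = _measure(pixels, "mean-then-convert")
        pixel_mode = _measure(pixels, "per-pixel")

        # oracle, mean route: channel means are (127.5, 0, 127.5)
        exp_mean = to_xy(127.5, 0.0, 127.5)
        # oracle, per-pixel route: average the two chromaticities
        red, blue = to_xy(255, 0, 0), to_xy(0, 0, 255)
        exp_pixel = ((red[0] + blue[0]) / 2, (red[1] + blue[1]) / 2)

        np.testing.assert_allclose((mean_mode.x, mean_mode.y), exp_mean, atol=1e-12)
        np.testing.assert_allclose((pixel_mode.x, pixel_mode.y), exp_pixel, atol=1e-12)
        assert abs(mean_mode.x - pixel_mode.x) > 1e-3  # the routes genuinely differ

    def test_black_roi_mean_mode_errors(self, constant_image):
        with pytest.raises(ValueError, match="pure black"):
            measure_specimen(constant_image((0, 0, 0)), FULL, mode="mean-then-convert")

    def test_per_pixel_excludes_black(self):
        pixels = [[[0, 0, 0], [200, 100, 50]]]
        m = _measure(pixels, "per-pixel")
        assert m.n_black_excluded == 1
        single = _measure([[[200, 100, 50], [200, 100, 50]]], "per-pixel")
        assert m.x == pytest.approx(single.x, abs=1e-12)

    def test_all_black_per_pixel_errors(self, constant_image):
        with pytest.raises(ValueError, match="black"):
            measure_specimen(constant_image((0, 0, 0)), FULL, mode="per-pixel")

    def test_options_recorded(self, constant_image):
        opts = ConversionOptions(linearize=False)
        m = measure_specimen(constant_image((90, 90, 90)), FULL, options=opts)
        assert m.linearize is False
        assert m.mode == "mean-then-convert"


def _meas(x, y, cond="c", sid="s"):
    from cvchroma.quantify import SpecimenMeasurement

    return SpecimenMeasurement(
        specimen_id=sid, condition=cond, x=x, y=y, L=50, a=0, b=0,
        mean_r=0.5, mean_g=0.5, mean_b=0.5, n_pixels=100,
        mode="mean-then-convert", linearize=True,
    )


class TestSummarizeGroup:
    def test_single_measurement_flagged(self):
        s = summarize_group([_meas(0.31, 0.32)])
        assert (s.mean_x, s.mean_y) == (0.31, 0.32)
        assert s.sd_x == s.sd_y == 0.0
        assert s.single_replicate and s.n == 1

    def test_two_point_sample_sd(self):
        s = summarize_group([_meas(0.30, 0.30), _meas(0.32, 0.34)])
        assert s.mean_x == pytest.approx(0.31)
        assert s.mean_y == pytest.approx(0.32)
        assert s.sd_x == pytest.approx(0.02 / math.sqrt(2), abs=1e-6)  # 0.014142
        assert s.sd_y == pytest.approx(0.04 / math.sqrt(2), abs=1e-6)  # 0.028284

    def test_identical_points_zero_sd(self):
        s = summarize_group([_meas(0.3, 0.3)] * 3)
        assert s.sd_x == 0.0 and s.sd_y == 0.0 and not s.single_replicate

    def test_empty_and_mixed_conditions_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_group([])
        with pytest.raises(ValueError, match="mixed"):
            summarize_group([_meas(0.3, 0.3, "a"), _meas(0.3, 0.3, "b")])


class TestCompareGroups:
    def test_identical_groups_zero(self):
        a = summarize_group([_meas(0.31, 0.32)])
        assert compare_groups(a, a).delta_c == 0.0

    def test_published_group_means(self):
        """Bare Ti vs 3-day E. coli rounded group means give ΔC ≈ 0.0112."""
        a = summarize_group([_meas(0.3237, 0.3425, "Ti only")])
        b = summarize_group([_meas(0.3171, 0.3335, "E. coli 3d", sid="t")])
        assert compare_groups(a, b).delta_c == pytest.approx(0.011161, abs=1e-5)

    def test_three_four_five(self):
        a = summarize_group([_meas(0.300, 0.300)])
        b = summarize_group([_meas(0.303, 0.304, "d", sid="t")])
        assert compare_groups(a, b).delta_c == pytest.approx(0.005, abs=1e-12)

    def test_symmetry(self):
        a = summarize_group([_meas(0.31, 0.33, "a")])
        b = summarize_group([_meas(0.30, 0.32, "b")])
        assert compare_groups(a, b).delta_c == compare_groups(b, a).delta_c


@pytest.fixture
def synthetic_sheet(tmp_path):
    exp = SyntheticExperiment(
        conditions=(
            ("base", SyntheticSpec(target_xy=(0.3237, 0.3425), size=(16, 16)), 3),
            ("day3", SyntheticSpec(target_xy=(0.3171, 0.3335), size=(16, 16)), 3),
        )
    )
    return generate_experiment(exp, tmp_path / "exp", master_seed=11)


class TestRunExperiment:
    def test_counting_contract(self, synthetic_sheet):
        res = run_experiment(synthetic_sheet)
        assert len(res.measurements) == 6
        assert len(res.summaries) == 2
        assert len(res.differences) == 1
        assert res.baseline == "base"
        assert res.differences.iloc[0]["condition_b"] == "day3"

    def test_missing_file_collected_not_fatal(self, synthetic_sheet):
        sheet = pd.read_csv(synthetic_sheet)
        sheet["image_path"] = [
            str(synthetic_sheet.parent / p) for p in sheet["image_path"]
        ]
        sheet.loc[0, "image_path"] = "does_not_exist.png"
        res = run_experiment(sheet)
        assert len(res.measurements) == 5
        assert len(res.errors) == 1
        assert "does_not_exist" in res.errors[0]["error"] or res.errors[0]["specimen_id"]

    def test_all_failed_raises(self):
        sheet = pd.DataFrame(
            {"specimen_id": ["a"], "condition": ["c"], "image_path": ["gone.png"]}
        )
        with pytest.raises(RuntimeError, match="all 1"):
            run_experiment(sheet)

    def test_row_permutation_invariance(self, synthetic_sheet):
        sheet = pd.read_csv(synthetic_sheet)
        sheet["image_path"] = [
            str(synthetic_sheet.parent / p) for p in sheet["image_path"]
        ]
        res1 = run_experiment(sheet)
        res2 = run_experiment(sheet.sample(frac=1, random_state=3), baseline="base")
        pd.testing.assert_frame_equal(res1.measurements, res2.measurements)
        pd.testing.assert_frame_equal(res1.differences, res2.differences)

    def test_unknown_baseline_rejected(self, synthetic_sheet):
        with pytest.raises(ValueError, match="baseline"):
            run_experiment(synthetic_sheet, baseline="nope")
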