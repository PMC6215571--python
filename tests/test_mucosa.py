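"""Morphometry tests: ROI rasterization, Eq.-style per-um statistic, areas."""

from dataclasses import replace

import numpy as np
import pytest

from dabquant import (
    MucosaHeights,
    ROIPolygon,
    RunConfig,
    expression_per_um,
    generate_slide,
    mean_mucosal_height,
    mucosa_length,
    percent_dab_area,
    quantify_sample,
    rasterize_roi,
)
from dabquant.errors import (
    InvalidNormalizerError,
    InvalidROIError,
    MissingMeasurementError,
)
from dabquant.stains import RGBImage
from dabquant.validation import (
    height_sensitivity_ratio,
    tiling_additivity_error,
)


def _bruteforce_point_in_polygon(vertices, x, y):
    """Independent even-odd ray-casting oracle."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


class TestRasterizeRoi:
    def test_rectangle_on_half_integer_corners_counts_exactly(self):
        roi = ROIPolygon([(-0.5, -0.5), (9.5, -0.5), (9.5, 9.5), (-0.5, 9.5)])
        mask = rasterize_roi(roi, (20, 20))
        assert mask.sum() == 100
        assert mask[:10, :10].all()
        assert not mask[10:, :].any() and not mask[:, 10:].any()

    def test_triangle_matches_bruteforce_oracle(self):
        verts = [(1.2, 0.7), (17.3, 3.1), (8.9, 15.4)]
        roi = ROIPolygon(verts)
        mask = rasterize_roi(roi, (18, 19))
        expected = np.array(
            [[_bruteforce_point_in_polygon(verts, x, y) for x in range(19)] for y in range(18)]
        )
        assert np.array_equal(mask, expected)

    def test_polygon_fully_outside_warns_and_returns_empty(self):
        roi = ROIPolygon([(100.0, 100.0), (110.0, 100.0), (105.0, 110.0)])
        with pytest.warns(UserWarning):
            mask = rasterize_roi(roi, (20, 20))
        assert not mask.any()

    def test_polygon_partially_outside_is_clipped_with_warning(self):
        roi = ROIPolygon([(-5.5, -0.5), (9.5, -0.5), (9.5, 9.5), (-5.5, 9.5)])
        with pytest.warns(UserWarning):
            mask = rasterize_roi(roi, (20, 20))
        assert mask.sum() == 100  # only the in-image 10x10 block remains

    def test_degenerate_polygons_rejected(self):
        with pytest.raises(InvalidROIError):
            ROIPolygon([(0, 0), (1, 1)])  # too few vertices
        with pytest.raises(InvalidROIError):
            rasterize_roi(ROIPolygon([(0, 0), (5, 0), (10, 0)]), (20, 20))  # zero area
        bowtie = ROIPolygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(InvalidROIError):
            rasterize_roi(bowtie, (20, 20))  # self-intersecting


class TestHeightsAndLength:
    def test_mean_height_examples(self):
        with pytest.warns(UserWarning):  # one site instead of the usual ten
            assert mean_mucosal_height(MucosaHeights([300.0])) == 300.0
        assert mean_mucosal_height(MucosaHeights([250.0] * 10)) == 250.0
        tens = MucosaHeights([100, 200, 300, 400, 500, 600, 700, 800, 900, 1000])
        assert mean_mucosal_height(tens) == 550.0  # 5500 / 10

    def test_empty_heights_rejected(self):
        with pytest.raises(MissingMeasurementError):
            MucosaHeights([])

    def test_nonpositive_heights_rejected(self):
        with pytest.raises(ValueError):
            MucosaHeights([100.0, -3.0])

    @pytest.mark.parametrize(
        "area_px, px_um, height_um, expected",
        [
            (10_000, 1.0, 100.0, 100.0),
            (10_000, 0.5, 50.0, 50.0),  # 10000 * 0.25 / 50
        ],
    )
    def test_mucosa_length_examples(self, area_px, px_um, height_um, expected):
        assert mucosa_length(area_px, px_um, height_um) == pytest.approx(expected)

    def test_doubling_height_halves_length(self):
        assert mucosa_length(5000, 1.0, 200.0) == pytest.approx(
            mucosa_length(5000, 1.0, 100.0) / 2
        )

    def test_pixel_size_scales_length_quadratically(self):
        l1 = mucosa_length(7000, 1.0, 150.0)
        l2 = mucosa_length(7000, 2.0, 150.0)
        assert l2 == pytest.approx(4.0 * l1)

    def test_zero_height_rejected(self):
        with pytest.raises(InvalidNormalizerError):
            mucosa_length(100, 1.0, 0.0)


class TestExpressionStatistics:
    def test_expression_per_um_examples(self):
        assert expression_per_um(0.0, 123.0) == 0.0
        assert expression_per_um(5000.0, 100.0) == 50.0
        with pytest.raises(InvalidNormalizerError):
            expression_per_um(10.0, 0.0)

    def test_percent_dab_area_examples(self):
        roi = np.zeros((20, 20), bool)
        roi[:10, :20] = True  # 200-pixel ROI
        superset = np.ones((20, 20), bool)
        assert percent_dab_area(superset, roi) == 100.0
        disjoint = np.zeros((20, 20), bool)
        disjoint[15:, :] = True
        assert percent_dab_area(disjoint, roi) == 0.0
        partial = np.zeros((20, 20), bool)
        partial[:5, :5] = True  # 25 of 200
        assert percent_dab_area(partial, roi) == 12.5

    def test_percent_dab_area_errors(self):
        roi = np.zeros((4, 4), bool)
        with pytest.raises(InvalidROIError):
            percent_dab_area(np.ones((4, 4), bool), roi)
        with pytest.raises(InvalidROIError):
            percent_dab_area(np.ones((3, 3), bool), np.ones((4, 4), bool))

    def test_adding_positive_pixels_never_decreases_statistics(self):
        roi = np.ones((10, 10), bool)
        base = np.zeros((10, 10), bool)
        base[2:4, 2:4] = True
        more = base.copy()
        more[7, 7] = True
        assert percent_dab_area(more, roi) > percent_dab_area(base, roi)


class TestQuantifySample:
    def test_blank_white_image_measures_zero(self, default_config):
        image = RGBImage(np.full((64, 64, 3), 255, dtype=np.uint8), pixel_size_um=1.0)
        roi = ROIPolygon([(-0.5, -0.5), (63.5, -0.5), (63.5, 63.5), (-0.5, 63.5)])
        heights = MucosaHeights([40.0] * 10)
        res = quantify_sample(image, roi, heights, default_config)
        assert res.expr_per_um == 0.0
        assert res.pct_area == 0.0
        assert res.roi_area_px == 64 * 64

    def test_percent_area_tracks_ground_truth(self, noise_free_bundle, default_config):
        res = quantify_sample(
            noise_free_bundle.image,
            noise_free_bundle.roi,
            noise_free_bundle.heights,
            default_config,
        )
        assert res.pct_area == pytest.approx(noise_free_bundle.truth.area_fraction_pct, abs=2.0)

    def test_result_bookkeeping_invariants(self, noise_free_bundle, default_config):
        res = quantify_sample(
            noise_free_bundle.image,
            noise_free_bundle.roi,
            noise_free_bundle.heights,
            default_config,
        )
        assert res.length_um * res.mean_height_um == pytest.approx(res.roi_area_um2, rel=1e-6)
        assert 0.0 <= res.pct_area <= 100.0
        assert res.expr_per_um >= 0.0
        assert res.total_intensity <= 255 * res.n_dab_px

    def test_tiling_additivity_is_exact(self):
        assert tiling_additivity_error(seed=4) < 1e-9

    def test_doubling_height_doubles_expression(self):
        assert height_sensitivity_ratio(seed=4) == pytest.approx(2.0, abs=1e-12)

    def test_pixel_size_bookkeeping(self, small_spec, default_config):
        # same pixel grid declared at a different physical scale: length
        # scales as p^2 while the area invariant keeps holding
        bundle = generate_slide(replace(small_spec, seed=13))
        res1 = quantify_sample(bundle.image, bundle.roi, bundle.heights, default_config)
        rescaled = RGBImage(bundle.image.pixels, pixel_size_um=2.0)
        res2 = quantify_sample(rescaled, bundle.roi, bundle.heights, default_config)
        assert res2.length_um == pytest.approx(4.0 * res1.length_um, rel=1e-12)
        assert res2.length_um * res2.mean_height_um == pytest.approx(res2.roi_area_um2, rel=1e-6)
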