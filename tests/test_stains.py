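"""Stain-separation unit tests: OD conversion, deconvolution, 8-bit mapping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dabquant.errors import DegenerateStainBasisError, InvalidReferenceError
from dabquant.stains import (
    DABIntensityMap,
    StainMatrix,
    ThresholdWindow,
    apply_threshold_window,
    deconvolve,
    default_hdab_stain_matrix,
    detect_dab,
    rgb_to_od,
    to_inverted_8bit,
)


class TestStainMatrix:
    def test_default_matrix_satisfies_invariants(self):
        sm = default_hdab_stain_matrix()
        assert np.allclose(np.linalg.norm(sm.matrix, axis=1), 1.0, atol=1e-9)
        assert np.all(sm.matrix >= 0)
        assert sm.condition_number() < 1e6

    def test_pure_dab_pixel_deconvolves_to_zero_hematoxylin(self):
        # forward Beer-Lambert along the DAB direction only, inverted exactly
        sm = default_hdab_stain_matrix()
        c = 0.7
        od = c * sm.matrix[1]
        conc = deconvolve(od.reshape(1, 1, 3), sm)
        assert conc.hematoxylin[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert conc.dab[0, 0] == pytest.approx(c, abs=1e-9)
        assert conc.residual[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_singular_matrix_rejected(self):
        v = np.array([0.6, 0.6, np.sqrt(1 - 2 * 0.36)])
        with pytest.raises(DegenerateStainBasisError):
            StainMatrix(np.vstack([v, v, v]))

    def test_non_unit_rows_rejected(self):
        with pytest.raises(ValueError):
            StainMatrix(np.eye(3) * 2.0)


class TestRgbToOd:
    @pytest.mark.parametrize(
        "pixel, expected",
        [
            ((255, 255, 255), 0.0),
            ((25, 25, 25), -np.log10(25 / 255)),
            ((0, 0, 0), -np.log10(1 / 255)),  # epsilon guard keeps OD finite
        ],
    )
    def test_scalar_values(self, pixel, expected):
        img = np.full((1, 1, 3), pixel, dtype=np.uint8)
        od = rgb_to_od(img)
        assert od.od[0, 0] == pytest.approx([expected] * 3, abs=1e-12)

    def test_pixel_brighter_than_background_clamps_to_zero(self):
        img = np.full((1, 1, 3), 250, dtype=np.uint8)
        od = rgb_to_od(img, background=(200.0, 200.0, 200.0))
        assert np.all(od.od == 0.0)

    @pytest.mark.parametrize("bad", [(0, 255, 255), (-1, 255, 255), (256, 255, 255)])
    def test_invalid_background_rejected(self, bad):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        with pytest.raises(InvalidReferenceError):
            rgb_to_od(img, background=bad)


class TestDeconvolve:
    def test_matches_per_pixel_linear_solve(self):
        # independent oracle: one 3x3 solve per pixel
        rng = np.random.default_rng(42)
        sm = default_hdab_stain_matrix()
        conc_true = rng.uniform(0, 1, (5, 5, 3))
        od = conc_true @ sm.matrix
        fast = deconvolve(od, sm)
        fast_stack = np.stack([fast.hematoxylin, fast.dab, fast.residual], axis=-1)
        for i in range(5):
            for j in range(5):
                slow = np.clip(np.linalg.solve(sm.matrix.T, od[i, j]), 0, None)
                assert np.abs(fast_stack[i, j] - slow).max() < 1e-9

    def test_all_zero_od_gives_all_zero_concentrations(self):
        conc = deconvolve(np.zeros((3, 3, 3)), default_hdab_stain_matrix())
        assert not conc.hematoxylin.any()
        assert not conc.dab.any()
        assert not conc.residual.any()

    def test_negative_solutions_clipped(self):
        sm = default_hdab_stain_matrix()
        od = np.full((1, 1, 3), [1.0, 0.0, 0.0])  # outside the stain cone
        conc = deconvolve(od, sm)
        for fieldmap in (conc.hematoxylin, conc.dab, conc.residual):
            assert fieldmap.min() >= 0.0


class TestDetectDab:
    def test_zero_threshold_equals_positivity_support(self):
        field = np.array([[0.0, 0.1], [0.3, 0.0]])
        assert np.array_equal(detect_dab(field, 0.0), field > 0)

    def test_threshold_above_maximum_gives_empty_mask(self):
        field = np.array([[0.2, 0.4]])
        assert not detect_dab(field, 0.5).any()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_dab(np.zeros((2, 2)), -0.1)


class TestInverted8Bit:
    def test_saturation_and_zero_points(self):
        conc = np.array([[1.0, 0.0, 2.0]])
        mask = np.array([[True, True, True]])
        imap = to_inverted_8bit(conc, mask, scale_od=1.0)
        assert imap.values[0, 0] == 255  # concentration == scale_od saturates
        assert imap.values[0, 1] == 0  # zero concentration inside mask
        assert imap.values[0, 2] == 255  # above-scale clips

    def test_outside_mask_is_zero(self):
        conc = np.full((4, 4), 0.5)
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        imap = to_inverted_8bit(conc, mask)
        assert imap.values[1, 1] == 128
        assert imap.values.sum() == 128

    def test_inversion_reverses_pixel_ordering(self):
        # the convert-then-invert contract: 255 - g exactly reverses ranks
        rng = np.random.default_rng(0)
        g = rng.permutation(256).astype(np.uint8)
        inverted = (255 - g).astype(np.uint8)
        assert np.array_equal(np.argsort(g), np.argsort(inverted)[::-1])


class TestThresholdWindow:
    def test_full_window_changes_nothing(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        mask = values >= 0
        imap = DABIntensityMap(values=values, mask=mask, pixel_size_um=1.0)
        out = apply_threshold_window(imap, ThresholdWindow(0, 255))
        assert np.array_equal(out.values, imap.values)
        assert np.array_equal(out.mask, imap.mask)

    def test_window_empties_map_of_subthreshold_values(self):
        values = np.full((3, 3), 5, dtype=np.uint8)
        imap = DABIntensityMap(values=values, mask=np.ones((3, 3), bool), pixel_size_um=1.0)
        out = apply_threshold_window(imap, ThresholdWindow(10, 250))
        assert not out.mask.any()
        assert not out.values.any()

    def test_survivor_count_matches_histogram_mass(self):
        # independent oracle: histogram mass inside [low, high]
        rng = np.random.default_rng(2)
        values = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        mask = rng.random((32, 32)) < 0.8
        values[~mask] = 0
        imap = DABIntensityMap(values=values, mask=mask, pixel_size_um=1.0)
        low, high = 10, 250
        out = apply_threshold_window(imap, ThresholdWindow(low, high))
        hist = np.bincount(values[mask], minlength=256)
        assert out.mask.sum() == hist[low : high + 1].sum()

    @given(low=st.integers(0, 254), span=st.integers(1, 255), seed=st.integers(0, 10_000))
    def test_window_idempotent(self, low, span, seed):
        high = min(low + span, 255)
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 256, (6, 6)).astype(np.uint8)
        imap = DABIntensityMap(values=values, mask=values >= 0, pixel_size_um=1.0)
        window = ThresholdWindow(low, high)
        once = apply_threshold_window(imap, window)
        twice = apply_threshold_window(once, window)
        assert np.array_equal(once.values, twice.values)
        assert np.array_equal(once.mask, twice.mask)

    def test_mask_zero_consistency_after_chain(self):
        rng = np.random.default_rng(3)
        conc = rng.uniform(0, 1.2, (16, 16))
        mask = detect_dab(conc, 0.15)
        imap = to_inverted_8bit(conc, mask)
        out = apply_threshold_window(imap, ThresholdWindow(5, 250))
        assert not out.values[~out.mask].any()

    @pytest.mark.parametrize("low, high", [(5, 5), (10, 5), (-1, 100), (0, 256)])
    def test_invalid_windows_rejected(self, low, high):
        with pytest.raises(ValueError):
            ThresholdWindow(low, high)
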