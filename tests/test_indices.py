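"""Index evaluation: hand oracles, homogeneity, sign symmetry, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from veinindex import (
    FormatError,
    Hypercube,
    IndexFormula,
    IndexImage,
    VESSEL_FORMULA,
    eval_product_index,
    eval_ratio_index,
    eval_vessel_index,
    normalize_index,
)


def cube_from_pixel(i1, i2, i3):
    """1x1 cube holding one spectrum at 3 bands."""
    return Hypercube(
        values=np.array([[[i1, i2, i3]]], dtype=float),
        wavelengths_nm=[500.0, 600.0, 700.0],
    )


RATIO = IndexFormula("ratio", (500, 600, 700), (1, -2, 1, 1, 1, 1))
PRODUCT = IndexFormula("product_ratio", (500, 600, 700), (1, -1, -1, 1, 1, 1))


class TestFormulaInvariants:
    def test_all_zero_numerator_rejected(self):
        with pytest.raises(FormatError):
            IndexFormula("ratio", (500, 600, 700), (0, 0, 0, 1, 1, 1))

    def test_all_zero_denominator_rejected(self):
        with pytest.raises(FormatError):
            IndexFormula("ratio", (500, 600, 700), (1, 1, 1, 0, 0, 0))

    def test_coefficient_set_validation(self):
        f = IndexFormula("ratio", (500, 600, 700), (2, -2, 0, 1, 1, 1))
        f.validate_coefficients((-2, -1, 0, 1, 2))
        with pytest.raises(FormatError):
            f.validate_coefficients((-1, 0, 1))


class TestRatioIndex:
    def test_constant_cube_numerator_cancels(self):
        img = eval_ratio_index(cube_from_pixel(3.0, 3.0, 3.0), RATIO)
        assert img.values[0, 0] == 0.0
        assert img.valid[0, 0]

    def test_hand_arithmetic(self):
        img = eval_ratio_index(cube_from_pixel(2.0, 1.0, 1.0), RATIO)
        assert img.values[0, 0] == pytest.approx(0.25, abs=1e-15)

    @pytest.mark.parametrize("scale", [0.5, 3.0, 117.0])
    def test_degree_zero_homogeneity(self, random_cube, scale):
        f = IndexFormula("ratio", (450, 650, 900), (1, -2, 1, 1, 1, 1))
        base = eval_ratio_index(random_cube, f)
        scaled_cube = Hypercube(random_cube.values * scale, random_cube.wavelengths_nm)
        scaled = eval_ratio_index(scaled_cube, f)
        assert np.allclose(scaled.values[scaled.valid], base.values[base.valid], rtol=1e-10)

    def test_negating_all_six_coefficients_gives_identical_image(self, random_cube):
        f = IndexFormula("ratio", (450, 650, 900), (1, -2, 1, 1, 0, -1))
        g = IndexFormula("ratio", (450, 650, 900), (-1, 2, -1, -1, 0, 1))
        a, b = eval_ratio_index(random_cube, f), eval_ratio_index(random_cube, g)
        assert np.allclose(a.values[a.valid], b.values[b.valid], rtol=1e-12)


class TestProductIndex:
    def test_constant_cube_zero_numerator(self):
        img = eval_product_index(cube_from_pixel(2.0, 2.0, 2.0), PRODUCT)
        assert img.values[0, 0] == 0.0

    def test_hand_arithmetic(self):
        img = eval_product_index(cube_from_pixel(0.5, 0.3, 0.2), PRODUCT)
        assert img.values[0, 0] == pytest.approx(0.06, abs=1e-15)

    def test_degree_one_homogeneity(self, random_cube):
        f = IndexFormula("product_ratio", (450, 650, 900), (1, -1, -1, 1, 1, 1))
        base = eval_product_index(random_cube, f)
        scaled_cube = Hypercube(random_cube.values * 2.0, random_cube.wavelengths_nm)
        scaled = eval_product_index(scaled_cube, f)
        assert np.allclose(scaled.values[scaled.valid], 2.0 * base.values[base.valid], rtol=1e-10)

    def test_negating_denominator_negates_image(self, random_cube):
        f = IndexFormula("product_ratio", (450, 650, 900), (1, -1, -1, 1, 1, 1))
        g = IndexFormula("product_ratio", (450, 650, 900), (1, -1, -1, -1, -1, -1))
        a, b = eval_product_index(random_cube, f), eval_product_index(random_cube, g)
        assert np.allclose(a.values[a.valid], -b.values[b.valid], rtol=1e-12)

    def test_k1_is_shared_between_factors(self):
        # (2*I1 - I2)(2*I1 - I3) / (I1+I2+I3) at (1, 0.5, 0.25): 1.5 * 1.75 / 1.75 = 1.5
        f = IndexFormula("product_ratio", (500, 600, 700), (2, -1, -1, 1, 1, 1))
        img = eval_product_index(cube_from_pixel(1.0, 0.5, 0.25), f)
        assert img.values[0, 0] == pytest.approx(1.5, abs=1e-14)


class TestVesselIndex:
    def test_equals_product_index_at_published_parameters(self, nir_cube):
        via_product = eval_product_index(nir_cube, VESSEL_FORMULA)
        direct = eval_vessel_index(nir_cube)
        assert np.array_equal(direct.values, via_product.values)
        assert np.array_equal(direct.valid, via_product.valid)

    def test_hand_arithmetic(self):
        cube = Hypercube(
            values=np.array([[[0.5, 0.3, 0.2]]]),
            wavelengths_nm=[714.0, 738.0, 882.0],
        )
        img = eval_vessel_index(cube)
        assert img.values[0, 0] == pytest.approx(0.06, abs=1e-15)

    def test_constant_spectrum_gives_zero(self):
        cube = Hypercube(values=np.full((2, 2, 3), 5.0), wavelengths_nm=[714.0, 738.0, 882.0])
        assert np.all(eval_vessel_index(cube).values == 0.0)

    def test_cube_not_covering_nir_window_raises(self):
        cube = Hypercube(values=np.ones((1, 1, 3)), wavelengths_nm=[400.0, 450.0, 500.0])
        with pytest.raises(Exception, match="outside"):
            eval_vessel_index(cube)


def test_per_pixel_scalar_brute_force_oracle(rng):
    """Vectorized evaluation matches per-pixel scalar arithmetic to 1e-12."""
    values = rng.uniform(0.1, 2.0, size=(4, 4, 5))
    w = np.array([400.0, 550.0, 700.0, 850.0, 1000.0])
    cube = Hypercube(values=values, wavelengths_nm=w)
    for family, lambdas, k in [
        ("ratio", (400, 700, 1000), (1, -2, 1, 1, 1, 1)),
        ("ratio", (550, 700, 850), (2, 0, -1, 1, -1, 2)),
        ("product_ratio", (400, 700, 1000), (1, -1, -1, 1, 1, 1)),
        ("product_ratio", (550, 550, 850), (2, -1, 0, 0, 1, 1)),
    ]:
        f = IndexFormula(family, lambdas, k)
        img = (eval_ratio_index if family == "ratio" else eval_product_index)(cube, f)
        bands = [int(np.argmin(np.abs(w - lam))) for lam in lambdas]
        for r in range(4):
            for c in range(4):
                i1, i2, i3 = (float(values[r, c, b]) for b in bands)
                if family == "ratio":
                    num = k[0] * i1 + k[1] * i2 + k[2] * i3
                else:
                    num = (k[0] * i1 + k[1] * i2) * (k[0] * i1 + k[2] * i3)
                den = k[3] * i1 + k[4] * i2 + k[5] * i3
                if img.valid[r, c]:
                    assert img.values[r, c] == pytest.approx(num / den, abs=1e-12)


def test_repeated_wavelengths_reduce_to_two_wavelength_index():
    cube = cube_from_pixel(0.8, 0.4, 0.9)
    f = IndexFormula("ratio", (500.0, 600.0, 600.0), (1, -1, 0, 1, 1, 0))
    img = eval_ratio_index(cube, f)
    assert img.values[0, 0] == pytest.approx((0.8 - 0.4) / (0.8 + 0.4), rel=1e-14)


class TestNormalizeIndex:
    def _image(self, values):
        values = np.asarray(values, dtype=float)
        return IndexImage(values=values, valid=np.ones(values.shape, dtype=bool))

    def test_full_span_no_clip_is_affine_identity(self):
        values = np.linspace(0, 1, 16).reshape(4, 4)
        out = normalize_index(self._image(values), clip_percentiles=(0, 100))
        assert np.allclose(out.values, values)

    def test_constant_valid_values_map_to_zero(self):
        out = normalize_index(self._image(np.full((3, 3), 7.0)))
        assert np.all(out.values == 0.0)

    def test_percentile_clip_maps_extremes_to_unit_interval(self):
        values = np.arange(100, dtype=float).reshape(10, 10)
        out = normalize_index(self._image(values), clip_percentiles=(1, 99))
        lo, hi = np.percentile(values, [1, 99])
        assert out.values.min() == 0.0 and out.values.max() == 1.0
        inner = (values > lo) & (values < hi)
        assert np.allclose(out.values[inner], (values[inner] - lo) / (hi - lo))

    def test_invalid_pixels_unchanged_and_flagged(self):
        img = IndexImage(
            values=np.array([[0.0, 5.0], [10.0, 0.0]]),
            valid=np.array([[False, True], [True, False]]),
        )
        out = normalize_index(img, clip_percentiles=(0, 100))
        assert out.values[0, 0] == 0.0 and not out.valid[0, 0]
        assert out.values[1, 0] == 1.0

    def test_all_invalid_is_error(self):
        img = IndexImage(values=np.ones((2, 2)), valid=np.zeros((2, 2), dtype=bool))
        with pytest.raises(FormatError):
            normalize_index(img)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    i1=st.floats(0.05, 10.0),
    i2=st.floats(0.05, 10.0),
    i3=st.floats(0.05, 10.0),
    scale=st.floats(0.01, 100.0),
)
def test_ratio_family_scale_invariance_property(i1, i2, i3, scale):
    """R(c·I) == R(I) for any global brightness scale c > 0 (ratio family)."""
    f = IndexFormula("ratio", (500, 600, 700), (1, -2, 1, 1, 1, 1))
    a = eval_ratio_index(cube_from_pixel(i1, i2, i3), f)
    b = eval_ratio_index(cube_from_pixel(i1 * scale, i2 * scale, i3 * scale), f)
    if a.valid[0, 0] and b.valid[0, 0]:
        assert b.values[0, 0] == pytest.approx(a.values[0, 0], rel=1e-9, abs=1e-12)
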