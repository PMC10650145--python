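"""Generalized three-wavelength spectral indices.

Two formula families are supported, each parameterized by three wavelengths
(λ1, λ2, λ3) and six small integer coefficients (k1..k6):

* ``ratio`` — a ratio of two linear combinations of the band brightnesses,

      R = (k1·I1 + k2·I2 + k3·I3) / (k4·I1 + k5·I2 + k6·I3),

  which is homogeneous of degree 0: global illumination scaling cancels.

* ``product_ratio`` — a product of two differences over a linear sum,

      R = (k1·I1 + k2·I2)·(k1·I1 + k3·I3) / (k4·I1 + k5·I2 + k6·I3),

  with k1 shared between the two numerator factors; this family is
  homogeneous of degree 1 (scales linearly with illumination).

I_i is the brightness in the band whose center is nearest λ_i.  The reported
optimum for subcutaneous vein imaging is the product_ratio member at
λ = (714, 738, 882) nm with k = (1, −1, −1, 1, 1, 1), exposed as
:func:`eval_vessel_index`:

    II = (I714 − I738)·(I714 − I882) / (I714 + I738 + I882).

Pixels whose denominator is near zero (relative threshold ``DENOM_EPS_REL``
against the mean absolute denominator) are flagged invalid rather than
clamped, so they can be excluded from downstream scoring instead of
producing fake extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError
from .hypercube import Hypercube, band_at

__all__ = [
    "COEFF_SET_DEFAULT",
    "DENOM_EPS_REL",
    "VESSEL_FORMULA",
    "IndexFormula",
    "IndexImage",
    "eval_ratio_index",
    "eval_product_index",
    "eval_vessel_index",
    "normalize_index",
    "save_index_tiff",
    "save_index_png",
]

COEFF_SET_DEFAULT: tuple[int, ...] = (-2, -1, 0, 1, 2)

# Relative near-zero-denominator threshold: pixels with
# |den| < DENOM_EPS_REL * mean(|den|) are invalid.
DENOM_EPS_REL: float = 1e-6


@dataclass(frozen=True)
class IndexFormula:
    """A formula family tag plus three wavelengths and six integer coefficients.

    Repeated wavelengths inside the triple are permitted; they reduce the
    formula to a two-wavelength index.
    """

    family: str  # 'ratio' | 'product_ratio'
    lambdas_nm: tuple[float, float, float]
    coeffs: tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if self.family not in ("ratio", "product_ratio"):
            raise FormatError(f"unknown formula family '{self.family}'")
        object.__setattr__(self, "lambdas_nm", tuple(float(x) for x in self.lambdas_nm))
        object.__setattr__(self, "coeffs", tuple(int(k) for k in self.coeffs))
        if len(self.lambdas_nm) != 3:
            raise FormatError("a formula needs exactly three wavelengths")
        if len(self.coeffs) != 6:
            raise FormatError("a formula needs exactly six coefficients")
        if not any(self.coeffs[:3]):
            raise FormatError("numerator coefficients (k1, k2, k3) must not all be zero")
        if not any(self.coeffs[3:]):
            raise FormatError("denominator coefficients (k4, k5, k6) must not all be zero")

    def validate_coefficients(self, coefficient_set) -> None:
        allowed = set(int(c) for c in coefficient_set)
        for k in self.coeffs:
            if k not in allowed:
                raise FormatError(f"coefficient {k} outside the configured set {sorted(allowed)}")


#: The published optimum vessel-index formula.
VESSEL_FORMULA = IndexFormula(
    family="product_ratio",
    lambdas_nm=(714.0, 738.0, 882.0),
    coeffs=(1, -1, -1, 1, 1, 1),
)


@dataclass
class IndexImage:
    """A real-valued index map with a validity mask and provenance."""

    values: np.ndarray  # (H, W) float64; 0 at invalid pixels
    valid: np.ndarray  # (H, W) bool
    source_formula: IndexFormula | None = None
    band_centers_nm: tuple[float, float, float] | None = None
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _linear(k1: float, k2: float, k3: float, i1, i2, i3):
    """k1·I1 + k2·I2 + k3·I3 — shared by the evaluators and the fast search path
    so both produce bit-identical arithmetic."""
    return k1 * i1 + k2 * i2 + k3 * i3


def _product_numerator(k1: float, k2: float, k3: float, i1, i2, i3):
    """(k1·I1 + k2·I2)·(k1·I1 + k3·I3) with k1 shared, exactly as printed."""
    return (k1 * i1 + k2 * i2) * (k1 * i1 + k3 * i3)


def denominator_validity(den: np.ndarray) -> np.ndarray:
    """Validity mask for a denominator array under the relative threshold."""
    absden = np.abs(den)
    eps = DENOM_EPS_REL * absden.mean() if absden.size else 0.0
    if eps <= 0.0:
        return np.zeros(den.shape, dtype=bool)
    return absden >= eps

def _resolve_bands(cube: Hypercube, formula: IndexFormula):
    layers = [band_at(cube, lam) for lam in formula.lambdas_nm]
    centers = tuple(layer.center_wavelength_nm for layer in layers)
    return layers[0].values, layers[1].values, layers[2].values, centers


def _finish(num: np.ndarray, den: np.ndarray, formula: IndexFormula, centers) -> IndexImage:
    valid = denominator_validity(den)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = num / den
    values = np.where(valid, values, 0.0)
    return IndexImage(values=values, valid=valid, source_formula=formula, band_centers_nm=centers)


def eval_ratio_index(cube: Hypercube, formula: IndexFormula) -> IndexImage:
    """Evaluate a ratio-family formula on a cube."""
    if formula.family != "ratio":
        raise FormatError("eval_ratio_index expects a ratio-family formula")
    i1, i2, i3, centers = _resolve_bands(cube, formula)
    k = formula.coeffs
    num = _linear(k[0], k[1], k[2], i1, i2, i3)
    den = _linear(k[3], k[4], k[5], i1, i2, i3)
    return _finish(num, den, formula, centers)


def eval_product_index(cube: Hypercube, formula: IndexFormula) -> IndexImage:
    """Evaluate a product_ratio-family formula on a cube."""
    if formula.family != "product_ratio":
        raise FormatError("eval_product_index expects a product_ratio-family formula")
    i1, i2, i3, centers = _resolve_bands(cube, formula)
    k = formula.coeffs
    num = _product_numerator(k[0], k[1], k[2], i1, i2, i3)
    den = _linear(k[3], k[4], k[5], i1, i2, i3)
    return _finish(num, den, formula, centers)


def eval_vessel_index(cube: Hypercube) -> IndexImage:
    """Evaluate the published-optimum vessel index (λ = 714, 738, 882 nm)."""
    return eval_product_index(cube, VESSEL_FORMULA)


def eval_index(cube: Hypercube, formula: IndexFormula) -> IndexImage:
    """Dispatch on the formula family."""
    if formula.family == "ratio":
        return eval_ratio_index(cube, formula)
    return eval_product_index(cube, formula)


def normalize_index(img: IndexImage, clip_percentiles: tuple[float, float] = (1.0, 99.0)) -> IndexImage:
    """Percentile-clip the valid values and map them affinely to [0, 1].

    Invalid pixels keep value 0 and stay flagged.  A constant valid
    population maps to 0 by convention (zero range).
    """
    vals = img.values[img.valid]
    if vals.size == 0:
        raise FormatError("cannot normalize: all pixels invalid")
    lo, hi = np.percentile(vals, clip_percentiles)
    out = np.zeros_like(img.values)
    if hi > lo:
        out[img.valid] = (np.clip(vals, lo, hi) - lo) / (hi - lo)
    return IndexImage(
        values=out,
        valid=img.valid.copy(),
        source_formula=img.source_formula,
        band_centers_nm=img.band_centers_nm,
        normalized=True,
        meta=dict(img.meta, clip_percentiles=tuple(clip_percentiles)),
    )


def save_index_tiff(img: IndexImage, path) -> None:
    """Export the index map as a 32-bit float TIFF (invalid pixels as NaN)."""
    import tifffile

    data = img.values.astype(np.float32)
    data = np.where(img.valid, data, np.float32(np.nan))
    tifffile.imwrite(Path(path), data)


def save_index_png(img: IndexImage, path) -> None:
    """Export an 8-bit preview PNG of the normalized index map."""
    import imageio.v3 as iio

    shown = img if img.normalized else normalize_index(img)
    preview = np.clip(shown.values * 255.0, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), preview)
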