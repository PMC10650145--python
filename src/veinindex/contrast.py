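"""Dark-stripe detection and average Michelson contrast.

Vessels cross a vertical intensity profile (one image column, top to
bottom) as dark stripes — local minima of characteristic width.  Each
stripe's Michelson contrast is

    K_ij = (I_max − I_min) / (I_max + I_min),

where I_min is the minimum inside the fringe and I_max the larger of the two
flanking shoulder maxima.  The image-level figure of merit is the mean of
all per-stripe contrasts over all columns, reported together with the sample
standard deviation of the stripe population as the measurement error
estimate.

Detection runs :func:`scipy.signal.find_peaks` on the negated profile with a
prominence floor and width window; invalid pixels split the profile into
independently scanned segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import ContrastError
from .indices import IndexImage

__all__ = [
    "Stripe",
    "StripeMeasurement",
    "ContrastReport",
    "column_profile",
    "detect_dark_stripes",
    "stripe_contrast",
    "average_contrast",
]

DEFAULT_MIN_WIDTH_PX = 3
DEFAULT_MAX_WIDTH_FRACTION = 0.25  # of the profile length
DEFAULT_PROMINENCE_FRACTION = 0.05  # of the profile's dynamic range


@dataclass
class Stripe:
    """One detected dark fringe on a 1-D profile."""

    position: int  # index of the minimum along the profile
    width_px: int
    i_min: float
    i_max: float


@dataclass
class StripeMeasurement:
    column: int
    i_max: float
    i_min: float
    k_ij: float
    width_px: int


@dataclass
class ContrastReport:
    stripes: list[StripeMeasurement]
    mean_contrast: float
    abs_error: float
    meta: dict = field(default_factory=dict)

    @property
    def n_stripes(self) -> int:
        return len(self.stripes)

    def to_dict(self) -> dict:
        return {
            "mean_contrast": self.mean_contrast,
            "abs_error": self.abs_error,
            "n_stripes": self.n_stripes,
            "stripes": [
                {
                    "column": s.column,
                    "i_max": s.i_max,
                    "i_min": s.i_min,
                    "k_ij": s.k_ij,
                    "width_px": s.width_px,
                }
                for s in self.stripes
            ],
            **self.meta,
        }


def _as_values_valid(img) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(img, IndexImage):
        return img.values, img.valid
    arr = np.asarray(img, dtype=np.float64)
    return arr, np.ones(arr.shape, dtype=bool)


def column_profile(img, column: int) -> np.ma.MaskedArray:
    """One column of the image, top to bottom; invalid pixels are masked."""
    values, valid = _as_values_valid(img)
    if not (0 <= column < values.shape[1]):
        raise ContrastError(f"column {column} out of range for width {values.shape[1]}")
    return np.ma.MaskedArray(values[:, column], mask=~valid[:, column])


def detect_dark_stripes(
    profile,
    min_width_px: int = DEFAULT_MIN_WIDTH_PX,
    min_prominence: float | None = None,
    max_width_px: int | None = None,
) -> list[Stripe]:
    """Find dark fringes (local minima with prominence and width bounds).

    ``min_prominence`` defaults to 5% of the profile's dynamic range;
    ``max_width_px`` to 25% of the profile length.  Masked (invalid)
    positions split the profile into segments scanned independently.
    Returns stripes ordered by position; may be empty.
    """
    profile = np.ma.masked_invalid(np.ma.asarray(profile, dtype=np.float64))
    n = len(profile)
    if n < 3:
        return []
    if max_width_px is None:
        max_width_px = max(min_width_px, int(round(DEFAULT_MAX_WIDTH_FRACTION * n)))
    data = profile.compressed()
    if data.size < 3:
        return []
    if min_prominence is None:
        dyn = float(data.max() - data.min())
        min_prominence = DEFAULT_PROMINENCE_FRACTION * dyn
        if min_prominence <= 0:
            return []

    stripes: list[Stripe] = []
    for sl in np.ma.clump_unmasked(profile):
        start = sl.start
        seg = np.asarray(profile[sl])
        if len(seg) < 3:
            continue
        peaks, props = find_peaks(
            -seg,
            prominence=min_prominence,
            width=(min_width_px, max_width_px),
        )
        for p, lb, rb, w in zip(
            peaks, props["left_bases"], props["right_bases"], props["widths"]
        ):
            i_min = float(seg[p])
            i_max = float(max(seg[lb], seg[rb]))
            stripes.append(
                Stripe(
                    position=start + int(p),
                    width_px=int(round(w)),
                    i_min=i_min,
                    i_max=i_max,
                )
            )
    stripes.sort(key=lambda s: s.position)
    return stripes


def stripe_contrast(i_max: float, i_min: float) -> float:
    """Michelson contrast (I_max − I_min)/(I_max + I_min) of one fringe."""
    if not (i_max >= i_min >= 0):
        raise ContrastError(f"need i_max >= i_min >= 0, got ({i_max}, {i_min})")
    if i_max + i_min == 0:
        raise ContrastError("contrast undefined: i_max + i_min = 0")
    return (i_max - i_min) / (i_max + i_min)


def average_contrast(
    img,
    min_width_px: int = DEFAULT_MIN_WIDTH_PX,
    min_prominence: float | None = None,
    max_width_px: int | None = None,
) -> ContrastReport:
    """Detect dark stripes in every column and average their Michelson contrasts.

    ``abs_error`` is the sample standard deviation of the per-stripe
    contrasts (0 when fewer than two stripes).  When ``min_prominence`` is
    not given it is resolved once from the whole image's dynamic range over
    valid pixels, so every column uses the same floor.
    """
    values, valid = _as_values_valid(img)
    if min_prominence is None:
        vals = values[valid]
        if vals.size == 0:
            raise ContrastError("no valid pixels")
        dyn = float(vals.max() - vals.min())
        min_prominence = DEFAULT_PROMINENCE_FRACTION * dyn
        if min_prominence <= 0:
            raise ContrastError("constant image: no dark stripes detectable")

    measurements: list[StripeMeasurement] = []
    for col in range(values.shape[1]):
        profile = np.ma.MaskedArray(values[:, col], mask=~valid[:, col])
        for s in detect_dark_stripes(
            profile,
            min_width_px=min_width_px,
            min_prominence=min_prominence,
            max_width_px=max_width_px,
        ):
            measurements.append(
                StripeMeasurement(
                    column=col,
                    i_max=s.i_max,
                    i_min=s.i_min,
                    k_ij=stripe_contrast(s.i_max, s.i_min),
                    width_px=s.width_px,
                )
            )
    if not measurements:
        raise ContrastError(
            "no dark stripes detected in any column "
            f"(min_width_px={min_width_px}, min_prominence={min_prominence})"
        )
    k = np.array([m.k_ij for m in measurements])
    return ContrastReport(
        stripes=measurements,
        mean_contrast=float(k.mean()),
        abs_error=float(k.std(ddof=1)) if k.size > 1 else 0.0,
        meta={"min_width_px": min_width_px, "min_prominence": float(min_prominence)},
    )
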