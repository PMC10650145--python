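"""Expert vessel masks and the masked RMS objective.

The search is supervised by a hand-painted binary mask marking vessel
pixels.  A candidate index image is normalized to [0, 1] and its root mean
square distance to the ideal vessel value is computed *only inside the
mask*, under both polarities (vessels ideally 0 = dark, or ideally
1 = bright); the better polarity is kept.  Scoring both polarities makes the
objective insensitive to the global sign of a formula, matching the
exclusion of sign-symmetric duplicates from the search.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import MaskError
from .indices import IndexImage

__all__ = [
    "VesselMask",
    "ObjectiveScore",
    "read_mask",
    "write_mask",
    "masked_rms",
    "MAX_INVALID_VESSEL_FRACTION",
]

# Candidates with more than this fraction of vessel pixels invalid are
# rejected outright (near-zero denominators over the region of interest).
MAX_INVALID_VESSEL_FRACTION: float = 0.5


@dataclass
class VesselMask:
    """Binary expert annotation; True marks a vessel pixel."""

    values: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 2:
            raise MaskError("vessel mask must be 2-D")

    @property
    def is_empty(self) -> bool:
        return not bool(self.values.any())

    @property
    def n_vessel_pixels(self) -> int:
        return int(self.values.sum())


@dataclass
class ObjectiveScore:
    rms: float
    polarity: str  # 'vessels_dark' | 'vessels_bright'
    n_pixels_scored: int


def read_mask(path) -> VesselMask:
    """Read a single-channel PNG/PGM mask; pixels above 50% of max are True.

    Multi-channel images are accepted only when all channels agree.
    An all-zero image reads as an (unusable) empty mask.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        if not all(np.array_equal(arr[..., 0], arr[..., c]) for c in range(1, arr.shape[2])):
            raise MaskError(
                f"{path}: multi-channel mask with disagreeing channels; no collapse rule"
            )
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise MaskError(f"{path}: mask must be a 2-D image")
    peak = arr.max()
    if peak == 0:
        return VesselMask(values=np.zeros(arr.shape, dtype=bool))
    return VesselMask(values=arr > 0.5 * peak)


def write_mask(mask: VesselMask, path) -> None:
    """Write a mask as an 8-bit 0/255 image (PNG or PGM by extension)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.where(mask.values, 255, 0).astype(np.uint8))


def masked_rms(img: IndexImage, mask: VesselMask) -> ObjectiveScore:
    """RMS distance of a normalized index image to the ideal vessel value.

    Only valid vessel pixels are scored.  Both polarities are evaluated
    (target 0 for vessels_dark, 1 for vessels_bright) and the smaller RMS is
    returned; an exact tie reports vessels_dark.  Candidates with more than
    half of the vessel pixels invalid are rejected with :class:`MaskError`.
    """
    if not img.normalized:
        raise MaskError("masked_rms expects a normalized index image")
    if img.values.shape != mask.values.shape:
        raise MaskError(
            f"shape mismatch: image {img.values.shape} vs mask {mask.values.shape}"
        )
    if mask.is_empty:
        raise MaskError("empty vessel mask cannot serve as an objective")
    scored = mask.values & img.valid
    n = int(scored.sum())
    if n == 0:
        raise MaskError("no valid vessel pixels to score")
    if 1.0 - n / mask.n_vessel_pixels > MAX_INVALID_VESSEL_FRACTION:
        raise MaskError(
            f"candidate rejected: only {n}/{mask.n_vessel_pixels} vessel pixels valid"
        )
    v = img.values[scored]
    rms_dark = float(np.sqrt(np.mean(v ** 2)))
    rms_bright = float(np.sqrt(np.mean((1.0 - v) ** 2)))
    if rms_dark <= rms_bright:
        return ObjectiveScore(rms=rms_dark, polarity="vessels_dark", n_pixels_scored=n)
    return ObjectiveScore(rms=rms_bright, polarity="vessels_bright", n_pixels_scored=n)
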