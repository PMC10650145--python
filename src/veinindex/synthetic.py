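"""Synthetic forearm-like hyperspectral cubes with known vessel ground truth.

The generator is deliberately phenomenological — it reproduces the
statistical structure the index search relies on, not radiative transfer:

* a smooth skin baseline reflectance rising from the visible into the NIR,
  attenuated by a melanin factor that is strong at short wavelengths and
  fades toward 1000 nm (so skin tone shifts the visible baseline much more
  than the NIR one);
* vessels as smooth curvilinear dark paths whose spectra equal the baseline
  multiplied by Gaussian absorption dips (defaults at 740 and 970 nm,
  motivated by hemoglobin/water absorption in the NIR window), attenuated
  with vessel depth and spatially blurred by a depth-dependent kernel;
* additive zero-mean Gaussian sensor noise, clipped at 0.

Every sample carries the exact vessel footprint as a ground-truth mask and a
``truth`` block echoing the configuration and realized vessel parameters.
All randomness flows from a single seeded generator, so samples are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError
from .hypercube import Hypercube
from .reference import VesselMask

__all__ = [
    "SKIN_TYPE_MELANIN",
    "SkinSimConfig",
    "SyntheticSample",
    "skin_baseline_spectrum",
    "vessel_spectrum",
    "generate_sample",
]

# Melanin scale per skin-tone grade (fair .. dark).
SKIN_TYPE_MELANIN: dict[str, float] = {
    "fair": 0.05,
    "fair_tan": 0.15,
    "light_brown": 0.30,
    "light_brown_tan": 0.45,
    "dark_brown": 0.70,
    "dark": 1.00,
}


def _default_axis() -> np.ndarray:
    return np.linspace(400.0, 1000.0, 250)


@dataclass
class SkinSimConfig:
    """All tunables of the generator; defaults emulate a forearm acquisition."""

    height: int = 64
    width: int = 64
    wavelengths_nm: np.ndarray = field(default_factory=_default_axis)
    skin_type: str = "light_brown"
    melanin_scale: float | None = None  # mapped from skin_type when None
    n_vessels: int = 3
    vessel_width_px: tuple[float, float] = (3.0, 6.0)
    vessel_depth_mm: tuple[float, float] = (0.5, 2.0)
    dip_centers_nm: tuple[float, ...] = (740.0, 970.0)
    dip_widths_nm: tuple[float, ...] = (28.0, 45.0)
    dip_depths: tuple[float, ...] = (0.45, 0.30)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.skin_type not in SKIN_TYPE_MELANIN:
            raise ConfigError(
                f"unknown skin type '{self.skin_type}'; choose from {sorted(SKIN_TYPE_MELANIN)}"
            )
        if self.melanin_scale is None:
            self.melanin_scale = SKIN_TYPE_MELANIN[self.skin_type]
        if self.melanin_scale < 0:
            raise ConfigError("melanin_scale must be >= 0")
        if not (len(self.dip_centers_nm) == len(self.dip_widths_nm) == len(self.dip_depths)):
            raise ConfigError("dip centers, widths and depths must have equal length")
        wmin, wmax = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        for c in self.dip_centers_nm:
            if not (wmin <= c <= wmax):
                raise ConfigError(f"dip center {c} nm outside the wavelength axis")
        for d in self.dip_depths:
            if not (0.0 <= d < 1.0):
                raise ConfigError("dip depths must lie in [0, 1)")
        if self.vessel_width_px[0] < 1:
            raise ConfigError("vessel widths must be >= 1 px")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class SyntheticSample:
    cube: Hypercube
    mask: VesselMask
    truth: dict


def skin_baseline_spectrum(config: SkinSimConfig) -> np.ndarray:
    """Skin reflectance baseline per band, in (0, 1].

    A logistic ramp from the visible into the NIR times a melanin
    attenuation ``exp(-m * 1.2 * (λ/400)^-3)`` that decays with wavelength:
    darker skin is uniformly darker, with the gap shrinking toward 1000 nm.
    """
    lam = config.wavelengths_nm
    ramp = 0.35 + 0.45 / (1.0 + np.exp(-(lam - 600.0) / 60.0))
    melanin = np.exp(-config.melanin_scale * 1.2 * (lam / 400.0) ** -3.0)
    return ramp * melanin


# Depth scale (mm) over which vessel absorption dips fade.
_DEPTH_ATTENUATION_MM = 1.5


def vessel_spectrum(baseline: np.ndarray, config: SkinSimConfig, depth_mm: float) -> np.ndarray:
    """Vessel reflectance: baseline times depth-attenuated Gaussian dips.

    At depth 0 the ratio to baseline at a dip center equals 1 − dip_depth
    (up to overlap between dips); deeper vessels have uniformly weaker dips.
    """
    if depth_mm < 0:
        raise ConfigError("vessel depth must be >= 0 mm")
    lam = config.wavelengths_nm
    att = np.exp(-depth_mm / _DEPTH_ATTENUATION_MM)
    factor = np.ones_like(lam)
    for center, width, depth in zip(
        config.dip_centers_nm, config.dip_widths_nm, config.dip_depths
    ):
        factor *= 1.0 - depth * att * np.exp(-(((lam - center) / width) ** 2))
    return baseline * factor


def _vessel_paths(config: SkinSimConfig, rng: np.random.Generator) -> list[dict]:
    """Draw smooth sinusoidal vessel centerlines with width and depth."""
    h, w = config.height, config.width
    if w < config.vessel_width_px[1] + 2 or h < 4:
        raise ConfigError(f"grid {h}x{w} too small to place vessels")
    paths = []
    for _ in range(config.n_vessels):
        paths.append(
            {
                "col0": float(rng.uniform(0.15, 0.85) * w),
                "amp_px": float(rng.uniform(1.0, 4.0)),
                "period_px": float(rng.uniform(1.5, 3.0) * h),
                "phase": float(rng.uniform(0.0, 2.0 * np.pi)),
                "width_px": float(rng.uniform(*config.vessel_width_px)),
                "depth_mm": float(rng.uniform(*config.vessel_depth_mm)),
            }
        )
    return paths


def _rasterize(path: dict, height: int, width: int) -> np.ndarray:
    rows = np.arange(height)
    centers = path["col0"] + path["amp_px"] * np.sin(
        2.0 * np.pi * rows / path["period_px"] + path["phase"]
    )
    cols = np.arange(width)
    return np.abs(cols[None, :] - centers[:, None]) <= path["width_px"] / 2.0


def generate_sample(config: SkinSimConfig) -> SyntheticSample:
    """Generate a cube + exact mask + truth block, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    baseline = skin_baseline_spectrum(config)
    paths = _vessel_paths(config, rng)

    h, w, b = config.height, config.width, len(config.wavelengths_nm)
    # Multiplicative attenuation field composed vessel by vessel.
    attenuation = np.ones((h, w, b))
    mask = np.zeros((h, w), dtype=bool)
    for path in paths:
        footprint = _rasterize(path, h, w)
        mask |= footprint
        spectral_factor = vessel_spectrum(baseline, config, path["depth_mm"]) / baseline
        sigma = 0.5 + 0.6 * path["depth_mm"]  # deeper vessels look blurrier
        frac = np.clip(gaussian_filter(footprint.astype(np.float64), sigma=sigma), 0.0, 1.0)
        attenuation *= 1.0 - frac[:, :, None] * (1.0 - spectral_factor[None, None, :])

    cube_values = baseline[None, None, :] * attenuation
    if config.noise_sd > 0:
        cube_values = cube_values + rng.normal(0.0, config.noise_sd, size=cube_values.shape)
        cube_values = np.clip(cube_values, 0.0, None)

    truth = {
        "config": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(config).items()
        },
        "vessel_paths": paths,
        "seed": config.seed,
    }
    cube = Hypercube(
        values=cube_values,
        wavelengths_nm=config.wavelengths_nm.copy(),
        meta={"synthetic": True, "skin_type": config.skin_type, "seed": config.seed},
    )
    return SyntheticSample(cube=cube, mask=VesselMask(values=mask), truth=truth)
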