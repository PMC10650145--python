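"""Hyperspectral cube container and I/O.

A :class:`Hypercube` is an ``(H, W, B)`` array of non-negative sensor
brightnesses with a strictly increasing per-band wavelength axis in
nanometres.  Axis order is (row, column, band), row-major, 0-based; a
"vertical profile" is one column traversed top to bottom.

Two on-disk forms are supported:

* ENVI — a plain-text ``.hdr`` beside a raw binary payload.  BSQ and BIL
  interleaves are read; BSQ is written.  Wavelengths live in the header's
  ``wavelength`` field, in nm.
* A single-file array container (NumPy ``.npz``) with keys ``values`` and
  ``wavelengths_nm``.

Brightness units are arbitrary sensor counts; all index math downstream is
unit-free by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, WavelengthRangeError

__all__ = [
    "Hypercube",
    "BandLayer",
    "read_cube",
    "write_cube",
    "band_at",
    "normalize_white",
]

# ENVI numeric data-type codes we read/write.
_ENVI_DTYPES = {
    1: np.dtype(np.uint8),
    2: np.dtype(np.int16),
    3: np.dtype(np.int32),
    4: np.dtype(np.float32),
    5: np.dtype(np.float64),
    12: np.dtype(np.uint16),
    13: np.dtype(np.uint32),
}
_DTYPE_TO_ENVI = {v: k for k, v in _ENVI_DTYPES.items()}


@dataclass
class BandLayer:
    """A single spectral layer of a cube."""

    values: np.ndarray  # (H, W)
    center_wavelength_nm: float
    band_index: int


@dataclass
class Hypercube:
    """An (H, W, B) brightness cube with a strictly increasing wavelength axis."""

    values: np.ndarray
    wavelengths_nm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError(f"cube values must be 3-D (H, W, B), got {self.values.ndim}-D")
        if self.wavelengths_nm.ndim != 1:
            raise FormatError("wavelength axis must be 1-D")
        if len(self.wavelengths_nm) != self.values.shape[2]:
            raise FormatError(
                f"wavelength axis length {len(self.wavelengths_nm)} does not match "
                f"band count {self.values.shape[2]}"
            )
        if len(self.wavelengths_nm) < 1:
            raise FormatError("cube must have at least one band")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise FormatError("wavelength axis must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("cube values must be finite")
        if np.any(self.values < 0):
            raise FormatError("cube values must be non-negative")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band_at(self, wavelength_nm: float) -> BandLayer:
        return band_at(self, wavelength_nm)


def band_at(cube: Hypercube, wavelength_nm: float) -> BandLayer:
    """Return the band whose center wavelength is nearest to the request.

    The acceptable range is the axis extended by half the local band spacing
    at either end.  Exact midpoints tie toward the lower band index.
    """
    w = cube.wavelengths_nm
    if len(w) == 1:
        lo = hi = w[0]
    else:
        lo = w[0] - (w[1] - w[0]) / 2.0
        hi = w[-1] + (w[-1] - w[-2]) / 2.0
    if not (lo <= wavelength_nm <= hi):
        raise WavelengthRangeError(
            f"wavelength {wavelength_nm} nm outside extended axis [{lo}, {hi}] nm"
        )
    idx = int(np.argmin(np.abs(w - wavelength_nm)))  # argmin -> first (lower) index on ties
    return BandLayer(
        values=cube.values[:, :, idx],
        center_wavelength_nm=float(w[idx]),
        band_index=idx,
    )


def normalize_white(cube: Hypercube, reference_region: tuple[int, int, int, int]) -> Hypercube:
    """Divide each band by its mean brightness over a rectangular reference region.

    ``reference_region`` is ``(row_start, row_stop, col_start, col_stop)``,
    half-open.  Bands whose reference mean is <= 0 are left unscaled and
    listed in ``meta['white_reference']['unscaled_bands']``.
    """
    r0, r1, c0, c1 = reference_region
    if not (0 <= r0 < r1 <= cube.height and 0 <= c0 < c1 <= cube.width):
        raise FormatError(f"reference region {reference_region} empty or outside the grid")
    ref = cube.values[r0:r1, c0:c1, :].mean(axis=(0, 1))
    unscaled = np.flatnonzero(ref <= 0)
    scale = np.where(ref > 0, 1.0 / np.where(ref > 0, ref, 1.0), 1.0)
    meta = dict(cube.meta)
    meta["white_reference"] = {
        "region": tuple(int(x) for x in reference_region),
        "unscaled_bands": [int(b) for b in unscaled],
    }
    return Hypercube(values=cube.values * scale, wavelengths_nm=cube.wavelengths_nm.copy(), meta=meta)


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI header into a flat dict (keys lower-cased)."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic line)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # key = value, where value may be a {...} block spanning lines
    pattern = re.compile(r"^\s*([\w\s]+?)\s*=\s*(\{.*?\}|[^\n]*)\s*$", re.MULTILINE | re.DOTALL)
    pos = 0
    while pos < len(body):
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{") and not val.endswith("}"):
            end = body.find("}", m.start(2))
            if end == -1:
                raise FormatError(f"unterminated brace value for header field '{key}'")
            val = body[m.start(2): end + 1]
            pos = end + 1
        else:
            pos = m.end()
        fields[key] = val
    return fields


def _header_list(value: str) -> list[float]:
    inner = value.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.replace("\n", " ").split(",") if tok.strip()]


def _envi_paths(path: Path) -> tuple[Path, Path]:
    """Resolve (header, data) paths from either the header or the data path."""
    if path.suffix == ".hdr":
        hdr = path
        data = path.with_suffix("")
        if not data.exists():
            for cand in (path.with_suffix(".img"), path.with_suffix(".raw"), path.with_suffix(".dat")):
                if cand.exists():
                    data = cand
                    break
    else:
        data = path
        hdr = Path(str(path) + ".hdr")
        if not hdr.exists():
            hdr = path.with_suffix(".hdr")
    return hdr, data


def read_cube(path, format: str | None = None) -> Hypercube:
    """Read a hypercube from ENVI or the ``.npz`` array container.

    The format is inferred from the extension when not given.  The returned
    cube always has an ascending wavelength axis; bands stored descending are
    reordered consistently.
    """
    path = Path(path)
    if format is None:
        format = "array_container" if path.suffix == ".npz" else "envi"

    if format == "array_container":
        with np.load(path) as archive:
            if "values" not in archive or "wavelengths_nm" not in archive:
                raise FormatError("array container must hold 'values' and 'wavelengths_nm'")
            values = archive["values"]
            wavelengths = archive["wavelengths_nm"]
    elif format == "envi":
        hdr_path, data_path = _envi_paths(path)
        if not hdr_path.exists():
            raise FormatError(f"ENVI header not found for {path}")
        fields = _parse_envi_header(hdr_path.read_text())
        try:
            samples = int(fields["samples"])
            lines = int(fields["lines"])
            bands = int(fields["bands"])
            dtype_code = int(fields["data type"])
        except KeyError as exc:
            raise FormatError(f"ENVI header missing required field: {exc}") from exc
        if "wavelength" not in fields:
            raise FormatError("no wavelength axis: ENVI header lacks a 'wavelength' field")
        wavelengths = np.asarray(_header_list(fields["wavelength"]), dtype=np.float64)
        if len(wavelengths) != bands:
            raise FormatError(
                f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
            )
        if dtype_code not in _ENVI_DTYPES:
            raise FormatError(f"unsupported ENVI data type code {dtype_code}")
        dtype = _ENVI_DTYPES[dtype_code]
        if int(fields.get("byte order", "0")) != 0:
            dtype = dtype.newbyteorder(">")
        offset = int(fields.get("header offset", "0"))
        interleave = fields.get("interleave", "bsq").lower()
        raw = np.fromfile(data_path, dtype=dtype, offset=offset)
        expected = samples * lines * bands
        if raw.size != expected:
            raise FormatError(
                f"payload holds {raw.size} values but header declares "
                f"{lines}x{samples}x{bands} = {expected}"
            )
        if interleave == "bsq":
            values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
        elif interleave == "bil":
            values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
        else:
            raise FormatError(f"unsupported interleave '{interleave}' (bsq/bil readable)")
        values = np.ascontiguousarray(values, dtype=np.float64)
    else:
        raise FormatError(f"unknown cube format '{format}'")

    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    if wavelengths.ndim != 1 or len(wavelengths) != values.shape[2]:
        raise FormatError("wavelength axis does not match band count")
    diffs = np.diff(wavelengths)
    if np.any(diffs == 0):
        raise FormatError("duplicate wavelengths in axis")
    if np.any(diffs < 0):
        order = np.argsort(wavelengths, kind="stable")
        wavelengths = wavelengths[order]
        values = values[:, :, order]
    return Hypercube(values=values, wavelengths_nm=wavelengths)


def write_cube(cube: Hypercube, path, format: str | None = None) -> None:
    """Write a cube so that :func:`read_cube` reproduces it bit-exactly.

    ENVI output is BSQ, float64, with the wavelength list in the header.
    """
    path = Path(path)
    if cube.height == 0 or cube.width == 0:
        raise FormatError("refusing to write a cube with empty spatial extent")
    if format is None:
        format = "array_container" if path.suffix == ".npz" else "envi"

    if format == "array_container":
        np.savez(path, values=cube.values, wavelengths_nm=cube.wavelengths_nm)
    elif format == "envi":
        hdr_path = Path(str(path) + ".hdr") if path.suffix != ".hdr" else path
        data_path = path if path.suffix != ".hdr" else path.with_suffix("")
        wl = ", ".join(repr(float(w)) for w in cube.wavelengths_nm)
        header = (
            "ENVI\n"
            "description = {veinindex hyperspectral cube}\n"
            f"samples = {cube.width}\n"
            f"lines = {cube.height}\n"
            f"bands = {cube.n_bands}\n"
            "header offset = 0\n"
            "file type = ENVI Standard\n"
            f"data type = {_DTYPE_TO_ENVI[np.dtype(np.float64)]}\n"
            "interleave = bsq\n"
            "byte order = 0\n"
            "wavelength units = Nanometers\n"
            f"wavelength = {{ {wl} }}\n"
        )
        hdr_path.write_text(header)
        cube.values.transpose(2, 0, 1).astype(np.float64).tofile(data_path)
    else:
        raise FormatError(f"unknown cube format '{format}'")
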