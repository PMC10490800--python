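"""Hyperspectral cube I/O, reflectance correction, segmentation, extraction.

Cubes live in memory as ``rows x cols x bands`` float arrays tied to a
wavelength grid.  On disk they use the ENVI convention: a plain-text header
(``samples``/``lines``/``bands``, data type, interleave, wavelength list)
next to a raw binary file in BIL, BIP or BSQ order.

Reflectance correction follows the standard black/white calibration

    I = (I0 - IB) / (IW - IB)

with IB the all-dark frame (lens capped) and IW the ~99%-reflectance white
tile.  Entries where IW - IB <= 0 cannot be calibrated; the affected pixels
are dropped from the valid mask instead of being clamped or left non-finite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .core import SpectraSet, WavelengthGrid


class EnviError(ValueError):
    pass


class NoSampleError(RuntimeError):
    """Segmentation found no pellet pixels."""


@dataclass
class RawCube:
    """Uncorrected detector counts, rows x cols x bands."""

    data: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError("cube data must be 3-D (rows x cols x bands)")
        if d.shape[2] != len(self.grid):
            raise ValueError(
                f"cube has {d.shape[2]} bands but grid has {len(self.grid)}"
            )
        if min(d.shape) <= 0:
            raise ValueError("all cube dimensions must be positive")
        self.data = d

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReflectanceCube:
    """Calibrated reflectance with a per-pixel validity mask."""

    data: np.ndarray
    grid: WavelengthGrid
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        m = np.asarray(self.valid_mask, dtype=bool)
        if d.ndim != 3 or d.shape[2] != len(self.grid):
            raise ValueError("reflectance cube dims must match its grid")
        if m.shape != d.shape[:2]:
            raise ValueError("valid_mask must match the cube's spatial dims")
        if not np.all(np.isfinite(d[m])):
            raise ValueError("non-finite reflectance on valid pixels")
        self.data = d
        self.valid_mask = m

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------- ENVI I/O

_INTERLEAVES = ("bil", "bip", "bsq")


def write_envi(
    cube: RawCube | ReflectanceCube,
    header_path: str | Path,
    data_path: str | Path,
    interleave: str = "bil",
) -> None:
    """Write a cube as ENVI header + float32 binary."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviError(f"unsupported interleave {interleave!r}")
    rows, cols, bands = cube.data.shape
    if interleave == "bip":
        arr = cube.data  # (lines, samples, bands)
    elif interleave == "bil":
        arr = np.transpose(cube.data, (0, 2, 1))  # (lines, bands, samples)
    else:  # bsq
        arr = np.transpose(cube.data, (2, 0, 1))  # (bands, lines, samples)
    wl = ", ".join(repr(float(w)) for w in cube.grid.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    Path(header_path).write_text(header)
    arr.astype("<f4").tofile(data_path)


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise EnviError("not an ENVI header (missing magic)")
    # join brace-delimited multi-line values, then split into key = value
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip().lower()] = v.strip()
    return fields


def read_envi(header_path: str | Path, data_path: str | Path) -> RawCube:
    """Read an ENVI header + binary pair into a cube."""
    fields = _parse_envi_header(Path(header_path).read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields.get("data type", "4"))
        interleave = fields.get("interleave", "bil").lower()
    except KeyError as e:
        raise EnviError(f"header missing required field: {e}") from None
    if "wavelength" not in fields:
        raise EnviError("header missing wavelength list")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wl = np.array([float(t) for t in wl_text.split(",") if t.strip()])
    if wl.size != bands:
        raise EnviError(f"wavelength list has {wl.size} entries for {bands} bands")
    dtypes = {1: "u1", 2: "<i2", 4: "<f4", 5: "<f8", 12: "<u2"}
    if dtype_code not in dtypes:
        raise EnviError(f"unsupported ENVI data type {dtype_code}")
    raw = np.fromfile(data_path, dtype=dtypes[dtype_code])
    expected = rows * cols * bands
    if raw.size != expected:
        raise EnviError(
            f"binary holds {raw.size} values, header declares {expected}"
        )
    if interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:
        raise EnviError(f"unsupported interleave {interleave!r}")
    return RawCube(np.ascontiguousarray(data, dtype=float), WavelengthGrid(wl))


# ------------------------------------------------------- correction & masks


def correct_reflectance(
    raw: RawCube, dark: RawCube | np.ndarray, white: RawCube | np.ndarray
) -> ReflectanceCube:
    """Black/white calibration I = (I0 - IB) / (IW - IB).

    ``dark``/``white`` may be full cubes matching ``raw`` or per-band
    vectors.  Pixels with any non-calibratable band (IW <= IB) are excluded
    from the valid mask; their data are zero-filled, never non-finite.
    """
    ib = dark.data if isinstance(dark, RawCube) else np.asarray(dark, float)
    iw = white.data if isinstance(white, RawCube) else np.asarray(white, float)
    i0 = raw.data
    try:
        denom = np.broadcast_to(iw - ib, i0.shape)
        ib_b = np.broadcast_to(ib, i0.shape)
    except ValueError:
        raise ValueError("dark/white frames are not compatible with the cube")
    ok3 = denom > 0
    if not ok3.any():
        raise ValueError("degenerate references: white <= dark everywhere")
    data = np.where(ok3, (i0 - ib_b) / np.where(ok3, denom, 1.0), 0.0)
    valid = ok3.all(axis=2)
    return ReflectanceCube(data, raw.grid, valid)


def segment_sample(
    cube: ReflectanceCube,
    method: str = "otsu",
    min_component_size: int = 20,
    foreground: str = "bright",
) -> np.ndarray:
    """Binary pellet mask from the band-averaged reflectance image.

    Default: two-class automatic (Otsu) threshold on the band mean, keep
    the bright (or dark) class, drop connected components smaller than
    ``min_component_size`` pixels.
    """
    if method != "otsu":
        raise ValueError(f"unknown segmentation method {method!r}")
    mean_img = cube.data.mean(axis=2)
    vals = mean_img[cube.valid_mask]
    if vals.size == 0 or np.ptp(vals) < 1e-12:
        raise NoSampleError("no sample detected (image has no contrast)")
    t = threshold_otsu(vals)
    mask = (mean_img > t) if foreground == "bright" else (mean_img < t)
    mask &= cube.valid_mask
    if min_component_size > 1:
        # drop components strictly smaller than min_component_size pixels
        mask = remove_small_objects(mask, max_size=min_component_size - 1)
    if not mask.any():
        raise NoSampleError("no sample detected")
    return mask


def mean_spectrum(cube: ReflectanceCube, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean over masked pixels, one value per band."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape must match the cube's spatial dims")
    if not mask.any():
        raise ValueError("empty mask")
    if np.any(mask & ~cube.valid_mask):
        raise ValueError("mask includes invalid pixels")
    return cube.data[mask].mean(axis=0)


def pixel_spectra(cube: ReflectanceCube, mask: np.ndarray) -> SpectraSet:
    """Masked pixels as rows of a SpectraSet (IDs ``px<row>_<col>``)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rr, cc = np.nonzero(mask)
    ids = [f"px{r}_{c}" for r, c in zip(rr, cc)]
    return SpectraSet(cube.data[mask], cube.grid, ids)


def trim_bands(s: SpectraSet, lo_nm: float, hi_nm: float) -> SpectraSet:
    """Keep channels with lo_nm <= wavelength <= hi_nm (closed interval).

    On the stock 256-channel 935.5-2539 nm grid, trimming to [960, 2489]
    drops the low-SNR spectral edges and leaves 244 bands.
    """
    if lo_nm >= hi_nm:
        raise ValueError("lo_nm must be < hi_nm")
    wl = s.grid.wavelengths
    keep = (wl >= lo_nm) & (wl <= hi_nm)
    if not keep.any():
        raise ValueError("no channel inside the trim interval")
    return SpectraSet(s.matrix[:, keep], WavelengthGrid(wl[keep]), s.sample_ids)
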