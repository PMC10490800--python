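"""Synthetic NIR data generator for pellet-feed moisture studies.

Real acquisitions of this kind are rarely deposited, so the package ships a
generator that reproduces the statistical structure the downstream analysis
assumes: ~144 samples with moisture mostly in 8-14%, reflectance spectra on
[0, 1] with water absorption features near 1450 and 1940 nm, nuisance
constituent bands, per-sample multiplicative scatter and additive offset
(the distortions MSC/SNV are designed to remove), smooth baseline drift and
channel noise, plus full hyperspectral scenes with dark/white reference
frames and ground-truth masks.

The noiseless, scatter-free construction is exactly affine in moisture, so
a full-rank linear regressor recovers it perfectly; every stochastic term
is controlled by an explicit standard deviation in :class:`SimulationConfig`
and all randomness flows from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import ReferenceTable, SpectraSet, WavelengthGrid, default_grid
from .hypercube import RawCube

# (center nm, width nm sigma, reflectance drop per percentage point moisture)
WATER_PEAKS: tuple[tuple[float, float, float], ...] = (
    (1450.0, 45.0, 0.020),
    (1940.0, 55.0, 0.027),
)
# Nuisance constituents (protein/fat/fibre bands): (center, width, depth at unit
# concentration); concentrations vary sample-to-sample around 1.
NUISANCE_PEAKS: tuple[tuple[float, float, float], ...] = (
    (1100.0, 40.0, 0.05),
    (1720.0, 50.0, 0.06),
    (2300.0, 60.0, 0.05),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Noise/structure settings for the spectral simulator.

    All standard deviations are on the reflectance scale except
    ``conc_sd`` (relative constituent-concentration spread).
    """

    n_samples: int = 144
    moisture_range: tuple[float, float] = (8.0, 14.0)
    other_fraction: float = 0.1
    water_peaks: tuple[tuple[float, float, float], ...] = WATER_PEAKS
    constituent_peaks: tuple[tuple[float, float, float], ...] = NUISANCE_PEAKS
    scatter_sd: float = 0.05
    offset_sd: float = 0.02
    baseline_coeffs_sd: tuple[float, ...] = (0.01, 0.005, 0.002)
    noise_sd: float = 0.002
    noise_corr_length: float = 4.0
    noise_white_sd: float = 1.5e-4
    conc_sd: float = 0.08
    seed: int = 20230901

    def __post_init__(self) -> None:
        lo, hi = self.moisture_range
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if lo >= hi:
            raise ValueError(f"invalid moisture interval: lo={lo} >= hi={hi}")
        for c, w, a in self.water_peaks + self.constituent_peaks:
            if w <= 0:
                raise ValueError(f"peak width must be positive (peak at {c} nm)")
        if self.noise_white_sd > self.noise_sd:
            raise ValueError("noise_white_sd cannot exceed the total noise_sd")
        for name in ("scatter_sd", "offset_sd", "noise_sd", "conc_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 0 for s in self.baseline_coeffs_sd):
            raise ValueError("baseline_coeffs_sd entries must be >= 0")

    def noiseless(self) -> "SimulationConfig":
        """Copy with every stochastic term switched off."""
        return replace(
            self,
            scatter_sd=0.0,
            offset_sd=0.0,
            noise_sd=0.0,
            noise_white_sd=0.0,
            conc_sd=0.0,
            baseline_coeffs_sd=tuple(0.0 for _ in self.baseline_coeffs_sd),
        )


@dataclass
class GroundTruth:
    """Oracle record written by the generators.

    ``true_coefficients`` is dX/dH: the per-band spectral signature of
    moisture (negative at the water bands — more water, less reflectance).
    Scene generation additionally records the pellet mask and the true
    per-pixel moisture field.
    """

    true_coefficients: np.ndarray
    per_pixel_moisture: np.ndarray | None = None
    sample_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sample_mask is not None and self.per_pixel_moisture is not None:
            if self.sample_mask.shape != self.per_pixel_moisture.shape:
                raise ValueError("mask and moisture field shapes must agree")


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _channel_noise(shape: tuple[int, ...], cfg: SimulationConfig, rng) -> np.ndarray:
    """Channel noise with total sd ``noise_sd``.

    Spectra here are means over thousands of pellet pixels, so iid detector
    noise averages down to ~1e-4 reflectance (the white floor); the bulk of
    the channel-to-channel noise budget is presentation/illumination
    variation that is smooth along wavelength (correlation length
    ``noise_corr_length`` channels).
    """
    if cfg.noise_sd == 0:
        return np.zeros(shape)
    smooth_sd = math.sqrt(max(cfg.noise_sd**2 - cfg.noise_white_sd**2, 0.0))
    out = cfg.noise_white_sd * rng.standard_normal(shape)
    if smooth_sd > 0 and cfg.noise_corr_length > 0:
        raw = rng.standard_normal(shape)
        sm = ndimage.gaussian_filter1d(raw, cfg.noise_corr_length, axis=-1)
        sd = sm.std()
        if sd > 0:
            out = out + smooth_sd * sm / sd
    elif smooth_sd > 0:
        out = out + smooth_sd * rng.standard_normal(shape)
    return out


def _water_profile(grid: WavelengthGrid, cfg: SimulationConfig) -> np.ndarray:
    wl = grid.wavelengths
    prof = np.zeros_like(wl)
    for c, w, a in cfg.water_peaks:
        prof += a * _gauss(wl, c, w)
    return prof


# Fixed dry-matter (cellulose/carbohydrate/lignin) absorption bands: these do
# not vary between samples and give the matrix spectrum its curvature.
MATRIX_BANDS: tuple[tuple[float, float, float], ...] = (
    (2100.0, 30.0, 0.12),
    (2350.0, 30.0, 0.09),
)


def _base_reflectance(grid: WavelengthGrid) -> np.ndarray:
    # Bright, gently sloping matrix reflectance typical of dried plant
    # pellets, with the fixed dry-matter absorption bands superimposed.
    wl = grid.wavelengths
    base = 0.70 - 8e-5 * (wl - wl[0])
    for c, w, a in MATRIX_BANDS:
        base = base - a * _gauss(wl, c, w)
    return base


def generate_reference_values(
    n: int = 144,
    range_: tuple[float, float] = (8.0, 14.0),
    other_fraction: float = 0.1,
    seed: int = 0,
) -> ReferenceTable:
    """Draw laboratory-style moisture references in percent.

    ``1 - other_fraction`` of the values fall uniformly inside ``range_``;
    the remainder (the histogram's "Other" bin) fall just outside it,
    weighted toward the dry side.
    """
    lo, hi = range_
    if lo >= hi:
        raise ValueError(f"invalid moisture interval: lo={lo} >= hi={hi}")
    if n < 4:
        raise ValueError("need at least 4 samples")
    if not 0.0 <= other_fraction <= 1.0:
        raise ValueError("other_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_other = int(round(other_fraction * n))
    inside = rng.uniform(lo, hi, size=n - n_other)
    n_low = (n_other * 3) // 5  # most "Other" feeds sit below the window
    low = rng.uniform(max(lo - 3.0, 0.5), lo - 1e-6, size=n_low)
    high = rng.uniform(hi + 1e-6, hi + 2.0, size=n_other - n_low)
    h = np.concatenate([inside, low, high])
    rng.shuffle(h)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return ReferenceTable(ids, h)


def _sample_structure(
    refs: ReferenceTable, grid: WavelengthGrid, cfg: SimulationConfig, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless per-sample reflectance (before scatter/offset/noise) and dX/dH."""
    lo_nm, hi_nm = grid.span()
    for c, _, _ in cfg.water_peaks + cfg.constituent_peaks:
        if not lo_nm <= c <= hi_nm:
            raise ValueError(f"peak center {c} nm lies outside the grid span")
    wl = grid.wavelengths
    n = len(refs)
    water = _water_profile(grid, cfg)
    base = _base_reflectance(grid)

    # per-sample nuisance constituent concentrations around 1
    conc = 1.0 + cfg.conc_sd * rng.standard_normal((n, len(cfg.constituent_peaks)))
    conc = np.clip(conc, 0.1, None)
    nuis = np.zeros((n, wl.size))
    for j, (c, w, a) in enumerate(cfg.constituent_peaks):
        nuis += conc[:, [j]] * a * _gauss(wl, c, w)[None, :]

    # smooth per-sample baseline drift: low-order Chebyshev perturbation
    t = 2.0 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1.0
    basis = np.polynomial.chebyshev.chebvander(t, len(cfg.baseline_coeffs_sd) - 1)
    coeffs = rng.standard_normal((n, basis.shape[1])) * np.asarray(
        cfg.baseline_coeffs_sd
    )
    drift = coeffs @ basis.T

    clean = base[None, :] + drift - refs.moisture[:, None] * water[None, :] - nuis
    return clean, -water


def generate_spectra(
    refs: ReferenceTable, grid: WavelengthGrid, cfg: SimulationConfig
) -> tuple[SpectraSet, GroundTruth]:
    """Mean reflectance spectra for each reference sample.

    spectrum_i = gain_i * [base(l) + drift_i(l) - H_i*water(l) - nuisance_i(l)]
                 + offset_i + noise
    """
    if len(refs) == 0:
        raise ValueError("reference table is empty")
    rng = np.random.default_rng(cfg.seed)
    clean, dxdh = _sample_structure(refs, grid, cfg, rng)
    n, p = clean.shape
    gain = 1.0 + cfg.scatter_sd * rng.standard_normal((n, 1))
    offset = cfg.offset_sd * rng.standard_normal((n, 1))
    matrix = gain * clean + offset + _channel_noise((n, p), cfg, rng)
    return SpectraSet(matrix, grid, refs.sample_ids), GroundTruth(dxdh)


def _smooth_field(shape: tuple[int, int], sd: float, sigma_px: float, rng) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    s = field_.std()
    return field_ * (sd / s) if s > 0 else field_


def generate_scene(
    refs: ReferenceTable,
    grid: WavelengthGrid,
    cfg: SimulationConfig,
    shape: tuple[int, int] = (120, 160),
    spatial_sd: float = 0.3,
) -> tuple[RawCube, RawCube, RawCube, GroundTruth]:
    """One elliptical pellet region imaged against a dark tray.

    Pellet pixels carry the first reference sample's spectrum with a smooth
    low-frequency moisture perturbation (sd ``spatial_sd`` percentage
    points); the scene is returned as raw detector counts together with
    matching dark (sensor floor) and white (near-saturation) frames so the
    black/white correction is exercised end to end.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError("scene shape must be positive")
    if rows < 8 or cols < 8:
        raise ValueError("scene too small to hold a pellet region")
    rng = np.random.default_rng(cfg.seed + 1)
    p = len(grid)
    wl = grid.wavelengths

    yy, xx = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    mask = (((yy - cy) / (0.35 * rows)) ** 2 + ((xx - cx) / (0.35 * cols)) ** 2) <= 1.0

    h0 = float(refs.moisture[0])
    field_ = _smooth_field((rows, cols), spatial_sd, sigma_px=min(rows, cols) / 12, rng=rng)
    h_map = np.where(mask, h0 + field_, np.nan)

    one = ReferenceTable([refs.sample_ids[0]], np.array([h0]))
    clean_row, dxdh = _sample_structure(one, grid, cfg, np.random.default_rng(cfg.seed))
    # reflectance linear in per-pixel moisture around the sample spectrum
    water = -dxdh
    gain = 1.0 + cfg.scatter_sd * np.random.default_rng(cfg.seed).standard_normal()
    offset = cfg.offset_sd * np.random.default_rng(cfg.seed + 7).standard_normal()

    refl = np.full((rows, cols, p), 0.08)  # spectrally flat tray background
    hm = np.nan_to_num(h_map, nan=h0)
    pellet = clean_row[0][None, None, :] - (hm - h0)[:, :, None] * water[None, None, :]
    pellet = gain * pellet + offset
    refl = np.where(mask[:, :, None], pellet, refl)
    refl = refl + _channel_noise(refl.shape, cfg, rng)

    dark_counts = 120.0 + 10.0 * _smooth_field((rows, cols), 1.0, 6.0, rng)[..., None]
    dark_counts = np.broadcast_to(dark_counts, (rows, cols, p)).copy()
    vign = 1.0 - 0.05 * (((yy - cy) / cy) ** 2 + ((xx - cx) / cx) ** 2)
    white_counts = dark_counts + 3900.0 * vign[..., None] * np.ones(p)[None, None, :]
    raw_counts = dark_counts + refl * (white_counts - dark_counts)

    gt = GroundTruth(dxdh, per_pixel_moisture=h_map, sample_mask=mask)
    return (
        RawCube(raw_counts, grid),
        RawCube(dark_counts, grid),
        RawCube(white_counts, grid),
        gt,
    )


def generate_sparse_dataset(
    n_samples: int = 80,
    n_vars: int = 100,
    informative: Sequence[int] | None = None,
    coefs: Sequence[float] = (2.0, 2.5, 3.0, -2.5, 3.5),
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[SpectraSet, ReferenceTable, np.ndarray]:
    """Generic sparse-signal benchmark for variable-selection studies.

    ``y`` depends linearly on a handful of the columns; the rest are pure
    distractors.  Returns (X, y-table, informative index array).  The
    response is shifted to a moisture-like level around 11%.  By default
    the informative columns are spread evenly across the variable axis.
    """
    if informative is None:
        informative = np.linspace(0, n_vars - 1, len(coefs) + 2, dtype=int)[1:-1]
    informative = np.asarray(informative, dtype=int)
    if np.any(informative < 0) or np.any(informative >= n_vars):
        raise ValueError("informative indices out of range")
    coefs = np.asarray(coefs, dtype=float)
    if informative.size != coefs.size:
        raise ValueError("informative indices and coefficients must align")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, n_vars))
    y = 11.0 + X[:, informative] @ coefs * 0.5 + noise_sd * rng.standard_normal(n_samples)
    y = np.clip(y, 0.5, 99.0)
    grid = WavelengthGrid(np.linspace(1000.0, 1000.0 + 10.0 * (n_vars - 1), n_vars))
    ids = [f"Q{i + 1:03d}" for i in range(n_samples)]
    return SpectraSet(X, grid, ids), ReferenceTable(ids, y), informative
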