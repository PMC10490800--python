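"""Spectral preprocessing operators with a fit/apply split.

Seven operators, the standard toolbox for diffuse-reflectance NIR data:

* ``FD`` / ``SD`` — first/second finite-difference derivatives scaled by the
  channel spacing; remove additive offsets (FD) and linear baselines (SD).
* ``SG`` — Savitzky-Golay windowed polynomial derivative (default: second
  derivative, 9-point window, cubic fit); a smoothed alternative to SD.
* ``SNV`` — per-spectrum standardization (mean 0, sd 1, n-1 denominator).
* ``MSC`` — per-spectrum affine regression against the training-mean
  reference followed by inversion of the fitted gain/offset.
* ``MC`` — subtract training column means.
* ``MMN`` — per-band min-max scaling using training min/max.

Row-wise operators (FD/SD/SG/SNV) need no training statistics; MSC/MC/MMN
fit on the calibration set only and reuse those statistics on test and
pixel data, so no information leaks across the split.  Derivative outputs
shrink (no edge padding — fabricated edge values would otherwise enter
variable selection) and the wavelength grid shrinks with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import savgol_coeffs

from .core import SpectraSet, WavelengthGrid

METHODS = ("FD", "SD", "SG", "MSC", "SNV", "MC", "MMN")
_CONST_TOL = 1e-12  # sd / MSC-slope magnitude below this is a constant row


class ConstantRowError(ValueError):
    """A spectrum with (numerically) zero variance cannot be scatter-corrected."""


@dataclass
class Preprocessor:
    method: str
    sg_window: int = 9
    sg_degree: int = 3
    sg_deriv: int = 2
    _state: dict[str, Any] = field(default_factory=dict, repr=False)
    _fit_grid: WavelengthGrid | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        m = self.method.upper()
        if m not in METHODS:
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        self.method = m
        if m == "SG":
            if self.sg_window % 2 == 0 or self.sg_window <= self.sg_degree:
                raise ValueError("SG window must be odd and > polynomial degree")
            if self.sg_deriv not in (1, 2):
                raise ValueError("SG derivative order must be 1 or 2")

    # ------------------------------------------------------------------ fit

    @property
    def needs_fit(self) -> bool:
        return self.method in ("MSC", "MC", "MMN")

    @property
    def fitted(self) -> bool:
        return bool(self._state) or not self.needs_fit

    def fit(self, train: SpectraSet) -> "Preprocessor":
        if train.n_samples == 0:
            raise ValueError("empty training set")
        X = train.matrix
        if self.method == "MSC":
            self._state = {"reference": X.mean(axis=0)}
        elif self.method == "MC":
            self._state = {"means": X.mean(axis=0)}
        elif self.method == "MMN":
            mn, mx = X.min(axis=0), X.max(axis=0)
            if np.any(mx - mn < _CONST_TOL):
                raise ValueError(
                    "MMN needs per-band spread; a degenerate (e.g. single-sample) "
                    "training set has min = max"
                )
            self._state = {"min": mn, "max": mx}
        self._fit_grid = train.grid
        return self

    # ---------------------------------------------------------------- apply

    def output_grid(self, grid: WavelengthGrid) -> WavelengthGrid:
        wl = grid.wavelengths
        if self.method == "FD":
            return WavelengthGrid(0.5 * (wl[1:] + wl[:-1]))
        if self.method == "SD":
            return WavelengthGrid(wl[1:-1])
        if self.method == "SG":
            h = self.sg_window // 2
            if wl.size <= 2 * h:
                raise ValueError("spectrum shorter than the SG window")
            return WavelengthGrid(wl[h:-h])
        return grid

    def apply(self, s: SpectraSet) -> SpectraSet:
        if self.needs_fit:
            if not self._state:
                raise RuntimeError(f"{self.method} must be fitted before apply")
            if self._fit_grid is not None and (
                len(self._fit_grid) != len(s.grid)
                or not np.allclose(
                    self._fit_grid.wavelengths, s.grid.wavelengths, atol=0.1
                )
            ):
                raise ValueError("grid mismatch between fit and apply data")
        X = s.matrix
        m = self.method
        if m == "SNV":
            out = self._snv(X)
        elif m == "MSC":
            out = self._msc(X)
        elif m == "FD":
            step = s.grid.require_uniform()
            out = np.diff(X, axis=1) / step
        elif m == "SD":
            step = s.grid.require_uniform()
            out = np.diff(X, n=2, axis=1) / step**2
        elif m == "SG":
            out = self._sg(X, s.grid)
        elif m == "MC":
            out = X - self._state["means"]
        else:  # MMN
            mn, mx = self._state["min"], self._state["max"]
            out = (X - mn) / (mx - mn)
        return SpectraSet(out, self.output_grid(s.grid), s.sample_ids)

    def fit_apply(self, train: SpectraSet) -> SpectraSet:
        return self.fit(train).apply(train) if self.needs_fit else self.apply(train)

    # -------------------------------------------------------------- helpers

    @staticmethod
    def _snv(X: np.ndarray) -> np.ndarray:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        bad = np.nonzero(sd.ravel() < _CONST_TOL)[0]
        if bad.size:
            raise ConstantRowError(
                f"SNV undefined for constant spectra (rows {bad[:5].tolist()})"
            )
        return (X - mu) / sd

    def _msc(self, X: np.ndarray) -> np.ndarray:
        r = self._state["reference"]
        rc = r - r.mean()
        vr = rc @ rc
        if vr < _CONST_TOL:
            raise ConstantRowError("MSC reference spectrum is constant")
        b = (X - X.mean(axis=1, keepdims=True)) @ rc / vr
        bad = np.nonzero(np.abs(b) < _CONST_TOL)[0]
        if bad.size:
            raise ConstantRowError(
                f"MSC slope ~ 0 for rows {bad[:5].tolist()}; cannot invert"
            )
        a = X.mean(axis=1) - b * r.mean()
        return (X - a[:, None]) / b[:, None]

    def _sg(self, X: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
        step = grid.require_uniform()
        if X.shape[1] < self.sg_window:
            raise ValueError("spectrum shorter than the SG window")
        c = savgol_coeffs(
            self.sg_window, self.sg_degree, deriv=self.sg_deriv, delta=step
        )
        # savgol coefficients are convolution coefficients; correlation with
        # the reversed kernel evaluates the fitted polynomial's derivative at
        # each interior window center.
        win = np.lib.stride_tricks.sliding_window_view(X, self.sg_window, axis=1)
        return win @ c[::-1]
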