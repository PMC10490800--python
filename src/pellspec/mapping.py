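"""Pixel-wise moisture distribution mapping.

Every pellet pixel carries its own reflectance spectrum, so a trained
calibration (trim interval + fitted preprocessing + selected wavelengths +
regression model) can be applied per pixel to chart how moisture varies
across the sample.  Pixels whose spectra cannot be preprocessed (e.g. a
constant spectrum under SNV/MSC) are marked missing and counted, never
aborting the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import SpectraSet
from .feature_selection import SelectionResult
from .hypercube import ReflectanceCube, pixel_spectra, trim_bands
from .preprocessing import ConstantRowError, Preprocessor

_CONST_TOL = 1e-12


@dataclass
class MoistureMap:
    """Predicted moisture (%) per pellet pixel; NaN outside the mask."""

    values: np.ndarray
    mask: np.ndarray
    n_failed: int = 0
    model_id: str = ""
    preprocess_id: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes must agree")
        on = self.values[self.mask]
        # failed pixels are NaN inside the mask but counted
        if np.sum(~np.isfinite(on)) != self.n_failed:
            raise ValueError("n_failed inconsistent with NaNs inside the mask")
        if np.any(np.isfinite(self.values[~self.mask])):
            raise ValueError("values outside the mask must be missing")

    def masked_mean(self) -> float:
        on = self.values[self.mask]
        return float(np.nanmean(on))

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.6g")


def predict_map(
    cube: ReflectanceCube,
    mask: np.ndarray,
    model,
    preprocessor: Preprocessor | None,
    selection: SelectionResult | None,
    trim: tuple[float, float] | None = (960.0, 2489.0),
) -> MoistureMap:
    """Apply the trained calibration chain to every masked pixel.

    Per pixel: trim bands -> apply the *training-fitted* preprocessing ->
    restrict to the selected wavelengths (indices live on the preprocessed
    grid, so derivative-induced shrinkage is already accounted for) ->
    predict.  Unmasked pixels hold NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    spectra = pixel_spectra(cube, mask)
    if trim is not None:
        spectra = trim_bands(spectra, *trim)

    n_px = spectra.n_samples
    ok = np.ones(n_px, dtype=bool)
    if preprocessor is not None:
        # pre-screen rows the row-wise scatter corrections cannot handle
        if preprocessor.method == "SNV":
            ok = spectra.matrix.std(axis=1, ddof=1) >= _CONST_TOL
        elif preprocessor.method == "MSC":
            r = preprocessor._state["reference"]
            rc = r - r.mean()
            b = (spectra.matrix - spectra.matrix.mean(axis=1, keepdims=True)) @ rc / (rc @ rc)
            ok = np.abs(b) >= _CONST_TOL
        good = SpectraSet(
            spectra.matrix[ok],
            spectra.grid,
            [spectra.sample_ids[i] for i in np.nonzero(ok)[0]],
        )
        processed = preprocessor.apply(good)
    else:
        processed = spectra

    Xp = processed.matrix
    if selection is not None:
        Xp = Xp[:, selection.selected_indices]
    pred_ok = model.predict(Xp)

    pred = np.full(n_px, np.nan)
    pred[ok] = np.asarray(pred_ok, dtype=float).ravel()
    values = np.full(mask.shape, np.nan)
    values[mask] = pred
    return MoistureMap(
        values=values,
        mask=mask,
        n_failed=int(np.sum(~ok)),
        model_id=type(model).__name__,
        preprocess_id=preprocessor.method if preprocessor else "none",
    )


def render_map(
    map_: MoistureMap, lo: float, hi: float, out_path: str | Path
) -> Path:
    """Render the map with a blue-to-red colormap over [lo, hi].

    Values are clipped for display only (the data are untouched); the
    background is neutral gray and a colorbar in percent is attached.
    Renders are byte-deterministic for identical inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if lo >= hi:
        raise ValueError("lo must be < hi")
    if not map_.mask.any():
        raise ValueError("empty map")
    shown = np.ma.masked_invalid(np.clip(map_.values, lo, hi))
    cmap = plt.get_cmap("jet").copy()
    cmap.set_bad("0.8")
    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.imshow(shown, cmap=cmap, vmin=lo, vmax=hi, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="Moisture content (%)")
    ax.set_axis_off()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, metadata={"Software": "pellspec"})
    plt.close(fig)
    return out_path


def default_display_range(map_: MoistureMap) -> tuple[float, float]:
    """1st/99th percentile display bounds for a map."""
    on = map_.values[map_.mask]
    on = on[np.isfinite(on)]
    lo, hi = np.percentile(on, [1, 99])
    if lo >= hi:
        lo, hi = lo - 0.5, hi + 0.5
    return float(lo), float(hi)
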