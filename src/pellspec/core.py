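"""Core containers: wavelength grids, spectra matrices, reference tables.

Spectra are stored as a plain samples x bands float matrix tied to a
wavelength grid (nm) and a list of sample identifiers; moisture references
are percent-by-mass values keyed by the same identifiers.  CSV layout for
spectra: first column ``sample_id``, one column per wavelength, header row
holds the wavelengths in nm at one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Spectrometer span of the imaging system this package targets:
# 256 channels covering 935.5-2539 nm (~6.29 nm sampling).
DEFAULT_N_BANDS = 256
DEFAULT_LO_NM = 935.5
DEFAULT_HI_NM = 2539.0


class GridError(ValueError):
    """Raised for malformed wavelength grids."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Channel centers in nm, strictly increasing.

    Grids built programmatically (``default_grid``, trimming, derivative
    outputs) are uniform to numerical precision; grids read back from CSV
    headers are rounded to 0.1 nm, so operators that need uniform spacing
    tolerate up to 2% spacing deviation.
    """

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise GridError("wavelength grid must be a nonempty 1-D array")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise GridError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def spacing(self) -> float:
        """Mean channel spacing in nm."""
        if len(self) < 2:
            raise GridError("spacing undefined for a single-channel grid")
        return float(np.mean(np.diff(self.wavelengths)))

    def require_uniform(self, rel_tol: float = 2e-2) -> float:
        """Return the spacing, or raise if the grid is not near-uniform."""
        d = np.diff(self.wavelengths)
        step = float(np.mean(d))
        if np.max(np.abs(d - step)) > rel_tol * step:
            raise GridError("operation requires a (near-)uniform wavelength grid")
        return step

    def is_uniform(self, abs_tol: float = 1e-9) -> bool:
        d = np.diff(self.wavelengths)
        return bool(np.max(np.abs(d - np.mean(d))) <= abs_tol) if d.size else True

    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])


def default_grid(
    n_bands: int = DEFAULT_N_BANDS,
    lo_nm: float = DEFAULT_LO_NM,
    hi_nm: float = DEFAULT_HI_NM,
) -> WavelengthGrid:
    """The instrument grid: ``n_bands`` channels linearly spanning [lo, hi] nm."""
    if n_bands < 2 or lo_nm >= hi_nm:
        raise GridError("need at least 2 bands and lo < hi")
    return WavelengthGrid(np.linspace(lo_nm, hi_nm, n_bands))


@dataclass
class SpectraSet:
    """Samples x bands matrix on a wavelength grid with per-row IDs."""

    matrix: np.ndarray
    grid: WavelengthGrid
    sample_ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("spectra matrix must be 2-D (samples x bands)")
        if m.shape[1] != len(self.grid):
            raise ValueError(
                f"matrix has {m.shape[1]} bands but grid has {len(self.grid)}"
            )
        ids = [str(s) for s in self.sample_ids]
        if len(ids) != m.shape[0]:
            raise ValueError("sample_ids length must match matrix rows")
        if not np.all(np.isfinite(m)):
            raise ValueError("spectra matrix contains non-finite values")
        self.matrix = m
        self.sample_ids = ids

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bands(self) -> int:
        return self.matrix.shape[1]

    def subset_rows(self, idx: Sequence[int] | np.ndarray) -> "SpectraSet":
        idx = np.asarray(idx, dtype=int)
        return SpectraSet(self.matrix[idx], self.grid, [self.sample_ids[i] for i in idx])

    def drop_ids(self, ids: Iterable[str]) -> "SpectraSet":
        drop = set(ids)
        keep = [i for i, s in enumerate(self.sample_ids) if s not in drop]
        return self.subset_rows(keep)

    def to_csv(self, path: str | Path) -> None:
        cols = [f"{w:.1f}" for w in self.grid.wavelengths]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraSet":
        df = pd.read_csv(path)
        if "sample_id" not in df.columns:
            raise ValueError("spectra CSV must have a sample_id column")
        ids = df["sample_id"].astype(str).tolist()
        wl = np.array([float(c) for c in df.columns if c != "sample_id"])
        return cls(df.drop(columns="sample_id").to_numpy(float), WavelengthGrid(wl), ids)


@dataclass
class ReferenceTable:
    """Laboratory moisture references (percent by mass) keyed by sample ID."""

    sample_ids: list[str]
    moisture: np.ndarray

    def __post_init__(self) -> None:
        ids = [str(s) for s in self.sample_ids]
        h = np.asarray(self.moisture, dtype=float)
        if h.ndim != 1 or len(ids) != h.size:
            raise ValueError("sample_ids and moisture must be 1-D and aligned")
        if len(set(ids)) != len(ids):
            raise ValueError("sample IDs must be unique")
        if np.any(h < 0) or np.any(h >= 100):
            raise ValueError("moisture values must lie in [0, 100) percent")
        self.sample_ids = ids
        self.moisture = h

    def __len__(self) -> int:
        return len(self.sample_ids)

    def aligned_to(self, ids: Sequence[str]) -> np.ndarray:
        """Moisture values reordered to match ``ids``."""
        lookup = {s: v for s, v in zip(self.sample_ids, self.moisture)}
        try:
            return np.array([lookup[s] for s in ids], dtype=float)
        except KeyError as e:  # pragma: no cover - message clarity
            raise KeyError(f"sample {e} has no reference value") from None

    def drop_ids(self, ids: Iterable[str]) -> "ReferenceTable":
        drop = set(ids)
        keep = [(s, v) for s, v in zip(self.sample_ids, self.moisture) if s not in drop]
        return ReferenceTable([s for s, _ in keep], np.array([v for _, v in keep]))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"sample_id": self.sample_ids, "moisture": self.moisture}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        df = pd.read_csv(path)
        return cls(df["sample_id"].astype(str).tolist(), df["moisture"].to_numpy(float))
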