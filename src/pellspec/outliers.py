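"""Monte Carlo cross-validation (MCCV) abnormal-sample detection.

Repeatedly split the samples at random (default 75% calibration / 25%
held out, 1000 cycles), fit a PLS model on each calibration subset, and
accumulate each sample's held-out prediction residuals.  A sample's
residual mean (MEAN) exposes reference-value errors; its residual spread
(STD) exposes unstable spectra.  Samples far from the bulk of the
MEAN-STD cloud are abnormal; the default rejection rule is a robust
z-score (median/MAD) above 3 on either axis.

MCCV runs on the trimmed raw spectra, before preprocessing, so the
detector sees the data exactly as measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ReferenceTable, SpectraSet
from .regression import fit_plsr, select_nc


@dataclass(frozen=True)
class MccvConfig:
    train_fraction: float = 0.75
    n_iterations: int = 1000
    pls_components: int | None = None  # None -> choose once by 10-fold CV, cap 15
    seed: int = 0
    z_threshold: float = 3.0
    robust: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 100:
            raise ValueError("n_iterations must be >= 100 for stable statistics")
        if self.pls_components is not None and self.pls_components < 1:
            raise ValueError("pls_components must be >= 1")


@dataclass
class OutlierReport:
    sample_ids: list[str]
    mean: np.ndarray
    std: np.ndarray
    n_appearances: np.ndarray
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.n_appearances <= 0):
            warnings.warn(
                "insufficient coverage: some samples were never held out; "
                "increase n_iterations"
            )
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.std))):
            raise ValueError("non-finite residual statistics")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "MEAN": self.mean,
                "STD": self.std,
                "n_appearances": self.n_appearances,
                "flagged": [s in set(self.flagged) for s in self.sample_ids],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def mccv_residuals(
    X: SpectraSet, y: ReferenceTable, cfg: MccvConfig = MccvConfig()
) -> OutlierReport:
    """Per-sample held-out residual MEAN/STD over MCCV cycles.

    The PLS component count is chosen once on the full data (10-fold CV,
    capped at 15) and held fixed across cycles.  Deterministic for a fixed
    seed; the flag list is filled by :func:`flag_outliers` with the
    config's rule.
    """
    # canonical row order (by sample ID) so the report is invariant to the
    # order samples arrive in, up to relabeling
    order = np.argsort(np.asarray(X.sample_ids))
    X = X.subset_rows(order)
    yv = y.aligned_to(X.sample_ids)
    n = X.n_samples
    n_train = int(round(cfg.train_fraction * n))
    if n_train >= n or n_train < 2:
        raise ValueError("train fraction leaves no held-out (or no training) samples")
    if cfg.pls_components is None:
        nc, _ = select_nc(X.matrix, yv, max_nc=15, folds=10, seed=cfg.seed)
    else:
        nc = cfg.pls_components
    if nc >= n_train:
        raise ValueError("pls_components must be below the training-subset size")

    rng = np.random.default_rng(cfg.seed)
    s1 = np.zeros(n)
    s2 = np.zeros(n)
    cnt = np.zeros(n, dtype=int)
    Xm = X.matrix
    for _ in range(cfg.n_iterations):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit_plsr(Xm[tr], yv[tr], nc)
        res = yv[te] - model.predict(Xm[te])
        s1[te] += res
        s2[te] += res**2
        cnt[te] += 1

    safe = np.maximum(cnt, 1)
    mean = s1 / safe
    var = (s2 - safe * mean**2) / np.maximum(safe - 1, 1)
    std = np.sqrt(np.maximum(var, 0.0))
    report = OutlierReport(list(X.sample_ids), mean, std, cnt)
    report.flagged = flag_outliers(report, cfg.z_threshold, cfg.robust)
    return report


def _zscores(v: np.ndarray, robust: bool) -> np.ndarray:
    if robust:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad > 0:
            return (v - med) / (1.4826 * mad)
        warnings.warn("MAD = 0; falling back to classical z-score")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def flag_outliers(
    report: OutlierReport, z_threshold: float = 3.0, robust: bool = True
) -> list[str]:
    """Sample IDs whose MEAN (two-sided) or STD (high side) robust z-score
    exceeds the threshold, sorted by decreasing deviation."""
    zm = np.abs(_zscores(report.mean, robust))
    zs = _zscores(report.std, robust)
    dev = np.maximum(zm, zs)
    hit = dev > z_threshold
    order = np.argsort(dev[hit])[::-1]
    ids = np.asarray(report.sample_ids)[hit][order]
    return [str(s) for s in ids]
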