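"""Calibration models and chemometric evaluation metrics.

PLSR (latent-variable regression, component count picked by 10-fold
cross-validation) and random-forest regression, plus the standard NIR
calibration report: R2/RMSE on the calibration set (RC2, RMSEC), in
cross-validation (RCV2, RMSECV) and on the prediction set (RP2, RMSEP),
the ratio of performance to deviation RPD = sd(y_test)/RMSEP, and the
bias-corrected standard error of prediction SE.  RPD > 3 and SE below
twice the laboratory standard error (SEL) are the usual "usable model"
rules of thumb.

The model fits delegate to scikit-learn (PLSRegression, NIPALS variant;
RandomForestRegressor) behind this module's interface; metrics, tuning
loops, splits and the mass-balance moisture utility are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .core import ReferenceTable, SpectraSet


def moisture_from_mass(m1: float, m2: float) -> float:
    """Moisture percent from wet mass ``m1`` and dried mass ``m2``.

    H = 100 * (M1 - M2) / M1.
    """
    if m1 <= 0:
        raise ValueError("mass before drying must be positive")
    if m2 < 0 or m2 > m1:
        raise ValueError("dried mass must satisfy 0 <= M2 <= M1 (no mass gain)")
    return 100.0 * (m1 - m2) / m1


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, SpectraSet):
        if isinstance(y, ReferenceTable):
            y = y.aligned_to(X.sample_ids)
        X = X.matrix
    elif isinstance(y, ReferenceTable):
        y = y.moisture
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    return X, y


# ------------------------------------------------------------------- PLSR


@dataclass
class PlsModel:
    """Fitted PLS regression: latent factorization plus flat coefficients.

    Prediction through the factorization (scikit-learn estimator) and
    through the flattened affine form ``b0 + X @ b`` agree to numerical
    precision; the flat form is what pixel-wise mapping and serialization
    use.
    """

    n_components: int
    b0: float
    b: np.ndarray
    estimator: PLSRegression = field(repr=False)

    def predict(self, X) -> np.ndarray:
        X = X.matrix if isinstance(X, SpectraSet) else np.asarray(X, dtype=float)
        return self.b0 + X @ self.b

    def to_dict(self) -> dict:
        return {
            "model": "plsr",
            "n_components": int(self.n_components),
            "intercept": float(self.b0),
            "coefficients": [float(v) for v in self.b],
        }


def fit_plsr(X, y, n_components: int) -> PlsModel:
    X, y = _as_xy(X, y)
    max_nc = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= max_nc:
        raise ValueError(
            f"n_components must lie in [1, {max_nc}] for this data shape"
        )
    est = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # y-residual exhaustion at high nc
        est.fit(X, y)
    b = np.asarray(est.coef_).reshape(-1)
    # estimator predicts on centered X; fold the centering into the intercept
    b0 = float(np.asarray(est.intercept_).reshape(-1)[0] - X.mean(axis=0) @ b)
    return PlsModel(n_components, b0, b, est)


def cv_rmse(
    X, y, n_components: int, folds: int = 10, seed: int = 0
) -> float:
    """Pooled k-fold RMSECV of a PLS model (deterministic given seed)."""
    X, y = _as_xy(X, y)
    n = X.shape[0]
    if folds > n:
        raise ValueError("more folds than samples")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sq = np.empty(n)
    for tr, te in kf.split(X):
        nc = min(n_components, len(tr) - 1, X.shape[1])
        model = fit_plsr(X[tr], y[tr], nc)
        sq[te] = (y[te] - model.predict(X[te])) ** 2
    return float(np.sqrt(sq.mean()))


def select_nc(
    X, y, max_nc: int = 15, folds: int = 10, seed: int = 0
) -> tuple[int, np.ndarray]:
    """Scan nc = 1..max_nc by k-fold RMSECV; return (argmin, curve).

    Ties resolve to the smallest component count.  ``max_nc`` is capped by
    the rank bound of the smallest training fold.
    """
    X, y = _as_xy(X, y)
    if max_nc < 1:
        raise ValueError("max_nc must be >= 1")
    n = X.shape[0]
    if folds > n:
        raise ValueError("more folds than samples")
    cap = min(max_nc, n - int(np.ceil(n / folds)) - 1, X.shape[1])
    cap = max(cap, 1)
    curve = np.array(
        [cv_rmse(X, y, nc, folds=folds, seed=seed) for nc in range(1, cap + 1)]
    )
    return int(np.argmin(curve)) + 1, curve


# -------------------------------------------------------------------- RFR


def fit_rfr(
    X,
    y,
    n_trees: int = 100,
    min_leaf: int = 5,
    seed: int = 0,
    max_features: float | str = 0.333,
) -> RandomForestRegressor:
    """Random-forest regression: bootstrapped CART trees, random feature
    subsets (default a third of the bands, the regression-forest custom),
    mean aggregation."""
    X, y = _as_xy(X, y)
    if n_trees < 1 or min_leaf < 1:
        raise ValueError("n_trees and min_leaf must be >= 1")
    if min_leaf > X.shape[0]:
        raise ValueError("min_leaf exceeds the number of samples")
    est = RandomForestRegressor(
        n_estimators=n_trees,
        min_samples_leaf=min_leaf,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return est


def tune_rfr(
    X,
    y,
    trees_grid: Sequence[int] = tuple(range(100, 1001, 100)),
    leaf_grid: Sequence[int] = tuple(range(1, 11)),
    folds: int = 10,
    seed: int = 0,
) -> tuple[int, int, float]:
    """Grid-search (n_trees, min_leaf) by k-fold CV RMSE.

    Returns (n_trees, min_leaf, best_rmse).  Ties prefer fewer trees, then
    a larger leaf (the smoother model).
    """
    X, y = _as_xy(X, y)
    if not len(trees_grid) or not len(leaf_grid):
        raise ValueError("grids must be nonempty")
    if len(trees_grid) == 1 and len(leaf_grid) == 1:
        return int(trees_grid[0]), int(leaf_grid[0]), float("nan")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best: tuple[float, int, int] | None = None
    for nt in sorted(trees_grid):
        for leaf in sorted(leaf_grid, reverse=True):
            sq = np.empty(X.shape[0])
            for tr, te in splits:
                est = fit_rfr(X[tr], y[tr], n_trees=nt, min_leaf=leaf, seed=seed)
                sq[te] = (y[te] - est.predict(X[te])) ** 2
            rmse = float(np.sqrt(sq.mean()))
            if best is None or rmse < best[0]:
                best = (rmse, nt, leaf)
    assert best is not None
    return best[1], best[2], best[0]


# ---------------------------------------------------------------- metrics


@dataclass
class EvaluationReport:
    """Calibration / cross-validation / prediction metrics in the layout
    chemometric papers tabulate them."""

    rmsecv: float | None = None
    rcv2: float | None = None
    rmsec: float | None = None
    rc2: float | None = None
    rmsep: float | None = None
    rp2: float | None = None
    rpd: float | None = None
    se: float | None = None
    sel: float | None = None

    def to_dict(self) -> dict:
        keys = ("rmsecv", "rcv2", "rmsec", "rc2", "rmsep", "rp2", "rpd", "se", "sel")
        return {
            k.upper(): (None if getattr(self, k) is None else float(getattr(self, k)))
            for k in keys
        }


def evaluate(y_ref, y_pred, role: str = "test") -> dict:
    """R2 / RMSE (all roles) plus RPD and bias-corrected SE for the test set.

    R2 = 1 - SS_res/SS_tot; RMSE = sqrt(mean squared residual);
    RPD = sd_{n-1}(y_ref) / RMSEP; SE = sd_{n-1} of the residuals (the
    standard error of prediction with the mean bias removed).
    """
    y = np.asarray(y_ref, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if y.size != p.size or y.size < 2:
        raise ValueError("need equal-length arrays with at least 2 values")
    e = y - p
    rmse = float(np.sqrt(np.mean(e**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(e**2)) / ss_tot if ss_tot > 0 else float("nan")
    out = {"r2": r2, "rmse": rmse, "n": int(y.size)}
    if role == "test":
        sd = float(np.std(y, ddof=1))
        out["rpd"] = sd / rmse if rmse > 0 else float("inf")
        if ss_tot == 0:
            out["rpd"] = float("nan")
        out["se"] = float(np.sqrt(np.sum((e - e.mean()) ** 2) / (e.size - 1)))
    return out


def sel_from_replicates(pairs: Sequence[tuple[float, float]]) -> float:
    """Standard error of the laboratory from duplicate determinations.

    SEL = sqrt( sum d_i^2 / (2 m) ) over the m duplicate differences d_i —
    the usual duplicate-analysis convention, which converges to the
    single-measurement sd of the reference method.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 replicate pairs")
    d = np.array([a - b for a, b in pairs], dtype=float)
    return float(np.sqrt(np.sum(d**2) / (2 * d.size)))


# ----------------------------------------------------------------- splits


def random_split(
    n: int, test_fraction: float = 0.25, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random calibration/prediction split; returns (train_idx, test_idx)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def kennard_stone_split(
    X, test_fraction: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Kennard-Stone calibration set selection (max-min Euclidean).

    Deterministic: seeds with the two most distant spectra, then greedily
    adds the sample farthest from the current calibration set.
    """
    X = X.matrix if isinstance(X, SpectraSet) else np.asarray(X, dtype=float)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = X.shape[0]
    n_train = n - max(1, int(round(test_fraction * n)))
    if n_train < 2:
        raise ValueError("calibration set would have fewer than 2 samples")
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    chosen = [int(i), int(j)]
    mind = np.minimum(d2[i], d2[j])
    while len(chosen) < n_train:
        mind[chosen] = -1.0
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, d2[nxt])
    train = np.sort(np.array(chosen))
    test = np.setdiff1d(np.arange(n), train)
    return train, test
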