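"""Characteristic-wavelength selection: CARS and SPA.

CARS (competitive adaptive reweighted sampling) runs N Monte Carlo rounds.
Each round fits a PLS model on a random sample subset using the currently
retained wavelengths, weights every wavelength by its absolute regression
coefficient,

    w_i = |B_i| / sum_j |B_j|,

then applies two competitions: an enforced cut keeping the top ceil(r_i * n)
wavelengths, where the retention ratio follows the exponentially decreasing
function (EDF)

    r_i = mu * exp(-k i),  mu = (n/2)^(1/(N-1)),  k = ln(n/2) / (N-1),

so r_1 = 1 (everything retained) and r_N = 2/n (two wavelengths survive a
full schedule); and, from round 2 on, adaptive reweighted sampling — a
weighted bootstrap over the surviving wavelengths whose unique draws become
the retained set.  Every round's retained set is scored by k-fold PLS
RMSECV and the round with the smallest RMSECV wins.

SPA (successive projections algorithm) is a forward chain: starting from a
column, each step projects all remaining columns orthogonally to the last
selected one and picks the column with the largest projected norm, which
minimizes collinearity among the selected wavelengths.  Candidate chains
over all start columns and chain lengths are scored by cross-validated PLS
RMSE and the best (smallest-RMSE, then shortest, then lowest start) subset
is returned.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ReferenceTable, SpectraSet
from .regression import cv_rmse, fit_plsr, select_nc


def edf_ratio(i: int, n: int, N: int) -> float:
    """Retention ratio r_i = mu e^{-ki} = (n/2)^((1-i)/(N-1))."""
    if N < 2:
        raise ValueError("need at least 2 runs")
    if not 1 <= i <= N:
        raise ValueError(f"run index {i} outside [1, {N}]")
    if n <= 2:
        raise ValueError("need more than 2 variables for the EDF schedule")
    mu = (n / 2.0) ** (1.0 / (N - 1))
    k = math.log(n / 2.0) / (N - 1)
    return mu * math.exp(-k * i)


def coefficient_weights(B: np.ndarray) -> np.ndarray:
    """Normalized importance weights w_i = |B_i| / sum|B_j|."""
    B = np.abs(np.asarray(B, dtype=float).ravel())
    s = B.sum()
    if s <= 0:
        raise ValueError("all regression coefficients are zero")
    return B / s


@dataclass(frozen=True)
class CarsConfig:
    n_runs: int = 40
    mc_sample_fraction: float = 0.80
    cv_folds: int = 10
    pls_components: int | None = None
    use_ars: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not 0 < self.mc_sample_fraction < 1:
            raise ValueError("mc_sample_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SelectionResult:
    method: str
    selected_indices: np.ndarray
    selected_wavelengths: np.ndarray
    rmsecv_trace: np.ndarray
    chosen: int  # run number (CARS) or chain length (SPA)
    n_total: int
    retained_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_indices, dtype=int)
        if idx.size != np.unique(idx).size:
            raise ValueError("selected indices must be unique")
        order = np.argsort(idx)
        self.selected_indices = idx[order]
        self.selected_wavelengths = np.asarray(self.selected_wavelengths, float)[order]

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)

    @property
    def selected_fraction_pct(self) -> float:
        return selected_fraction_pct(self.n_selected, self.n_total)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected_indices": [int(i) for i in self.selected_indices],
            "selected_wavelengths": [round(float(w), 2) for w in self.selected_wavelengths],
            "rmsecv_trace": [float(v) for v in self.rmsecv_trace],
            "chosen": int(self.chosen),
            "n_total": int(self.n_total),
            "n_selected": self.n_selected,
            "selected_fraction_pct": self.selected_fraction_pct,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def selected_fraction_pct(n_selected: int, n_total: int) -> float:
    """Selected wavelengths as a percentage of the full band, one decimal."""
    if n_total <= 0 or n_selected < 0 or n_selected > n_total:
        raise ValueError("need 0 <= n_selected <= n_total with n_total > 0")
    return round(100.0 * n_selected / n_total, 1)


def _sorted_by_ids(X: SpectraSet, y: ReferenceTable) -> tuple[np.ndarray, np.ndarray, SpectraSet]:
    """Row order canonicalized by sample ID so selection is invariant to
    input permutation."""
    order = np.argsort(np.asarray(X.sample_ids))
    Xs = X.subset_rows(order)
    return Xs.matrix, y.aligned_to(Xs.sample_ids), Xs


def cars_select(X: SpectraSet, y: ReferenceTable, cfg: CarsConfig) -> SelectionResult:
    """Competitive adaptive reweighted sampling over the band axis."""
    Xm, yv, Xs = _sorted_by_ids(X, y)
    n_samples, n_vars = Xm.shape
    if n_samples < 2 * cfg.cv_folds:
        raise ValueError("need at least 2x cv_folds samples")
    if n_vars <= 2:
        raise ValueError("need more than 2 wavelengths")
    rng = np.random.default_rng(cfg.seed)
    if cfg.pls_components is None:
        nc, _ = select_nc(Xm, yv, max_nc=10, folds=cfg.cv_folds, seed=cfg.seed)
    else:
        nc = cfg.pls_components
    n_sub = int(np.ceil(cfg.mc_sample_fraction * n_samples))

    retained = np.arange(n_vars)
    traces: list[float] = []
    counts: list[int] = []
    snapshots: list[np.ndarray] = []
    for i in range(1, cfg.n_runs + 1):
        sub = rng.choice(n_samples, size=n_sub, replace=False)
        nc_i = max(1, min(nc, retained.size, n_sub - 1))
        model = fit_plsr(Xm[np.ix_(sub, retained)], yv[sub], nc_i)
        w = coefficient_weights(model.b)

        keep = int(np.ceil(edf_ratio(i, n_vars, cfg.n_runs) * n_vars))
        keep = max(2, min(keep, retained.size))
        top = np.argsort(w)[::-1][:keep]
        retained = retained[np.sort(top)]
        w_kept = w[np.sort(top)]

        if cfg.use_ars and i > 1:
            ws = w_kept / w_kept.sum()
            drawn = rng.choice(retained, size=keep, replace=True, p=ws)
            uniq = np.unique(drawn)
            if uniq.size >= 2:
                retained = uniq
        if retained.size < nc:
            warnings.warn(
                f"run {i}: retained set ({retained.size}) below the PLS "
                "component count; evaluating with reduced components"
            )
        nc_eval = max(1, min(nc, retained.size, n_samples - 1))
        traces.append(
            cv_rmse(Xm[:, retained], yv, nc_eval, folds=cfg.cv_folds, seed=cfg.seed)
        )
        counts.append(retained.size)
        snapshots.append(retained.copy())

    chosen = int(np.argmin(traces))  # ties -> earlier run
    sel = snapshots[chosen]
    return SelectionResult(
        method="CARS",
        selected_indices=sel,
        selected_wavelengths=Xs.grid.wavelengths[sel],
        rmsecv_trace=np.array(traces),
        chosen=chosen + 1,
        n_total=n_vars,
        retained_counts=np.array(counts),
    )


# -------------------------------------------------------------------- SPA


def spa_chain(X: np.ndarray, k0: int, N: int) -> np.ndarray:
    """Successive-projections chain of ``N`` column indices starting at k0.

    Columns are mean-centered; at each step every remaining column is
    replaced by its component orthogonal to the last selected (projected)
    column, and the largest-norm column is selected next.  The chain
    truncates with a warning once the residual space is numerically
    exhausted.
    """
    X = X.matrix if isinstance(X, SpectraSet) else np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= k0 < p:
        raise ValueError("start column out of range")
    if N < 1 or N > min(n - 1, p):
        raise ValueError("chain length must satisfy 1 <= N <= min(samples-1, cols)")
    P = X - X.mean(axis=0)
    chain = [k0]
    avail = np.ones(p, dtype=bool)
    avail[k0] = False
    for _ in range(N - 1):
        v = P[:, chain[-1]]
        vv = v @ v
        if vv < 1e-12:
            warnings.warn("SPA chain truncated: projection space exhausted")
            break
        P = P - np.outer(v, v @ P) / vv
        norms = np.linalg.norm(P, axis=0)
        norms[~avail] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] < 1e-12:
            warnings.warn("SPA chain truncated: all residual projections ~ 0")
            break
        chain.append(nxt)
        avail[nxt] = False
    return np.array(chain, dtype=int)


def spa_select(
    X: SpectraSet,
    y: ReferenceTable,
    n_min: int = 1,
    n_max: int | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    starts: Sequence[int] | None = None,
    pls_components: int | None = None,
) -> SelectionResult:
    """Score SPA chains over start columns and lengths by CV PLS RMSE.

    Ties prefer the shorter chain, then the lower start index.  ``starts``
    restricts the start-column scan (default: every column).
    """
    Xm, yv, Xs = _sorted_by_ids(X, y)
    n, p = Xm.shape
    if n_max is None:
        n_max = min(n - 1, p)
    if n_max < n_min or n_min < 1:
        raise ValueError("need 1 <= n_min <= n_max")
    if n_max > min(n - 1, p):
        raise ValueError("n_max exceeds min(samples-1, columns)")
    starts = range(p) if starts is None else starts
    chains = {int(k0): spa_chain(Xm, int(k0), n_max) for k0 in starts}
    best: tuple[float, int, int] | None = None
    trace: dict[int, float] = {}
    for size in range(n_min, n_max + 1):
        for k0 in sorted(chains):
            sub = chains[k0][:size]
            if sub.size < size:
                continue
            nc = max(1, min(pls_components or 10, size, n - 1))
            r = cv_rmse(Xm[:, sub], yv, nc, folds=cv_folds, seed=seed)
            # numerical ties resolve to the smaller chain / lower start
            if best is None or r < best[0] * (1 - 1e-9) - 1e-12:
                best = (r, size, k0)
            trace[size] = min(trace.get(size, np.inf), r)
    if best is None:
        raise ValueError("no feasible SPA subset")
    rmse, size, k0 = best
    sel = chains[k0][:size]
    sizes = sorted(trace)
    return SelectionResult(
        method="SPA",
        selected_indices=sel,
        selected_wavelengths=Xs.grid.wavelengths[sel],
        rmsecv_trace=np.array([trace[s] for s in sizes]),
        chosen=size,
        n_total=p,
    )
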