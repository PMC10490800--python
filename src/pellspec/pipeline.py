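"""Declarative end-to-end pipeline.

One config drives the whole sequence: simulate (or ingest ENVI cubes) ->
extract mean spectra -> trim edge bands -> MCCV outlier rejection ->
preprocess -> wavelength selection -> calibration -> evaluation -> pixel
map.  Every stage writes its artifact to the output directory and the run
ends with a manifest (config hash, seeds, artifact paths, metrics) that
suffices to reproduce every number; identical config + seed give
byte-identical evaluation JSON.

Leakage discipline: outlier rejection sees the trimmed raw spectra of all
samples; the calibration/prediction split happens next; preprocessing
statistics, wavelength selection and model hyperparameters are fitted on
the calibration set only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import synthetic
from .core import ReferenceTable, SpectraSet, default_grid
from .feature_selection import CarsConfig, SelectionResult, cars_select, spa_select
from .hypercube import (
    correct_reflectance,
    mean_spectrum,
    read_envi,
    segment_sample,
    trim_bands,
)
from .mapping import default_display_range, predict_map, render_map
from .outliers import MccvConfig, flag_outliers, mccv_residuals
from .preprocessing import Preprocessor
from .regression import (
    EvaluationReport,
    cv_rmse,
    evaluate,
    fit_plsr,
    fit_rfr,
    kennard_stone_split,
    random_split,
    select_nc,
)

log = logging.getLogger("pellspec.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Everything a run needs; see module docstring for stage order."""

    out_dir: str = "pellspec_run"
    seed: int = 20230901
    # input: either simulate or ENVI cubes + refs
    simulate: bool = True
    n_samples: int = 144
    scene_shape: tuple[int, int] = (120, 160)
    cube_header: str | None = None
    cube_data: str | None = None
    dark_header: str | None = None
    dark_data: str | None = None
    white_header: str | None = None
    white_data: str | None = None
    refs_csv: str | None = None
    # stages
    trim_nm: tuple[float, float] = (960.0, 2489.0)
    mccv_iterations: int = 1000
    mccv_enabled: bool = True
    preprocess: str = "SD"
    selector: str = "cars"  # cars | spa | none
    cars_runs: int = 40
    model: str = "plsr"  # plsr | rfr
    test_fraction: float = 0.25
    split_method: str = "random"  # random | kennard_stone
    make_map: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise PipelineError("config", "unknown-keys", f"unknown config keys {sorted(bad)}")
        cfg = cls(**d)
        for k in ("trim_nm", "scene_shape"):
            setattr(cfg, k, tuple(getattr(cfg, k)))
        if cfg.selector not in ("cars", "spa", "none"):
            raise PipelineError("config", "bad-selector", f"selector {cfg.selector!r}")
        if cfg.model not in ("plsr", "rfr"):
            raise PipelineError("config", "bad-model", f"model {cfg.model!r}")
        if not cfg.simulate:
            needed = ("cube_header", "cube_data", "dark_header", "dark_data",
                      "white_header", "white_data", "refs_csv")
            for k in needed:
                v = getattr(cfg, k)
                if v is None or not Path(v).exists():
                    raise PipelineError("config", "missing-input", f"{k}={v!r}")
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d)

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                out = fn(*a, **k)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, "failed", str(e)) from e
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured run; returns (and writes) the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    rng_seed = int(cfg.seed)

    # ---- ingest / simulate --------------------------------------------
    @_stage("ingest")
    def ingest():
        if cfg.simulate:
            sim = synthetic.SimulationConfig(n_samples=cfg.n_samples, seed=rng_seed)
            refs = synthetic.generate_reference_values(
                cfg.n_samples, sim.moisture_range, sim.other_fraction, seed=rng_seed
            )
            grid = default_grid()
            spectra, _ = synthetic.generate_spectra(refs, grid, sim)
            scene = (
                synthetic.generate_scene(refs, grid, sim, cfg.scene_shape)
                if cfg.make_map
                else None
            )
            return spectra, refs, scene
        raw = read_envi(cfg.cube_header, cfg.cube_data)
        dark = read_envi(cfg.dark_header, cfg.dark_data)
        white = read_envi(cfg.white_header, cfg.white_data)
        refs = ReferenceTable.from_csv(cfg.refs_csv)
        cube = correct_reflectance(raw, dark, white)
        mask = segment_sample(cube)
        spec = mean_spectrum(cube, mask)
        spectra = SpectraSet(spec[None, :], cube.grid, [refs.sample_ids[0]])
        return spectra, refs, (raw, dark, white, None)

    spectra, refs, scene = ingest()
    spectra.to_csv(out / "spectra.csv")
    refs.to_csv(out / "references.csv")
    artifacts["spectra"] = "spectra.csv"
    artifacts["references"] = "references.csv"

    # ---- trim ----------------------------------------------------------
    @_stage("trim")
    def trim():
        return trim_bands(spectra, *cfg.trim_nm)

    trimmed = trim()

    # ---- outlier rejection --------------------------------------------
    removed: list[str] = []
    if cfg.mccv_enabled and trimmed.n_samples >= 20:

        @_stage("outliers")
        def outliers():
            mc = MccvConfig(n_iterations=cfg.mccv_iterations, seed=rng_seed)
            report = mccv_residuals(trimmed, refs, mc)
            report.to_csv(out / "outlier_report.csv")
            return report

        report = outliers()
        artifacts["outlier_report"] = "outlier_report.csv"
        removed = report.flagged
    clean_X = trimmed.drop_ids(removed)
    clean_refs = refs.drop_ids(removed)

    # ---- split ---------------------------------------------------------
    @_stage("split")
    def split():
        if cfg.split_method == "kennard_stone":
            return kennard_stone_split(clean_X, cfg.test_fraction)
        return random_split(clean_X.n_samples, cfg.test_fraction, seed=rng_seed)

    tr_idx, te_idx = split()
    Xtr, Xte = clean_X.subset_rows(tr_idx), clean_X.subset_rows(te_idx)
    ytr = clean_refs.aligned_to(Xtr.sample_ids)
    yte = clean_refs.aligned_to(Xte.sample_ids)

    # ---- preprocess ----------------------------------------------------
    @_stage("preprocess")
    def preprocess():
        if cfg.preprocess.lower() in ("none", "raw"):
            return None, Xtr, Xte
        pp = Preprocessor(cfg.preprocess)
        if pp.needs_fit:
            pp.fit(Xtr)
        return pp, pp.apply(Xtr), pp.apply(Xte)

    pp, Ptr, Pte = preprocess()
    Ptr.to_csv(out / "preprocessed_train.csv")
    artifacts["preprocessed_train"] = "preprocessed_train.csv"

    # ---- selection -----------------------------------------------------
    @_stage("select")
    def select():
        if cfg.selector == "none":
            idx = np.arange(Ptr.n_bands)
            return SelectionResult(
                method="none",
                selected_indices=idx,
                selected_wavelengths=Ptr.grid.wavelengths,
                rmsecv_trace=np.array([]),
                chosen=0,
                n_total=Ptr.n_bands,
            )
        if cfg.selector == "cars":
            refs_tr = ReferenceTable(Xtr.sample_ids, ytr)
            return cars_select(
                Ptr, refs_tr, CarsConfig(n_runs=cfg.cars_runs, seed=rng_seed)
            )
        refs_tr = ReferenceTable(Xtr.sample_ids, ytr)
        return spa_select(
            Ptr, refs_tr, n_min=5, n_max=min(40, Ptr.n_samples - 1), seed=rng_seed,
            starts=range(0, Ptr.n_bands, max(1, Ptr.n_bands // 32)),
        )

    selection = select()
    selection.to_json(out / "selection.json")
    artifacts["selection"] = "selection.json"
    Str = Ptr.matrix[:, selection.selected_indices]
    Ste = Pte.matrix[:, selection.selected_indices]

    # ---- train + evaluate ---------------------------------------------
    @_stage("train")
    def train():
        if cfg.model == "plsr":
            nc, _ = select_nc(Str, ytr, max_nc=15, folds=10, seed=rng_seed)
            model = fit_plsr(Str, ytr, nc)
            rmsecv = cv_rmse(Str, ytr, nc, folds=10, seed=rng_seed)
            meta = {"nc": nc}
        else:
            model = fit_rfr(Str, ytr, seed=rng_seed)
            from sklearn.model_selection import KFold

            kf = KFold(10, shuffle=True, random_state=rng_seed)
            sq = np.empty(len(ytr))
            for tri, tei in kf.split(Str):
                est = fit_rfr(Str[tri], ytr[tri], seed=rng_seed)
                sq[tei] = (ytr[tei] - est.predict(Str[tei])) ** 2
            rmsecv = float(np.sqrt(sq.mean()))
            meta = {"n_trees": 100, "min_leaf": 5}
        return model, rmsecv, meta

    model, rmsecv, meta = train()

    @_stage("evaluate")
    def evaluate_stage():
        cal = evaluate(ytr, model.predict(Str), role="train")
        tst = evaluate(yte, model.predict(Ste), role="test")
        rcv2 = 1.0 - rmsecv**2 / np.var(ytr, ddof=0) if np.var(ytr) > 0 else float("nan")
        rep = EvaluationReport(
            rmsecv=rmsecv,
            rcv2=rcv2,
            rmsec=cal["rmse"],
            rc2=cal["r2"],
            rmsep=tst["rmse"],
            rp2=tst["r2"],
            rpd=tst["rpd"],
            se=tst["se"],
        )
        d = rep.to_dict()
        d.update(
            {
                "model": cfg.model,
                "preprocess": cfg.preprocess,
                "selector": cfg.selector,
                "n_selected": selection.n_selected,
                "selected_fraction_pct": selection.selected_fraction_pct,
                "n_train": int(len(ytr)),
                "n_test": int(len(yte)),
                "removed_outliers": sorted(removed),
                **meta,
            }
        )
        _write_json(out / "evaluation.json", d)
        return rep, d

    report, report_dict = evaluate_stage()
    artifacts["evaluation"] = "evaluation.json"

    model_doc = {
        "config_digest": cfg.digest(),
        "preprocess": cfg.preprocess,
        "selection": selection.to_dict(),
        "metadata": meta,
    }
    if hasattr(model, "to_dict"):
        model_doc["model"] = model.to_dict()
    else:
        model_doc["model"] = {"model": "rfr", **meta}
    _write_json(out / "model.json", model_doc)
    artifacts["model"] = "model.json"

    # ---- map -----------------------------------------------------------
    map_stats = None
    if cfg.make_map and cfg.simulate and scene is not None and cfg.model == "plsr":

        @_stage("map")
        def mapping():
            raw, dark, white, gt = scene
            cube = correct_reflectance(raw, dark, white)
            mask = segment_sample(cube)
            m = predict_map(cube, mask, model, pp, selection, trim=cfg.trim_nm)
            m.to_csv(out / "moisture_map.csv")
            lo, hi = default_display_range(m)
            render_map(m, lo, hi, out / "moisture_map.png")
            stats = {"masked_mean": m.masked_mean(), "n_failed": m.n_failed}
            if gt is not None and gt.per_pixel_moisture is not None:
                both = mask & gt.sample_mask
                err = np.abs(m.values - gt.per_pixel_moisture)[both]
                stats["mae_vs_truth"] = float(np.nanmean(err))
            return stats

        map_stats = mapping()
        artifacts["map"] = "moisture_map.csv"
        artifacts["map_render"] = "moisture_map.png"

    manifest = {
        "config": json.loads(cfg.canonical_json()),
        "config_digest": cfg.digest(),
        "seed": rng_seed,
        "artifacts": artifacts,
        "metrics": report_dict,
        "map": map_stats,
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
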