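"""End-to-end orchestration: preprocess -> GWPCA -> FCM -> grouped fits.

One :func:`run_pipeline` call reproduces the full comparison a spectral
classification study makes: pooled (unclassified) calibration, calibration
within spectral clusters found by GWPCA + fuzzy c-means, and — when the
library carries land-cover strata — calibration within strata.  All three
use the same per-group Kennard-Stone 2:1 validation protocol so their
report rows are directly comparable.

A single run seed fans out into independent per-stage seeds (stable hash
of the stage name) so individual stages can be re-run reproducibly.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from spectroclust.spectral_data import (
    SpectralDataset,
    read_spectra_table,
    resample_spectra,
    to_absorbance,
    savgol_smooth,
)
from spectroclust.gwpca import KernelSpec, fit_gwpca, select_bandwidth, standardize, choose_n_components
from spectroclust.fuzzy_clustering import fcm_fit, sweep_clusters
from spectroclust.calibration_models import fit_per_group, fit_global
from spectroclust.evaluation import evaluate_grouped
from spectroclust.synthetic_scene import preset_config, generate_scene, scene_presets


class PipelineError(RuntimeError):
    pass


def _package_version() -> str:
    import spectroclust

    return spectroclust.__version__


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the run seed and stage name."""
    return (zlib.crc32(stage.encode()) ^ (seed * 2654435761)) % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``input`` is either a path to a wide spectral CSV or the name of a
    synthetic scene preset.  ``gwpca_bandwidth`` is a number (km for the
    haversine metric), ``"auto"`` for leave-one-out selection, or
    ``"adaptive"`` for an n/2-nearest-neighbor adaptive kernel.
    ``fcm_c="auto"`` sweeps 2..10 and picks by FPI/NCE rank-sum.
    """

    input: str
    seed: int
    outdir: str | None = None
    resample_interval: float | None = None
    savgol_window: int = 15
    savgol_order: int = 2
    gwpca_k: int | str = "auto"
    gwpca_bandwidth: float | str = "adaptive"
    gwpca_metric: str = "haversine"
    fcm_c: int | str = "auto"
    fcm_fuzziness: float = 1.5
    fcm_max_iter: int = 300
    fcm_tol: float = 1e-3
    fcm_restarts: int = 5
    split_ratio: tuple = (2, 1)
    models: tuple = ("plsr", "cubist")
    groupings: tuple = ("none", "cluster", "stratum")
    min_group_size: int = 30
    model_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "split_ratio" in raw:
            raw["split_ratio"] = tuple(raw["split_ratio"])
        for key in ("models", "groupings"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunResult:
    manifest: dict
    reports: dict  # {model: {grouping: GroupedReport}}
    dataset: SpectralDataset
    scores: np.ndarray
    cluster_labels: np.ndarray
    memberships: np.ndarray


def _load(cfg: RunConfig):
    if cfg.input in scene_presets():
        scene_cfg = preset_config(cfg.input, seed=stage_seed(cfg.seed, "scene"))
        ds, labels, _ = generate_scene(scene_cfg)
        return ds, {"source": f"preset:{cfg.input}", "scene_seed": scene_cfg.seed}
    ds = read_spectra_table(cfg.input)
    return ds, {"source": str(cfg.input)}


def run_pipeline(cfg: RunConfig) -> RunResult:
    t0 = time.perf_counter()
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "version": _package_version(),
        "stages": {},
    }
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def record(stage, t_start, **info):
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t_start, 3), **info}

    try:
        # ---- load ------------------------------------------------------
        t = time.perf_counter()
        ds, meta = _load(cfg)
        record("load", t, n=ds.n_samples, m=ds.n_bands, **meta)

        # ---- preprocess ------------------------------------------------
        t = time.perf_counter()
        if cfg.resample_interval:
            ds = resample_spectra(ds, cfg.resample_interval)
        if ds.mode == "reflectance":
            ds = to_absorbance(ds)
        ds = savgol_smooth(ds, cfg.savgol_window, cfg.savgol_order)
        record("preprocess", t, m=ds.n_bands)

        # ---- gwpca -----------------------------------------------------
        t = time.perf_counter()
        Xstd = standardize(ds.values)
        k = choose_n_components(Xstd) if cfg.gwpca_k == "auto" else int(cfg.gwpca_k)
        if cfg.gwpca_bandwidth == "auto":
            kernel = select_bandwidth(Xstd, ds.coords, k, metric=cfg.gwpca_metric)
        elif cfg.gwpca_bandwidth == "adaptive":
            kernel = KernelSpec(
                max(k + 2, ds.n_samples // 2), metric=cfg.gwpca_metric,
                adaptive=True,
            )
        else:
            kernel = KernelSpec(float(cfg.gwpca_bandwidth), metric=cfg.gwpca_metric)
        gw = fit_gwpca(ds, k, kernel)
        record("gwpca", t, k=k, bandwidth=float(kernel.bandwidth),
               adaptive=kernel.adaptive, metric=kernel.metric)

        # ---- clustering ------------------------------------------------
        t = time.perf_counter()
        fcm_seed = stage_seed(cfg.seed, "fcm")
        fcm_kw = dict(
            fuzziness=cfg.fcm_fuzziness, max_iter=cfg.fcm_max_iter,
            tol=cfg.fcm_tol, restarts=cfg.fcm_restarts, seed=fcm_seed,
        )
        validity = None
        if cfg.fcm_c == "auto":
            validity = sweep_clusters(gw.scores, range(2, 11), **fcm_kw)
            fcm = validity.results[validity.chosen_c]
            chosen_c = validity.chosen_c
        else:
            chosen_c = int(cfg.fcm_c)
            fcm = fcm_fit(gw.scores, chosen_c, **fcm_kw)
        record("cluster", t, c=chosen_c, fpi=fcm.fpi, nce=fcm.nce,
               iterations=fcm.iterations)

        # ---- grouped calibration --------------------------------------
        reports: dict = {}
        group_sources = {}
        for grouping in cfg.groupings:
            if grouping == "cluster":
                group_sources[grouping] = np.array(
                    [f"Cluster{l + 1}" for l in fcm.labels], dtype=object)
            elif grouping == "stratum":
                if ds.strata is None:
                    continue
                group_sources[grouping] = ds.strata
            elif grouping == "none":
                group_sources[grouping] = None
            else:
                raise PipelineError(f"unknown grouping {grouping!r}")

        for model in cfg.models:
            t = time.perf_counter()
            reports[model] = {}
            params = cfg.model_params.get(model, {})
            for grouping, labels in group_sources.items():
                if labels is None:
                    gc = fit_global(
                        ds, model, model_params=params, ratio=cfg.split_ratio)
                else:
                    gc = fit_per_group(
                        ds, labels, model, model_params=params,
                        min_size=cfg.min_group_size, ratio=cfg.split_ratio,
                    )
                reports[model][grouping] = evaluate_grouped(gc)
            record(f"calibrate:{model}", t)

        manifest["wall_time_s"] = round(time.perf_counter() - t0, 3)
        metric_tables = {
            model: {
                grouping: rep.to_frame().to_dict(orient="records")
                for grouping, rep in by_group.items()
            }
            for model, by_group in reports.items()
        }
        manifest["reports"] = metric_tables

        # ---- artifacts -------------------------------------------------
        if outdir:
            pd.DataFrame(
                gw.scores, columns=[f"PC{i + 1}" for i in range(gw.k)]
            ).assign(id=ds.ids).to_csv(outdir / "scores.csv", index=False)
            mem = pd.DataFrame(
                fcm.U.T, columns=[f"mu_{i + 1}" for i in range(fcm.U.shape[0])]
            )
            mem.insert(0, "id", ds.ids)
            mem["label"] = fcm.labels
            mem.to_csv(outdir / "memberships.csv", index=False)
            if validity is not None:
                pd.DataFrame(
                    {"c": validity.c_values, "fpi": validity.fpi,
                     "nce": validity.nce}
                ).to_csv(outdir / "validity_curve.csv", index=False)
            for model, by_group in reports.items():
                for grouping, rep in by_group.items():
                    rep.to_frame().to_csv(
                        outdir / f"report_{grouping}_{model}.csv", index=False)
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=_json_default)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        if outdir:
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=_json_default)
        raise

    return RunResult(
        manifest=manifest,
        reports=reports,
        dataset=ds,
        scores=gw.scores,
        cluster_labels=fcm.labels,
        memberships=fcm.U,
    )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
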