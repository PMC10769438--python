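"""End-to-end orchestration: simulate/load -> extract -> analyze -> report.

A YAML config drives the run; every stage is a pure function of
(inputs, config, seed) and writes plain CSV/JSON artifacts into the
output directory.  Analysis-stage failures are logged and skipped so
earlier artifacts survive; the bundle records which stages failed.

Config schema (all keys optional unless noted)::

    seed: 1
    out_dir: results            # required for file output
    data:
      synthetic: true           # generate inputs instead of loading
      generator: {...}          # GeneratorConfig overrides
      tracks_dir: path/to/h5    # used when synthetic is false
      bite_table: path/to/bites.csv
      px_per_mm: 10.0           # calibration scale (per run/session)
    kinematics:
      smooth_window: 21         # odd frames; null disables smoothing
      max_gap: 5
    gam:
      responses: [length_mm, volume_mm3]
      shrinkage: false
    peaks:
      grid_resolution: 50
      prominence_frac: 0.05
    plots: false
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import BitescapeError, ValidationError
from .gam import candidate_models, fit_gam, select_models
from .io import (
    CalibrationScale,
    bite_table_frame,
    calibrate_track,
    load_bite_table,
    read_track,
)
from .kinematics import summarize_dataset
from .landscape import count_interior_peaks, predict_surface
from .mixed_effects import LMMSpec, compare_lmm, fit_lmm
from .multivariate import lda_classify, pca_correlation
from .synthetic import GeneratorConfig, SurfaceParams, generate_dataset, merge_kinematics_bites

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": None,
    "data": {"synthetic": True, "generator": {}, "px_per_mm": 10.0},
    "kinematics": {"smooth_window": 21, "max_gap": 5},
    "lmm": {"responses": ["g", "jp", "ja", "ttpg", "rs", "length_mm", "width_mm", "depth_mm"]},
    "gam": {"responses": ["length_mm", "volume_mm3"], "shrinkage": False},
    "peaks": {"grid_resolution": 50, "prominence_frac": 0.05},
    "plots": False,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        p = Path(path_or_dict)
        if not p.exists():
            raise ValidationError(f"config file not found: {p}")
        user = yaml.safe_load(p.read_text()) or {}
    return _merge(DEFAULT_CONFIG, user)


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d or {})
    if "surface" in d and not isinstance(d["surface"], SurfaceParams):
        s = dict(d["surface"])
        for key in ("centers", "widths"):
            if key in s:
                s[key] = tuple(tuple(x) for x in s[key])
        if "amplitudes" in s:
            s["amplitudes"] = tuple(s["amplitudes"])
        d["surface"] = SurfaceParams(**s)
    if "species" in d:
        d["species"] = tuple(d["species"])
    return GeneratorConfig(**d)


@dataclass
class ReportBundle:
    out_dir: Path | None
    kinematics: pd.DataFrame | None = None
    bites: pd.DataFrame | None = None
    merged: pd.DataFrame | None = None
    pca: object = None
    lda: dict = field(default_factory=dict)
    lmm_summaries: pd.DataFrame | None = None
    lmm_comparison: pd.DataFrame | None = None
    gam_tables: dict = field(default_factory=dict)
    best_fits: dict = field(default_factory=dict)
    surfaces: dict = field(default_factory=dict)
    peak_reports: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    failed_stages: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failed_stages


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def stage_simulate(config: dict, out_dir: Path | None):
    gen = generator_config_from_dict(config["data"].get("generator"))
    ds = generate_dataset(gen, seed=int(config["seed"]), out_dir=out_dir)
    return ds


def stage_extract(config: dict, tracks, px_per_mm: float) -> pd.DataFrame:
    scale = CalibrationScale(px_per_mm=px_per_mm)
    calibrated = (calibrate_track(t, scale) for t in tracks)
    kcfg = config["kinematics"]
    return summarize_dataset(
        calibrated,
        smooth_window=kcfg.get("smooth_window"),
        max_gap=int(kcfg.get("max_gap", 5)),
    )


def _load_tracks(tracks_dir: Path):
    paths = sorted(Path(tracks_dir).glob("*.h5"))
    if not paths:
        raise FileNotFoundError(f"no .h5 tracks found in {tracks_dir}")
    return [read_track(p) for p in paths]


def run_pipeline(config_path_or_dict, seed: int | None = None) -> ReportBundle:
    """Run every stage in order; see the module docstring for the config."""
    config = load_config(config_path_or_dict)
    if seed is not None:
        config["seed"] = int(seed)
    out_dir = Path(config["out_dir"]) if config.get("out_dir") else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out_dir)
    t_start = time.time()

    # ---- inputs -----------------------------------------------------
    data_cfg = config["data"]
    if data_cfg.get("synthetic", False):
        ds = stage_simulate(config, out_dir / "synthetic" if out_dir else None)
        tracks = ds.tracks
        bites = bite_table_frame(ds.bites)
        px_per_mm = ds.config.px_per_mm
    else:
        tracks_dir = data_cfg.get("tracks_dir")
        bite_path = data_cfg.get("bite_table")
        if not tracks_dir or not Path(tracks_dir).exists():
            raise FileNotFoundError(f"tracks directory not found: {tracks_dir}")
        if not bite_path or not Path(bite_path).exists():
            raise FileNotFoundError(f"bite table not found: {bite_path}")
        tracks = _load_tracks(tracks_dir)
        bites = bite_table_frame(load_bite_table(bite_path))
        px_per_mm = float(data_cfg.get("px_per_mm", 10.0))
    bundle.bites = bites
    log.info("inputs ready: %d tracks, %d bite rows", len(tracks), len(bites))

    # ---- extraction -------------------------------------------------
    t0 = time.time()
    kin = stage_extract(config, tracks, px_per_mm)
    bundle.kinematics = kin
    merged = merge_kinematics_bites(kin, bites)
    bundle.merged = merged
    log.info("extracted kinematics for %d strikes in %.1fs", len(kin), time.time() - t0)
    if out_dir:
        kin.to_csv(out_dir / "kinematics.csv", index=False)
        merged.to_csv(out_dir / "strikes_with_bites.csv", index=False)

    def _analysis(name, fn):
        t1 = time.time()
        try:
            fn()
            log.info("stage %s done in %.1fs", name, time.time() - t1)
        except Exception as exc:  # noqa: BLE001 - keep earlier outputs
            log.error("stage %s failed: %s", name, exc)
            bundle.failed_stages.append({"stage": name, "error": str(exc)})

    # ---- multivariate -----------------------------------------------
    def _multivariate():
        pca = pca_correlation(kin)
        bundle.pca = pca
        for grouping in ("species", "strike_type"):
            bundle.lda[grouping] = lda_classify(kin, grouping)
        if out_dir:
            pca.loadings.to_csv(out_dir / "pca_loadings.csv")
            pd.DataFrame(
                {"variance_fraction": pca.variance_fraction},
                index=pca.loadings.columns,
            ).to_csv(out_dir / "pca_variance.csv")
            for grouping, res in bundle.lda.items():
                res.confusion.to_csv(out_dir / f"lda_confusion_{grouping}.csv")

    _analysis("multivariate", _multivariate)

    # ---- mixed models -----------------------------------------------
    def _lmm():
        rows = []
        for resp in config["lmm"]["responses"]:
            if resp not in merged.columns:
                continue
            try:
                res = fit_lmm(LMMSpec(response=resp), merged)
            except BitescapeError as exc:
                log.warning("mixed model for %s skipped: %s", resp, exc)
                rows.append(
                    pd.DataFrame([{"response": resp, "term": "", "error": str(exc)}])
                )
                continue
            fe = res.fixed_effects.reset_index(names="term")
            fe.insert(0, "response", resp)
            fe["re_variance"] = res.random_intercept_variance
            fe["resid_variance"] = res.residual_variance
            fe["aic"] = res.aic
            rows.append(fe)
        bundle.lmm_summaries = (
            pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        )
        if "length_mm" in config["lmm"]["responses"] and "length_mm" in merged.columns:
            base = LMMSpec(response="length_mm")
            bundle.lmm_comparison = compare_lmm(
                [
                    base,
                    LMMSpec(
                        response="length_mm",
                        interactions=(("species", "strike_type"),),
                    ),
                    LMMSpec(response="length_mm", random_slopes=("g",)),
                ],
                merged,
            )
        if out_dir:
            bundle.lmm_summaries.to_csv(out_dir / "lmm_summaries.csv", index=False)
            if bundle.lmm_comparison is not None:
                bundle.lmm_comparison.to_csv(out_dir / "lmm_comparison.csv", index=False)

    _analysis("lmm", _lmm)

    # ---- GAM selection + surfaces + peaks ---------------------------
    def _gam():
        for resp in config["gam"]["responses"]:
            if resp not in merged.columns:
                continue
            cands = candidate_models(resp, shrinkage=bool(config["gam"].get("shrinkage")))
            table = select_models(cands, merged)
            bundle.gam_tables[resp] = table
            fits = table.attrs["fits"]
            best = None
            for f in fits:
                if f is not None and f.bivariate_smooth is not None:
                    if best is None or f.aic < best.aic:
                        best = f
            bundle.best_fits[resp] = best
            if out_dir:
                table.drop(columns=[], errors="ignore").to_csv(
                    out_dir / f"gam_model_table_{resp}.csv", index=False
                )

    _analysis("gam", _gam)

    def _peaks():
        pk_cfg = config["peaks"]
        for resp, best in bundle.best_fits.items():
            if best is None:
                continue
            surface = predict_surface(
                best, grid_resolution=int(pk_cfg.get("grid_resolution", 50))
            )
            report = count_interior_peaks(
                surface, prominence_frac=float(pk_cfg.get("prominence_frac", 0.05))
            )
            bundle.surfaces[resp] = surface
            bundle.peak_reports[resp] = report
            if out_dir:
                surface.to_frame().to_csv(out_dir / f"surface_{resp}.csv", index=False)
                (out_dir / f"peaks_{resp}.json").write_text(
                    json.dumps(
                        {
                            "count": report.count,
                            "prominence_threshold": report.prominence_threshold,
                            "peaks": [dataclasses.asdict(p) for p in report.peaks],
                        },
                        indent=2,
                    )
                )
                if config.get("plots"):
                    _plot_surface(surface, out_dir / f"surface_{resp}.png")

    _analysis("peaks", _peaks)

    bundle.manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config["seed"],
        "config_hash": _config_hash(config),
        "n_tracks": len(tracks),
        "n_strikes_extracted": len(kin),
        "failed_stages": bundle.failed_stages,
        "elapsed_s": round(time.time() - t_start, 2),
    }
    if out_dir:
        (out_dir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
    return bundle


def _plot_surface(surface, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.where(surface.hull_mask, surface.values, np.nan)
    fig, ax = plt.subplots(figsize=(5, 4))
    m = ax.pcolormesh(surface.g_grid, surface.jp_grid, vals.T, shading="auto")
    fig.colorbar(m, ax=ax, label=surface.response)
    ax.set_xlabel("peak gape (mm)")
    ax.set_ylabel("peak jaw protrusion (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
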