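"""End-to-end orchestration of the mapping workflow.

A run takes a survey CSV through: scale decision -> empirical variograms
(three estimators) -> weighted-least-squares exponential fits -> LOO
cross-validation and model selection -> ordinary kriging on a grid ->
kriging-variance masking -> percent-of-EAR surface with quartile classes,
with optional block kriging over GeoJSON polygons and an optional
biomarker spatial-LMM stage. Every stage's decisions and outputs are
serialized into the run directory so the run is reproducible from the
config and seed alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dietary import IntakeEarTable, percent_ear_for, quartile_classes
from .exploratory import choose_scale
from .io import (read_grid_csv, read_polygons_geojson, read_survey_csv,
                 write_grid_csv, write_polygons_geojson)
from .kriging import block_krige, krige_grid, select_model, variance_mask
from .lmm import SpatialLMM, lrt_fixed_effect
from .variogram import ESTIMATORS, empirical_variogram, fit_exponential_wls

log = logging.getLogger("geograin")


@dataclass
class RunConfig:
    """Settings for one pipeline run; serializable to/from YAML."""

    survey_csv: str
    out_dir: str
    grid_csv: str | None = None
    grid_spacing_km: float = 5.0
    element: str = "Zn"
    crop: str = "maize"
    scale_override: str | None = None     # "original" | "log_e"
    max_lag_km: float = 100.0
    bin_width_km: float = 10.0
    estimators: tuple = tuple(ESTIMATORS)
    neighborhood: int | None = None
    mask_fraction: float = 0.75
    blocks_geojson: str | None = None
    block_spacing_km: float = 1.0
    biomarker_csv: str | None = None
    lmm_method: str = "REML"
    nu_grid: tuple = (0.25, 0.5, 1.0, 2.0)
    fdr_q: float = 0.05
    intake_ear_yaml: str | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("grid_spacing_km", "max_lag_km", "bin_width_km",
                     "mask_fraction", "block_spacing_km", "fdr_q"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["estimators"] = tuple(raw.get("estimators", ESTIMATORS))
        raw["nu_grid"] = tuple(raw.get("nu_grid", (0.25, 0.5, 1.0, 2.0)))
        return cls(**raw)

    def validate_paths(self) -> None:
        for p in (self.survey_csv, self.grid_csv, self.blocks_geojson,
                  self.biomarker_csv, self.intake_ear_yaml):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _default_grid(survey: pd.DataFrame, spacing_km: float) -> pd.DataFrame:
    lat_mid = float(survey["lat"].mean())
    dlat = spacing_km / 111.195
    dlon = spacing_km / (111.195 * max(np.cos(np.radians(lat_mid)), 1e-6))
    xs = np.arange(survey["lon"].min(), survey["lon"].max() + dlon / 2, dlon)
    ys = np.arange(survey["lat"].min(), survey["lat"].max() + dlat / 2, dlat)
    gx, gy = np.meshgrid(xs, ys)
    return pd.DataFrame({"lon": gx.ravel(), "lat": gy.ravel()})


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    meta: dict = {"config": {**asdict(config),
                             "estimators": list(config.estimators),
                             "nu_grid": list(config.nu_grid)},
                  "version": __version__}
    stage = "read_survey"
    try:
        survey = read_survey_csv(config.survey_csv)
        log.info("read %d survey rows from %s", len(survey), config.survey_csv)

        stage = "choose_scale"
        if config.scale_override:
            scale = config.scale_override
            meta["scale_decision"] = {"scale": scale, "override": True}
        else:
            dec = choose_scale(survey["value"].to_numpy())
            scale = dec.scale
            meta["scale_decision"] = dec.to_dict()
        work = survey.copy()
        if scale == "log_e":
            work["value"] = np.log(work["value"])
        work.attrs["scale"] = scale
        log.info("analysis scale: %s", scale)

        stage = "variogram"
        candidates = {}
        for est in config.estimators:
            emp = empirical_variogram(work, config.max_lag_km,
                                      config.bin_width_km, estimator=est)
            fit = fit_exponential_wls(emp)
            candidates[est] = fit.model
            write_grid_csv(out / f"variogram_{est}.csv", emp.to_frame())
            (out / f"model_{est}.yaml").write_text(yaml.safe_dump(fit.to_dict()))
            log.info("fitted %s: %s", est, fit.to_dict())

        stage = "cross_validate/select_model"
        sel = select_model(work, candidates)
        meta["model_selection"] = {
            "estimator": sel.estimator, "model": sel.model.to_dict(),
            "rationale": sel.rationale, "warning": sel.warning,
            "reports": {k: v.to_dict() for k, v in sel.reports.items()}}
        log.info("selected %s model (%s)", sel.estimator, sel.rationale)

        stage = "krige_grid"
        grid = (read_grid_csv(config.grid_csv) if config.grid_csv
                else _default_grid(survey, config.grid_spacing_km))
        gmap = krige_grid(work, sel.model, grid, scale=scale,
                          neighborhood=config.neighborhood)

        stage = "variance_mask"
        data_var = float(np.var(work["value"].to_numpy(), ddof=1))
        gmap["masked"] = variance_mask(gmap["variance"].to_numpy(), data_var,
                                       config.mask_fraction)
        write_grid_csv(out / "grid_predictions.csv", gmap)

        stage = "dietary"
        table = (IntakeEarTable.from_yaml(config.intake_ear_yaml)
                 if config.intake_ear_yaml else IntakeEarTable())
        dmap = gmap[["lon", "lat", "masked"]].copy()
        dmap["percent_ear"] = percent_ear_for(table, config.crop, config.element,
                                              gmap["prediction"].to_numpy())
        dmap["quartile_class"] = quartile_classes(dmap["percent_ear"].to_numpy(),
                                                  dmap["masked"].to_numpy())
        write_grid_csv(out / "dietary_percent_ear.csv", dmap)

        if config.blocks_geojson:
            stage = "block_krige"
            feats = read_polygons_geojson(config.blocks_geojson)
            out_feats = []
            for props, geom in feats:
                res = block_krige(work, sel.model, geom,
                                  spacing_km=config.block_spacing_km)
                props = dict(props)
                props.update(block_prediction=res.prediction,
                             block_variance=res.variance, scale=scale)
                out_feats.append((props, geom))
            write_polygons_geojson(out / "block_predictions.geojson", out_feats)
            log.info("block-kriged %d polygons", len(out_feats))

        if config.biomarker_csv:
            stage = "lmm"
            ea = pd.read_csv(config.biomarker_csv)
            from .lmm import nearest_grain_link
            linked = nearest_grain_link(ea, survey)
            null_fit = SpatialLMM.from_dataframe(
                linked, "log_biomarker", [], ).fit(method="ML",
                                                   nu_grid=config.nu_grid)
            full_fit = SpatialLMM.from_dataframe(
                linked, "log_biomarker", ["grain_value"]).fit(
                method="ML", nu_grid=config.nu_grid)
            L, p = lrt_fixed_effect(full_fit, null_fit)
            report_fit = (full_fit if config.lmm_method == "ML" else
                          SpatialLMM.from_dataframe(
                              linked, "log_biomarker", ["grain_value"]).fit(
                              method="REML", nu_grid=config.nu_grid))
            meta["lmm"] = {"fit": report_fit.to_dict(), "L": float(L),
                           "p": float(p),
                           "median_link_km": linked.attrs["median_distance_km"]}
            (out / "lmm_fit.yaml").write_text(yaml.safe_dump(meta["lmm"]))
            log.info("biomarker LMM: slope %.4g (L=%.3f, p=%.3g)",
                     report_fit.params[1], L, p)
        else:
            log.info("no biomarker table configured; skipping LMM stages")
    except Exception:
        meta["failed_stage"] = stage
        (out / "run_metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
        log.exception("pipeline failed at stage %s", stage)
        log.removeHandler(fh)
        fh.close()
        raise
    (out / "run_metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    log.removeHandler(fh)
    fh.close()
    return out
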