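"""End-to-end orchestration: simulate -> extract -> screen -> fit ->
evaluate -> report.

The candidate feature table carries exactly 107 predictors per plot:

* 61 point-cloud metrics plus the detected-tree summaries H and W
  (the detected stem count N is computed but, following the original
  variable inventory, not a candidate predictor),
* 17 visible vegetation indices,
* 24 co-occurrence texture features (3 bands x 8 statistics),
* the terrain factors ``h`` (altitude) and ``slope``, and the plot ``area``.

Column names are frozen: vegetation indices by their abbreviations,
textures as ``<band>_<feature>``, metrics as ``H_*`` / ``I_*``.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, evaluation, geostat
from .learners import DEFAULT_CONFIGS, LearnerConfig, feature_importance, fit as fit_learner
from .lidar import METRIC_NAMES, detect_trees, normalize_heights, plot_metrics, rasterize_chm
from .optical import GLCMConfig, GLCM_FEATURE_NAMES, VI_NAMES, glcm_features, \
    terrain_factors, vegetation_indices
from .screening import screen_features
from .synthetic import Landscape, LandscapeConfig, simulate

__all__ = ["PREDICTOR_COLUMNS", "RunConfig", "build_feature_table",
           "predictor_columns", "residual_variogram_table", "run"]

logger = logging.getLogger(__name__)

_BANDS = ("R", "G", "B")
TEXTURE_COLUMNS = [f"{b}_{f}" for b in _BANDS for f in GLCM_FEATURE_NAMES]
#: the frozen 107-column candidate-predictor contract
PREDICTOR_COLUMNS = (list(METRIC_NAMES) + ["H", "W"] + list(VI_NAMES)
                     + TEXTURE_COLUMNS + ["h", "slope", "area"])
_META_COLUMNS = ("M", "center_x", "center_y")


def predictor_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLUMNS]


def build_feature_table(landscape: Landscape, cutoff_m: float = 2.0,
                        chm_pixel_m: float = 0.5,
                        glcm_config: GLCMConfig = GLCMConfig()) -> pd.DataFrame:
    """Per-plot candidate predictors plus the response M and coordinates."""
    rows = []
    for plot in landscape.plots:
        row: dict[str, float] = {}
        cloud = landscape.clouds[plot.plot_id]
        norm = normalize_heights(cloud, landscape.dem)
        row.update(plot_metrics(norm, cutoff_m))
        chm = rasterize_chm(norm, chm_pixel_m)
        _, H, W = detect_trees(chm, min_height_m=cutoff_m)
        row["H"] = H
        row["W"] = W
        tile = landscape.tiles[plot.plot_id]
        row.update(vegetation_indices(tile))
        for bi, bname in enumerate(_BANDS):
            feats = glcm_features(tile.band(bi), glcm_config)
            row.update({f"{bname}_{k}": v for k, v in feats.items()})
        alt, slope = terrain_factors(landscape.dem, plot.center_xy_m)
        row["h"] = alt
        row["slope"] = slope
        row["area"] = plot.area_ha
        row["M"] = plot.response_m3ha
        row["center_x"] = plot.center_xy_m[0]
        row["center_y"] = plot.center_xy_m[1]
        rows.append(pd.Series(row, name=plot.plot_id))
    table = pd.DataFrame(rows)
    table.index.name = "plot_id"
    return table[PREDICTOR_COLUMNS + list(_META_COLUMNS)]


def residual_variogram_table(table: pd.DataFrame, locations_km: np.ndarray,
                             configs: dict[str, LearnerConfig] | None = None,
                             response: str = "M", threshold: float = 0.4,
                             alpha: float = 0.05, seed: int = 0, n_bins: int = 12
                             ) -> tuple[pd.DataFrame, pd.Series]:
    """Fit each base learner on all plots and model its residual variogram.

    Returns the variogram summary (one row per base, mirroring the report
    columns model family / range / nugget / partial sill / sill effect) and
    the forest's feature-importance ranking.
    """
    configs = {**DEFAULT_CONFIGS, **(configs or {})}
    _, reduced = screen_features(table[predictor_columns(table) + [response]],
                                 response, threshold, alpha)
    feat_cols = [c for c in reduced.columns if c != response]
    X = table[feat_cols]
    y = table[response].to_numpy(dtype=float)
    rows = []
    importance = None
    for kind in ("rf", "svr", "ann"):
        base = fit_learner(configs[kind].with_seed(seed), X, y)
        if kind == "rf":
            importance = feature_importance(base)
        hm = geostat.hybrid_fit(base, X, y, locations_km, n_bins=n_bins)
        vg = hm.variogram
        rows.append({"residual": f"R_{kind.upper()}",
                     "model": vg.family.capitalize(),
                     "range_km": vg.range_km, "nugget": vg.nugget,
                     "partial_sill": vg.partial_sill,
                     "sill_effect": vg.sill_effect if vg.sill > 0 else float("nan")})
    return pd.DataFrame(rows), importance


_KNOWN_TOP_KEYS = {"simulate", "screening", "learners", "evaluation", "geostat",
                   "output_dir", "seed"}


@dataclass
class RunConfig:
    simulate: LandscapeConfig = field(default_factory=LandscapeConfig)
    screening: dict = field(default_factory=lambda: {"threshold": 0.4, "alpha": 0.05})
    learners: dict[str, LearnerConfig] = field(default_factory=dict)
    evaluation: dict = field(default_factory=lambda: {
        "models": ["rf", "svr", "ann", "rfk", "svrk", "annk"],
        "screen_in_fold": True})
    geostat: dict = field(default_factory=lambda: {"n_bins": 12})
    output_dir: str = "forestvol_run"
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "output_dir" in raw:
            cfg.output_dir = str(raw["output_dir"])
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            known = set(LandscapeConfig.__dataclass_fields__)
            bad = set(sim) - known
            if bad:
                raise ValueError(f"unknown simulate key(s): {sorted(bad)}")
            if "residual_variogram" in sim:
                sim["residual_variogram"] = geostat.VariogramModel(**sim["residual_variogram"])
            for tup in ("area_range_ha", "elev_range_m", "slope_range_deg",
                        "stems_per_ha_range"):
                if tup in sim:
                    sim[tup] = tuple(sim[tup])
            cfg.simulate = LandscapeConfig(**sim)
        for block in ("screening", "evaluation", "geostat"):
            if block in raw:
                base = dict(getattr(cfg, block))
                bad = set(raw[block]) - set(base)
                if bad:
                    raise ValueError(f"unknown {block} key(s): {sorted(bad)}")
                base.update(raw[block])
                setattr(cfg, block, base)
        if "learners" in raw:
            for kind, overrides in raw["learners"].items():
                if kind not in DEFAULT_CONFIGS:
                    raise ValueError(f"unknown learner {kind!r}")
                known = set(LearnerConfig.__dataclass_fields__) - {"kind"}
                bad = set(overrides) - known
                if bad:
                    raise ValueError(f"unknown {kind} key(s): {sorted(bad)}")
                from dataclasses import replace
                cfg.learners[kind] = replace(DEFAULT_CONFIGS[kind], **overrides)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)


def run(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write all artifacts; returns their paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    from dataclasses import replace
    sim_cfg = replace(config.simulate, seed=config.seed)
    logger.info("stage simulate: %d plots, seed %d", sim_cfg.n_plots, config.seed)
    landscape = simulate(sim_cfg)

    logger.info("stage features")
    table = build_feature_table(landscape)
    artifacts["features"] = out / "features.csv"
    table.to_csv(artifacts["features"])

    logger.info("stage screen")
    scr = config.screening
    report_df, _ = screen_features(table[predictor_columns(table) + ["M"]], "M",
                                   scr["threshold"], scr["alpha"])
    artifacts["screening"] = out / "screening.csv"
    report_df.to_csv(artifacts["screening"], index=False)

    locations_km = table[["center_x", "center_y"]].to_numpy() / 1000.0

    logger.info("stage fit + residual variograms")
    vg_table, importance = residual_variogram_table(
        table, locations_km, configs=config.learners,
        threshold=scr["threshold"], alpha=scr["alpha"], seed=config.seed,
        n_bins=config.geostat["n_bins"])
    artifacts["variograms"] = out / "residual_variograms.csv"
    vg_table.to_csv(artifacts["variograms"], index=False)

    logger.info("stage evaluate (leave-one-out)")
    ev = config.evaluation
    cv = evaluation.loo_cv(table[predictor_columns(table) + ["M"]], locations_km,
                           models=tuple(ev["models"]), configs=config.learners,
                           threshold=scr["threshold"], alpha=scr["alpha"],
                           screen_in_fold=ev["screen_in_fold"], seed=config.seed,
                           variogram_bins=config.geostat["n_bins"])
    paths = evaluation.report(cv, out, importance=importance)
    artifacts.update(paths)

    manifest = {
        "forestvol_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_plots": sim_cfg.n_plots,
        "n_candidate_predictors": len(predictor_columns(table)),
        "models": list(ev["models"]),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    artifacts["manifest"] = out / "run_manifest.json"
    artifacts["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("run complete: %s", out)
    return artifacts
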