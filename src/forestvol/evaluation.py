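"""Leave-one-out cross-validation of the base and hybrid models.

Each plot in turn is held out; screening, the base learner fit, its
training residuals and the residual variogram are all recomputed on the
remaining n-1 plots, and the held-out plot is predicted (base prediction
plus, for hybrids, the kriged residual at its location).  Accuracy is
pooled over the n held-out predictions:

    MAE  = mean |O - P|
    RMSE = sqrt(mean (O - P)^2)
    R^2  = 1 - sum (O - P)^2 / sum (O - Obar)^2

(The per-fold averaging form of these metrics is degenerate under
leave-one-out — each fold holds a single observation, so a per-fold R^2
denominator is zero — and pooling is the standard convention; with one
observation per fold the pooled MAE equals the fold-mean MAE anyway.)

The improvement statistic of a hybrid over its base is
(RMSE_base - RMSE_hybrid) / RMSE_base * 100, in percent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geostat
from .learners import DEFAULT_CONFIGS, LearnerConfig, fit as fit_learner, \
    predict as predict_learner
from .screening import screen_features

__all__ = ["CVReport", "metrics", "improvement", "loo_cv", "report"]

logger = logging.getLogger(__name__)

BASE_MODELS = ("rf", "svr", "ann")
HYBRID_OF = {"rfk": "rf", "svrk": "svr", "annk": "ann"}


def metrics(observed, predicted) -> tuple[float, float, float]:
    """(MAE, RMSE, R^2) of predictions against observations."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(o) != len(p):
        raise ValueError("length mismatch")
    if not (np.isfinite(o).all() and np.isfinite(p).all()):
        raise ValueError("non-finite values in observed/predicted")
    err = o - p
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: zero variance in observations")
    r2 = 1.0 - float(np.sum(err ** 2)) / ss_tot
    return mae, rmse, r2


def improvement(rmse_base: float, rmse_hybrid: float) -> float:
    """Percentage RMSE improvement of a hybrid over its base, 2 dp."""
    if rmse_base <= 0:
        raise ValueError("base RMSE must be positive")
    return round((rmse_base - rmse_hybrid) / rmse_base * 100.0, 2)


@dataclass
class CVReport:
    models: list[str]
    mae: dict[str, float]
    rmse: dict[str, float]
    r2: dict[str, float]
    predictions: pd.DataFrame               # index plot_id, columns observed + models
    improvement_pct: dict[str, float] = field(default_factory=dict)
    delta_r2: dict[str, float] = field(default_factory=dict)
    variogram_fallbacks: dict[str, int] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            rows.append({
                "model": m.upper(),
                "MAE_loo": self.mae[m],
                "RMSE_loo": self.rmse[m],
                "R2_loo": self.r2[m],
                "delta_R2": self.delta_r2.get(m, float("nan")),
                "improvement_pct": self.improvement_pct.get(m, float("nan")),
            })
        return pd.DataFrame(rows)


def loo_cv(table: pd.DataFrame, locations_km: np.ndarray,
           models=("rf", "svr", "ann", "rfk", "svrk", "annk"),
           configs: dict[str, LearnerConfig] | None = None,
           response: str = "M", threshold: float = 0.4, alpha: float = 0.05,
           screen_in_fold: bool = True, seed: int = 0,
           variogram_bins: int = 12) -> CVReport:
    """Leave-one-out evaluation of the requested base and hybrid models.

    ``table`` holds predictor columns plus the response; ``locations_km``
    is (n, 2).  Hybrids reuse their base learner's fold fit.  When a fold's
    residual variogram cannot be fitted the hybrid falls back to the base
    prediction for that fold (counted in ``variogram_fallbacks``).
    ``screen_in_fold=False`` screens once on the full table instead
    (the likely historical practice; the honest default screens per fold).
    """
    n = len(table)
    if n < 10:
        raise ValueError("leave-one-out evaluation needs at least 10 plots")
    locations_km = np.asarray(locations_km, dtype=float)
    if locations_km.shape != (n, 2):
        raise ValueError("locations_km must be (n, 2)")
    configs = {**DEFAULT_CONFIGS, **(configs or {})}
    bases_needed = sorted({m for m in models if m in BASE_MODELS}
                          | {HYBRID_OF[m] for m in models if m in HYBRID_OF})
    unknown = [m for m in models if m not in BASE_MODELS and m not in HYBRID_OF]
    if unknown:
        raise ValueError(f"unknown model(s) {unknown}")

    obs = table[response].to_numpy(dtype=float)
    preds = {m: np.full(n, np.nan) for m in models}
    fallbacks = {m: 0 for m in models if m in HYBRID_OF}

    global_reduced = None
    if not screen_in_fold:
        _, global_reduced = screen_features(table, response, threshold, alpha)

    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        fold_table = (global_reduced if global_reduced is not None else table)
        if screen_in_fold:
            _, fold_reduced = screen_features(table.iloc[train_idx], response,
                                              threshold, alpha)
            feat_cols = [c for c in fold_reduced.columns if c != response]
        else:
            feat_cols = [c for c in fold_table.columns if c != response]
        X_train = table.iloc[train_idx][feat_cols]
        y_train = obs[train_idx]
        X_test = table.iloc[[i]][feat_cols]
        loc_train = locations_km[train_idx]
        loc_test = locations_km[[i]]

        for b in bases_needed:
            cfg = configs[b].with_seed(seed * 10007 + i)
            base = fit_learner(cfg, X_train, y_train)
            p_test = float(predict_learner(base, X_test)[0])
            if b in preds:
                preds[b][i] = p_test
            hyb = next((h for h, bb in HYBRID_OF.items()
                        if bb == b and h in preds), None)
            if hyb is not None:
                try:
                    hm = geostat.hybrid_fit(base, X_train, y_train, loc_train,
                                            n_bins=variogram_bins)
                    kriged, _ = geostat.ok_predict(hm.variogram,
                                                   hm.train_locations_km,
                                                   hm.train_residuals, loc_test)
                    preds[hyb][i] = p_test + float(kriged[0])
                except Exception as exc:
                    logger.warning("fold %d: residual variogram failed (%s); "
                                   "hybrid %s falls back to base", i, exc, hyb)
                    fallbacks[hyb] += 1
                    preds[hyb][i] = p_test

    mae, rmse, r2 = {}, {}, {}
    for m in models:
        mae[m], rmse[m], r2[m] = metrics(obs, preds[m])
    imp, dr2 = {}, {}
    for h, b in HYBRID_OF.items():
        if h in rmse and b in rmse:
            imp[h] = improvement(rmse[b], rmse[h])
            dr2[h] = round(r2[h] - r2[b], 2)
    pred_df = pd.DataFrame({"observed": obs, **{m: preds[m] for m in models}},
                           index=table.index)
    return CVReport(models=list(models), mae=mae, rmse=rmse, r2=r2,
                    predictions=pred_df, improvement_pct=imp, delta_r2=dr2,
                    variogram_fallbacks=fallbacks)


def report(cv: CVReport, path: str | Path,
           importance: pd.Series | None = None) -> dict[str, Path]:
    """Write the CV report: accuracy CSV + JSON, per-plot scatter data, and
    (optionally) the forest's importance ranking."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    tbl = cv.table()
    out["accuracy_csv"] = path / "cv_accuracy.csv"
    tbl.to_csv(out["accuracy_csv"], index=False)
    out["scatter_csv"] = path / "cv_predictions.csv"
    cv.predictions.to_csv(out["scatter_csv"])
    payload = {
        "models": cv.models,
        "mae": cv.mae, "rmse": cv.rmse, "r2": cv.r2,
        "improvement_pct": cv.improvement_pct, "delta_r2": cv.delta_r2,
        "variogram_fallbacks": cv.variogram_fallbacks,
        "note": "pooled leave-one-out metrics over all held-out plots",
    }
    out["accuracy_json"] = path / "cv_accuracy.json"
    out["accuracy_json"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    if importance is not None:
        out["importance_csv"] = path / "rf_importance.csv"
        importance.rename("importance").to_csv(out["importance_csv"],
                                               index_label="feature")
    return out
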