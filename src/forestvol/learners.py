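"""The three base regressors behind a uniform fit/predict contract.

Hyperparameters default to the study configuration: a 500-tree random
forest (max depth 8, min split 5, min leaf 2, up to 58 features per split,
bootstrapped), an RBF support-vector regressor with C = 150 and
gamma = 0.001, and a two-hidden-layer (50, 50) relu network trained with
Adam at learning rate 0.01 for up to 1000 epochs with early-stopping
patience 20.  Solver internals are delegated to scikit-learn; this module
owns configuration, standardization and the contract.

SVR and the network are fitted on z-scored features AND a z-scored
response, with predictions transformed back to m^3/ha (the RBF kernel,
the epsilon tube and Adam all assume comparable scales; an unscaled
response in the hundreds leaves Adam at learning rate 0.01 hopelessly far
from the output bias it needs).  The forest sees raw features and the raw
response.  Test-time standardization reuses the training statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

__all__ = ["LearnerConfig", "FittedLearner", "standardize", "fit", "predict",
           "feature_importance", "DEFAULT_CONFIGS"]

logger = logging.getLogger(__name__)

Kind = Literal["rf", "svr", "ann"]


@dataclass(frozen=True)
class LearnerConfig:
    kind: Kind
    seed: int = 0
    # random forest
    n_trees: int = 500
    max_features: int = 58
    min_split: int = 5
    min_leaf: int = 2
    max_depth: int = 8
    bootstrap: bool = True
    # SVR
    C: float = 150.0
    gamma: float = 0.001
    # ANN
    hidden_layers: tuple[int, int] = (50, 50)
    learning_rate: float = 0.01
    max_epochs: int = 1000
    patience: int = 20
    validation_fraction: float = 0.1

    def with_seed(self, seed: int) -> "LearnerConfig":
        return replace(self, seed=seed)


DEFAULT_CONFIGS: dict[str, LearnerConfig] = {
    "rf": LearnerConfig("rf"),
    "svr": LearnerConfig("svr"),
    "ann": LearnerConfig("ann"),
}


@dataclass
class FittedLearner:
    config: LearnerConfig
    model: object
    feature_names: list[str]
    scaler_mean: pd.Series | None = field(default=None, repr=False)
    scaler_sd: pd.Series | None = field(default=None, repr=False)
    response_mean: float = 0.0
    response_sd: float = 1.0


def standardize(table: pd.DataFrame, stats: tuple[pd.Series, pd.Series] | None = None
                ) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """Z-score each column; constant columns pass through unchanged.

    When ``stats = (mean, sd)`` is given (test time), those statistics are
    reused instead of recomputed so the training transform is reproduced.
    """
    if stats is None:
        mean = table.mean()
        sd = table.std(ddof=0)
        const = sd == 0
        if const.any():
            logger.warning("constant columns passed through unstandardized: %s",
                           list(table.columns[const]))
        sd = sd.where(~const, 1.0)
        mean = mean.where(~const, 0.0)
        stats = (mean, sd)
    mean, sd = stats
    return (table - mean) / sd, stats


def _validate_features(features: pd.DataFrame) -> None:
    bad = features.columns[~np.isfinite(features.to_numpy(dtype=float)).all(axis=0)]
    if len(bad):
        raise ValueError(f"non-finite values in feature column(s) {list(bad)}")


def fit(config: LearnerConfig, features: pd.DataFrame, response) -> FittedLearner:
    """Fit one base learner; deterministic for a fixed config seed."""
    response = np.asarray(response, dtype=float)
    if len(features) < 5:
        raise ValueError("need at least 5 training rows")
    if len(features) != len(response):
        raise ValueError("features and response length mismatch")
    _validate_features(features)
    if not np.isfinite(response).all():
        raise ValueError("non-finite values in response")

    names = list(features.columns)
    scaler_mean = scaler_sd = None
    y_mean, y_sd = 0.0, 1.0
    if config.kind == "rf":
        max_feat = config.max_features
        if max_feat > len(names):
            logger.debug("max_features %d exceeds %d available predictors; clamped",
                         max_feat, len(names))
            max_feat = len(names)
        model = RandomForestRegressor(
            n_estimators=config.n_trees, max_features=max_feat,
            min_samples_split=config.min_split, min_samples_leaf=config.min_leaf,
            max_depth=config.max_depth, bootstrap=config.bootstrap,
            random_state=config.seed)
        X = features.to_numpy(dtype=float)
    elif config.kind == "svr":
        model = SVR(kernel="rbf", C=config.C, gamma=config.gamma)
        Xdf, (scaler_mean, scaler_sd) = standardize(features)
        X = Xdf.to_numpy(dtype=float)
    elif config.kind == "ann":
        # early stopping needs a validation split; below 10 rows train in full
        early = len(features) >= 10
        model = MLPRegressor(
            hidden_layer_sizes=config.hidden_layers, activation="relu",
            solver="adam", learning_rate_init=config.learning_rate,
            max_iter=config.max_epochs, early_stopping=early,
            validation_fraction=config.validation_fraction,
            n_iter_no_change=config.patience, random_state=config.seed)
        Xdf, (scaler_mean, scaler_sd) = standardize(features)
        X = Xdf.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown learner kind {config.kind!r}")
    y = response
    if config.kind in ("svr", "ann"):
        y_mean = float(response.mean())
        sd = float(response.std())
        y_sd = sd if sd > 0 else 1.0
        y = (response - y_mean) / y_sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        model.fit(X, y)
    return FittedLearner(config, model, names, scaler_mean, scaler_sd,
                         response_mean=y_mean, response_sd=y_sd)


def predict(learner: FittedLearner, features: pd.DataFrame) -> np.ndarray:
    """Predict m^3/ha; features must match training names and order."""
    if list(features.columns) != learner.feature_names:
        raise ValueError("feature names/order differ from the training table")
    _validate_features(features)
    if learner.scaler_mean is not None:
        features, _ = standardize(features, (learner.scaler_mean, learner.scaler_sd))
    raw = np.asarray(learner.model.predict(features.to_numpy(dtype=float)), dtype=float)
    return raw * learner.response_sd + learner.response_mean


def feature_importance(learner: FittedLearner) -> pd.Series:
    """Impurity-based importances of a fitted forest, sorted descending."""
    if learner.config.kind != "rf":
        raise ValueError("feature importance is only available for the random forest")
    scores = pd.Series(learner.model.feature_importances_, index=learner.feature_names)
    return scores.sort_values(ascending=False)
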