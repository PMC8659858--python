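"""Residual geostatistics: empirical semivariogram, model fitting, ordinary
kriging and the regression-kriging hybrid.

The semivariogram of a spatial variable Z is

    gamma(h) = (1 / 2N(h)) * sum_{|x_i - x_j| ~ h} (Z(x_i) - Z(x_j))**2

estimated over equal-width lag bins.  Two permissible model families are
fitted by weighted least squares:

* spherical:  gamma(h) = c0 + c * (1.5 h/a - 0.5 (h/a)^3) for h <= a, sill
  beyond the (exact) range a;
* gaussian:   gamma(h) = c0 + c * (1 - exp(-3 h^2 / a^2)), with a the
  effective range at which 95% of the sill is reached.

c0 is the nugget, c the partial sill, c0 + c the sill, and the *sill effect*
c0 / (c0 + c) indexes how much of the variance is spatially unstructured
(lower = stronger autocorrelation).  gamma(0) = 0 by convention for both
families — the nugget is a discontinuity for h > 0 only — which makes
ordinary kriging an exact interpolator at the observations, a property the
hybrid predictor relies on.

The regression-kriging hybrid predicts

    M(s) = M_hat(s) + E_hat(s)

where M_hat is the fitted base regressor (random forest, SVR or neural
network) and E_hat the ordinary-kriging interpolation of its training
residuals.  All coordinates handed to this module are expected in
kilometres so that fitted ranges read in the units of the study reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

from .learners import FittedLearner, predict as learner_predict

__all__ = [
    "EmpiricalVariogram", "VariogramModel", "empirical_semivariogram",
    "model_gamma", "fit_variogram", "ok_predict", "sill_effect",
    "HybridModel", "hybrid_fit", "hybrid_predict",
]

logger = logging.getLogger(__name__)

FAMILIES = ("spherical", "gaussian")


@dataclass
class EmpiricalVariogram:
    lags: np.ndarray        # bin centers, km
    gamma: np.ndarray       # semivariance, (response units)^2
    counts: np.ndarray      # pair counts per bin

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.gamma < 0) or np.any(self.counts < 1):
            raise ValueError("semivariances must be >= 0 with >= 1 pair per bin")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag bins must be strictly increasing")


@dataclass
class VariogramModel:
    family: str
    nugget: float
    partial_sill: float
    range_km: float
    fit_sse: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_km <= 0:
            raise ValueError("nugget/partial sill must be >= 0 and range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def sill_effect(self) -> float:
        return sill_effect(self)


def sill_effect(model: VariogramModel) -> float:
    """Nugget-to-sill ratio in [0, 1]; undefined (error) when the sill is 0."""
    if model.sill <= 0:
        raise ValueError("sill effect undefined for a zero-sill model")
    return model.nugget / model.sill


def model_gamma(model: VariogramModel, h):
    """Model semivariance at lag(s) h >= 0, with gamma(0) = 0 exactly."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("lag distances must be non-negative")
    a = model.range_km
    c0, c = model.nugget, model.partial_sill
    if model.family == "spherical":
        u = np.minimum(h / a, 1.0)
        g = c0 + c * (1.5 * u - 0.5 * u ** 3)
    else:  # gaussian, effective range at 95% sill
        g = c0 + c * (1.0 - np.exp(-3.0 * h ** 2 / a ** 2))
    g = np.where(h == 0.0, 0.0, g)
    return float(g) if g.ndim == 0 else g


def empirical_semivariogram(locations, values, n_bins: int = 12,
                            max_lag: float | None = None) -> EmpiricalVariogram:
    """Isotropic empirical semivariogram over equal-width lag bins.

    ``locations`` is (n, 2) in km; ``max_lag`` defaults to half the maximum
    pairwise distance.  Empty bins are dropped.
    """
    locations = np.asarray(locations, dtype=float)
    values = np.asarray(values, dtype=float)
    if locations.ndim != 2 or locations.shape[0] != len(values):
        raise ValueError("locations must be (n, 2) matching values")
    if len(values) < 3:
        raise ValueError("need at least 3 points")
    d = pdist(locations)
    dmax = d.max()
    if dmax == 0:
        raise ValueError("all points are coincident")
    if max_lag is None:
        max_lag = dmax / 2.0
    elif max_lag > dmax:
        raise ValueError("max_lag exceeds the maximum pairwise distance")
    sqdiff = pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    idx = np.digitize(d, edges[1:-1])          # bin index per pair
    keep = d <= max_lag
    lags, gam, cnt = [], [], []
    for b in range(n_bins):
        m = keep & (idx == b)
        n = int(m.sum())
        if n == 0:
            continue
        lags.append(0.5 * (edges[b] + edges[b + 1]))
        gam.append(float(sqdiff[m].sum()) / (2.0 * n))
        cnt.append(n)
    return EmpiricalVariogram(np.array(lags), np.array(gam), np.array(cnt))


def _gamma_raw(family: str, h, c0, c, a):
    if family == "spherical":
        u = np.minimum(h / a, 1.0)
        return c0 + c * (1.5 * u - 0.5 * u ** 3)
    return c0 + c * (1.0 - np.exp(-3.0 * h ** 2 / a ** 2))


def fit_variogram(emp: EmpiricalVariogram, families=FAMILIES,
                  ) -> VariogramModel:
    """Fit nugget / partial sill / range by weighted least squares.

    Weights are N(h) / h^2 (more pairs and shorter lags count more), the
    standard empirical-variogram weighting.  Each family is fitted from a
    small grid of data-driven starting points and the family with the lowest
    weighted SSE wins.
    """
    if len(emp.lags) < 4:
        raise ValueError("need at least 4 populated lag bins to fit a variogram")
    h, g, n = emp.lags, emp.gamma, emp.counts
    w = np.sqrt(n / h ** 2)
    gmax = max(g.max(), 1e-12)
    best: VariogramModel | None = None
    diagnostics = []
    for family in families:
        starts = []
        for c0_frac in (0.0, 0.5):
            for a0_frac in (1.0 / 3.0, 2.0 / 3.0, 1.0):
                c0_0 = c0_frac * g[0]
                starts.append((c0_0, max(gmax - c0_0, 1e-12 * gmax), a0_frac * h[-1]))
        for c0_0, c_0, a_0 in starts:
            try:
                res = least_squares(
                    lambda p: w * (_gamma_raw(family, h, p[0], p[1], p[2]) - g),
                    x0=[c0_0, c_0, a_0],
                    bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                    max_nfev=2000)
            except Exception as exc:  # pragma: no cover - optimizer edge
                diagnostics.append((family, str(exc)))
                continue
            sse = float(np.sum(res.fun ** 2))
            model = VariogramModel(family, float(res.x[0]), float(res.x[1]),
                                   float(res.x[2]), fit_sse=sse)
            if best is None or sse < best.fit_sse:
                best = model
    if best is None:
        raise RuntimeError(f"variogram fit failed for all starts: {diagnostics}")
    if best.sill > 0 and best.sill_effect > 0.95:
        logger.warning("near-pure-nugget fit (sill effect %.2f): range %.3g km is "
                       "poorly identified", best.sill_effect, best.range_km)
    return best


def ok_predict(model: VariogramModel, obs_locations, obs_values, targets):
    """Ordinary-kriging predictions and weights with a global neighbourhood.

    Solves, for each target s0, the (n+1) system

        [ Gamma  1 ] [ lambda ]   [ gamma(d(s_i, s0)) ]
        [ 1^T    0 ] [ mu     ] = [ 1                 ]

    so the weights sum to one (unbiasedness).  Returns ``(predictions,
    weights)`` with weights shaped (n_targets, n_obs).  A zero-sill model
    degenerates to the sample mean with equal weights.
    """
    obs_locations = np.asarray(obs_locations, dtype=float)
    obs_values = np.asarray(obs_values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(obs_values)
    if n < 2:
        raise ValueError("ordinary kriging needs at least 2 observations")
    dobs = squareform(pdist(obs_locations))
    dup = np.argwhere((dobs == 0) & ~np.eye(n, dtype=bool))
    if len(dup):
        i, j = dup[0]
        raise ValueError(f"duplicate observation locations at rows {i} and {j}")
    if model.sill <= 0:
        w = np.full((len(targets), n), 1.0 / n)
        return np.full(len(targets), obs_values.mean()), w
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model_gamma(model, dobs)
    A[n, :n] = A[:n, n] = 1.0
    A[n, n] = 0.0
    dt = cdist(targets, obs_locations)
    B = np.empty((n + 1, len(targets)))
    B[:n] = model_gamma(model, dt).T
    B[n] = 1.0
    try:
        sol = solve(A, B, assume_a="sym")
    except Exception as exc:
        raise ValueError(f"singular kriging system: {exc}") from exc
    weights = sol[:n].T
    preds = weights @ obs_values
    return preds, weights


@dataclass
class HybridModel:
    """Fitted base learner plus a kriging model of its training residuals."""

    base: FittedLearner
    train_locations_km: np.ndarray
    train_residuals: np.ndarray
    variogram: VariogramModel

    def __post_init__(self) -> None:
        self.train_locations_km = np.asarray(self.train_locations_km, dtype=float)
        self.train_residuals = np.asarray(self.train_residuals, dtype=float)


def hybrid_fit(base: FittedLearner, features, response, locations_km,
               families=FAMILIES, n_bins: int = 12) -> HybridModel:
    """Fit the residual variogram of a base learner at its training plots."""
    response = np.asarray(response, dtype=float)
    resid = response - learner_predict(base, features)
    emp = empirical_semivariogram(locations_km, resid, n_bins=n_bins)
    vg = fit_variogram(emp, families=families)
    logger.info("residual variogram: %s range=%.3f km nugget=%.1f psill=%.1f "
                "sill_effect=%.2f", vg.family, vg.range_km, vg.nugget,
                vg.partial_sill, vg.sill_effect if vg.sill > 0 else float("nan"))
    return HybridModel(base, np.asarray(locations_km, float), resid, vg)


def hybrid_predict(model: HybridModel, features, locations_km) -> np.ndarray:
    """Base prediction plus kriged residual at each target location."""
    base_pred = learner_predict(model.base, features)
    kriged, _ = ok_predict(model.variogram, model.train_locations_km,
                           model.train_residuals, locations_km)
    return base_pred + kriged
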