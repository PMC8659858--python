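"""Optical predictors: 17 visible-band vegetation indices, 24 grey-level
co-occurrence texture features and 2 terrain factors.

Vegetation indices use the raw channels R, G, B and the chromatic
coordinates r = R/(R+G+B), g = G/(R+G+B), b = B/(R+G+B); every formula is
evaluated per pixel and averaged over the valid pixels of a plot tile.
Pixels where a formula's denominator vanishes (e.g. the Woebbecke index at
r = g) are masked for that index only.

Texture follows the second-order co-occurrence recipe: each band is
quantized to 64 equal-width grey levels over its own min-max, a 3x3 window
is slid over the interior pixels, the window's co-occurrence matrix at
pixel offset (1, 1) (one step down, one step right) is accumulated
symmetrically, and eight statistics — mean, variance, homogeneity,
contrast, heterogeneity (absolute-difference dissimilarity), entropy,
second moment and correlation — are averaged over windows.  Three bands
times eight statistics gives 24 texture columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import Grid, Raster, horn_slope_deg

__all__ = ["GLCMConfig", "VI_NAMES", "GLCM_FEATURE_NAMES", "vegetation_indices",
           "glcm_features", "terrain_factors"]

logger = logging.getLogger(__name__)

VI_NAMES = ["NGRDI", "EXG", "CIVE", "VEG", "EXGR", "WI", "VDVI", "RGRI", "NGBDI",
            "GBRI", "GBRVI", "MGRVI", "DEVI", "GLI", "COM", "COM2", "EXR"]

GLCM_FEATURE_NAMES = ["mean", "variance", "homogeneity", "contrast",
                      "heterogeneity", "entropy", "second_moment", "correlation"]


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 64
    window: tuple[int, int] = (3, 3)
    offset: tuple[int, int] = (1, 1)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 grey levels")
        if self.offset == (0, 0):
            raise ValueError("offset must be nonzero")
        if self.window != (3, 3):
            raise ValueError("only the 3x3 processing window is supported")


def _masked_mean(arr: np.ndarray, valid: np.ndarray, name: str) -> float:
    ok = valid & np.isfinite(arr)
    n_bad = int(valid.sum() - ok.sum())
    if n_bad:
        logger.debug("%s: %d pixels masked (undefined formula)", name, n_bad)
    if not ok.any():
        logger.warning("%s: no valid pixels; emitting NaN", name)
        return float("nan")
    return float(arr[ok].mean())


def vegetation_indices(tile: Raster) -> dict[str, float]:
    """Plot means of the 17 visible vegetation indices of an RGB tile."""
    if tile.n_bands != 3:
        raise ValueError("vegetation indices need a 3-band RGB tile")
    R = tile.band(0).astype(float)
    G = tile.band(1).astype(float)
    B = tile.band(2).astype(float)
    total = R + G + B
    valid = total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(valid, R / total, np.nan)
        g = np.where(valid, G / total, np.nan)
        b = np.where(valid, B / total, np.nan)
        per_pixel = {
            "NGRDI": (G - R) / (G + R),
            "EXG": 2 * g - r - b,
            "CIVE": 0.44 * r - 0.88 * g + 0.39 * b + 18.79,
            "VEG": g / (r ** 0.67 * b ** 0.33),
            "WI": (g - b) / (r - g),
            "VDVI": (2 * G - R - B) / (2 * G + R + B),
            "RGRI": r / g,
            "NGBDI": (G - B) / (G + B),
            "GBRI": b / g,
            "GBRVI": (G ** 2 - B * R) / (G ** 2 + B * R),
            "MGRVI": (G ** 2 - R ** 2) / (G ** 2 + R ** 2),
            "DEVI": G / (3 * G) + R / (3 * G) + B / (3 * G),
            "GLI": (2 * g - r - b) / (2 * g + r + b),
            "EXR": 1.4 * r - g,
        }
        per_pixel["EXGR"] = per_pixel["EXG"] - 1.4 * r - g
        per_pixel["COM"] = (0.25 * per_pixel["EXG"] + 0.3 * per_pixel["EXGR"]
                            + 0.33 * per_pixel["CIVE"] + 0.12 * per_pixel["VEG"])
        per_pixel["COM2"] = (0.36 * per_pixel["EXG"] + 0.47 * per_pixel["CIVE"]
                             + 0.17 * per_pixel["VEG"])
    return {name: _masked_mean(per_pixel[name], valid, name) for name in VI_NAMES}


def _quantize(band: np.ndarray, levels: int) -> np.ndarray:
    band = np.asarray(band, dtype=float)
    lo, hi = band.min(), band.max()
    if hi == lo:
        return np.zeros(band.shape, dtype=np.int32)
    q = np.floor((band - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def glcm_features(band: np.ndarray, config: GLCMConfig = GLCMConfig()) -> dict[str, float]:
    """Eight co-occurrence statistics averaged over 3x3 windows of one band.

    Each interior pixel's window contributes the four (down-right) pixel
    pairs at offset (1, 1); with symmetric counting those are 8 matrix
    entries with probabilities in multiples of 1/8.  Edge pixels without a
    complete window are excluded from the plot mean.  Correlation of a
    window with zero marginal variance is defined as 0.
    """
    q = _quantize(band, config.levels)
    H, W = q.shape
    if H < 3 or W < 3:
        raise ValueError("band smaller than the 3x3 processing window")
    # first/second elements of the 4 offset-(1,1) pairs inside each window
    firsts, seconds = [], []
    for da in (0, 1):
        for db in (0, 1):
            firsts.append(q[da:da + H - 2, db:db + W - 2])
            seconds.append(q[da + 1:da + H - 1, db + 1:db + W - 1])
    i4 = np.stack([f.ravel() for f in firsts])    # (4, n_windows)
    j4 = np.stack([s.ravel() for s in seconds])
    if config.symmetric:
        I = np.concatenate([i4, j4])               # (8, n_windows)
        J = np.concatenate([j4, i4])
    else:
        I, J = i4, j4
    m = I.shape[0]
    I = I.astype(float)
    J = J.astype(float)

    diff = I - J
    contrast = np.mean(diff ** 2, axis=0)
    heterogeneity = np.mean(np.abs(diff), axis=0)
    homogeneity = np.mean(1.0 / (1.0 + diff ** 2), axis=0)
    mu = np.mean(I, axis=0)
    var = np.mean((I - mu) ** 2, axis=0)
    # multiplicity of each (i, j) entry within its window
    code = (I * config.levels + J).astype(np.int32)
    eq = (code[:, None, :] == code[None, :, :])
    mult = eq.sum(axis=1)                          # (m, n_windows)
    second_moment = np.mean(mult / m, axis=0)
    entropy = -np.mean(np.log(mult / m), axis=0)
    cov = np.mean(I * J, axis=0) - mu ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(var > 0, cov / var, 0.0)

    stats = {"mean": mu, "variance": var, "homogeneity": homogeneity,
             "contrast": contrast, "heterogeneity": heterogeneity,
             "entropy": entropy, "second_moment": second_moment,
             "correlation": corr}
    return {k: float(v.mean()) for k, v in stats.items()}


def terrain_factors(dem: Grid, plot_center: tuple[float, float]) -> tuple[float, float]:
    """(altitude_m, slope_deg) at a plot center.

    Altitude is a bilinear sample of the DEM; slope is Horn's 3x3 method
    evaluated at the DEM cell containing the center.
    """
    x, y = plot_center
    if not dem.contains(x, y):
        raise ValueError(f"plot center {plot_center} outside DEM extent")
    altitude = float(dem.sample(x, y))
    slope_grid = horn_slope_deg(dem)
    row, col = dem._frac_index(x, y)
    nr, nc = dem.shape
    ri = int(np.clip(np.round(row), 0, nr - 1))
    ci = int(np.clip(np.round(col), 0, nc - 1))
    return altitude, float(slope_grid[ri, ci])
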