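"""Point-cloud predictors: height normalization, the 61 plot metrics,
canopy-height-model rasterization and a simple tree-top detector.

Heights are normalized by subtracting the ground surface interpolated from
a TIN (Delaunay triangulation) of the ground-classified returns, with a DEM
fallback outside the triangulation hull.  Plot metrics are computed over
the returns above a height cutoff (default 2 m, the conventional understory
threshold): 15 height percentiles {1, 5, 10, 20, 25, 30, 40, 50, 60, 70,
75, 80, 90, 95, 99}, 11 distribution statistics, and 10 vertical density
fractions; the same percentile/statistic set minus canopy-relief ratio and
densities is computed over intensities (25 columns), for 61 metrics total.

Skewness and kurtosis are population moments with kurtosis non-excess; the
mean absolute deviation is taken about the mean; the canopy relief ratio is
(mean - min)/(max - min).  Percentiles interpolate linearly between order
statistics.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .grids import Grid
from .pointcloud import PointCloud

__all__ = ["PERCENTILES", "HEIGHT_METRIC_NAMES", "DENSITY_METRIC_NAMES",
           "INTENSITY_METRIC_NAMES", "METRIC_NAMES", "normalize_heights",
           "height_metrics", "density_metrics", "intensity_metrics",
           "plot_metrics", "rasterize_chm", "detect_trees"]

logger = logging.getLogger(__name__)

PERCENTILES = (1, 5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95, 99)
_STAT_SUFFIXES = ("max", "min", "mean", "med", "std", "var", "mad")

HEIGHT_METRIC_NAMES = ([f"H_{p}" for p in PERCENTILES]
                       + [f"H_{s}" for s in _STAT_SUFFIXES]
                       + ["H_skew", "H_kurt", "H_crr", "H_cv"])
DENSITY_METRIC_NAMES = [f"H_d{i}" for i in range(10)]
INTENSITY_METRIC_NAMES = ([f"I_{p}" for p in PERCENTILES]
                          + [f"I_{s}" for s in _STAT_SUFFIXES]
                          + ["I_skew", "I_kurt", "I_cv"])
#: the 61 point-cloud metric columns, height block first
METRIC_NAMES = HEIGHT_METRIC_NAMES + DENSITY_METRIC_NAMES + INTENSITY_METRIC_NAMES


def normalize_heights(cloud: PointCloud, dem: Grid | None = None) -> PointCloud:
    """Replace z by height above the interpolated ground surface.

    Ground elevation comes from a TIN over the ground-classified points;
    points outside the TIN hull fall back to a DEM sample when a DEM is
    given, else to the nearest ground point.  Negative heights are clamped
    to 0.
    """
    ground = cloud.is_ground
    n_ground = int(ground.sum())
    if n_ground == 0 and dem is None:
        raise ValueError("cannot normalize: no ground points and no DEM supplied")
    z_ground = np.full(len(cloud), np.nan)
    if n_ground >= 3:
        pts = np.column_stack([cloud.x[ground], cloud.y[ground]])
        tin = LinearNDInterpolator(pts, cloud.z[ground])
        z_ground = tin(cloud.x, cloud.y)
        hole = ~np.isfinite(z_ground)
        if hole.any():
            if dem is not None:
                z_ground[hole] = dem.sample(cloud.x[hole], cloud.y[hole])
            else:
                nn = NearestNDInterpolator(pts, cloud.z[ground])
                z_ground[hole] = nn(cloud.x[hole], cloud.y[hole])
    elif dem is not None:
        z_ground = dem.sample(cloud.x, cloud.y)
    else:
        raise ValueError("fewer than 3 ground points and no DEM supplied")
    z_norm = np.maximum(cloud.z - z_ground, 0.0)
    return PointCloud(cloud.x, cloud.y, z_norm, cloud.intensity, cloud.is_ground,
                      plot_id=cloud.plot_id, normalized=True)


def _distribution_stats(v: np.ndarray, prefix: str, with_crr: bool) -> dict[str, float]:
    out = {}
    for p in PERCENTILES:
        out[f"{prefix}_{p}"] = float(np.percentile(v, p))  # linear interpolation
    vmax, vmin = float(v.max()), float(v.min())
    mean = float(v.mean())
    std = float(v.std(ddof=0))
    out[f"{prefix}_max"] = vmax
    out[f"{prefix}_min"] = vmin
    out[f"{prefix}_mean"] = mean
    out[f"{prefix}_med"] = float(np.median(v))
    out[f"{prefix}_std"] = std
    out[f"{prefix}_var"] = std ** 2
    out[f"{prefix}_mad"] = float(np.mean(np.abs(v - mean)))
    if std > 0:
        z = (v - mean) / std
        out[f"{prefix}_skew"] = float(np.mean(z ** 3))
        out[f"{prefix}_kurt"] = float(np.mean(z ** 4))  # non-excess
    else:
        out[f"{prefix}_skew"] = 0.0
        out[f"{prefix}_kurt"] = 0.0
    if with_crr:
        if vmax > vmin:
            out[f"{prefix}_crr"] = (mean - vmin) / (vmax - vmin)
        else:
            logger.warning("%s_crr undefined for zero spread; emitting 0", prefix)
            out[f"{prefix}_crr"] = 0.0
    out[f"{prefix}_cv"] = std / mean if mean != 0 else 0.0
    return out


def _above_cutoff(cloud: PointCloud, cutoff_m: float) -> np.ndarray:
    if not cloud.normalized:
        raise ValueError("metrics expect a height-normalized cloud")
    return cloud.z > cutoff_m


def height_metrics(cloud: PointCloud, cutoff_m: float = 2.0) -> dict[str, float]:
    """The 26 height statistics over returns above the cutoff."""
    m = _above_cutoff(cloud, cutoff_m)
    if m.sum() < 2:
        logger.warning("plot %s: fewer than 2 returns above %.1f m; height metrics NaN",
                       cloud.plot_id, cutoff_m)
        return {k: float("nan") for k in HEIGHT_METRIC_NAMES}
    return _distribution_stats(cloud.z[m], "H", with_crr=True)


def density_metrics(cloud: PointCloud, cutoff_m: float = 2.0) -> dict[str, float]:
    """Fractions of above-cutoff returns in 10 equal-height layers.

    Layers span [z_min, z_max] of the above-cutoff returns; the top edge is
    inclusive, and the fractions always sum to 1.  A zero-spread cloud puts
    everything in the bottom layer.
    """
    m = _above_cutoff(cloud, cutoff_m)
    if m.sum() < 1:
        logger.warning("plot %s: no returns above cutoff; density metrics NaN",
                       cloud.plot_id)
        return {k: float("nan") for k in DENSITY_METRIC_NAMES}
    z = cloud.z[m]
    lo, hi = float(z.min()), float(z.max())
    if hi == lo:
        counts = np.zeros(10)
        counts[0] = len(z)
    else:
        counts, _ = np.histogram(z, bins=np.linspace(lo, hi, 11))
    frac = counts / len(z)
    return {f"H_d{i}": float(frac[i]) for i in range(10)}


def intensity_metrics(cloud: PointCloud, cutoff_m: float = 2.0) -> dict[str, float]:
    """The 25 intensity statistics over returns above the height cutoff."""
    m = _above_cutoff(cloud, cutoff_m)
    if m.sum() < 2:
        logger.warning("plot %s: fewer than 2 returns above cutoff; intensity metrics NaN",
                       cloud.plot_id)
        return {k: float("nan") for k in INTENSITY_METRIC_NAMES}
    return _distribution_stats(cloud.intensity[m], "I", with_crr=False)


def plot_metrics(cloud: PointCloud, cutoff_m: float = 2.0) -> dict[str, float]:
    """All 61 metric columns for one normalized plot cloud."""
    out = height_metrics(cloud, cutoff_m)
    out.update(density_metrics(cloud, cutoff_m))
    out.update(intensity_metrics(cloud, cutoff_m))
    return out


def rasterize_chm(cloud: PointCloud, pixel_m: float = 0.5) -> Grid:
    """Canopy height model: per-pixel max normalized height.

    Pixels without returns are filled once with the 3x3 median of their
    populated neighbours; pixels still empty after that pass are 0.
    """
    if pixel_m <= 0:
        raise ValueError("pixel size must be positive")
    if len(cloud) == 0:
        return Grid(np.zeros((1, 1)), origin=(0.0, 0.0), pixel_size=pixel_m)
    if not cloud.normalized:
        raise ValueError("CHM expects a height-normalized cloud")
    x0, y1 = float(cloud.x.min()), float(cloud.y.max())
    nc = max(int(np.ceil((cloud.x.max() - x0) / pixel_m)), 1)
    nr = max(int(np.ceil((y1 - cloud.y.min()) / pixel_m)), 1)
    col = np.clip(((cloud.x - x0) / pixel_m).astype(int), 0, nc - 1)
    row = np.clip(((y1 - cloud.y) / pixel_m).astype(int), 0, nr - 1)
    chm = np.full((nr, nc), -np.inf)
    np.maximum.at(chm, (row, col), cloud.z)
    empty = ~np.isfinite(chm)
    if empty.any():
        filled = np.where(empty, np.nan, chm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            med = ndimage.generic_filter(filled, np.nanmedian, size=3,
                                         mode="constant", cval=np.nan)
        chm = np.where(empty, med, chm)
        chm = np.where(np.isfinite(chm), chm, 0.0)
    return Grid(chm, origin=(x0, y1), pixel_size=pixel_m)


def detect_trees(chm: Grid, min_height_m: float = 2.0, window_px: int = 5
                 ) -> tuple[int, float, float]:
    """Tree count N, mean top height H and mean crown width W from a CHM.

    Tops are local maxima above ``min_height_m`` within a ``window_px``
    sliding window; each canopy pixel (CHM >= min height) is assigned to its
    nearest top, and the crown width of a top is the diameter of the circle
    with its assigned area, W = 2 sqrt(A / pi).  This local-maxima detector
    is a reproducible stand-in for interactive watershed segmentation.

    Returns (0, nan, nan) when no top exceeds the threshold.
    """
    z = chm.data
    peaks = peak_local_max(z, min_distance=max(window_px // 2, 1),
                           threshold_abs=min_height_m, exclude_border=False)
    n = len(peaks)
    if n == 0:
        return 0, float("nan"), float("nan")
    heights = z[peaks[:, 0], peaks[:, 1]]
    canopy = np.argwhere(z >= min_height_m)
    tree = cKDTree(peaks.astype(float))
    _, assign = tree.query(canopy.astype(float))
    areas = np.bincount(assign, minlength=n) * chm.pixel_size ** 2
    widths = 2.0 * np.sqrt(areas / np.pi)
    return int(n), float(heights.mean()), float(widths.mean())
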