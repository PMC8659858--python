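"""Synthetic study landscape with known ground truth.

Emulates the structure of a conifer-plantation inventory campaign: ~52
square field plots of 0.06-0.2 ha spread over a hilly domain (elevations
170-575 m, slopes mostly 10-20 deg), three species in a 41/5/6 plot split,
per-plot airborne point clouds at >= 2.8 returns/m^2 with ground/canopy
classification and intensity, and 12 cm RGB tiles.  Every plot carries a
known true stand volume (closure with the volume module), and a zero-mean
Gaussian random field with a configurable variogram is added to the
delivered response so that regression residuals contain spatial structure
whose parameters are recoverable by the geostatistics stage.

What is deliberately simple: crowns are vertical cones that follow the
terrain, radiometry is a two-class colour model with noise, and every
return is a single echo.  The generator is driven entirely by one integer
seed; identical (config, seed) pairs produce identical datasets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geostat import VariogramModel, model_gamma
from .grids import Grid, Raster, horn_slope_deg
from .pointcloud import PointCloud, read_cloud_csv, read_las, write_cloud_csv, write_las
from .volume import plot_volume_per_ha

__all__ = ["SPECIES", "LandscapeConfig", "PlotTruth", "Landscape", "generate_dem",
           "generate_stand_truth", "generate_point_cloud", "generate_rgb_tile",
           "simulate", "stand_attribute_table", "write_dataset", "read_dataset"]

logger = logging.getLogger(__name__)

SPECIES = ("larix", "koraiensis", "sylvestris")

# stream tags so each stage draws from an independent, reproducible stream
_TAG_DEM, _TAG_STAND, _TAG_CLOUD, _TAG_TILE = 11, 22, 33, 44

# species-specific asymptote (m) of the saturating height-diameter curve
_HEIGHT_ASYMPTOTE = {"larix": 30.0, "koraiensis": 27.0, "sylvestris": 25.0}


def _default_variogram() -> VariogramModel:
    return VariogramModel("spherical", nugget=600.0, partial_sill=1800.0, range_km=3.0)


@dataclass
class LandscapeConfig:
    n_plots: int = 52
    area_range_ha: tuple[float, float] = (0.06, 0.2)
    species_mix: dict[str, int] = field(
        default_factory=lambda: {"larix": 41, "koraiensis": 5, "sylvestris": 6})
    elev_range_m: tuple[float, float] = (170.0, 575.0)
    slope_range_deg: tuple[float, float] = (10.0, 20.0)
    point_density_per_m2: float = 3.0
    pixel_size_m: float = 0.12
    residual_variogram: VariogramModel = field(default_factory=_default_variogram)
    trend_coefficients: dict[str, float] = field(
        default_factory=lambda: {"elev": -0.4, "slope": -0.2})
    noise_sd: float = 0.0
    seed: int = 0
    # landscape geometry
    domain_size_m: float = 8000.0
    dem_pixel_m: float = 30.0
    # stand-structure knobs (documented in the manifest; not in the study text)
    stems_per_ha_range: tuple[float, float] = (600.0, 1200.0)
    dbh_median_cm: float = 16.0
    dbh_sigma_log: float = 0.3
    height_noise_sd_m: float = 1.0
    ground_roughness_m: float = 0.05
    rgb_noise_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.n_plots < 3:
            raise ValueError("n_plots must be >= 3")
        lo, hi = self.area_range_ha
        if not (0 < lo <= hi <= 1):
            raise ValueError("area_range_ha must lie within (0, 1] with lo <= hi")
        if self.point_density_per_m2 <= 0:
            raise ValueError("point density must be positive")
        if self.pixel_size_m <= 0 or self.dem_pixel_m <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.elev_range_m[0] > self.elev_range_m[1]:
            raise ValueError("degenerate elevation range (min > max)")

    def species_sequence(self) -> list[str]:
        """Per-plot species labels honouring the mix, proportional otherwise."""
        mix = dict(self.species_mix)
        total = sum(mix.values())
        if total != self.n_plots:
            logger.info("species mix totals %d for %d plots; rescaling proportionally",
                        total, self.n_plots)
            raw = {s: c * self.n_plots / total for s, c in mix.items()}
            mix = {s: int(np.floor(v)) for s, v in raw.items()}
            rem = self.n_plots - sum(mix.values())
            for s in sorted(raw, key=lambda s: raw[s] - mix[s], reverse=True)[:rem]:
                mix[s] += 1
        out: list[str] = []
        for s, c in mix.items():
            out.extend([s] * c)
        return out


@dataclass
class PlotTruth:
    plot_id: str
    center_xy_m: tuple[float, float]
    area_ha: float
    side_m: float
    species: str
    trees: pd.DataFrame          # species, dbh_cm, height_m, x_m, y_m, crown_radius_m
    true_volume_m3ha: float
    residual_truth_m3ha: float
    noise_m3ha: float = 0.0

    @property
    def response_m3ha(self) -> float:
        """The volume delivered downstream: truth plus the planted adjustment."""
        return self.true_volume_m3ha + self.residual_truth_m3ha + self.noise_m3ha


@dataclass
class Landscape:
    config: LandscapeConfig
    dem: Grid
    plots: list[PlotTruth]
    clouds: dict[str, PointCloud]
    tiles: dict[str, Raster]


def generate_dem(config: LandscapeConfig) -> Grid:
    """Smooth synthetic terrain: a sum of low-frequency harmonics rescaled
    into the configured elevation range.

    Wavelengths are drawn between 0.18 and 0.35 of the domain size so that
    for the default 8 km domain and 405 m relief the Horn slope
    distribution overlaps the 10-20 deg band; the relief amplitude is
    capped so the steepest cell never exceeds 28 deg.
    """
    emin, emax = config.elev_range_m
    if emin > emax:
        raise ValueError("degenerate elevation range")
    rng = np.random.default_rng([config.seed, _TAG_DEM])
    n = max(int(np.ceil(config.domain_size_m / config.dem_pixel_m)), 8)
    xs = (np.arange(n) + 0.5) * config.dem_pixel_m
    X, Y = np.meshgrid(xs, xs[::-1])
    z = np.zeros((n, n))
    for _ in range(6):
        wavelength = rng.uniform(0.18, 0.35) * config.domain_size_m
        theta = rng.uniform(0, 2 * np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        kx, ky = np.cos(theta) / wavelength, np.sin(theta) / wavelength
        z += amp * np.cos(2 * np.pi * (kx * X + ky * Y) + phase)
    span = z.max() - z.min()
    if span == 0 or emin == emax:
        z = np.full_like(z, 0.5 * (emin + emax))
        return Grid(z, origin=(0.0, config.domain_size_m),
                    pixel_size=config.dem_pixel_m)
    z = emin + (z - z.min()) / span * (emax - emin)
    grid = Grid(z, origin=(0.0, config.domain_size_m), pixel_size=config.dem_pixel_m)
    max_tan = np.tan(np.radians(horn_slope_deg(grid).max()))
    cap_tan = np.tan(np.radians(28.0))
    if max_tan > cap_tan:
        mid = 0.5 * (z.max() + z.min())
        grid.data = mid + (z - mid) * (cap_tan / max_tan)
    return grid


def _residual_field(config: LandscapeConfig, centers: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian field with the truth variogram, by Cholesky."""
    vg = config.residual_variogram
    if vg.sill <= 0:
        return np.zeros(len(centers))
    d_km = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1) / 1000.0
    cov = vg.sill - model_gamma(vg, d_km)      # gamma(0)=0 puts the full sill on the diagonal
    cov = cov + np.eye(len(centers)) * (1e-9 * vg.sill)
    L = np.linalg.cholesky(cov)
    return L @ rng.standard_normal(len(centers))


def generate_stand_truth(config: LandscapeConfig, dem: Grid) -> list[PlotTruth]:
    """Place non-overlapping square plots and draw their tree lists.

    Stem density is uniform over ``stems_per_ha_range``; DBH is lognormal
    around a site-dependent median (the terrain trend); height follows a
    saturating Chapman-Richards-type curve of DBH plus Gaussian noise.  The
    spatially autocorrelated residual field is sampled at the plot centers.
    """
    rng = np.random.default_rng([config.seed, _TAG_STAND])
    species_seq = config.species_sequence()
    n = config.n_plots
    sides = np.sqrt(rng.uniform(*config.area_range_ha, size=n) * 1e4)

    centers = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 2000 * n
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping plots in a "
                f"{config.domain_size_m:.0f} m domain after {max_attempts} tries")
        attempts += 1
        margin = sides[placed] / 2 + 2 * config.dem_pixel_m
        c = rng.uniform(margin, config.domain_size_m - margin, size=2)
        ok = True
        for j in range(placed):
            half = (sides[placed] + sides[j]) / 2 + 10.0
            if abs(c[0] - centers[j, 0]) < half and abs(c[1] - centers[j, 1]) < half:
                ok = False
                break
        if ok:
            centers[placed] = c
            placed += 1

    slope_grid = horn_slope_deg(dem)
    emin, emax = config.elev_range_m
    smin, smax = config.slope_range_deg

    plots: list[PlotTruth] = []
    residuals = _residual_field(config, centers, rng)
    for i in range(n):
        cx, cy = centers[i]
        side = sides[i]
        area_ha = side ** 2 / 1e4
        species = species_seq[i]
        elev = dem.sample(cx, cy)
        row, col = dem._frac_index(cx, cy)
        slope = slope_grid[int(np.clip(round(row), 0, dem.shape[0] - 1)),
                           int(np.clip(round(col), 0, dem.shape[1] - 1))]
        elev_norm = (elev - emin) / (emax - emin) if emax > emin else 0.5
        slope_norm = np.clip((slope - smin) / (smax - smin), 0, 1) if smax > smin else 0.5
        tc = config.trend_coefficients
        site = float(np.exp(tc.get("elev", 0.0) * (elev_norm - 0.5)
                            + tc.get("slope", 0.0) * (slope_norm - 0.5)))

        density = rng.uniform(*config.stems_per_ha_range)
        n_trees = max(int(round(density * area_ha)), 1)
        dbh = np.exp(rng.normal(np.log(config.dbh_median_cm * site),
                                config.dbh_sigma_log, n_trees))
        dbh = np.clip(dbh, 5.0, 50.0)
        asym = _HEIGHT_ASYMPTOTE[species] if species in _HEIGHT_ASYMPTOTE else 28.0
        height = (1.3 + (asym - 1.3) * (1 - np.exp(-0.06 * dbh)) ** 1.3
                  + rng.normal(0.0, config.height_noise_sd_m, n_trees))
        height = np.clip(height, 2.0, asym + 3.0)
        crown = np.clip(0.5 + 0.045 * dbh + rng.normal(0, 0.15, n_trees), 0.3, 9.9)
        trees = pd.DataFrame({
            "species": species,
            "dbh_cm": dbh,
            "height_m": height,
            "x_m": rng.uniform(cx - side / 2, cx + side / 2, n_trees),
            "y_m": rng.uniform(cy - side / 2, cy + side / 2, n_trees),
            "crown_radius_m": crown,
        })
        true_vol = plot_volume_per_ha(trees, area_ha)
        noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
        plots.append(PlotTruth(
            plot_id=f"P{i:03d}", center_xy_m=(float(cx), float(cy)),
            area_ha=float(area_ha), side_m=float(side), species=species,
            trees=trees, true_volume_m3ha=float(true_vol),
            residual_truth_m3ha=float(residuals[i]), noise_m3ha=noise))
    return plots


def generate_point_cloud(plot: PlotTruth, dem: Grid, config: LandscapeConfig
                         ) -> PointCloud:
    """Per-plot synthetic returns: terrain-following ground points plus
    conical crown points per tree, at >= the configured density.

    Crown points sit inside a vertical cone whose apex is the tree top;
    each tree also contributes one exact apex return.  Crown heights are
    measured above the ground directly beneath each return, so normalized
    heights are bounded by the tree height.  Intensities are drawn from
    separate ground and canopy distributions (arbitrary 0-255 units).
    """
    idx = int(plot.plot_id.lstrip("P"))
    rng = np.random.default_rng([config.seed, _TAG_CLOUD, idx])
    cx, cy = plot.center_xy_m
    side = plot.side_m
    area_m2 = plot.area_ha * 1e4
    n_target = int(np.ceil(area_m2 * config.point_density_per_m2 * 1.15))

    trees = plot.trees
    if len(trees) == 0:
        n_ground = n_target
    else:
        cover = min(float(np.pi * (trees["crown_radius_m"] ** 2).sum()) / area_m2, 0.95)
        n_ground = int(np.ceil(n_target * max(1.0 - 0.75 * cover, 0.25)))
    gx = rng.uniform(cx - side / 2, cx + side / 2, n_ground)
    gy = rng.uniform(cy - side / 2, cy + side / 2, n_ground)
    gz = dem.sample(gx, gy) + rng.normal(0, config.ground_roughness_m, n_ground)
    gi = np.clip(rng.normal(45, 8, n_ground), 1, 255)

    xs, ys, zs, ii = [gx], [gy], [gz], [gi]
    flags = [np.ones(n_ground, dtype=bool)]
    if len(trees) > 0:
        n_canopy = max(n_target - n_ground, len(trees))
        w = (trees["crown_radius_m"] ** 2).to_numpy()
        alloc = np.maximum(np.round(n_canopy * w / w.sum()).astype(int), 1)
        for (_, t), k in zip(trees.iterrows(), alloc):
            h, r = float(t["height_m"]), float(t["crown_radius_m"])
            base = 0.35 * h
            tt = np.sqrt(rng.uniform(0, 1, k))          # biased toward the crown top
            rad = (1 - tt) * r * np.sqrt(rng.uniform(0, 1, k))
            ang = rng.uniform(0, 2 * np.pi, k)
            px = t["x_m"] + rad * np.cos(ang)
            py = t["y_m"] + rad * np.sin(ang)
            pz_rel = base + tt * (h - base)
            # exact apex return at the tree top
            px = np.append(px, t["x_m"])
            py = np.append(py, t["y_m"])
            pz_rel = np.append(pz_rel, h)
            xs.append(px)
            ys.append(py)
            zs.append(dem.sample(px, py) + pz_rel)
            ii.append(np.clip(rng.normal(120, 20, k + 1), 1, 255))
            flags.append(np.zeros(k + 1, dtype=bool))
    return PointCloud(np.concatenate(xs), np.concatenate(ys), np.concatenate(zs),
                      np.concatenate(ii), np.concatenate(flags), plot_id=plot.plot_id)


def generate_rgb_tile(plot: PlotTruth, config: LandscapeConfig) -> Raster:
    """RGB tile of a plot: green-dominant crowns over brown/grey gaps.

    Crown disks get a per-tree brightness factor and a radial shading ramp
    (both multiplicative, so green dominance survives them); additive pixel
    noise with sd ``rgb_noise_sd`` keeps the co-occurrence textures
    non-degenerate.  Bands are 8-bit, georeferenced to the plot square.
    """
    idx = int(plot.plot_id.lstrip("P"))
    rng = np.random.default_rng([config.seed, _TAG_TILE, idx])
    side = plot.side_m
    npx = max(int(np.ceil(side / config.pixel_size_m)), 8)
    px = config.pixel_size_m
    x0 = plot.center_xy_m[0] - side / 2
    y1 = plot.center_xy_m[1] + side / 2

    canopy_rgb = np.array([45.0, 96.0, 40.0])
    gap_rgb = np.array([120.0, 104.0, 86.0])
    img = np.empty((3, npx, npx))
    img[:] = gap_rgb[:, None, None]
    # gap mottling (multiplicative, band-neutral)
    img *= rng.uniform(0.9, 1.1, size=(1, npx, npx))

    xc = x0 + (np.arange(npx) + 0.5) * px
    yc = y1 - (np.arange(npx) + 0.5) * px
    for _, t in plot.trees.iterrows():
        r = float(t["crown_radius_m"])
        tx, ty = float(t["x_m"]), float(t["y_m"])
        c0 = max(int((tx - r - x0) / px), 0)
        c1 = min(int((tx + r - x0) / px) + 1, npx)
        r0 = max(int((y1 - (ty + r)) / px), 0)
        r1 = min(int((y1 - (ty - r)) / px) + 1, npx)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = xc[c0:c1][None, :] - tx
        dy = yc[r0:r1][:, None] - ty
        d = np.hypot(dx, dy)
        inside = d <= r
        if not inside.any():
            continue
        shade = (0.75 + 0.5 * (1 - d / r)) * float(rng.uniform(0.85, 1.15))
        patch = img[:, r0:r1, c0:c1]
        for band in range(3):
            pb = patch[band]
            pb[inside] = canopy_rgb[band] * shade[inside]
    if config.rgb_noise_sd > 0:
        img += rng.normal(0, config.rgb_noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return Raster(img, origin=(x0, y1), pixel_size=px)


def simulate(config: LandscapeConfig, with_clouds: bool = True,
             with_tiles: bool = True) -> Landscape:
    """Full landscape: DEM, plot truth, and (optionally) clouds and tiles."""
    dem = generate_dem(config)
    plots = generate_stand_truth(config, dem)
    clouds = {p.plot_id: generate_point_cloud(p, dem, config) for p in plots} \
        if with_clouds else {}
    tiles = {p.plot_id: generate_rgb_tile(p, config) for p in plots} \
        if with_tiles else {}
    return Landscape(config, dem, plots, clouds, tiles)


def stand_attribute_table(plots: list[PlotTruth], dem: Grid) -> pd.DataFrame:
    """Cheap plot-level stand attributes straight from the tree lists.

    Used by replicate experiments where the full raster/point-cloud feature
    stack would be wasteful: mean DBH and height, stem density, basal area,
    plot area and the two terrain factors, plus the delivered response M
    and plot coordinates.
    """
    from .optical import terrain_factors
    rows = []
    for p in plots:
        t = p.trees
        alt, slope = terrain_factors(dem, p.center_xy_m)
        rows.append({
            "plot_id": p.plot_id,
            "mean_dbh_cm": float(t["dbh_cm"].mean()),
            "mean_height_m": float(t["height_m"].mean()),
            "stems_per_ha": len(t) / p.area_ha,
            "basal_area_m2ha": float((np.pi * (t["dbh_cm"] / 200.0) ** 2).sum()) / p.area_ha,
            "area": p.area_ha,
            "h": alt,
            "slope": slope,
            "center_x": p.center_xy_m[0],
            "center_y": p.center_xy_m[1],
            "M": p.response_m3ha,
        })
    return pd.DataFrame(rows).set_index("plot_id")


# ---------------------------------------------------------------------------
# on-disk dataset


def _config_to_jsonable(config: LandscapeConfig) -> dict:
    d = asdict(config)
    d["residual_variogram"] = {
        "family": config.residual_variogram.family,
        "nugget": config.residual_variogram.nugget,
        "partial_sill": config.residual_variogram.partial_sill,
        "range_km": config.residual_variogram.range_km,
    }
    return d


def _truth_checksum(truth: dict) -> str:
    blob = json.dumps(truth, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_dataset(landscape: Landscape, path: str | Path) -> dict:
    """Write the dataset tree and return the manifest.

    Layout: ``dem.npy/json``, ``plots.csv``, ``trees.csv``,
    ``clouds/<id>.las`` + ``clouds/<id>.csv``, ``tiles/<id>.npy/json`` and
    ``manifest.json`` (seed, config, per-plot truth and a SHA-256 checksum
    over the truth block).
    """
    path = Path(path)
    (path / "clouds").mkdir(parents=True, exist_ok=True)
    (path / "tiles").mkdir(exist_ok=True)
    landscape.dem.save(path / "dem")
    plots_df = pd.DataFrame([
        {"plot_id": p.plot_id, "center_x": p.center_xy_m[0],
         "center_y": p.center_xy_m[1], "area_ha": p.area_ha}
        for p in landscape.plots])
    plots_df.to_csv(path / "plots.csv", index=False)
    trees_df = pd.concat([p.trees.assign(plot_id=p.plot_id) for p in landscape.plots],
                         ignore_index=True)
    cols = ["plot_id", "species", "dbh_cm", "height_m", "x_m", "y_m", "crown_radius_m"]
    trees_df[cols].to_csv(path / "trees.csv", index=False)
    for pid, cloud in landscape.clouds.items():
        write_las(cloud, path / "clouds" / f"{pid}.las")
        write_cloud_csv(cloud, path / "clouds" / f"{pid}.csv")
    for pid, tile in landscape.tiles.items():
        tile.save(path / "tiles" / pid)
    truth = {p.plot_id: {"true_volume_m3ha": p.true_volume_m3ha,
                         "residual_truth_m3ha": p.residual_truth_m3ha,
                         "noise_m3ha": p.noise_m3ha,
                         "side_m": p.side_m, "species": p.species}
             for p in landscape.plots}
    manifest = {"seed": landscape.config.seed,
                "config": _config_to_jsonable(landscape.config),
                "truth": truth,
                "truth_checksum": _truth_checksum(truth)}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_dataset(path: str | Path, prefer_csv_clouds: bool = True) -> dict:
    """Read a written dataset back; verifies the truth checksum.

    Returns a dict with keys ``manifest``, ``dem``, ``plots`` (DataFrame),
    ``trees`` (DataFrame), ``clouds`` and ``tiles``.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    expect = manifest.get("truth_checksum")
    actual = _truth_checksum(manifest["truth"])
    if expect != actual:
        raise ValueError(f"{path}: truth block checksum mismatch "
                         f"(manifest {expect!r} != computed {actual!r})")
    dem = Grid.load(path / "dem")
    plots = pd.read_csv(path / "plots.csv", float_precision="round_trip")
    trees = pd.read_csv(path / "trees.csv", float_precision="round_trip")
    clouds: dict[str, PointCloud] = {}
    for pid in plots["plot_id"]:
        csv_p = path / "clouds" / f"{pid}.csv"
        las_p = path / "clouds" / f"{pid}.las"
        if prefer_csv_clouds and csv_p.exists():
            clouds[pid] = read_cloud_csv(csv_p, plot_id=pid)
        elif las_p.exists():
            clouds[pid] = read_las(las_p, plot_id=pid)
    tiles: dict[str, Raster] = {}
    for pid in plots["plot_id"]:
        if (path / "tiles" / f"{pid}.npy").exists():
            tiles[pid] = Raster.load(path / "tiles" / pid)
    return {"manifest": manifest, "dem": dem, "plots": plots, "trees": trees,
            "clouds": clouds, "tiles": tiles}
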