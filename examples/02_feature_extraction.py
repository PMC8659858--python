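"""Extract the optical and point-cloud predictors for one plot.

Shows the three feature families behind the 107-column candidate table:
visible vegetation indices from the RGB tile, co-occurrence textures per
band, and the normalized point-cloud metrics with the tree-top summaries.
"""

from forestvol.lidar import detect_trees, normalize_heights, plot_metrics, rasterize_chm
from forestvol.optical import glcm_features, terrain_factors, vegetation_indices
from forestvol.synthetic import LandscapeConfig, simulate

cfg = LandscapeConfig(n_plots=6, domain_size_m=2500.0, pixel_size_m=0.3, seed=3)
land = simulate(cfg)
plot = land.plots[0]

vi = vegetation_indices(land.tiles[plot.plot_id])
print("vegetation indices (plot means):")
print("  " + "  ".join(f"{k}={vi[k]:.3f}" for k in ("NGRDI", "EXG", "GLI", "VDVI")))

tex = glcm_features(land.tiles[plot.plot_id].band(1))
print("green-band textures: contrast=%.2f entropy=%.2f homogeneity=%.3f"
      % (tex["contrast"], tex["entropy"], tex["homogeneity"]))

norm = normalize_heights(land.clouds[plot.plot_id], land.dem)
metrics = plot_metrics(norm)
print("height metrics: H_95=%.1f m  H_mean=%.1f m  H_cv=%.2f"
      % (metrics["H_95"], metrics["H_mean"], metrics["H_cv"]))
chm = rasterize_chm(norm, pixel_m=0.5)
n, h, w = detect_trees(chm)
print("tree detection: N=%d tops, mean top height H=%.1f m, crown width W=%.1f m"
      % (n, h, w))
print("truth: %d stems, tallest tree %.1f m"
      % (len(plot.trees), plot.trees["height_m"].max()))
alt, slope = terrain_factors(land.dem, plot.center_xy_m)
print("terrain: altitude %.0f m, slope %.1f deg" % (alt, slope))
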