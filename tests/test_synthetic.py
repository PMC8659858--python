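import json

import numpy as np
import pandas as pd
import pytest

from forestvol.geostat import VariogramModel, empirical_semivariogram, fit_variogram
from forestvol.grids import horn_slope_deg
from forestvol.optical import vegetation_indices
from forestvol.synthetic import (LandscapeConfig, generate_dem,
                                 generate_point_cloud, generate_rgb_tile,
                                 generate_stand_truth, read_dataset, simulate,
                                 write_dataset)
from forestvol.volume import plot_volume_per_ha


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            LandscapeConfig(n_plots=2)
        with pytest.raises(ValueError):
            LandscapeConfig(area_range_ha=(0.2, 0.06))
        with pytest.raises(ValueError):
            LandscapeConfig(point_density_per_m2=0)
        with pytest.raises(ValueError):
            LandscapeConfig(elev_range_m=(575, 170))


class TestDEM:
    def test_collapsed_range_gives_flat_terrain(self):
        cfg = LandscapeConfig(elev_range_m=(300.0, 300.0), seed=3)
        dem = generate_dem(cfg)
        assert np.all(dem.data == 300.0)
        assert horn_slope_deg(dem).max() == 0.0

    def test_seed_determinism(self):
        cfg = LandscapeConfig(seed=5)
        np.testing.assert_array_equal(generate_dem(cfg).data,
                                      generate_dem(cfg).data)
        other = generate_dem(LandscapeConfig(seed=6))
        assert not np.array_equal(generate_dem(cfg).data, other.data)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_elevation_and_slope_envelope(self, seed):
        cfg = LandscapeConfig(seed=seed)
        dem = generate_dem(cfg)
        assert dem.data.min() >= cfg.elev_range_m[0] - 1e-9
        assert dem.data.max() <= cfg.elev_range_m[1] + 1e-9
        slopes = horn_slope_deg(dem)
        assert 0 <= slopes.min() and slopes.max() <= 30.0
        # distribution overlaps the configured band
        lo, hi = cfg.slope_range_deg
        assert ((slopes >= lo) & (slopes <= hi)).mean() > 0.1


class TestStandTruth:
    def test_default_species_split(self):
        cfg = LandscapeConfig(seed=2)
        plots = generate_stand_truth(cfg, generate_dem(cfg))
        counts = pd.Series([p.species for p in plots]).value_counts()
        assert len(plots) == 52
        assert counts["larix"] == 41 and counts["koraiensis"] == 5
        assert counts["sylvestris"] == 6

    def test_volume_closure_with_volume_module(self, small_landscape):
        for p in small_landscape.plots:
            direct = plot_volume_per_ha(p.trees, p.area_ha)
            assert abs(direct - p.true_volume_m3ha) <= 1e-9 * max(direct, 1.0)

    def test_degenerate_variogram_zero_residuals(self):
        cfg = LandscapeConfig(
            n_plots=8, domain_size_m=2000.0, seed=1,
            residual_variogram=VariogramModel("spherical", 0.0, 0.0, 1.0))
        plots = generate_stand_truth(cfg, generate_dem(cfg))
        assert all(p.residual_truth_m3ha == 0.0 for p in plots)
        assert all(p.response_m3ha == p.true_volume_m3ha for p in plots)

    def test_plots_do_not_overlap(self, small_landscape):
        plots = small_landscape.plots
        for i in range(len(plots)):
            for j in range(i + 1, len(plots)):
                dx = abs(plots[i].center_xy_m[0] - plots[j].center_xy_m[0])
                dy = abs(plots[i].center_xy_m[1] - plots[j].center_xy_m[1])
                half = (plots[i].side_m + plots[j].side_m) / 2
                assert max(dx, dy) > half

    def test_impossible_packing_raises(self):
        cfg = LandscapeConfig(n_plots=52, domain_size_m=300.0, seed=0)
        with pytest.raises(RuntimeError, match="non-overlapping"):
            generate_stand_truth(cfg, generate_dem(cfg))

    def test_residual_field_recovers_truth_structure(self):
        # dense landscape: the empirical variogram of the planted field
        # should rise from ~nugget toward ~sill by the truth range
        truth = VariogramModel("spherical", nugget=100.0, partial_sill=900.0,
                               range_km=2.0)
        cfg = LandscapeConfig(n_plots=500, domain_size_m=12000.0,
                              area_range_ha=(0.06, 0.08),
                              residual_variogram=truth, seed=11)
        plots = generate_stand_truth(cfg, generate_dem(cfg))
        locs = np.array([p.center_xy_m for p in plots]) / 1000.0
        resid = np.array([p.residual_truth_m3ha for p in plots])
        emp = empirical_semivariogram(locs, resid)
        fitted = fit_variogram(emp)
        assert fitted.sill == pytest.approx(truth.sill, rel=0.25)
        near = emp.gamma[emp.lags < 0.5].mean()
        far = emp.gamma[emp.lags > 2.0].mean()
        assert near < far


class TestPointClouds:
    def test_density_floor(self, small_landscape, small_config):
        for p in small_landscape.plots[:4]:
            cloud = small_landscape.clouds[p.plot_id]
            assert len(cloud) >= p.area_ha * 1e4 * small_config.point_density_per_m2

    def test_crown_points_bounded_by_tree_height(self, small_landscape):
        dem = small_landscape.dem
        p = small_landscape.plots[0]
        cloud = small_landscape.clouds[p.plot_id]
        canopy = cloud.canopy
        above = canopy.z - dem.sample(canopy.x, canopy.y)
        assert above.max() <= p.trees["height_m"].max() + 1e-6
        assert above.min() > 0

    def test_treeless_plot_all_ground(self, small_config):
        dem = generate_dem(small_config)
        plots = generate_stand_truth(small_config, dem)
        p = plots[0]
        p.trees = p.trees.iloc[0:0]
        cloud = generate_point_cloud(p, dem, small_config)
        assert cloud.is_ground.all() and len(cloud) > 0

    def test_intensity_separates_ground_and_canopy(self, small_landscape):
        cloud = small_landscape.clouds[small_landscape.plots[0].plot_id]
        assert cloud.intensity[~cloud.is_ground].mean() > \
            cloud.intensity[cloud.is_ground].mean()


class TestRGBTiles:
    def test_closed_canopy_green_dominant(self):
        # tiny plot so a single 9.9 m crown closes the whole canopy
        cfg = LandscapeConfig(n_plots=3, area_range_ha=(0.01, 0.01),
                              domain_size_m=1200.0, rgb_noise_sd=0.0, seed=4)
        dem = generate_dem(cfg)
        p = generate_stand_truth(cfg, dem)[0]
        p.trees = p.trees.iloc[:1].assign(
            x_m=p.center_xy_m[0], y_m=p.center_xy_m[1],
            crown_radius_m=9.9, height_m=20.0)
        assert p.side_m < 2 * 9.9 / np.sqrt(2), "crown must cover the square"
        tile = generate_rgb_tile(p, cfg)
        G = tile.band(1).astype(int)
        assert np.all(G > tile.band(0).astype(int))
        assert np.all(G > tile.band(2).astype(int))
        vi = vegetation_indices(tile)
        assert vi["NGRDI"] > 0

    def test_default_tile_has_texture(self, small_landscape):
        tile = small_landscape.tiles[small_landscape.plots[0].plot_id]
        for b in range(3):
            assert len(np.unique(tile.band(b))) > 1


class TestDatasetIO:
    def test_roundtrip_and_checksum(self, tmp_path):
        cfg = LandscapeConfig(n_plots=4, domain_size_m=1500.0,
                              pixel_size_m=0.5, seed=9)
        land = simulate(cfg)
        manifest = write_dataset(land, tmp_path / "ds")
        assert manifest["seed"] == 9
        back = read_dataset(tmp_path / "ds")
        assert len(back["plots"]) == 4
        pid = land.plots[0].plot_id
        np.testing.assert_array_equal(back["clouds"][pid].z,
                                      land.clouds[pid].z)
        np.testing.assert_array_equal(back["tiles"][pid].data,
                                      land.tiles[pid].data)
        np.testing.assert_array_equal(back["dem"].data, land.dem.data)
        trees_back = back["trees"]
        orig = land.plots[0].trees
        got = trees_back[trees_back["plot_id"] == pid]
        np.testing.assert_array_equal(got["dbh_cm"].to_numpy(),
                                      orig["dbh_cm"].to_numpy())

    def test_tampered_truth_detected(self, tmp_path):
        cfg = LandscapeConfig(n_plots=4, domain_size_m=1500.0,
                              pixel_size_m=0.5, seed=9)
        land = simulate(cfg)
        write_dataset(land, tmp_path / "ds")
        mpath = tmp_path / "ds" / "manifest.json"
        manifest = json.loads(mpath.read_text())
        pid = next(iter(manifest["truth"]))
        manifest["truth"][pid]["true_volume_m3ha"] += 1.0
        mpath.write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="checksum"):
            read_dataset(tmp_path / "ds")

    def test_identical_seed_identical_dataset(self):
        cfg = LandscapeConfig(n_plots=4, domain_size_m=1500.0,
                              pixel_size_m=0.5, seed=13)
        l1, l2 = simulate(cfg), simulate(cfg)
        pid = l1.plots[0].plot_id
        np.testing.assert_array_equal(l1.clouds[pid].z, l2.clouds[pid].z)
        np.testing.assert_array_equal(l1.tiles[pid].data, l2.tiles[pid].data)
        assert l1.plots[0].response_m3ha == l2.plots[0].response_m3ha
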