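import numpy as np
import pytest

from crownagb import synthetic_forest as sf
from crownagb.core import GROUND, HIGH_VEGETATION, TreeRecord


class TestSampleTreePopulation:
    def test_default_config_counts(self, default_trees):
        assert len(default_trees) == 126 + 127 + 290 + 82 == 625
        per_plot = {}
        for t in default_trees:
            per_plot[t.plot_id] = per_plot.get(t.plot_id, 0) + 1
        assert per_plot == {1: 126, 2: 127, 3: 290, 4: 82}

    def test_attributes_within_ranges(self, default_trees):
        cfg = sf.default_forest_config(seed=0)
        profiles = {p.plot_id: p.profile for p in cfg.plots}
        for t in default_trees:
            prof = profiles[t.plot_id]
            assert prof.H_range[0] <= t.H <= prof.H_range[1]
            assert prof.DBH_range[0] <= t.DBH <= prof.DBH_range[1]
            assert prof.R_range[0] <= t.R <= prof.R_range[1]

    def test_single_tree(self):
        prof = sf.SpeciesProfile("larch", (8, 16), (12, 19), (1.5, 3.5))
        cfg = sf.SyntheticForestConfig(
            plots=[sf.PlotConfig(1, prof, 1, (0, 0, 10, 10))], seed=5)
        trees = sf.sample_tree_population(cfg)
        assert len(trees) == 1
        t = trees[0]
        assert 8 <= t.H <= 16 and 12 <= t.DBH <= 19 and 1.5 <= t.R <= 3.5
        assert 0 <= t.x <= 10 and 0 <= t.y <= 10

    def test_zero_noise_is_deterministic_power_law(self):
        prof = sf.SpeciesProfile("larch", (8, 16), (12, 19), (1.5, 3.5),
                                 noise_sd_H=0.0, noise_sd_R=0.0)
        cfg = sf.SyntheticForestConfig(
            plots=[sf.PlotConfig(1, prof, 40, (0, 0, 30, 30))], seed=2)
        for t in sf.sample_tree_population(cfg):
            # independent arithmetic: exp/log instead of ** on the sample
            h_expect = prof.hd_scale * np.exp(
                prof.hd_exponent * np.log(t.DBH))
            r_expect = prof.rd_scale * np.exp(
                prof.rd_exponent * np.log(t.DBH))
            assert t.H == pytest.approx(np.clip(h_expect, 8, 16), rel=1e-9)
            assert t.R == pytest.approx(np.clip(r_expect, 1.5, 3.5), rel=1e-9)

    def test_power_law_calibration_hits_range_endpoints(self):
        prof = sf.SpeciesProfile("larch", (8.15, 15.98), (12.24, 18.93),
                                 (1.62, 3.32))
        assert prof.hd_scale * 12.24 ** prof.hd_exponent == pytest.approx(8.15)
        assert prof.hd_scale * 18.93 ** prof.hd_exponent == pytest.approx(15.98)
        assert prof.rd_scale * 12.24 ** prof.rd_exponent == pytest.approx(1.62)

    def test_min_spacing_respected(self, default_trees):
        cfg = sf.default_forest_config(seed=0)
        for pid in (1, 2, 3, 4):
            pos = np.array([[t.x, t.y] for t in default_trees
                            if t.plot_id == pid])
            d = np.hypot(pos[:, None, 0] - pos[None, :, 0],
                         pos[:, None, 1] - pos[None, :, 1])
            np.fill_diagonal(d, np.inf)
            assert d.min() >= cfg.min_spacing

    def test_determinism(self):
        a = sf.sample_tree_population(sf.default_forest_config(seed=42))
        b = sf.sample_tree_population(sf.default_forest_config(seed=42))
        assert a == b

    def test_different_seeds_differ(self):
        a = sf.sample_tree_population(sf.default_forest_config(seed=1))
        b = sf.sample_tree_population(sf.default_forest_config(seed=2))
        assert a != b

    def test_impossible_packing_rejected_at_config(self):
        prof = sf.SpeciesProfile("larch", (8, 16), (12, 19), (1.5, 3.5))
        with pytest.raises(ValueError, match="too small"):
            sf.SyntheticForestConfig(
                plots=[sf.PlotConfig(1, prof, 100, (0, 0, 5, 5))],
                min_spacing=2.0)

    def test_placement_failure_names_plot(self):
        # Feasible area, but a one-attempt budget cannot satisfy the
        # spacing constraint for many trees.
        prof = sf.SpeciesProfile("larch", (8, 16), (12, 19), (1.5, 3.5))
        cfg = sf.SyntheticForestConfig(
            plots=[sf.PlotConfig(7, prof, 50, (0, 0, 21.0, 21.0))],
            min_spacing=2.0, seed=0, placement_attempts=1)
        with pytest.raises(sf.PlacementError, match="plot 7"):
            sf.sample_tree_population(cfg)

    def test_grid_layout(self):
        prof = sf.SpeciesProfile("larch", (8, 16), (12, 19), (1.5, 3.5))
        cfg = sf.SyntheticForestConfig(
            plots=[sf.PlotConfig(1, prof, 9, (0, 0, 20, 20))],
            min_spacing=4.0, layout="grid", seed=0)
        trees = sf.sample_tree_population(cfg)
        pos = np.array([[t.x, t.y] for t in trees])
        d = np.hypot(pos[:, None, 0] - pos[None, :, 0],
                     pos[:, None, 1] - pos[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 4.0 - 1e-9

    def test_invalid_profile_ranges(self):
        with pytest.raises(ValueError):
            sf.SpeciesProfile("larch", (16, 8), (12, 19), (1.5, 3.5))
        with pytest.raises(ValueError):
            sf.SpeciesProfile("larch", (8, 16), (12, 19), (1.5, 3.5),
                              noise_sd_H=-1)


def _single_conifer(h=15.0, r=3.0, dbh=20.0):
    return TreeRecord(tree_id=0, plot_id=1, species="larch",
                      x=10.0, y=10.0, H=h, DBH=dbh, R=r)


class TestRenderPointCloud:
    def test_apex_is_height_maximum(self):
        cloud = sf.render_point_cloud([_single_conifer()], mode="ALS",
                                      density=100, extent=(0, 0, 20, 20),
                                      noise_sd_z=0.0, seed=1)
        assert cloud.z.max() == pytest.approx(15.0)

    def test_apex_with_noise_stays_below_cap(self):
        sigma = 0.1
        cloud = sf.render_point_cloud([_single_conifer()], mode="ALS",
                                      density=100, extent=(0, 0, 20, 20),
                                      noise_sd_z=sigma, seed=1)
        assert 15.0 - 3 * sigma <= cloud.z.max() <= 15.0

    def test_tls_trunk_slice_is_exact_circle(self):
        cloud = sf.render_point_cloud([_single_conifer(dbh=20.0)],
                                      mode="TLS", density=50,
                                      extent=(0, 0, 20, 20),
                                      noise_sd_z=0.0, seed=2)
        z = cloud.z
        sel = np.abs(z - 1.3) <= 0.05
        # only trunk points live at that height for this stand
        d = np.hypot(cloud.x[sel] - 10.0, cloud.y[sel] - 10.0)
        assert sel.sum() >= 50
        np.testing.assert_allclose(d, 0.10, rtol=1e-9)

    def test_density_contract(self):
        cloud = sf.render_point_cloud([], mode="ALS", density=2281.92,
                                      extent=(0, 0, 10, 10), seed=3)
        assert len(cloud) == pytest.approx(228192, rel=0.10)

    def test_empty_stand_is_all_ground(self):
        cloud = sf.render_point_cloud([], mode="ALS", density=50,
                                      extent=(0, 0, 10, 10), seed=4)
        assert np.all(cloud.labels == GROUND)

    def test_crown_labels_marked_vegetation(self):
        cloud = sf.render_point_cloud([_single_conifer()], mode="ALS",
                                      density=100, extent=(0, 0, 20, 20),
                                      seed=5)
        veg = cloud.labels == HIGH_VEGETATION
        assert veg.any()
        d = np.hypot(cloud.x[veg] - 10.0, cloud.y[veg] - 10.0)
        assert d.max() <= 3.0 + 1e-9

    def test_determinism(self):
        t = [_single_conifer()]
        a = sf.render_point_cloud(t, density=80, extent=(0, 0, 20, 20),
                                  noise_sd_z=0.05, seed=9)
        b = sf.render_point_cloud(t, density=80, extent=(0, 0, 20, 20),
                                  noise_sd_z=0.05, seed=9)
        np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_errors(self):
        with pytest.raises(ValueError, match="density"):
            sf.render_point_cloud([], density=-1, extent=(0, 0, 10, 10))
        with pytest.raises(ValueError, match="area"):
            sf.render_point_cloud([_single_conifer()], density=10,
                                  extent=(0, 0, 0, 10))
        with pytest.raises(ValueError, match="outside"):
            sf.render_point_cloud([_single_conifer()], density=10,
                                  extent=(50, 50, 60, 60))
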