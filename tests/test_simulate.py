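"""Synthetic-data generator: determinism, calibration, ground-truth links."""

import numpy as np
import pandas as pd
import pytest

from beescape.landscape import (
    PERIODS,
    QUADRAT_AREA_M2,
    check_no_overlap,
    landtype_median,
    landscape_resource_table,
    transect_density,
)
from beescape.simulate import (
    LAND_TYPES,
    SimulationConfig,
    generate_floral_data,
    generate_landscape,
    generate_predictor_panel,
    generate_species_pool,
    generate_visits,
    standardize,
    true_density_table,
)


@pytest.fixture(scope="module")
def small_world():
    cfg = SimulationConfig(seed=5, n_sites=6, n_locations=20, patches_per_tile=25)
    patches, locations = generate_landscape(cfg)
    return cfg, patches, locations


class TestLandscapeGeneration:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=99, n_sites=3, n_locations=8)
        p1, l1 = generate_landscape(cfg)
        p2, l2 = generate_landscape(cfg)
        pd.testing.assert_frame_equal(l1, l2)
        assert [p.polygon.wkt for p in p1] == [p.polygon.wkt for p in p2]

    def test_patches_tile_without_overlap(self, small_world):
        _, patches, _ = small_world
        check_no_overlap(patches, tol=1e-3)

    def test_locations_inside_resource_patches(self, small_world):
        from shapely.geometry import Point

        _, patches, locations = small_world
        resource = [p for p in patches if p.category == "resource_providing"]
        for loc in locations.itertuples(index=False):
            pt = Point(loc.x_m, loc.y_m)
            assert any(p.polygon.buffer(1e-6).contains(pt) for p in resource)

    def test_location_count_and_sites(self, small_world):
        _, _, locations = small_world
        assert len(locations) == 20
        assert locations["site_id"].nunique() == 6

    def test_category_proportions_converge(self):
        """At many patches the realised area proportions approach the
        configured ones (law of large numbers)."""
        cfg = SimulationConfig(seed=1, n_sites=13, n_locations=26, patches_per_tile=40)
        patches, _ = generate_landscape(cfg)
        total = sum(p.polygon.area for p in patches)
        by_cat = {}
        for p in patches:
            by_cat[p.category] = by_cat.get(p.category, 0.0) + p.polygon.area
        for cat, want in cfg.category_proportions.items():
            got = by_cat.get(cat, 0.0) / total
            assert got == pytest.approx(want, abs=0.05)


class TestFloralGeneration:
    def test_zero_intensity_gives_no_counts(self, small_world):
        cfg, patches, locations = small_world
        dens = true_density_table(cfg, np.random.default_rng(0))
        dens["true_density_mm3_m2"] = 0.0
        out = generate_floral_data(
            cfg, patches, locations, np.random.default_rng(1), density=dens
        )
        assert out["quadrats"].empty

    def test_expected_transect_density_matches_truth(self):
        """With heavy replication the mean estimated transect density for a
        land type converges on the generating true density."""
        cfg = SimulationConfig(
            seed=2, n_sites=4, n_locations=80, patches_per_tile=12,
            quadrat_dispersion=5.0,
        )
        rng = np.random.default_rng(3)
        patches, locations = generate_landscape(cfg, rng)
        out = generate_floral_data(cfg, patches, locations, rng)
        dens = out["density"].set_index(["land_type", "period"])
        land_of = locations.set_index("location_id")["land_type"]
        ratios = []
        est = {}
        for (loc, period), grp in out["quadrats"].groupby(["location_id", "period"]):
            lt = land_of.loc[loc]
            est.setdefault((lt, period), []).append(
                transect_density(grp, out["volumes"])
            )
        for (lt, period), vals in est.items():
            if len(vals) < 15:
                continue
            truth = float(dens.loc[(lt, period), "true_density_mm3_m2"])
            ratios.append(np.mean(vals) / truth)
        assert ratios, "need at least one well-replicated land type"
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_species_pool_has_cucurbits_and_capitula(self, rng):
        cfg = SimulationConfig(seed=4)
        pool = generate_species_pool(cfg, rng)
        assert {"Cucurbita_pepo", "Cucumis_sativus"} <= set(pool["species_id"])
        assert (pool["floral_unit"] == "capitulum").any()
        assert (pool[["length_mm", "width_mm", "height_mm"]] > 0).all().all()


class TestVisitGeneration:
    def test_mean_matches_analytic_expectation(self):
        """Simulated mean of y matches (1−π)·mean(μ) within Monte-Carlo
        error at large n."""
        cfg = SimulationConfig(seed=6, hypothesis="H0", pi=0.2, theta=2.0,
                               sigma2_site=0.0, sigma2_period=0.0, beta0=0.5)
        rng = np.random.default_rng(8)
        panel = generate_predictor_panel(20, 65, rng)  # 5200 rows
        out, truth = generate_visits(cfg, panel, rng)
        minutes = out["observation_time"].to_numpy(dtype=float)
        mu = np.exp(cfg.beta0) * minutes
        expect = (1 - cfg.pi) * mu
        assert out["visits"].mean() == pytest.approx(expect.mean(), rel=0.05)

    def test_doubling_observation_time_doubles_expected_counts(self):
        cfg = SimulationConfig(seed=6, hypothesis="H0", pi=0.0, theta=5.0,
                               sigma2_site=0.0, sigma2_period=0.0)
        rng = np.random.default_rng(9)
        panel = generate_predictor_panel(12, 40, rng)
        panel["observation_time"] = 30.0
        y1, _ = generate_visits(cfg, panel, np.random.default_rng(10))
        panel2 = panel.copy()
        panel2["observation_time"] = 60.0
        y2, _ = generate_visits(cfg, panel2, np.random.default_rng(11))
        assert y2["visits"].mean() / y1["visits"].mean() == pytest.approx(2.0, abs=0.15)

    def test_h2b_effect_is_negative(self):
        cfg = SimulationConfig(seed=7, hypothesis="H2b")
        rng = np.random.default_rng(12)
        panel = generate_predictor_panel(10, 4, rng)
        _, truth = generate_visits(cfg, panel, rng)
        assert truth["effects"]["present_fr"] < 0

    def test_determinism(self):
        cfg = SimulationConfig(seed=123, hypothesis="H3b")
        p1 = generate_predictor_panel(5, 4, np.random.default_rng(123))
        p2 = generate_predictor_panel(5, 4, np.random.default_rng(123))
        pd.testing.assert_frame_equal(p1, p2)
        v1, t1 = generate_visits(cfg, p1, np.random.default_rng(5))
        v2, t2 = generate_visits(cfg, p2, np.random.default_rng(5))
        pd.testing.assert_frame_equal(v1, v2)
        assert t1 == t2


class TestPanelStructure:
    def test_change_in_fr_nonpositive_and_cumulative_exceeds_present(self):
        panel = generate_predictor_panel(15, 5, np.random.default_rng(3))
        assert (panel["change_in_fr"] <= 1e-9).all()
        assert (panel["cumulative_fr"] >= panel["present_fr"] - 1e-9).all()

    def test_standardize_zscores(self):
        panel = generate_predictor_panel(10, 5, np.random.default_rng(4))
        z = standardize(panel)
        for c in ("present_fr", "cumulative_fr"):
            assert z[c].mean() == pytest.approx(0.0, abs=1e-9)
            assert z[c].std(ddof=0) == pytest.approx(1.0, rel=1e-6)


class TestImputationGap:
    def test_gap_vanishes_without_unknown_land(self):
        """With no unknown or soybean area the median and minimum variants
        of the landscape totals coincide exactly."""
        cfg = SimulationConfig(
            seed=8,
            n_sites=4,
            n_locations=10,
            patches_per_tile=15,
            category_proportions={
                "non_resource": 0.5,
                "resource_providing": 0.5,
                "unknown": 0.0,
                "soybean": 0.0,
            },
        )
        rng = np.random.default_rng(13)
        patches, locations = generate_landscape(cfg, rng)
        out = generate_floral_data(cfg, patches, locations, rng)
        land_of = locations.set_index("location_id")["land_type"]
        rows = [
            {
                "location_id": loc,
                "land_type": land_of.loc[loc],
                "period": period,
                "density_mm3_m2": transect_density(grp, out["volumes"]),
            }
            for (loc, period), grp in out["quadrats"].groupby(["location_id", "period"])
        ]
        medians = landtype_median(pd.DataFrame(rows))
        # complete the median table so no resource land type is demoted to
        # unknown for lack of sampling: the invariant under test is purely
        # "no unknown area -> no imputation gap"
        resource_types = sorted(
            {p.land_type for p in patches if p.category == "resource_providing"}
        )
        full_index = pd.MultiIndex.from_product(
            [resource_types, list(PERIODS)], names=["land_type", "period"]
        )
        medians = (
            medians.set_index(["land_type", "period"])
            .reindex(full_index, fill_value=0.0)
            .reset_index()
        )
        table = landscape_resource_table(patches, locations, medians, radii_m=[500])
        wide = table.pivot_table(
            index=["location_id", "period"], columns="variant", values="total_mm3"
        )
        np.testing.assert_allclose(wide["median"], wide["minimum"], rtol=1e-12)

    def test_minimum_below_median_with_unknown_land(self, small_world):
        cfg, patches, locations = small_world
        rng = np.random.default_rng(14)
        out = generate_floral_data(cfg, patches, locations, rng)
        land_of = locations.set_index("location_id")["land_type"]
        rows = [
            {
                "location_id": loc,
                "land_type": land_of.loc[loc],
                "period": period,
                "density_mm3_m2": transect_density(grp, out["volumes"]),
            }
            for (loc, period), grp in out["quadrats"].groupby(["location_id", "period"])
        ]
        medians = landtype_median(pd.DataFrame(rows))
        table = landscape_resource_table(patches, locations, medians, radii_m=[500])
        wide = table.pivot_table(
            index=["location_id", "period"], columns="variant", values="total_mm3"
        )
        assert (wide["minimum"] <= wide["median"] + 1e-9).all()
        assert (wide["minimum"] < wide["median"] - 1e-9).any()
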