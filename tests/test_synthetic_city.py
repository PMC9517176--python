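"""Synthetic-city generator: determinism, counts, distributions, truth."""

import numpy as np
import pytest
from shapely.strtree import STRtree

from urban3d.landscape3d import estimate_height
from urban3d.stats import one_way_anova
from urban3d.synthetic_city import (
    CityConfig,
    SyntheticTruth,
    area_per_site,
    generate_buildings,
    generate_gwr_testbed,
    generate_meteorology,
    generate_monitoring_panel,
    generate_parcels,
    generate_roads,
    write_city,
    generate_city,
    zone_mean_heights,
)


class TestConfigValidation:
    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            CityConfig(n_sites=0)
        with pytest.raises(ValueError):
            CityConfig(n_months=0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            CityConfig(noise_sd=-1.0)


class TestParcels:
    def test_zone_counts_match_study_design(self, default_city_seed0):
        cands = default_city_seed0["candidates"]
        counts = {
            t: sum(1 for c in cands if c.intended_type == t)
            for t in ("industrial", "educational", "residential", "commercial")
        }
        assert counts == {"industrial": 16, "educational": 14,
                          "residential": 18, "commercial": 13}

    def test_zone_areas_within_ranges(self, default_city_seed0):
        cfg = default_city_seed0["config"]
        for c in default_city_seed0["candidates"]:
            if c.intended_type == "mixed":
                continue
            spec = cfg.zone_specs[c.intended_type]
            area = c.polygon.area / 1e6
            assert spec.area_min_km2 - 1e-9 <= area <= spec.area_max_km2 + 1e-9

    def test_mixed_candidates_have_no_dominant_class(self, default_city_seed0):
        from urban3d.zoning import classify_zone

        parcels = default_city_seed0["parcels"]
        for c in default_city_seed0["candidates"]:
            if c.intended_type != "mixed":
                continue
            shares = {}
            for p in parcels:
                if p.parcel_id and p.parcel_id.startswith(c.zone_id):
                    inter = p.geometry.intersection(c.polygon).area
                    shares[p.land_use] = shares.get(p.land_use, 0) + inter / c.polygon.area
            assert classify_zone(shares) is None

    def test_seed_determinism_is_byte_level(self, tmp_path):
        cfgs = [CityConfig(seed=5), CityConfig(seed=5)]
        files = []
        for i, cfg in enumerate(cfgs):
            city = generate_city(cfg)
            out = tmp_path / f"run{i}"
            write_city(city, out)
            files.append((out / "parcels.geojson").read_bytes())
        assert files[0] == files[1]

    def test_different_seed_differs(self):
        p1, _ = generate_parcels(CityConfig(seed=1))
        p2, _ = generate_parcels(CityConfig(seed=2))
        assert len(p1) != len(p2) or any(
            a.geometry.bounds != b.geometry.bounds for a, b in zip(p1, p2)
        )


class TestBuildings:
    def test_footprints_pairwise_disjoint_within_zone(self, default_city_seed0):
        cfg = default_city_seed0["config"]
        buildings = generate_buildings(cfg, default_city_seed0["candidates"])
        zone_id = buildings[0].zone_id
        geoms = [b.footprint for b in buildings if b.zone_id == zone_id]
        tree = STRtree(geoms)
        for i, g in enumerate(geoms):
            for j in tree.query(g):
                if j != i:
                    assert not geoms[j].intersects(g)

    def test_count_tracks_density_times_area(self, default_city_seed0):
        cfg = default_city_seed0["config"]
        buildings = generate_buildings(cfg, default_city_seed0["candidates"])
        per_zone = {}
        for b in buildings:
            per_zone[b.zone_id] = per_zone.get(b.zone_id, 0) + 1
        for c in default_city_seed0["candidates"]:
            if c.intended_type == "mixed":
                continue
            expected = cfg.zone_specs[c.intended_type].density_per_km2 * c.polygon.area / 1e6
            if expected >= 30:  # rounding dominates tiny zones
                assert abs(per_zone[c.zone_id] - expected) / expected <= 0.10

    def test_industrial_zones_lower_than_residential(self, default_city_seed0):
        cfg = default_city_seed0["config"]
        buildings = generate_buildings(cfg, default_city_seed0["candidates"])
        means = zone_mean_heights(buildings, default_city_seed0["candidates"])
        assert np.mean(means["industrial"]) < np.mean(means["residential"])

    def test_zone_type_height_anova_rejects(self, default_city_seed0):
        """Zone-type height distributions differ: one-way ANOVA on zone mean
        heights across the four types rejects at the 5% level."""
        cfg = default_city_seed0["config"]
        buildings = generate_buildings(cfg, default_city_seed0["candidates"])
        means = zone_mean_heights(buildings, default_city_seed0["candidates"])
        table = one_way_anova([means[t] for t in
                               ("industrial", "educational", "residential", "commercial")])
        assert table.p < 0.05

    def test_heights_follow_storey_rule(self, default_city_seed0):
        cfg = default_city_seed0["config"]
        buildings = generate_buildings(cfg, default_city_seed0["candidates"])
        for b in buildings[::301]:
            assert b.height == pytest.approx(estimate_height(b.floors, b.use_class))


class TestPanel:
    def test_record_count_is_sites_times_months(self, default_city_seed0):
        panel = default_city_seed0["panel"]
        assert len(panel) == 16 * 12

    def test_zero_noise_reproduces_truth_equation(self):
        from urban3d import lur

        cfg = CityConfig(seed=11, noise_sd=0.0, noise_rel=None)
        parcels, cands = generate_parcels(cfg)
        roads = generate_roads(cfg)
        truth = SyntheticTruth()
        panel = generate_monitoring_panel(cfg, parcels, roads, truth, candidates=cands)
        sites = panel[["site_id", "x", "y"]].drop_duplicates("site_id")
        pred = lur.predictor_table(sites, parcels, roads)
        met_t = lur.transform_met(panel[list(truth.met_stats)], truth.met_stats,
                                  truth.met_scale)
        expected = np.full(len(panel), truth.coefficients["Intercept"])
        for name, coef in truth.coefficients.items():
            if name == "Intercept":
                continue
            if name in truth.met_stats:
                expected += coef * met_t[name].to_numpy()
            else:
                expected += coef * pred.loc[panel["site_id"], name].to_numpy()
        assert np.max(np.abs(panel["PM25"].to_numpy() - expected)) < 1e-10

    def test_panel_seed_determinism(self, default_city_seed0):
        cfg = default_city_seed0["config"]
        truth = SyntheticTruth()
        again = generate_monitoring_panel(
            cfg,
            default_city_seed0["parcels"],
            default_city_seed0["roads"],
            truth,
            candidates=default_city_seed0["candidates"],
        )
        assert again.equals(default_city_seed0["panel"])

    def test_meteorology_monthly_city_level(self):
        met = generate_meteorology(CityConfig(seed=2))
        assert len(met) == 12
        assert (met["PRS_Sea"] > met["PRS"]).all()  # sea-level reduction adds


class TestGWRTestbed:
    def test_point_and_response_counts(self):
        tb = generate_gwr_testbed(CityConfig(seed=1), SyntheticTruth(), n=75)
        assert tb.coords.shape == (75, 2)
        assert len(tb.y) == 75

    def test_zero_noise_is_exactly_linear_in_truth(self):
        tb = generate_gwr_testbed(CityConfig(seed=1), SyntheticTruth(), n=50, noise_rel=0.0)
        recon = tb.true_betas[:, 0] + np.sum(tb.true_betas[:, 1:] * tb.X, axis=1)
        assert np.max(np.abs(tb.y - recon)) < 1e-12

    def test_constant_surfaces_give_global_linear_model(self):
        truth = SyntheticTruth(
            gwr_surfaces={"intercept": (5.0, 0.0, 0.0), "x1": (2.0, 0.0, 0.0)}
        )
        tb = generate_gwr_testbed(CityConfig(seed=4), truth, n=40, noise_rel=0.0)
        assert np.max(np.abs(tb.y - (5.0 + 2.0 * tb.X[:, 0]))) < 1e-12

    def test_surfaces_include_monotone_gradients(self):
        truth = SyntheticTruth()
        a, b, c = truth.gwr_surfaces["x1"]
        assert b < 0  # west -> east decreasing
        a2, b2, c2 = truth.gwr_surfaces["x2"]
        assert c2 != 0  # north -> south gradient present


def test_area_per_site_reproduces_study_density():
    assert round(area_per_site(562.46, 16)) == 35
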