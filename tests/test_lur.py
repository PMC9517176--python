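"""LUR chain: buffer extraction, screening, stepwise fit, CV, prediction."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from urban3d import lur
from urban3d.io import Parcel, Road
from urban3d.synthetic_city import (
    CityConfig,
    SyntheticTruth,
    generate_monitoring_panel,
    generate_parcels,
    generate_roads,
)

BIG = box(-20000, -20000, 20000, 20000)


def unions(parcels):
    return lur.build_landuse_unions(parcels)


class TestBufferExtraction:
    def test_buffer_inside_single_class(self):
        lu = unions([Parcel(geometry=BIG, land_use="ecological")])
        out = lur.extract_buffer_variables(Point(0, 0), lu, lur.build_road_unions([]), (500,))
        assert out["VEG500"] == pytest.approx(1.0, abs=1e-12)
        assert out["INDU500"] == 0.0
        assert out["MROAD500"] == 0.0

    def test_half_disc_share(self):
        # ecological half-plane through the site centre
        lu = unions([Parcel(geometry=box(-20000, -20000, 0, 20000), land_use="ecological")])
        out = lur.extract_buffer_variables(Point(0, 0), lu, lur.build_road_unions([]), (1000,))
        assert out["VEG1000"] == pytest.approx(0.5, abs=1e-6)

    def test_tessellation_invariance(self):
        """Merging parcels of one class leaves the extraction unchanged."""
        split = [
            Parcel(geometry=box(-5000, -5000, 0, 5000), land_use="ecological"),
            Parcel(geometry=box(0, -5000, 5000, 5000), land_use="ecological"),
        ]
        merged = [Parcel(geometry=box(-5000, -5000, 5000, 5000), land_use="ecological")]
        site = Point(120, -340)
        rd = lur.build_road_unions([])
        a = lur.extract_buffer_variables(site, unions(split), rd, (500, 2000))
        b = lur.extract_buffer_variables(site, unions(merged), rd, (500, 2000))
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_veg_aggregates_water_and_ecological(self):
        """VEG is the union of ecological and water; on disjoint halves the
        joint share equals the sum of the separate shares."""
        eco = Parcel(geometry=box(-20000, -20000, 0, 20000), land_use="ecological")
        wat = Parcel(geometry=box(0, -20000, 20000, 20000), land_use="water")
        rd = lur.build_road_unions([])
        both = lur.extract_buffer_variables(Point(0, 0), unions([eco, wat]), rd, (1000,))
        only_eco = lur.extract_buffer_variables(Point(0, 0), unions([eco]), rd, (1000,))
        only_wat = lur.extract_buffer_variables(Point(0, 0), unions([wat]), rd, (1000,))
        assert both["VEG1000"] == pytest.approx(
            only_eco["VEG1000"] + only_wat["VEG1000"], abs=1e-12
        )

    def test_road_density_units(self):
        # one straight main road through the buffer: length = diameter
        roads = [Road(geometry=LineString([(-5000, 0), (5000, 0)]), road_class="main")]
        rd = lur.build_road_unions(roads)
        out = lur.extract_buffer_variables(Point(0, 0), unions([]), rd, (1000,))
        buf = Point(0, 0).buffer(1000, quad_segs=32)
        assert out["MROAD1000"] == pytest.approx(2000.0 / buf.area, rel=1e-3)
        assert out["TAL1000"] == out["MROAD1000"]
        assert out["SROAD1000"] == 0.0


from shapely.geometry import LineString  # noqa: E402


class TestScreening:
    def test_family_winner_and_collinearity_pruning(self, rng):
        n = 200
        y = rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)  # latent driver of the collinear pair
        X = pd.DataFrame(
            {
                # VEG5000 tracks y closely, VEG500 loosely -> VEG500 dropped in stage 1
                "VEG5000": y + rng.normal(0, 0.3, n),
                "VEG500": y + rng.normal(0, 2.0, n),
                # two singleton met variables, mutually collinear but
                # unrelated to the response
                "PRS": z + rng.normal(0, 0.1, n),
                "TEM": z + rng.normal(0, 0.1, n),
                # an independent variable survives
                "WIN": rng.normal(0, 1, n),
            }
        )
        kept = lur.screen_variables(y, X)
        assert "VEG500" not in kept
        assert "VEG5000" in kept
        # exactly one of the collinear singleton pair survives
        assert ("PRS" in kept) != ("TEM" in kept)
        assert "WIN" in kept

    def test_orthogonal_family_winners_all_kept(self, rng):
        n = 100
        X = pd.DataFrame(
            {
                "VEG5000": rng.normal(0, 1, n),
                "INDU500": rng.normal(0, 1, n),
                "PRS": rng.normal(0, 1, n),
            }
        )
        y = rng.normal(0, 1, n)
        assert set(lur.screen_variables(y, X)) == {"VEG5000", "INDU500", "PRS"}

    def test_constant_column_excluded_with_warning(self, rng):
        X = pd.DataFrame({"VEG500": np.ones(30), "PRS": rng.normal(0, 1, 30)})
        with pytest.warns(UserWarning, match="constant"):
            kept = lur.screen_variables(rng.normal(0, 1, 30), X)
        assert kept == ["PRS"]


class TestStepwiseFit:
    def test_noiseless_identifiability(self, rng):
        """With a zero-noise response built from 4 variables plus 6 decoys,
        the stepwise keeps exactly the 4 and recovers them to machine
        precision."""
        n = 80
        names = ["VEG500", "INDU1000", "PRS", "TEM", "WAT500", "RAR1000",
                 "POP2000", "WIN", "RHU", "MROAD500"]
        X = pd.DataFrame(rng.normal(0, 1, (n, len(names))), columns=names)
        true = {"VEG500": -3.0, "INDU1000": 2.0, "PRS": -1.5, "TEM": 0.7}
        y = 10.0 + sum(c * X[v] for v, c in true.items())
        model = lur.fit_lur(y, X, names, enforce_signs="off")
        assert set(model.coefficients) == set(true)
        assert model.intercept == pytest.approx(10.0, abs=1e-8)
        for v, c in true.items():
            assert model.coefficients[v] == pytest.approx(c, abs=1e-8)

    def test_sign_enforcement_removes_contradictory_buffered(self, rng):
        """A buffered variable whose true effect contradicts its assumed
        direction is removed when enforcement is on, kept when off."""
        n = 200
        X = pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=["VEG500", "INDU500"])
        # VEG acting positively contradicts its assumed negative direction
        y = 5.0 + 2.0 * X["VEG500"] + 1.0 * X["INDU500"] + rng.normal(0, 0.1, n)
        kept_on = lur.fit_lur(y, X, ["VEG500", "INDU500"], enforce_signs="buffered")
        assert "VEG500" not in kept_on.coefficients
        kept_off = lur.fit_lur(y, X, ["VEG500", "INDU500"], enforce_signs="off")
        assert "VEG500" in kept_off.coefficients

    def test_pure_noise_rarely_retains(self):
        """Under a pure-noise response the expected retention rate is at
        most about alpha per variable."""
        names = ["VEG500", "INDU500", "PRS", "TEM", "WIN"]
        total = 0
        runs = 20
        for s in range(runs):
            r = np.random.default_rng(s)
            X = pd.DataFrame(r.normal(0, 1, (60, len(names))), columns=names)
            y = r.normal(0, 1, 60)
            model = lur.fit_lur(y, X, names, enforce_signs="off")
            total += len(model.coefficients)
        assert total / (runs * len(names)) <= 2 * 0.10

    def test_empty_model_is_intercept_only(self, rng):
        X = pd.DataFrame({"VEG500": rng.normal(0, 1, 50)})
        y = pd.Series(np.full(50, 7.0) + rng.normal(0, 1e-3, 50))
        model = lur.fit_lur(y, X, ["VEG500"])
        if not model.coefficients:
            assert model.intercept == pytest.approx(float(np.mean(y)))
            assert model.settings.get("empty_model")


class TestCrossValidation:
    def test_perfect_model_scores_zero(self, rng):
        X = pd.DataFrame({"VEG500": rng.normal(0, 1, 40)})
        y = 20.0 + 3.0 * X["VEG500"]
        mae_rate, rmse = lur.cross_validate(y, X, ["VEG500"], split_seed=0)
        assert mae_rate == pytest.approx(0.0, abs=1e-10)
        assert rmse == pytest.approx(0.0, abs=1e-10)

    def test_seed_determinism(self, rng):
        X = pd.DataFrame({"VEG500": rng.normal(0, 1, 40)})
        y = 20.0 + 3.0 * X["VEG500"] + rng.normal(0, 1, 40)
        a = lur.cross_validate(y, X, ["VEG500"], split_seed=7)
        b = lur.cross_validate(y, X, ["VEG500"], split_seed=7)
        c = lur.cross_validate(y, X, ["VEG500"], split_seed=8)
        assert a == b
        assert a != c


class TestPredictSurface:
    def _model(self):
        return lur.LURModel(
            intercept=41.308,
            coefficients={"VEG5000": -5.921, "INDU500": 4.088},
            r2=1.0,
            adj_r2=1.0,
        )

    def test_background_cell_gives_intercept(self):
        raster = lur.predict_surface(
            self._model(), [], [], bounds=(0, 0, 400, 400), resolution=200
        )
        assert np.allclose(raster.values, 41.308)

    def test_full_vegetation_cell(self):
        parcels = [Parcel(geometry=box(-50000, -50000, 50000, 50000), land_use="ecological")]
        raster = lur.predict_surface(
            self._model(), parcels, [], bounds=(0, 0, 400, 400), resolution=200
        )
        assert np.allclose(raster.values, 41.308 - 5.921, atol=1e-9)

    def test_deterministic_output(self):
        parcels = [Parcel(geometry=box(0, 0, 5000, 5000), land_use="industrial")]
        a = lur.predict_surface(self._model(), parcels, [], (0, 0, 2000, 2000), 500)
        b = lur.predict_surface(self._model(), parcels, [], (0, 0, 2000, 2000), 500)
        assert np.array_equal(a.values, b.values)

    def test_surface_linearity_in_one_predictor(self):
        """Doubling one coefficient shifts every cell by coefficient x layer."""
        parcels = [Parcel(geometry=box(0, 0, 5000, 5000), land_use="ecological")]
        m1 = self._model()
        m2 = lur.LURModel(
            intercept=m1.intercept,
            coefficients={"VEG5000": 2 * -5.921, "INDU500": 4.088},
            r2=1.0, adj_r2=1.0,
        )
        a = lur.predict_surface(m1, parcels, [], (0, 0, 2000, 2000), 1000)
        b = lur.predict_surface(m2, parcels, [], (0, 0, 2000, 2000), 1000)
        layer = (b.values - a.values) / -5.921  # implied VEG5000 layer
        c = lur.predict_surface(
            lur.LURModel(intercept=0.0, coefficients={"VEG5000": 1.0}, r2=1, adj_r2=1),
            parcels, [], (0, 0, 2000, 2000), 1000,
        )
        assert np.allclose(layer, c.values, atol=1e-9)


class TestRecovery:
    def test_twenty_seed_coefficient_recovery(self):
        """Panels simulated from the reference equation at 1% relative noise:
        the pipeline recovers the intercept and the VEG5000 coefficient
        within 5 relative % in at least 18 of 20 seeds."""
        ok = 0
        for seed in range(100, 120):
            cfg = CityConfig(seed=seed)
            parcels, cands = generate_parcels(cfg)
            roads = generate_roads(cfg)
            truth = SyntheticTruth()
            panel = generate_monitoring_panel(cfg, parcels, roads, truth, candidates=cands)
            model = lur.build_lur(panel, parcels, roads)
            b0_ok = abs(model.intercept - 41.308) / 41.308 < 0.05
            bv = model.coefficients.get("VEG5000")
            bv_ok = bv is not None and abs(bv - (-5.921)) / 5.921 < 0.05
            ok += b0_ok and bv_ok
        assert ok >= 18
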