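"""Utilization distributions, overlap index, NSD fits and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import MultiPolygon, box

from migragen.movement import (
    MovementModel,
    NSDFit,
    RangePolygon,
    UtilizationDistribution,
    classify_animal,
    compute_io,
    compute_nsd,
    date_to_numeric,
    estimate_ud,
    isopleth,
    migration_params,
    reference_bandwidth,
    select_reference_point,
    _migrant,
)
from migragen.simulate import SimulationConfig, simulate_track
from conftest import make_track


def _range(geom):
    if not isinstance(geom, MultiPolygon):
        geom = MultiPolygon([geom])
    return RangePolygon(geometry=geom, area=geom.area, level=0.95)


def _gaussian_ud(sigma=1.0, cell=0.08, extent=6.0):
    x = np.arange(-extent, extent + cell, cell)
    y = np.arange(-extent, extent + cell, cell)
    d = np.exp(-0.5 * ((x[None, :] ** 2 + y[:, None] ** 2) / sigma**2))
    d /= d.sum() * cell**2
    return UtilizationDistribution(x, y, d, cell, sigma)


class TestUD:
    def test_reference_bandwidth_formula(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((1000, 2))
        h = reference_bandwidth(pts)
        sd = 0.5 * (pts[:, 0].std() + pts[:, 1].std())
        assert h == pytest.approx(sd * 1000 ** (-1 / 6), rel=1e-12)
        assert h == pytest.approx(0.316, abs=0.02)

    def test_grid_mass_is_one(self):
        rng = np.random.default_rng(1)
        ud = estimate_ud(rng.standard_normal((200, 2)) * 3.0)
        assert ud.mass == pytest.approx(1.0, abs=1e-6)

    def test_density_peak_near_centroid(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((500, 2)) + [10.0, -4.0]
        ud = estimate_ud(pts)
        iy, ix = np.unravel_index(ud.density.argmax(), ud.density.shape)
        assert abs(ud.x[ix] - pts[:, 0].mean()) < 3 * ud.h_ref
        assert abs(ud.y[iy] - pts[:, 1].mean()) < 3 * ud.h_ref

    def test_identical_points_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_ud(np.zeros((40, 2)))


class TestIsopleth:
    def test_gaussian_95_area_matches_closed_form(self):
        # 95% region of an isotropic bivariate normal: pi * chi2_2(0.95) * s^2
        from scipy.stats import chi2

        ud = _gaussian_ud(sigma=1.0)
        poly = isopleth(ud, 0.95)
        assert poly.area == pytest.approx(np.pi * chi2.ppf(0.95, 2), rel=0.03)

    def test_level_monotonicity(self):
        ud = _gaussian_ud()
        assert isopleth(ud, 0.99).area > isopleth(ud, 0.95).area

    def test_bimodal_input_gives_two_parts(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.standard_normal((200, 2)),
                         rng.standard_normal((200, 2)) + [40.0, 0.0]])
        poly = isopleth(estimate_ud(pts), 0.95)
        assert len(poly.geometry.geoms) == 2

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.5, 1.7])
    def test_invalid_level_rejected(self, level):
        with pytest.raises(ValueError):
            isopleth(_gaussian_ud(), level)


class TestIO:
    def test_identical_polygons_give_one(self):
        p = _range(box(0, 0, 2, 1))
        assert compute_io(p, p) == 1.0

    def test_disjoint_polygons_give_zero(self):
        assert compute_io(_range(box(0, 0, 1, 1)), _range(box(5, 5, 6, 6))) == 0.0

    def test_half_overlap_arithmetic(self):
        # A1 = A2 = 2, A12 = 1 -> IO = 2*1/(2+2) = 0.5
        a = _range(box(0, 0, 2, 1))
        b = _range(box(1, 0, 3, 1))
        assert compute_io(a, b) == pytest.approx(0.5, abs=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(0, 3), st.floats(0, 3), st.floats(-50, 50), st.floats(-50, 50))
    def test_symmetric_and_rigid_motion_invariant(self, w, h, dx, dy):
        a = _range(box(0, 0, 2 + w, 1 + h))
        b = _range(box(1, 0, 3, 2))
        io_ab = compute_io(a, b)
        assert io_ab == pytest.approx(compute_io(b, a), abs=1e-12)
        from shapely.affinity import translate

        a2 = _range(translate(a.geometry, dx, dy))
        b2 = _range(translate(b.geometry, dx, dy))
        assert compute_io(a2, b2) == pytest.approx(io_ab, abs=1e-9)


class TestDates:
    @pytest.mark.parametrize("date,day", [
        ("2017-01-01", 1),
        ("2017-04-10", 100),   # worked example: April 10 in a non-leap year
        ("2017-12-31", 365),
        ("2016-02-29", 60),
        ("2016-12-31", 366),
    ])
    def test_numeric_day(self, date, day):
        assert date_to_numeric(date) == day

    def test_invalid_date_raises(self):
        with pytest.raises(ValueError):
            date_to_numeric(3.14)


class TestNSD:
    def test_stationary_track_is_zero(self):
        ts = pd.date_range("2015-01-01 12:00", periods=30, freq="D")
        track = make_track(ts, np.ones((30, 2)) * 7)
        days, nsd = compute_nsd(track, 0)
        assert np.all(nsd == 0)
        np.testing.assert_array_equal(days, np.arange(1, 31))

    def test_straight_line_motion_quadratic(self):
        v = 3.0
        ts = pd.date_range("2015-01-01 12:00", periods=50, freq="D")
        xy = np.column_stack([v * np.arange(50), np.zeros(50)])
        track = make_track(ts, xy)
        days, nsd = compute_nsd(track, 0)
        np.testing.assert_allclose(nsd, (v * (days - 1)) ** 2)

    def test_non_track_reference_rejected(self):
        ts = pd.date_range("2015-01-01 12:00", periods=10, freq="D")
        track = make_track(ts, np.zeros((10, 2)))
        with pytest.raises(ValueError, match="not a track point"):
            compute_nsd(track, (99.0, 99.0))


class TestModelFits:
    def test_constant_series_selects_resident(self):
        res = MovementModel(np.full(365, 12.0)).fit()
        assert res.best.model == "resident"
        assert res.best.params["gamma"] == pytest.approx(12.0)

    def test_noiseless_migrant_recovered_within_one_percent(self):
        t = np.arange(1, 366, dtype=float)
        y = _migrant(t, 2500.0, 150.0, 5.0, 60.0, 5.0)
        best = MovementModel(y, t).fit().best
        assert best.model == "migrant"
        for name, truth in zip(("delta", "theta", "phi", "rho", "phi2"),
                               (2500.0, 150.0, 5.0, 60.0, 5.0)):
            assert best.params[name] == pytest.approx(truth, rel=0.01)

    def test_linear_series_selects_nomad(self):
        t = np.arange(1, 366, dtype=float)
        rng = np.random.default_rng(4)
        y = 4 * 1.5 * t + rng.normal(0, 20, t.size)
        res = MovementModel(y, t).fit()
        assert res.best.model == "nomad"
        assert res.best.params["D"] == pytest.approx(1.5, rel=0.05)

    def test_selection_only_over_converged_fits(self):
        res = MovementModel(np.full(365, 3.0)).fit()
        assert all(f.converged or f.model in res.fits for f in res.fits.values())
        assert res.best.model in res.fits

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            MovementModel(np.zeros(100))

    def test_summary_names_best_model(self):
        text = MovementModel(np.full(365, 5.0)).fit().summary()
        assert "best model: resident" in text


class TestReferencePoint:
    def test_stationary_track_resident_regardless_of_reference(self):
        ts = pd.date_range("2015-01-01 12:00", periods=365, freq="D")
        rng = np.random.default_rng(5)
        track = make_track(ts, rng.normal(0, 0.5, (365, 2)))
        idx, res = select_reference_point(track, n_candidate_days=30, step=10)
        assert res.best.model == "resident"

    def test_track_starting_mid_migration_prefers_later_reference(self):
        # first 20 days are the tail of a previous migration; the stable
        # winter range starts at day 21
        ts = pd.date_range("2015-01-01 12:00", periods=365, freq="D")
        rng = np.random.default_rng(6)
        xy = np.zeros((365, 2))
        xy[:20, 1] = np.linspace(30.0, 0.0, 20)          # arriving
        xy[150:260, 1] += 50.0                            # summer range
        xy += rng.normal(0, 1.0, (365, 2))
        track = make_track(ts, xy)
        idx, res = select_reference_point(track, n_candidate_days=40, step=5)
        # the day-1 candidate sits mid-descent (y = 30 km) and must lose to a
        # candidate on the settled winter range
        assert idx >= 10
        assert res.best.model in ("migrant", "mixed-migrant")

    def test_deterministic_choice(self):
        ts = pd.date_range("2015-01-01 12:00", periods=365, freq="D")
        rng = np.random.default_rng(7)
        xy = rng.normal(0, 2.0, (365, 2))
        track = make_track(ts, xy)
        a = select_reference_point(track, n_candidate_days=20, step=5)[0]
        b = select_reference_point(track, n_candidate_days=20, step=5)[0]
        assert a == b


def _fit(model, delta=2500.0):
    params = {"delta": delta, "theta": 140.0, "phi": 5.0, "rho": 60.0,
              "phi2": 5.0}
    if model == "resident":
        params = {"gamma": 30.0}
    return NSDFit(model, params, 1.0, 0.0, 365, True)


class TestClassification:
    def test_consistent_migrant_included(self):
        cls = classify_animal("a", {y: _fit("migrant") for y in (2014, 2015, 2016)})
        assert cls.final == "migrant" and cls.included

    def test_switcher_excluded(self):
        cls = classify_animal("a", {2014: _fit("migrant"), 2015: _fit("resident")})
        assert cls.final == "switcher" and not cls.included

    def test_single_resident_year_included(self):
        cls = classify_animal("a", {2015: _fit("resident")})
        assert cls.final == "resident" and cls.included

    def test_disperser_years_excluded_from_binary(self):
        cls = classify_animal("a", {2014: _fit("disperser"), 2015: _fit("migrant")})
        assert cls.yearly_binary[2014] is None
        assert cls.final == "migrant"

    def test_mixed_migrant_counts_as_migrant_by_default(self):
        cls = classify_animal("a", {2015: _fit("mixed-migrant")})
        assert cls.final == "migrant"


class TestMigrationParams:
    def test_distance_is_square_root_of_delta(self):
        p = migration_params("a", {2015: _fit("migrant", delta=2500.0)})
        assert p.distance_km == 50.0

    def test_multi_year_average(self):
        fits = {2014: _fit("migrant", delta=1600.0),
                2015: _fit("migrant", delta=3600.0)}
        p = migration_params("a", fits)
        assert p.distance_km == pytest.approx((40 + 60) / 2)

    def test_non_migrant_fit_rejected(self):
        with pytest.raises(ValueError, match="migrant"):
            migration_params("a", {2015: _fit("resident")})

    def test_latitudinal_shift_of_50km_northward_at_60N(self):
        # simulated migrant with summer range 50 km due north of winter
        from migragen.telemetry import EqualAreaProjection

        proj = EqualAreaProjection(lon0=-120.0, lat0=60.0)
        summer = _range(box(-5, 45, 5, 55))    # centred (0, 50)
        winter = _range(box(-5, -5, 5, 5))     # centred (0, 0)
        p = migration_params("a", {2015: _fit("migrant")},
                             ranges=[(summer, winter)], projection=proj)
        assert p.centroid_distance_km == pytest.approx(50.0, abs=1e-6)
        assert p.lat_shift_deg == pytest.approx(0.45, abs=0.01)
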