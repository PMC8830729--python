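"""Ingestion, projection, daily thinning, seasons and screening rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from migragen.telemetry import (
    EqualAreaProjection,
    SeasonWindow,
    TelemetryTrack,
    read_telemetry,
    thin_daily,
    assign_seasons,
    screen_for_io,
    screen_for_nsd,
)
from conftest import make_track


def _write_csv(tmp_path, rows, columns):
    path = tmp_path / "telemetry.csv"
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


class TestReadTelemetry:
    def test_clean_geographic_file_yields_tracks(self, tmp_path):
        rows = [
            (a, f"2015-06-{d:02d}T12:00:00", -120.0 + 0.01 * d, 60.0)
            for a in ("a1", "a2", "a3") for d in range(1, 6)
        ]
        path = _write_csv(tmp_path, rows,
                          ["animal_id", "timestamp", "longitude", "latitude"])
        tracks, proj = read_telemetry(path)
        assert len(tracks) == 3
        assert all(len(t) == 5 for t in tracks)
        assert proj is not None

    def test_projected_input_passes_through(self, tmp_path):
        rows = [("a1", "2015-06-01T12:00:00", 10.5, -3.25, "SYNTH-AEQA-KM")]
        path = _write_csv(tmp_path, rows,
                          ["animal_id", "timestamp", "x_km", "y_km", "crs"])
        tracks, proj = read_telemetry(path)
        assert proj is None
        assert tracks[0].fixes["x_km"].iloc[0] == 10.5
        assert tracks[0].fixes["y_km"].iloc[0] == -3.25

    def test_missing_column_names_the_column(self, tmp_path):
        path = _write_csv(tmp_path, [("2015-01-01", 0, 0)],
                          ["timestamp", "x_km", "y_km"])
        with pytest.raises(ValueError, match="animal_id"):
            read_telemetry(path)

    def test_unparseable_timestamp_reports_row(self, tmp_path):
        rows = [("a1", "2015-06-01T12:00:00", 0.0, 0.0),
                ("a1", "not-a-date", 0.0, 1.0)]
        path = _write_csv(tmp_path, rows,
                          ["animal_id", "timestamp", "x_km", "y_km"])
        with pytest.raises(ValueError, match="row 2"):
            read_telemetry(path)


class TestProjection:
    def test_one_degree_latitude_is_111_km(self):
        proj = EqualAreaProjection(lon0=-118.0, lat0=58.0)
        x1, y1 = proj.forward(-118.0, 57.5)
        x2, y2 = proj.forward(-118.0, 58.5)
        assert np.hypot(x2 - x1, y2 - y1) == pytest.approx(111.2, abs=0.5)

    def test_inverse_round_trip(self):
        proj = EqualAreaProjection(lon0=-130.0, lat0=62.0)
        lon = np.array([-132.0, -128.5, -130.0])
        lat = np.array([60.0, 63.5, 62.0])
        x, y = proj.forward(lon, lat)
        lon2, lat2 = proj.inverse(x, y)
        np.testing.assert_allclose(lon2, lon, atol=1e-9)
        np.testing.assert_allclose(lat2, lat, atol=1e-9)


class TestThinning:
    def test_hourly_fixes_reduce_to_noon_nearest(self):
        ts = pd.date_range("2015-03-01", periods=240, freq="h")
        track = make_track(ts, np.arange(480).reshape(240, 2))
        thinned = thin_daily(track)
        assert len(thinned) == 10
        assert (thinned.fixes["timestamp"].dt.hour == 12).all()

    def test_idempotent_on_daily_track(self):
        ts = pd.date_range("2015-03-01 09:00", periods=20, freq="D")
        track = make_track(ts, np.zeros((20, 2)))
        once = thin_daily(track)
        twice = thin_daily(once)
        pd.testing.assert_frame_equal(once.fixes, twice.fixes)

    def test_tie_keeps_earlier_fix(self):
        track = make_track(["2015-03-01 11:00", "2015-03-01 13:00"],
                           [[1.0, 1.0], [2.0, 2.0]])
        thinned = thin_daily(track)
        assert len(thinned) == 1
        assert thinned.fixes["x_km"].iloc[0] == 1.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=24 * 30 - 1),
                    min_size=1, max_size=60, unique=True))
    def test_thinning_never_increases_and_preserves_coordinates(self, hours):
        base = pd.Timestamp("2015-06-01")
        ts = [base + pd.Timedelta(hours=h) for h in sorted(hours)]
        xy = np.column_stack([np.arange(len(ts)), np.arange(len(ts))]).astype(float)
        track = make_track(ts, xy)
        thinned = thin_daily(track)
        assert len(thinned) <= len(track)
        assert len(thinned) == len({t.date() for t in ts})
        # kept coordinates appear exactly in the original
        orig = set(map(tuple, xy))
        kept = set(map(tuple, thinned.fixes[["x_km", "y_km"]].to_numpy()))
        assert kept <= orig


class TestSeasons:
    @pytest.mark.parametrize("date,season,season_year", [
        ("2010-12-15", "winter", 2011),   # December keys to the January side
        ("2011-08-01", "summer", 2011),
        ("2011-11-01", "none", 2011),
        ("2011-04-30", "winter", 2011),
        ("2011-09-15", "summer", 2011),
        ("2011-09-16", "none", 2011),
    ])
    def test_window_assignment(self, date, season, season_year):
        track = make_track([f"{date} 12:00"], [[0.0, 0.0]])
        out = assign_seasons(track).fixes
        assert out["season"].iloc[0] == season
        assert out["season_year"].iloc[0] == season_year

    def test_partition_is_exhaustive_and_disjoint(self):
        ts = pd.date_range("2014-01-01 12:00", "2015-12-31 12:00", freq="D")
        track = make_track(ts, np.zeros((len(ts), 2)))
        out = assign_seasons(track).fixes
        assert set(out["season"]) <= {"summer", "winter", "none"}
        assert len(out) == len(ts)


def _season_track(n_summer, n_winter, animal_id="a1", year=2015):
    """Winter Dec of ``year`` + summer Jul of ``year+1``: one season-year."""
    ts = list(pd.date_range(f"{year}-12-01 12:00", periods=n_winter, freq="D"))
    ts += list(pd.date_range(f"{year + 1}-07-01 12:00", periods=n_summer, freq="D"))
    # pad monitoring span past one year
    ts = [pd.Timestamp(f"{year}-06-01 12:00")] + ts + \
        [pd.Timestamp(f"{year + 1}-10-30 12:00")]
    track = make_track(ts, np.zeros((len(ts), 2)), animal_id)
    return assign_seasons(track)


class TestScreening:
    def test_29_winter_fixes_excluded_30_included(self):
        short = _season_track(40, 29, "short")
        exact = _season_track(30, 30, "exact")
        eligible, excl = screen_for_io([short, exact])
        ids = [a for a, _ in eligible]
        assert "exact" in ids and "short" not in ids
        assert (excl["animal_id"] == "short").any()

    def test_sub_year_monitoring_dropped(self):
        ts = pd.date_range("2015-07-01 12:00", periods=200, freq="D")
        track = assign_seasons(make_track(ts, np.zeros((200, 2)), "brief"))
        eligible, excl = screen_for_io([track])
        assert eligible == []
        assert "monitoring span" in excl["reason"].iloc[0]

    def test_planted_cohort_eligibility(self):
        # animal 'good' has full seasons in two season-years, 'gappy' in none
        good = _season_track(40, 60, "good")
        gappy = _season_track(25, 60, "gappy")
        eligible, _ = screen_for_io([good, gappy])
        assert eligible == [("good", 2016)]

    def test_nsd_complete_year_eligible(self):
        ts = pd.date_range("2015-01-01 12:00", periods=365, freq="D")
        track = make_track(ts, np.zeros((365, 2)))
        eligible, _ = screen_for_nsd([track], max_gap_days=1)
        assert eligible == [("a1", 2015)]

    def test_nsd_three_day_gap_fails_strict_daily_rule(self):
        ts = pd.date_range("2015-01-01 12:00", periods=365, freq="D")
        ts = ts.delete([100, 101, 102])
        track = make_track(ts, np.zeros((len(ts), 2)))
        eligible, excl = screen_for_nsd([track], max_gap_days=1)
        assert eligible == []
        eligible7, _ = screen_for_nsd([track], max_gap_days=7)
        assert eligible7 == [("a1", 2015)]
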