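"""GPS telemetry ingestion, projection, daily thinning and screening.

Collars record at heterogeneous intervals; all analyses downstream
assume at most one location per day, so tracks are thinned to the fix
nearest local noon (earlier fix wins ties).  Geographic coordinates are
projected onto a single Lambert azimuthal equal-area plane centred on
the dataset centroid so that inter-animal distances and centroids are
comparable in km.

Screening enforces the data-sufficiency rules of the analyses: the
range-overlap index needs >= 30 locations in each of summer and winter
of the same season-year, and movement-model classification needs a full
year of (near-)daily coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "TelemetryTrack",
    "SeasonWindow",
    "EqualAreaProjection",
    "read_telemetry",
    "thin_daily",
    "assign_seasons",
    "screen_for_io",
    "screen_for_nsd",
]


@dataclass
class EqualAreaProjection:
    """Lambert azimuthal equal-area projection on a spherical Earth (km)."""

    lon0: float
    lat0: float

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        k = np.sqrt(2.0 / denom)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam)
        y = EARTH_RADIUS_KM * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam)
        )
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        phi0 = np.radians(self.lat0)
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho == 0,
                phi0,
                np.arcsin(
                    np.clip(
                        np.cos(c) * np.sin(phi0)
                        + np.where(rho == 0, 0.0, y * np.sin(c) / np.maximum(rho, 1e-300))
                        * np.cos(phi0),
                        -1.0,
                        1.0,
                    )
                ),
            )
            lam = np.where(
                rho == 0,
                0.0,
                np.arctan2(
                    x * np.sin(c),
                    rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
                ),
            )
        return np.degrees(lam) + self.lon0, np.degrees(phi)


@dataclass
class TelemetryTrack:
    """Timestamped projected positions (km) for one animal."""

    animal_id: str
    fixes: pd.DataFrame  # columns: timestamp, x_km, y_km [+ season, season_year]
    crs: str = "aeqa-km"

    def __post_init__(self) -> None:
        xy = self.fixes[["x_km", "y_km"]].to_numpy(dtype=float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError(f"non-finite coordinates for {self.animal_id}")

    @property
    def span(self):
        if self.fixes.empty:
            return None
        ts = self.fixes["timestamp"]
        return ts.iloc[0], ts.iloc[-1]

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass(frozen=True)
class SeasonWindow:
    """Seasonal windows: summer 1 Jul–15 Sep, winter 1 Dec–30 Apr.

    Winter spans the year boundary; December fixes are keyed to the
    season-year of the following January–April block so each winter is
    contiguous under one key.
    """

    summer_start: tuple[int, int] = (7, 1)
    summer_end: tuple[int, int] = (9, 15)
    winter_start: tuple[int, int] = (12, 1)
    winter_end: tuple[int, int] = (4, 30)


REQUIRED_ANY = [["longitude", "latitude"], ["x_km", "y_km"]]


def read_telemetry(path, crs_config=None):
    """Read a telemetry CSV into per-animal tracks.

    Accepts either geographic columns (longitude/latitude, WGS84) —
    projected to a dataset-wide azimuthal equal-area plane in km — or
    already-projected ``x_km``/``y_km`` with a declared ``crs`` column,
    which pass through unchanged.  Returns ``(tracks, projection)``;
    projection is None for pre-projected input.
    """
    df = pd.read_csv(path)
    if "animal_id" not in df.columns:
        raise ValueError("schema error: missing required column 'animal_id'")
    if "timestamp" not in df.columns:
        raise ValueError("schema error: missing required column 'timestamp'")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(df["timestamp"], errors="coerce")
        bad = np.flatnonzero(parsed.isna().to_numpy())
        if bad.size:
            raise ValueError(
                f"unparseable timestamp at data row {bad[0] + 1}: "
                f"{df['timestamp'].iloc[bad[0]]!r}"
            )
        df["timestamp"] = parsed

    projection = None
    if {"x_km", "y_km"}.issubset(df.columns):
        crs = df["crs"].iloc[0] if "crs" in df.columns else (crs_config or "unknown")
    elif {"longitude", "latitude"}.issubset(df.columns):
        projection = EqualAreaProjection(
            lon0=float(df["longitude"].mean()), lat0=float(df["latitude"].mean())
        )
        df["x_km"], df["y_km"] = projection.forward(
            df["longitude"].to_numpy(), df["latitude"].to_numpy()
        )
        crs = f"aeqa-km:{projection.lon0:.4f},{projection.lat0:.4f}"
    else:
        raise ValueError(
            "schema error: need either 'longitude'/'latitude' or 'x_km'/'y_km'"
        )

    tracks = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        dup = grp["timestamp"].duplicated()
        if dup.any():
            logger.warning(
                "%s: %d duplicate timestamps collapsed (first kept)",
                animal_id, int(dup.sum()),
            )
            grp = grp[~dup]
        tracks.append(
            TelemetryTrack(
                animal_id=str(animal_id),
                fixes=grp[["timestamp", "x_km", "y_km"]].reset_index(drop=True),
                crs=str(crs),
            )
        )
    return tracks, projection


def thin_daily(track):
    """Reduce a track to one fix per calendar day (nearest local noon).

    Ties between fixes equidistant from 12:00 keep the earlier fix.
    Idempotent; kept coordinates are preserved exactly.
    """
    if track.fixes.empty:
        return track
    df = track.fixes
    ts = df["timestamp"]
    noon = ts.dt.normalize() + pd.Timedelta(hours=12)
    dist = (ts - noon).abs()
    order = np.lexsort((np.arange(len(df)), dist.to_numpy()))
    ranked = df.iloc[order]
    kept = ranked[~ranked["timestamp"].dt.date.duplicated()].sort_values("timestamp")
    return TelemetryTrack(track.animal_id, kept.reset_index(drop=True), track.crs)


def assign_seasons(track, seasons=SeasonWindow()):
    """Label each fix summer / winter / none with a season-year key.

    December winter fixes are keyed to the following calendar year so a
    winter (Dec–Apr) is one contiguous block per key; fixes outside both
    windows get season 'none' and their own calendar year.
    """
    df = track.fixes.copy()
    month, day, year = (
        df["timestamp"].dt.month.to_numpy(),
        df["timestamp"].dt.day.to_numpy(),
        df["timestamp"].dt.year.to_numpy(),
    )
    md = month * 100 + day
    s0 = seasons.summer_start[0] * 100 + seasons.summer_start[1]
    s1 = seasons.summer_end[0] * 100 + seasons.summer_end[1]
    w0 = seasons.winter_start[0] * 100 + seasons.winter_start[1]
    w1 = seasons.winter_end[0] * 100 + seasons.winter_end[1]
    in_summer = (md >= s0) & (md <= s1)
    in_winter_late = md >= w0          # Dec
    in_winter_early = md <= w1         # Jan–Apr
    season = np.where(in_summer, "summer",
                      np.where(in_winter_late | in_winter_early, "winter", "none"))
    season_year = year + np.where(in_winter_late, 1, 0)
    df["season"] = season
    df["season_year"] = season_year
    return TelemetryTrack(track.animal_id, df, track.crs)


def screen_for_io(tracks, min_locations=30, min_monitoring_days=365):
    """Animal-season-years eligible for the range-overlap analysis.

    Keeps (animal, season-year) pairs with at least ``min_locations``
    fixes in both summer and winter of that season-year; animals
    monitored for less than one year are dropped entirely.  Returns
    ``(eligible, exclusions)`` where eligible is a list of
    (animal_id, season_year) and exclusions a DataFrame of reasons.
    """
    eligible, exclusions = [], []
    for track in tracks:
        if track.fixes.empty:
            exclusions.append((track.animal_id, None, "empty track"))
            continue
        first, last = track.span
        span_days = (last.normalize() - first.normalize()).days + 1  # inclusive
        if span_days < min_monitoring_days:
            exclusions.append(
                (track.animal_id, None,
                 f"monitoring span {span_days} d < {min_monitoring_days} d")
            )
            logger.info("excluded %s: <1 year of monitoring", track.animal_id)
            continue
        df = track.fixes
        if "season" not in df.columns:
            raise ValueError("tracks must have season labels (run assign_seasons)")
        counts = (
            df[df["season"] != "none"]
            .groupby(["season_year", "season"])
            .size()
            .unstack(fill_value=0)
        )
        for season_year, row in counts.iterrows():
            n_summer = int(row.get("summer", 0))
            n_winter = int(row.get("winter", 0))
            if n_summer >= min_locations and n_winter >= min_locations:
                eligible.append((track.animal_id, int(season_year)))
            else:
                exclusions.append(
                    (track.animal_id, int(season_year),
                     f"summer={n_summer}, winter={n_winter} fixes "
                     f"(need >= {min_locations} each)")
                )
    excl_df = pd.DataFrame(exclusions, columns=["animal_id", "season_year", "reason"])
    for _, row in excl_df.iterrows():
        logger.info("IO screening excluded %s (%s): %s", *row)
    return eligible, excl_df


def screen_for_nsd(tracks, max_gap_days=1):
    """Animal-years eligible for movement-model classification.

    A calendar year is eligible when fixes span it end to end and the
    spacing between consecutive fixes never exceeds ``max_gap_days``
    (1 = literal daily coverage; a 3-day spacing needs max_gap_days
    >= 3).  The leading/trailing slack to 1 Jan / 31 Dec is held to the
    same limit.  Returns ``(eligible, exclusions)``.
    """
    eligible, exclusions = [], []
    for track in tracks:
        if track.fixes.empty:
            continue
        dates = track.fixes["timestamp"].dt.normalize()
        for year in sorted(dates.dt.year.unique()):
            in_year = dates[dates.dt.year == year].reset_index(drop=True)
            lead = int((in_year.iloc[0] - pd.Timestamp(f"{year}-01-01")).days)
            tail = int((pd.Timestamp(f"{year}-12-31") - in_year.iloc[-1]).days)
            spacing = in_year.diff().dt.days.dropna()
            max_spacing = int(spacing.max()) if len(spacing) else 366
            if (max_spacing <= max_gap_days
                    and lead <= max_gap_days - 1 and tail <= max_gap_days - 1):
                eligible.append((track.animal_id, int(year)))
            else:
                exclusions.append(
                    (track.animal_id, int(year),
                     f"coverage gap: lead={lead} d, tail={tail} d, "
                     f"max spacing={max_spacing} d (limit {max_gap_days} d)")
                )
                logger.info(
                    "NSD screening excluded %s year %d", track.animal_id, year
                )
    excl_df = pd.DataFrame(exclusions, columns=["animal_id", "year", "reason"])
    return eligible, excl_df
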