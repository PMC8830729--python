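"""Seasonal range overlap and net-squared-displacement classification.

Two complementary measures of migratory behaviour are computed per
animal:

* **Index of Overlap (IO)** between the 95% fixed-kernel isopleths of
  the summer and winter utilization distributions,
  ``IO = 2*A12 / (A1 + A2)`` — 0 for fully separated seasonal ranges
  (migrant-like), 1 for identical ranges (resident-like).

* **NSD model selection**: the daily net squared displacement series
  (km^2 from a reference point) is fit by five movement models —
  migrant (bell curve returning to the start), mixed-migrant (returns
  to an intermediate level), disperser (one-way sigmoid), nomad
  (linear) and resident (constant) — and the minimum-AIC model gives
  the annual classification.  The migrant model's residence time on the
  second range is bounded below by 30 days.

The model family is::

    migrant(t)       = d/(1+exp((th-t)/ph)) - d/(1+exp((t2-t)/ph2))
    mixed-migrant(t) = d/(1+exp((th-t)/ph)) - (d-d2)/(1+exp((t2-t)/ph2))
    disperser(t)     = d/(1+exp((th-t)/ph))
    nomad(t)         = 4*D*t
    resident(t)      = g
    with t2 = th + 2*ph + rho + 2*ph2,  rho >= 30 days

where d is the asymptotic NSD (km^2, sqrt(d) = separation of seasonal
ranges), th the departure inflection day, ph/ph2 transition duration
scales, rho the residence time on the second range, d2 the return
asymptote, D a diffusion rate, and g a constant.  AIC uses the Gaussian
residual likelihood, AIC = n*ln(RSS/n) + 2k with k = #parameters + 1.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union
from skimage import measure

from migragen.telemetry import TelemetryTrack

logger = logging.getLogger(__name__)

__all__ = [
    "UtilizationDistribution",
    "RangePolygon",
    "NSDFit",
    "MovementModel",
    "MovementModelResults",
    "MigrationClassification",
    "MigrationParams",
    "estimate_ud",
    "isopleth",
    "compute_io",
    "compute_nsd",
    "fit_movement_models",
    "select_reference_point",
    "classify_animal",
    "migration_params",
    "date_to_numeric",
    "reference_bandwidth",
]


# ---------------------------------------------------------------------------
# Utilization distribution and isopleths

@dataclass
class UtilizationDistribution:
    """Kernel utilization density on a regular grid (km, mass 1)."""

    x: np.ndarray          # (nx,) cell-centre eastings
    y: np.ndarray          # (ny,) cell-centre northings
    density: np.ndarray    # (ny, nx), integrates to 1
    cell: float            # km
    h_ref: float           # km

    @property
    def mass(self) -> float:
        return float(self.density.sum() * self.cell**2)


@dataclass
class RangePolygon:
    """A seasonal range: isopleth polygon(s) with area in km^2."""

    geometry: MultiPolygon
    area: float
    level: float
    season: str | None = None

    @property
    def centroid(self):
        c = self.geometry.centroid
        return float(c.x), float(c.y)


def reference_bandwidth(points):
    """Reference (normal-rule) bandwidth h_ref = 0.5*(sd_x+sd_y)*n^(-1/6)."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    return 0.5 * (pts[:, 0].std(ddof=0) + pts[:, 1].std(ddof=0)) * n ** (-1.0 / 6.0)


def estimate_ud(points, cell=None, pad_bandwidths=4.0):
    """Bivariate Gaussian kernel UD of seasonal fixes.

    Grid cell defaults to h_ref/4; the grid extends ``pad_bandwidths``
    bandwidths beyond the data so the isopleth closes.  Raises on
    degenerate (all-identical) input, which callers map to the resident
    shortcut.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    h = reference_bandwidth(pts)
    if not np.isfinite(h) or h <= 0:
        raise ValueError("degenerate input: all points identical (h_ref = 0)")
    if cell is None:
        cell = h / 4.0
    x0, x1 = pts[:, 0].min() - pad_bandwidths * h, pts[:, 0].max() + pad_bandwidths * h
    y0, y1 = pts[:, 1].min() - pad_bandwidths * h, pts[:, 1].max() + pad_bandwidths * h
    gx = np.arange(x0, x1 + cell, cell)
    gy = np.arange(y0, y1 + cell, cell)
    dx = (gx[None, :] - pts[:, 0][:, None]) / h          # (n, nx)
    dy = (gy[None, :] - pts[:, 1][:, None]) / h          # (n, ny)
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    density = ky.T @ kx                                   # (ny, nx)
    density /= density.sum() * cell**2
    return UtilizationDistribution(x=gx, y=gy, density=density, cell=cell, h_ref=h)


def isopleth(ud, level=0.95, season=None):
    """Smallest-density-threshold region holding >= ``level`` of UD mass.

    The threshold region is polygonised from the grid by marching
    squares; inner contours contained in an outer one become holes.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("isopleth level must lie in (0, 1)")
    d = ud.density
    flat = np.sort(d.ravel())[::-1]
    cum = np.cumsum(flat) * ud.cell**2
    k = int(np.searchsorted(cum, level))
    thr = flat[min(k, flat.size - 1)]
    # pad with zeros so contours at the grid edge close
    padded = np.pad(d, 1, mode="constant")
    contours = measure.find_contours(padded, thr)
    rings = []
    for c in contours:
        # rows are y, cols are x; remove the pad offset
        xs = ud.x[0] + (c[:, 1] - 1) * ud.cell
        ys = ud.y[0] + (c[:, 0] - 1) * ud.cell
        if len(xs) >= 4:
            poly = Polygon(np.column_stack([xs, ys]))
            if poly.is_valid and poly.area > 0:
                rings.append(poly)
    if not rings:
        raise ValueError("no isopleth contour found (degenerate UD)")
    rings.sort(key=lambda p: p.area, reverse=True)
    shells, holes = [], []
    for p in rings:
        container = next((s for s in shells if s.contains(p)), None)
        (holes if container is not None else shells).append(p)
    geom = unary_union(shells)
    for h in holes:
        geom = geom.difference(h)
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    return RangePolygon(geometry=geom, area=float(geom.area), level=level,
                        season=season)


def compute_io(summer, winter):
    """Index of Overlap IO = 2*A12 / (A1 + A2), clipped to [0, 1]."""
    a1, a2 = summer.area, winter.area
    if a1 + a2 <= 0:
        raise ValueError("undefined IO: zero total range area")
    a12 = summer.geometry.intersection(winter.geometry).area
    return float(np.clip(2.0 * a12 / (a1 + a2), 0.0, 1.0))


# ---------------------------------------------------------------------------
# NSD series and movement-model fits

def date_to_numeric(date):
    """Ordinal day within the year (1 Jan = 1; 29 Feb = 60 in leap years)."""
    if isinstance(date, str):
        date = pd.Timestamp(date)
    if isinstance(date, (pd.Timestamp, _dt.datetime)):
        date = date.date()
    if not isinstance(date, _dt.date):
        raise ValueError(f"not a calendar date: {date!r}")
    return date.timetuple().tm_yday


def compute_nsd(track, reference=0):
    """NSD series: squared km distance from a reference fix, per day.

    ``reference`` is the integer index of a fix in the (thinned) track;
    a coordinate pair is accepted only if it coincides with a track
    point.  Returns ``(days, nsd)`` with days counted from the first
    fix (day 1).
    """
    xy = track.fixes[["x_km", "y_km"]].to_numpy(dtype=float)
    if isinstance(reference, (int, np.integer)):
        if not (0 <= reference < len(xy)):
            raise ValueError(f"reference index {reference} out of range")
        ref = xy[reference]
    else:
        ref = np.asarray(reference, dtype=float)
        if not np.any(np.all(np.isclose(xy, ref, atol=1e-9), axis=1)):
            raise ValueError("reference point is not a track point")
    ts = track.fixes["timestamp"].dt.normalize()
    days = (ts - ts.iloc[0]).dt.days.to_numpy() + 1
    nsd = ((xy - ref) ** 2).sum(axis=1)
    return days.astype(float), nsd


def _clip_exp(z):
    return np.exp(np.clip(z, -500.0, 500.0))


def _migrant(t, d, th, ph, rho, ph2):
    t2 = th + 2 * ph + rho + 2 * ph2
    return d / (1 + _clip_exp((th - t) / ph)) - d / (1 + _clip_exp((t2 - t) / ph2))


def _mixed(t, d, th, ph, rho, ph2, d2):
    t2 = th + 2 * ph + rho + 2 * ph2
    return (d / (1 + _clip_exp((th - t) / ph))
            - (d - d2) / (1 + _clip_exp((t2 - t) / ph2)))


def _disperser(t, d, th, ph):
    return d / (1 + _clip_exp((th - t) / ph))


MODEL_PARAM_NAMES = {
    "resident": ("gamma",),
    "nomad": ("D",),
    "disperser": ("delta", "theta", "phi"),
    "migrant": ("delta", "theta", "phi", "rho", "phi2"),
    "mixed-migrant": ("delta", "theta", "phi", "rho", "phi2", "delta2"),
}
MODEL_ORDER = ("resident", "nomad", "disperser", "migrant", "mixed-migrant")
MIN_RESIDENCE_DAYS = 30.0
_RSS_FLOOR = 1e-12


@dataclass
class NSDFit:
    """One movement-model fit to an annual NSD series."""

    model: str
    params: dict
    rss: float
    aic: float
    n: int
    converged: bool
    reference_index: int = 0

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.model == "resident":
            return np.full_like(t, p["gamma"])
        if self.model == "nomad":
            return 4.0 * p["D"] * t
        if self.model == "disperser":
            return _disperser(t, p["delta"], p["theta"], p["phi"])
        if self.model == "migrant":
            return _migrant(t, p["delta"], p["theta"], p["phi"], p["rho"], p["phi2"])
        return _mixed(t, p["delta"], p["theta"], p["phi"], p["rho"], p["phi2"],
                      p["delta2"])


def _aic(rss, n, k):
    return n * np.log(max(rss, _RSS_FLOOR) / n) + 2 * (k + 1)


def _initial_guesses(t, y, rho_min):
    """Data-driven multi-start initials for the sigmoid family."""
    win = max(5, len(y) // 60)
    smooth = pd.Series(y).rolling(win, center=True, min_periods=1).mean().to_numpy()
    d0 = max(float(np.quantile(smooth, 0.95)), 1e-3)
    above = smooth >= d0 / 2
    th0 = float(t[np.argmax(above)]) if above.any() else float(np.median(t))
    n_above = int(above.sum())
    rho0 = max(rho_min, n_above - 20.0)
    guesses = [
        (d0, th0, 5.0, rho0, 5.0),
        (d0, th0, 10.0, max(rho_min, 60.0), 10.0),
        (float(np.max(y)) or 1e-3, max(1.0, th0 - 15.0), 5.0, rho0 + 30.0, 5.0),
    ]
    return guesses


class MovementModel:
    """NSD movement-model family fitted to one annual series.

    Parameters
    ----------
    nsd : array
        Daily net squared displacement (km^2).
    days : array, optional
        Day index of each value (default 1..n).
    """

    def __init__(self, nsd, days=None, min_days=360):
        self.nsd = np.asarray(nsd, dtype=float)
        self.days = (np.arange(1, len(self.nsd) + 1, dtype=float)
                     if days is None else np.asarray(days, dtype=float))
        if len(self.days) != len(self.nsd):
            raise ValueError("days and nsd must have equal length")
        if len(self.nsd) < min_days:
            raise ValueError(
                f"series too short: {len(self.nsd)} < {min_days} daily values"
            )

    def fit(self, models=MODEL_ORDER, rho_min=MIN_RESIDENCE_DAYS, n_starts=3):
        t, y, n = self.days, self.nsd, len(self.nsd)
        fits = {}
        for name in models:
            try:
                fit = self._fit_one(name, t, y, n, rho_min, n_starts)
            except Exception as exc:  # noqa: BLE001 - per-model isolation
                logger.warning("model %s failed to fit: %s", name, exc)
                continue
            if fit is not None:
                fits[name] = fit
        return MovementModelResults(self, fits)

    def _fit_one(self, name, t, y, n, rho_min, n_starts=3):
        if name == "resident":
            g = float(y.mean())
            rss = float(((y - g) ** 2).sum())
            return NSDFit("resident", {"gamma": g}, rss, _aic(rss, n, 1), n, True)
        if name == "nomad":
            denom = float((16.0 * t**2).sum())
            dcoef = float((4.0 * t * y).sum() / denom)
            rss = float(((y - 4.0 * dcoef * t) ** 2).sum())
            return NSDFit("nomad", {"D": dcoef}, rss, _aic(rss, n, 1), n, True)

        tmax = float(t.max())
        ymax = max(float(y.max()), 1e-3)
        best = None
        for d0, th0, ph0, rho0, ph20 in _initial_guesses(t, y, rho_min)[:n_starts]:
            if name == "disperser":
                x0 = [d0, th0, ph0]
                lo = [1e-6, 1.0, 0.5]
                hi = [4 * ymax, tmax, 200.0]
                fun = lambda p: _disperser(t, *p) - y
                k = 3
            elif name == "migrant":
                x0 = [d0, th0, ph0, rho0, ph20]
                lo = [1e-6, 1.0, 0.5, rho_min, 0.5]
                hi = [4 * ymax, tmax, 200.0, tmax, 200.0]
                fun = lambda p: _migrant(t, *p) - y
                k = 5
            else:  # mixed-migrant
                x0 = [d0, th0, ph0, rho0, ph20, 0.1 * d0]
                lo = [1e-6, 1.0, 0.5, rho_min, 0.5, 0.0]
                hi = [4 * ymax, tmax, 200.0, tmax, 200.0, 4 * ymax]
                fun = lambda p: _mixed(t, *p) - y
                k = 6
            x0 = np.clip(x0, lo, hi)
            try:
                sol = least_squares(fun, x0, bounds=(lo, hi), method="trf",
                                    max_nfev=2000)
            except Exception:
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol)
        if best is None:
            return None
        rss, sol = best
        params = dict(zip(MODEL_PARAM_NAMES[name], map(float, sol.x)))
        if not np.all(np.isfinite(sol.x)):
            return None
        return NSDFit(name, params, rss, _aic(rss, n, len(sol.x)), n,
                      bool(sol.success))


class MovementModelResults:
    """Fits of the movement-model family; selection is by minimum AIC."""

    def __init__(self, model, fits):
        self.model = model
        self.fits = fits

    @property
    def best(self):
        if not self.fits:
            raise ValueError("no model converged for this series")
        return min(
            self.fits.values(),
            key=lambda f: (f.aic, MODEL_ORDER.index(f.model)),
        )

    @property
    def aic_table(self):
        rows = [
            {"model": f.model, "k": len(f.params), "rss": f.rss, "aic": f.aic,
             "converged": f.converged}
            for f in sorted(self.fits.values(), key=lambda f: f.aic)
        ]
        return pd.DataFrame(rows)

    def summary(self):
        lines = ["Movement-model selection (NSD, Gaussian error)",
                 f"n = {len(self.model.nsd)} daily values", ""]
        lines.append(self.aic_table.to_string(index=False,
                                              float_format=lambda v: f"{v:.3f}"))
        b = self.best
        lines.append("")
        lines.append(f"best model: {b.model}")
        for k, v in b.params.items():
            lines.append(f"  {k:>7s} = {v:.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.days, self.model.nsd, ".", ms=2, alpha=0.5,
                label="NSD")
        t = np.linspace(self.model.days.min(), self.model.days.max(), 400)
        for f in self.fits.values():
            style = "-" if f.model == self.best.model else "--"
            ax.plot(t, f.predict(t), style, label=f"{f.model} (AIC {f.aic:.0f})")
        ax.set_xlabel("day")
        ax.set_ylabel("NSD (km$^2$)")
        ax.legend(fontsize=7)
        return ax


def fit_movement_models(nsd, days=None, min_days=360, models=MODEL_ORDER,
                        rho_min=MIN_RESIDENCE_DAYS, n_starts=3):
    """Fit all movement models to an NSD series; list of NSDFit by AIC."""
    res = MovementModel(nsd, days=days, min_days=min_days).fit(
        models=models, rho_min=rho_min, n_starts=n_starts
    )
    return res


def select_reference_point(track, n_candidate_days=60, step=1, min_days=360,
                           models=MODEL_ORDER, n_starts=3):
    """Choose the NSD reference fix minimizing the best-model AIC.

    Candidates are the fixes among the first ``n_candidate_days`` daily
    fixes (subsampled every ``step``); ties go to the earliest day.
    Returns ``(reference_index, results)`` for the winning candidate.
    """
    n = len(track.fixes)
    candidates = list(range(0, min(n_candidate_days, n), step))
    best = None
    for idx in candidates:
        days, nsd = compute_nsd(track, idx)
        try:
            res = MovementModel(nsd, days=days, min_days=min_days).fit(
                models=models, n_starts=n_starts)
            fit = res.best
        except ValueError:
            continue
        if best is None or fit.aic < best[1]:
            best = (idx, fit.aic, res)
    if best is None:
        raise ValueError(f"animal-year unclassifiable: no candidate fit "
                         f"converged for {track.animal_id}")
    idx, _, res = best
    for f in res.fits.values():
        f.reference_index = idx
    return idx, res


@dataclass
class MigrationClassification:
    """Across-year migrant/resident classification for one animal."""

    animal_id: str
    yearly: dict            # year -> model name of the min-AIC fit
    yearly_binary: dict     # year -> 'migrant' | 'resident' | None (excluded)
    final: str              # 'migrant' | 'resident' | 'switcher' | 'unclassified'
    included: bool          # usable in association analyses


def classify_animal(animal_id, fits_by_year,
                    migrant_models=("migrant", "mixed-migrant")):
    """Map per-year best models to a final migrant/resident class.

    Years whose best model is disperser or nomad are flagged and
    excluded from the binary phenotype.  Animals whose remaining years
    disagree are 'switcher' and excluded from association input.
    """
    yearly, binary = {}, {}
    for year, fit in fits_by_year.items():
        name = fit.model if isinstance(fit, NSDFit) else fit.best.model
        yearly[year] = name
        if name in migrant_models:
            binary[year] = "migrant"
        elif name == "resident":
            binary[year] = "resident"
        else:
            binary[year] = None
            logger.info("%s year %s: %s year excluded from binary phenotype",
                        animal_id, year, name)
    classes = {c for c in binary.values() if c is not None}
    if not classes:
        final, included = "unclassified", False
    elif len(classes) == 2:
        final, included = "switcher", False
    else:
        final, included = classes.pop(), True
    return MigrationClassification(animal_id, yearly, binary, final, included)


@dataclass
class MigrationParams:
    """Per-animal migration descriptors, averaged across years."""

    animal_id: str
    distance_km: float          # sqrt(delta)
    timing_day: float           # departure inflection, numeric day of year
    centroid_distance_km: float | None = None
    lat_shift_deg: float | None = None


def migration_params(animal_id, migrant_fits, ranges=None, projection=None,
                     start_dates=None):
    """Distance, timing and range-centroid metrics for a migrant.

    ``migrant_fits`` is a mapping year -> NSDFit of the migrant (or
    mixed-migrant) model.  Distance is sqrt(delta) km and timing the
    departure inflection day (numeric, 1 Jan = 1), both averaged across
    years.  When summer/winter RangePolygons are given, the Euclidean
    centroid distance is added; with a projection, the latitudinal
    shift (summer - winter centroid latitude) as well.
    """
    if not migrant_fits:
        raise ValueError("migration_params called with no migrant-model fits")
    for fit in migrant_fits.values():
        if fit.model not in ("migrant", "mixed-migrant"):
            raise ValueError(
                f"migration_params requires migrant fits, got {fit.model!r}"
            )
    distances, timings = [], []
    for year, fit in migrant_fits.items():
        distances.append(float(np.sqrt(fit.params["delta"])))
        theta = fit.params["theta"]
        if start_dates and year in start_dates:
            day = date_to_numeric(start_dates[year]) + theta - 1
            theta = ((day - 1) % 365) + 1
        timings.append(float(theta))
    cdist = lat_shift = None
    if ranges is not None:
        cds, shifts = [], []
        for summer, winter in ranges:
            cs, cw = np.array(summer.centroid), np.array(winter.centroid)
            cds.append(float(np.hypot(*(cs - cw))))
            if projection is not None:
                _, lat_s = projection.inverse(cs[0], cs[1])
                _, lat_w = projection.inverse(cw[0], cw[1])
                shifts.append(float(lat_s - lat_w))
        cdist = float(np.mean(cds)) if cds else None
        lat_shift = float(np.mean(shifts)) if shifts else None
    return MigrationParams(
        animal_id=animal_id,
        distance_km=float(np.mean(distances)),
        timing_day=float(np.mean(timings)),
        centroid_distance_km=cdist,
        lat_shift_deg=lat_shift,
    )
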