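"""Synthetic tracking data, wind grids and rasters with known ground
truth.

The generator reproduces the *statistical structure* the analysis
assumes — duty-cycled ARGOS and 10-min GPS cadences, daily travel of
roughly 120–220 km/day, multi-day stopovers, latitude-banded zonal
winds on a 2.5 deg / 6-h grid, and an elevation ridge blocking the
direct route — not behaviourally realistic birds.  Every stochastic
draw flows from one seeded generator per dataset and the generating
parameters are returned as ground truth, so recovery by the analysis
modules is an exact, testable statement.

Movement model: daily steps in the coordinate frame of the reference
great circle from start to goal.  The along-path coordinate advances
by Normal(mean_daily_km, sd) each travel day; the perpendicular
(right-of-path) offset performs the drift random walk
``y += beta * crosswind + Normal(0, sigma_perp)`` with no homing
correction, which is exactly the linear drift framework the wind
module estimates.  Stopovers are inserted as runs of near-stationary
(< 10 km/day) calendar days at configured fractions of the route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from . import geodesy
from .errors import NumericalError, ValidationError
from .terrain import LANDCOVER_CLASSES, Raster, ReclassMap
from .tracks import Fix, MigrationTrack
from .wind import WindGrid

UTC = timezone.utc


# ---------------------------------------------------------------------------
# wind

@dataclass(frozen=True)
class WindSpec:
    """Zonal-band wind field: easterlies south of the subtropical edge,
    westerlies to the north, with a linear transition whose knots sit
    on grid latitudes so trilinear interpolation is exact."""
    lon_min: float = 40.0
    lon_max: float = 100.0
    lat_min: float = 0.0
    lat_max: float = 60.0
    resolution_deg: float = 2.5
    start: datetime = datetime(2020, 3, 1, tzinfo=UTC)
    days: int = 120
    u_south: float = -3.0          # easterlies below transition, m/s
    u_north: float = 4.0           # westerlies above transition, m/s
    transition_lats: tuple[float, float] = (27.5, 32.5)
    v_ms: float = 1.0
    noise_sd: float = 0.5


def make_wind_grid(spec: WindSpec = WindSpec(), seed: int = 0
                   ) -> tuple[WindGrid, "callable"]:
    """Build the 6-hourly wind grid plus the analytic (noise-free)
    function it discretises, for oracle checks."""
    lo1, lo2 = spec.transition_lats
    if lo2 <= lo1:
        raise ValidationError("transition latitudes must increase")

    def analytic(lon, lat, time=None):
        u = np.interp(lat, [spec.lat_min, lo1, lo2, spec.lat_max],
                      [spec.u_south, spec.u_south, spec.u_north, spec.u_north])
        return float(u), spec.v_ms

    lons = np.arange(spec.lon_min, spec.lon_max + 1e-9, spec.resolution_deg)
    lats = np.arange(spec.lat_min, spec.lat_max + 1e-9, spec.resolution_deg)
    times = (np.datetime64(spec.start.replace(tzinfo=None), "ns")
             + np.arange(spec.days * 4) * np.timedelta64(6 * 3600, "s"))
    u0 = np.interp(lats, [spec.lat_min, lo1, lo2, spec.lat_max],
                   [spec.u_south, spec.u_south, spec.u_north, spec.u_north])
    u = np.broadcast_to(u0[None, :, None],
                        (len(times), len(lats), len(lons))).copy()
    v = np.full_like(u, spec.v_ms)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        u += rng.normal(0.0, spec.noise_sd, u.shape)
        v += rng.normal(0.0, spec.noise_sd, v.shape)
    return WindGrid(lons=lons, lats=lats, times=times, u=u, v=v), analytic


# ---------------------------------------------------------------------------
# tracks

@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults emulate the tracked population: 9 individuals, 40 tracks,
    wintering grounds near 9 N and breeding grounds near 47 N, daily
    travel ~120-220 km/day, stopovers longer than 3 days, and the
    published drift coefficient as the generating beta."""
    seed: int = 0
    n_individuals: int = 9
    n_tracks: int = 40
    start: tuple[float, float] = (70.0, 9.0)    # (lon, lat) wintering
    goal: tuple[float, float] = (70.0, 47.0)    # breeding
    mean_daily_km: float = 170.0
    sd_daily_km: float = 25.0
    min_daily_km: float = 60.0
    beta_kmday_per_ms: float = 24.7
    sigma_perp_kmday: float = 10.0
    stopovers: tuple[tuple[float, int], ...] = ((0.45, 5),)
    waypoints: tuple[tuple[float, float], ...] = ()   # force a detour route
    tag: str = "gps"                            # "gps" | "ptt"
    start_time: datetime = datetime(2020, 3, 5, tzinfo=UTC)
    max_days: int = 120
    compensate: bool = False   # if True, perpendicular offset stays ~0

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if min(self.mean_daily_km, self.sd_daily_km + 1e-12,
               self.min_daily_km) <= 0:
            raise ValidationError("rates must be positive")
        if self.tag not in ("gps", "ptt"):
            raise ValidationError(f"unknown tag model {self.tag!r}")


@dataclass
class TrackTruth:
    """Generating parameters and per-day state of one synthetic track."""
    beta: float
    stopovers: list[tuple[datetime, datetime]]
    daily: pd.DataFrame        # day, forward_km, perp_km, u_ms, v_ms
    route_length_km: float
    goal_bearing_deg: float

    def to_dict(self) -> dict:
        return {"beta": self.beta,
                "stopovers": [[a.isoformat(), d.isoformat()]
                              for a, d in self.stopovers],
                "route_length_km": self.route_length_km,
                "goal_bearing_deg": self.goal_bearing_deg,
                "daily": self.daily.assign(
                    day=self.daily["day"].astype(str)).to_dict("records")}


def _path_position(gc_pts, total_km, x_km, y_km):
    """Map path coordinates (along, right-of) to lon/lat."""
    frac = min(max(x_km / total_km, 0.0), 1.0)
    base = geodesy.interpolate_along(gc_pts, frac)
    # local path bearing: toward the next point along the reference line
    ref = geodesy.interpolate_along(gc_pts, min(frac + 1e-4, 1.0))
    if ref == base:
        ref = geodesy.interpolate_along(gc_pts, max(frac - 1e-4, 0.0))
        brg = (geodesy.initial_bearing_deg(*ref, *base)) % 360.0
    else:
        brg = geodesy.initial_bearing_deg(*base, *ref)
    if y_km == 0.0:
        return base
    return geodesy.destination(*base, brg + 90.0, y_km)


def simulate_track(config: SimConfig, wind_fn, seed: int,
                   season: str = "spring", individual_id: str = "bird-01",
                   year: int = 2020) -> tuple[MigrationTrack, TrackTruth]:
    """Simulate one migration track against an analytic wind function.

    ``wind_fn(lon, lat, time) -> (u, v)`` supplies the wind the bird
    experiences (use the analytic half of :func:`make_wind_grid` so
    ground truth is exact).  Spring runs start->goal (northward),
    autumn the reverse.
    """
    rng = np.random.default_rng(seed)
    if season == "spring":
        a, b = config.start, config.goal
    elif season == "autumn":
        a, b = config.goal, config.start
    else:
        raise ValidationError(f"unknown season {season!r}")
    way = list(config.waypoints)
    if season == "autumn":
        way = way[::-1]
    nodes = [a, *way, b]
    gc_pts: list[tuple[float, float]] = [a]
    for p, q in zip(nodes[:-1], nodes[1:]):
        gc_pts.extend(geodesy.great_circle_route(p, q, 50.0)[1:])
    total = geodesy.geodesic_length_km(gc_pts)
    goal_bearing = geodesy.initial_bearing_deg(*a, *b)

    x, y = 0.0, 0.0
    day = config.start_time.replace(hour=0, minute=0, second=0, microsecond=0)
    pending = sorted(config.stopovers)
    stopover_log: list[tuple[datetime, datetime]] = []
    day_rows = []
    positions = [(day, _path_position(gc_pts, total, x, y))]
    n_days = 0
    while x < total:
        if n_days >= config.max_days:
            raise NumericalError("goal unreachable within max_days")
        if pending and x / total >= pending[0][0]:
            frac, dur = pending.pop(0)
            arrival = day
            for _ in range(dur):
                # near-stationary wander, returns to the same centre
                u, v = wind_fn(*positions[-1][1], day)
                day_rows.append({"day": day, "forward_km": 0.0,
                                 "perp_km": 0.0, "u_ms": u, "v_ms": v,
                                 "stopover": True})
                day += timedelta(days=1)
                jitter = rng.uniform(-0.02, 0.02, 2)
                lon0, lat0 = _path_position(gc_pts, total, x, y)
                positions.append((day, (lon0 + jitter[0], lat0 + jitter[1])))
                n_days += 1
            stopover_log.append((arrival, day))
            continue
        forward = max(config.min_daily_km,
                      rng.normal(config.mean_daily_km, config.sd_daily_km))
        forward = min(forward, total - x)
        # wind experienced over the day, sampled the way the analysis
        # measures it: (1, 2, 1)/4 over the segment's onset, temporal
        # midpoint and end (movement runs 00:00-14:00, roost to 24:00,
        # so the daily segment's temporal middle sits at 11:30)
        p0 = positions[-1][1]
        p1_fwd = _path_position(gc_pts, total, x + forward, y)
        mid_frac = min(11.5 / 14.0, 1.0)
        if p0 == p1_fwd:
            p_mid = p0
        else:
            p_mid = geodesy.gc_interpolate(p0, p1_fwd, [mid_frac])[0]
        samples = [wind_fn(*p0, day),
                   wind_fn(*p_mid, day + timedelta(hours=11, minutes=30)),
                   wind_fn(*p1_fwd, day + timedelta(hours=23))]
        u = (samples[0][0] + 2 * samples[1][0] + samples[2][0]) / 4.0
        v = (samples[0][1] + 2 * samples[1][1] + samples[2][1]) / 4.0
        g = math.radians(goal_bearing)
        crosswind = u * math.cos(g) - v * math.sin(g)
        if config.compensate:
            perp = rng.normal(0.0, config.sigma_perp_kmday)
            perp = float(np.clip(perp, -45.0, 45.0))
        else:
            perp = (config.beta_kmday_per_ms * crosswind
                    + rng.normal(0.0, config.sigma_perp_kmday))
        x += forward
        y += perp
        day += timedelta(days=1)
        positions.append((day, _path_position(gc_pts, total, x, y)))
        day_rows.append({"day": day - timedelta(days=1),
                         "forward_km": forward, "perp_km": perp,
                         "u_ms": u, "v_ms": v, "stopover": False})
        n_days += 1

    fixes = _emit_fixes(positions, config, individual_id)
    track = MigrationTrack(individual_id=individual_id, season=season,
                           year=year, fixes=fixes)
    truth = TrackTruth(
        beta=0.0 if config.compensate else config.beta_kmday_per_ms,
        stopovers=stopover_log, daily=pd.DataFrame(day_rows),
        route_length_km=total, goal_bearing_deg=goal_bearing)
    return track, truth


def _emit_fixes(positions, config: SimConfig,
                individual_id: str) -> list[Fix]:
    """Resample daily waypoints to the tag cadence.  Movement is
    executed 00:00-14:00 UTC (diurnal migrant); the bird then roosts at
    the day's end position.  GPS: 10-min fixes by day, hourly by night.
    PTT source fixes are emitted half-hourly and then duty-cycled by
    :func:`degrade_to_ptt`."""
    fixes: list[Fix] = []
    step_day = timedelta(minutes=10 if config.tag == "gps" else 30)
    step_night = timedelta(hours=1)
    for (d0, p0), (d1, p1) in zip(positions[:-1], positions[1:]):
        t = d0
        while t < d1:
            h = t.hour + t.minute / 60.0
            if h < 14.0:
                frac = min(h / 14.0, 1.0)
                if p0 == p1:
                    lon, lat = p0
                else:
                    lon, lat = geodesy.gc_interpolate(p0, p1, [frac])[0]
            else:
                lon, lat = p1
            fixes.append(Fix(individual_id=individual_id, timestamp=t,
                             lon=lon, lat=lat, quality="GPS",
                             altitude_amsl=500.0))
            t += step_day if h < 14.0 else step_night
    d_end, p_end = positions[-1]
    fixes.append(Fix(individual_id=individual_id, timestamp=d_end,
                     lon=p_end[0], lat=p_end[1], quality="GPS",
                     altitude_amsl=500.0))
    return fixes


# ---------------------------------------------------------------------------
# ARGOS degradation

@dataclass(frozen=True)
class LCNoiseModel:
    """Per-class positional noise (km, isotropic Gaussian) and class
    frequencies of a duty-cycled ARGOS tag."""
    sd_km: tuple = (("LC3", 0.15), ("LC2", 0.35), ("LC1", 1.0),
                    ("LC0", 3.0), ("LCA", 10.0), ("LCB", 25.0))
    probs: tuple = (("LC3", 0.20), ("LC2", 0.25), ("LC1", 0.25),
                    ("LC0", 0.15), ("LCA", 0.10), ("LCB", 0.05))
    on_hours: float = 10.0
    off_hours: float = 48.0

    def noise_scale(self, quality: str) -> float:
        return dict(self.sd_km)[quality]


def degrade_to_ptt(fixes: list[Fix], model: LCNoiseModel = LCNoiseModel(),
                   seed: int = 0) -> list[Fix]:
    """Duty-cycle a dense track (keep fixes inside ON windows of the
    ON/OFF cycle anchored at the first fix) and add per-class ARGOS
    positional noise."""
    if not fixes:
        return []
    rng = np.random.default_rng(seed)
    cycle = model.on_hours + model.off_hours
    t0 = fixes[0].timestamp
    classes = [c for c, _ in model.probs]
    probs = np.array([p for _, p in model.probs])
    probs = probs / probs.sum()
    out = []
    for f in fixes:
        phase = ((f.timestamp - t0).total_seconds() / 3600.0) % cycle
        if phase >= model.on_hours:
            continue
        q = str(rng.choice(classes, p=probs))
        sd = model.noise_scale(q)
        dx, dy = rng.normal(0.0, sd, 2)  # km east / north
        lat = f.lat + dy / 111.195
        lon = f.lon + dx / (111.195 * math.cos(math.radians(f.lat)))
        out.append(replace(f, lon=lon, lat=max(-90, min(90, lat)), quality=q))
    return out


# ---------------------------------------------------------------------------
# rasters

@dataclass(frozen=True)
class BarrierSpec:
    """Gaussian mountain ridge across the direct corridor.

    ``contour_width_km`` is the ridge's north-south width at
    ``contour_m`` (default: 700 km wide at the 3500 m contour, peaking
    at 6000 m), which fixes the Gaussian sigma."""
    lon_min: float = 55.0
    lon_max: float = 95.0
    lat_min: float = 5.0
    lat_max: float = 55.0
    cellsize_deg: float = 0.25
    background_m: float = 200.0
    ridge_lat: float = 33.0
    ridge_peak_m: float = 6000.0
    contour_m: float = 3500.0
    contour_width_km: float = 700.0
    ridge_west_edge_lon: float = 66.0   # ridge fades west of this
    edge_taper_km: float = 120.0

    @property
    def sigma_deg(self) -> float:
        peak_rel = self.ridge_peak_m - self.background_m
        thr_rel = self.contour_m - self.background_m
        sigma_km = self.contour_width_km / (
            2.0 * math.sqrt(2.0 * math.log(peak_rel / thr_rel)))
        return sigma_km / 111.195


def elevation_function(spec: BarrierSpec = BarrierSpec()):
    """Analytic elevation surface (m) as a vectorised (lon, lat) map."""
    def fn(lon, lat):
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        ridge = (spec.ridge_peak_m - spec.background_m) * np.exp(
            -((lat - spec.ridge_lat) ** 2) / (2.0 * spec.sigma_deg ** 2))
        west_km = (spec.ridge_west_edge_lon - lon) * 111.195 \
            * math.cos(math.radians(spec.ridge_lat))
        taper = np.where(west_km > 0,
                         np.exp(-(west_km / spec.edge_taper_km) ** 2 / 2.0),
                         1.0)
        return spec.background_m + ridge * taper
    return fn


def make_elevation(spec: BarrierSpec = BarrierSpec()) -> Raster:
    """Elevation raster: flat background plus the Gaussian ridge that
    blocks the direct route but not the western detour corridor."""
    fn = elevation_function(spec)
    nx = int(round((spec.lon_max - spec.lon_min) / spec.cellsize_deg))
    ny = int(round((spec.lat_max - spec.lat_min) / spec.cellsize_deg))
    xs = spec.lon_min + (np.arange(nx) + 0.5) * spec.cellsize_deg
    ys = spec.lat_min + (np.arange(ny) + 0.5) * spec.cellsize_deg
    gx, gy = np.meshgrid(xs, ys[::-1])
    return Raster(values=fn(gx, gy), xll=spec.lon_min, yll=spec.lat_min,
                  cellsize=spec.cellsize_deg, semantics="elevation_m")


#: synthetic source codes in the ESA-CCI numbering style
SYNTHETIC_CODES = {10: "Cropland", 30: "Cropland mosaic", 50: "Forest",
                   120: "Open natural ecosystem", 190: "Urban areas",
                   200: "Bare areas", 210: "Water body",
                   220: "Permanent snow and ice"}


def make_landcover(spec: BarrierSpec = BarrierSpec()
                   ) -> tuple[Raster, ReclassMap]:
    """Coded land-cover raster with latitude-zoned classes and
    elevation-controlled bare/snow belts, plus its reclassification map."""
    elev = make_elevation(spec)
    xs, ys = elev.cell_centers()
    _, gy = np.meshgrid(xs, ys)
    codes = np.full(elev.values.shape, 120.0)          # open natural
    codes[gy < 18.0] = 10.0                            # cropland south
    codes[(gy >= 28.0) & (gy < 36.0)] = 30.0           # mosaic mid
    codes[gy >= 48.0] = 50.0                           # forest north
    codes[(elev.values > spec.contour_m)
          & (elev.values <= 4500.0)] = 200.0           # bare
    codes[elev.values > 4500.0] = 220.0                # snow/ice
    raster = Raster(values=codes, xll=elev.xll, yll=elev.yll,
                    cellsize=elev.cellsize, semantics="landcover_code")
    return raster, ReclassMap(mapping=dict(SYNTHETIC_CODES))


@dataclass(frozen=True)
class NDVISpec:
    """Sinusoidal seasonal greenness for one stopover region."""
    lon_min: float = 70.0
    lon_max: float = 73.0
    lat_min: float = 27.0
    lat_max: float = 30.0
    cellsize_deg: float = 0.05
    peak_month: int = 9
    peak_value: float = 0.15
    min_value: float = 0.05


def make_ndvi_stack(spec: NDVISpec = NDVISpec()) -> dict[int, Raster]:
    """One NDVI raster per month (keys 1-12) with the configured
    seasonal peak."""
    nx = int(round((spec.lon_max - spec.lon_min) / spec.cellsize_deg))
    ny = int(round((spec.lat_max - spec.lat_min) / spec.cellsize_deg))
    amp = spec.peak_value - spec.min_value
    stack = {}
    for m in range(1, 13):
        val = spec.min_value + amp * (
            1.0 + math.cos(2.0 * math.pi * (m - spec.peak_month) / 12.0)) / 2.0
        stack[m] = Raster(values=np.full((ny, nx), val),
                          xll=spec.lon_min, yll=spec.lat_min,
                          cellsize=spec.cellsize_deg, semantics="ndvi")
    return stack


# ---------------------------------------------------------------------------
# cohort

def simulate_cohort(config: SimConfig, wind_fn=None
                    ) -> list[tuple[MigrationTrack, TrackTruth]]:
    """Simulate the full study cohort: ``n_tracks`` tracks spread over
    ``n_individuals`` individuals, alternating spring and autumn.
    Per-track seeds derive from ``config.seed``."""
    if wind_fn is None:
        _, wind_fn = make_wind_grid(WindSpec(noise_sd=0.0), config.seed)
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(config.n_tracks):
        ind = f"bird-{i % config.n_individuals + 1:02d}"
        season = "spring" if i % 2 == 0 else "autumn"
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        track, truth = simulate_track(config, wind_fn, sub_seed,
                                      season=season, individual_id=ind,
                                      year=2017 + i // config.n_individuals)
        out.append((track, truth))
    return out
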