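"""Gridded-wind extraction and the wind drift/compensation analysis.

A migration track defines an intended (goal) direction: the initial
great-circle bearing from the track's start to its end.  For every
movement segment, the wind experienced is the (1, 2, 1)/4 weighted
average of the wind interpolated at the segment's onset, midpoint and
end; wind and daily movement are then decomposed into components along
the goal direction (tailwind / forward movement) and perpendicular to
it (crosswind / perpendicular movement, positive to the RIGHT of the
goal bearing for both — only sign agreement matters for the behaviour
labels, so any consistent convention works).

Behaviour labels compare perpendicular movement (km/day) with
crosswind: moving sideways with the wind beyond a threshold is drift,
holding the line is compensation, moving sideways against the wind is
overcompensation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from . import geodesy
from .errors import NumericalError, OutOfBoundsError, ValidationError
from .tracks import MigrationTrack, Segment

BEHAVIOURS = ("drift", "compensation", "overcompensation")


@dataclass(frozen=True)
class WindVector:
    u: float  # m/s eastward
    v: float  # m/s northward

    @property
    def speed(self) -> float:
        return math.hypot(self.u, self.v)

    @property
    def direction_deg(self) -> float:
        """Heading the air moves TOWARD, degrees clockwise from north."""
        return math.degrees(math.atan2(self.u, self.v)) % 360.0

    @property
    def direction_from_deg(self) -> float:
        """Meteorological 'blowing from' direction, for report output."""
        return (self.direction_deg + 180.0) % 360.0


@dataclass
class WindGrid:
    """u/v wind on a regular lon/lat/time grid at one pressure level."""
    lons: np.ndarray          # ascending, degrees east
    lats: np.ndarray          # ascending, degrees north
    times: np.ndarray         # ascending, datetime64[ns], 6-hourly
    u: np.ndarray             # [time, lat, lon], m/s
    v: np.ndarray             # [time, lat, lon], m/s
    pressure_level: float = 925.0

    def __post_init__(self):
        shape = (len(self.times), len(self.lats), len(self.lons))
        if self.u.shape != shape or self.v.shape != shape:
            raise ValidationError(
                f"wind arrays must have shape {shape}, got {self.u.shape}")
        if np.isnan(self.u).any() or np.isnan(self.v).any():
            raise ValidationError("wind grid contains missing values")
        self._interp_u = None
        self._interp_v = None

    def _time_axis(self) -> np.ndarray:
        return self.times.astype("datetime64[s]").astype(float)

    def _interpolators(self):
        if self._interp_u is None:
            axes = (self._time_axis(), np.asarray(self.lats, float),
                    np.asarray(self.lons, float))
            self._interp_u = RegularGridInterpolator(
                axes, self.u, method="linear", bounds_error=True)
            self._interp_v = RegularGridInterpolator(
                axes, self.v, method="linear", bounds_error=True)
        return self._interp_u, self._interp_v

    def to_netcdf(self, path) -> None:
        """Write in the reanalysis dialect (uwnd/vwnd, m/s) as
        NETCDF3_CLASSIC via xarray's scipy backend."""
        ds = xr.Dataset(
            {"uwnd": (("time", "lat", "lon"), self.u, {"units": "m/s"}),
             "vwnd": (("time", "lat", "lon"), self.v, {"units": "m/s"})},
            coords={"time": self.times, "lat": self.lats, "lon": self.lons},
            attrs={"pressure_level_hPa": float(self.pressure_level)})
        ds.to_netcdf(path, engine="scipy", format="NETCDF3_CLASSIC")

    @classmethod
    def from_netcdf(cls, path, pressure_level: float = 925.0) -> "WindGrid":
        ds = xr.open_dataset(path, engine="scipy", decode_timedelta=False)
        names = {n.lower(): n for n in ds.variables}
        u_name = names.get("uwnd") or names.get("u")
        v_name = names.get("vwnd") or names.get("v")
        lat_name = names.get("lat") or names.get("latitude")
        lon_name = names.get("lon") or names.get("longitude")
        if not all((u_name, v_name, lat_name, lon_name, "time" in names)):
            raise ValidationError("NetCDF missing uwnd/vwnd/lat/lon/time")
        for nm in (u_name, v_name):
            units = ds[nm].attrs.get("units", "")
            if units not in ("m/s", "m s-1", "m s**-1"):
                raise ValidationError(f"variable {nm} has units {units!r}, "
                                      "expected m/s")
        u = ds[u_name].transpose("time", lat_name, lon_name).values
        v = ds[v_name].transpose("time", lat_name, lon_name).values
        lats = ds[lat_name].values
        lons = ds[lon_name].values
        order_lat = np.argsort(lats)
        order_lon = np.argsort(lons)
        grid = cls(lons=lons[order_lon], lats=lats[order_lat],
                   times=ds["time"].values.astype("datetime64[ns]"),
                   u=u[:, order_lat][:, :, order_lon],
                   v=v[:, order_lat][:, :, order_lon],
                   pressure_level=float(ds.attrs.get("pressure_level_hPa",
                                                     pressure_level)))
        ds.close()
        return grid


def _time_to_float(t: datetime) -> float:
    if t.tzinfo is not None:
        t = t.astimezone(timezone.utc).replace(tzinfo=None)
    return np.datetime64(t, "s").astype(float)


def interpolate_wind(grid: WindGrid, lon: float, lat: float,
                     time: datetime) -> WindVector:
    """Trilinear (bilinear in space, linear in time) interpolation of
    u and v.  Out-of-bounds queries raise; no extrapolation."""
    fu, fv = grid._interpolators()
    q = np.array([[_time_to_float(time), lat, lon]])
    try:
        return WindVector(u=float(fu(q)[0]), v=float(fv(q)[0]))
    except ValueError as e:
        raise OutOfBoundsError(
            f"wind query ({lon}, {lat}, {time}) outside grid bounds") from e


def segment_wind(onset: WindVector, midpoint: WindVector,
                 end: WindVector) -> WindVector:
    """(1, 2, 1)/4 weighted average, emphasising the segment midpoint."""
    return WindVector(u=(onset.u + 2.0 * midpoint.u + end.u) / 4.0,
                      v=(onset.v + 2.0 * midpoint.v + end.v) / 4.0)


def goal_direction(track: MigrationTrack) -> float:
    """Intended migration direction: initial great-circle bearing from
    the track's start fix to its end fix, degrees in [0, 360)."""
    start, end = track.start_fix.lonlat, track.end_fix.lonlat
    if start == end:
        raise ValidationError("goal direction undefined: track start "
                              "and end coincide")
    return geodesy.initial_bearing_deg(*start, *end)


@dataclass
class DriftRecord:
    segment: Segment
    goal_bearing_deg: float
    tailwind_ms: float
    crosswind_ms: float
    forward_move_kmday: float
    perp_move_kmday: float
    behaviour: str
    lat_band: str
    season: str | None = None
    wind: WindVector | None = None


def latitude_band(lat: float, band_edges: tuple[float, float] = (30.0, 40.0)) -> str:
    lo, hi = band_edges
    if lat < lo:
        return "south_of_30"
    if lat <= hi:
        return "band_30_40"
    return "north_of_40"


def classify_drift(perp_move_kmday: float, crosswind_ms: float,
                   threshold_kmday: float = 50.0) -> str:
    """Behaviour label from perpendicular movement vs crosswind.

    |perp| > threshold with matching sign: drift; within the +-threshold
    band: compensation; |perp| > threshold with opposite sign:
    overcompensation; |perp| > threshold but crosswind exactly zero:
    unclassified (sign agreement undefined)."""
    if not (math.isfinite(perp_move_kmday) and math.isfinite(crosswind_ms)):
        raise ValidationError("non-finite drift inputs")
    if abs(perp_move_kmday) <= threshold_kmday:
        return "compensation"
    if crosswind_ms == 0.0:
        return "unclassified"
    if math.copysign(1, perp_move_kmday) == math.copysign(1, crosswind_ms):
        return "drift"
    return "overcompensation"


def decompose(segment: Segment, wind: WindVector, goal_bearing: float,
              threshold_kmday: float = 50.0,
              band_edges: tuple[float, float] = (30.0, 40.0),
              season: str | None = None) -> DriftRecord:
    """Rotate wind and daily movement into the goal frame and label the
    segment's drift behaviour."""
    g = math.radians(goal_bearing)
    sin_g, cos_g = math.sin(g), math.cos(g)
    tailwind = wind.u * sin_g + wind.v * cos_g
    crosswind = wind.u * cos_g - wind.v * sin_g

    band = latitude_band(segment.midpoint.lat, band_edges)
    if segment.displacement_km <= 0:
        return DriftRecord(segment, goal_bearing, tailwind, crosswind,
                           0.0, 0.0, "unclassified", band, season, wind)
    theta = math.radians(geodesy.initial_bearing_deg(
        *segment.onset.lonlat, *segment.end.lonlat))
    rate = segment.daily_displacement_km_per_day
    east, north = rate * math.sin(theta), rate * math.cos(theta)
    forward = east * sin_g + north * cos_g
    perp = east * cos_g - north * sin_g
    return DriftRecord(segment, goal_bearing, tailwind, crosswind,
                       forward, perp,
                       classify_drift(perp, crosswind, threshold_kmday),
                       band, season, wind)


def wind_for_segment(grid: WindGrid, segment: Segment) -> WindVector:
    """Interpolated, (1,2,1)/4-weighted wind over one segment."""
    vectors = [interpolate_wind(grid, f.lon, f.lat, f.timestamp)
               for f in (segment.onset, segment.midpoint, segment.end)]
    return segment_wind(*vectors)


def analyse_track(track: MigrationTrack, segments: list[Segment],
                  grid: WindGrid, threshold_kmday: float = 50.0,
                  band_edges: tuple[float, float] = (30.0, 40.0)
                  ) -> list[DriftRecord]:
    """Decompose every segment of one track against its goal bearing."""
    goal = goal_direction(track)
    return [decompose(s, wind_for_segment(grid, s), goal,
                      threshold_kmday, band_edges, track.season)
            for s in segments]


def records_frame(records: list[DriftRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "onset_time": r.segment.onset.timestamp,
        "mid_lat": r.segment.midpoint.lat,
        "season": r.season,
        "goal_bearing_deg": r.goal_bearing_deg,
        "tailwind_ms": r.tailwind_ms, "crosswind_ms": r.crosswind_ms,
        "forward_move_kmday": r.forward_move_kmday,
        "perp_move_kmday": r.perp_move_kmday,
        "behaviour": r.behaviour, "lat_band": r.lat_band,
        "wind_speed_ms": r.wind.speed if r.wind else np.nan,
        "wind_to_deg": r.wind.direction_deg if r.wind else np.nan,
        "wind_from_deg": r.wind.direction_from_deg if r.wind else np.nan,
    } for r in records])


def band_frequencies(records: list[DriftRecord],
                     band_edges: tuple[float, float] = (30.0, 40.0)
                     ) -> tuple[pd.DataFrame, float, int, float]:
    """Counts of behaviour labels per latitudinal band, plus the
    Pearson chi-square statistic over the non-empty bands.

    Returns (table, chi2, dof, p); unclassified records are excluded
    from the table."""
    classified = [r for r in records if r.behaviour in BEHAVIOURS]
    band_order = ["south_of_30", "band_30_40", "north_of_40"]
    table = pd.DataFrame(0, index=band_order, columns=list(BEHAVIOURS))
    for r in classified:
        table.loc[r.lat_band, r.behaviour] += 1
    nonempty = table[table.sum(axis=1) > 0]
    if len(nonempty) < len(table):
        warnings.warn("empty latitude band excluded from chi-square",
                      stacklevel=2)
    cols = nonempty.loc[:, nonempty.sum(axis=0) > 0]
    if cols.shape[0] < 2 or cols.shape[1] < 2:
        return table, 0.0, 0, 1.0
    chi2, p, dof, _ = stats.chi2_contingency(cols.to_numpy(),
                                             correction=False)
    return table, float(chi2), int(dof), float(p)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    se: float
    t: float
    p: float
    n: int


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if len(x) < 3:
        raise ValidationError("need at least 3 records for regression")
    if np.ptp(x) == 0:
        raise NumericalError("constant predictor: slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(slope=float(model.params[1]),
                            intercept=float(model.params[0]),
                            se=float(model.bse[1]), t=float(model.tvalues[1]),
                            p=float(model.pvalues[1]), n=len(x))


def drift_regression(records: list[DriftRecord],
                     season: str | None = None
                     ) -> dict[str, RegressionResult]:
    """OLS of perpendicular movement on crosswind and of forward
    movement on tailwind (slopes in km/day per m/s), optionally
    restricted to one season."""
    recs = [r for r in records if season is None or r.season == season]
    cw = np.array([r.crosswind_ms for r in recs])
    pm = np.array([r.perp_move_kmday for r in recs])
    tw = np.array([r.tailwind_ms for r in recs])
    fm = np.array([r.forward_move_kmday for r in recs])
    return {"perp_on_crosswind": _ols(cw, pm),
            "forward_on_tailwind": _ols(tw, fm)}


@dataclass(frozen=True)
class PairedComparison:
    mean_amr: float
    mean_gcr: float
    mean_difference: float
    t: float
    p: float
    n: int


def tailwind_amr_vs_gcr(amr_records: list[DriftRecord],
                        gcr_records: list[DriftRecord]) -> PairedComparison:
    """Paired two-sided t comparison of tailwind along the actual route
    vs along the great-circle route (segments paired by identity:
    same timestamps, positions projected onto the reference route)."""
    if len(amr_records) != len(gcr_records):
        raise ValidationError("AMR and GCR record lists must be paired")
    a = np.array([r.tailwind_ms for r in amr_records])
    g = np.array([r.tailwind_ms for r in gcr_records])
    if np.allclose(a, g):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a, g)
    return PairedComparison(mean_amr=float(a.mean()), mean_gcr=float(g.mean()),
                            mean_difference=float((a - g).mean()),
                            t=float(t), p=float(p), n=len(a))
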