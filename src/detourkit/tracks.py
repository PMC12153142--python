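"""Track ingestion, quality filtering, stopover detection, route
geometry and segment construction.

Conventions (documented because the operational definitions matter):

* A "day" for the stopover rule is the UTC calendar day; a day's travel
  is the *net* displacement between the track's position at the day's
  start and at its end (positions linearly interpolated in time along
  the great circle between bracketing fixes, which keeps the rule
  well-defined for duty-cycled ARGOS tags that are silent for days).
* Stopovers are maximal runs of consecutive days each travelling less
  than 50 km, kept only when strictly longer than 3 days.
* Route length is the WGS84 geodesic length of the fix polyline; the
  great-circle reference route is spherical (see :mod:`.geodesy`).
* All time intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import geodesy
from .errors import (DegenerateTrackError, UnknownQualityError,
                     ValidationError)

QUALITY_CODES = ("LC3", "LC2", "LC1", "LC0", "LCA", "LCB", "GPS")

#: qualities always retained / always dropped by the default policy
ALWAYS_KEEP = frozenset({"GPS", "LC1", "LC2", "LC3"})
ALWAYS_DROP = frozenset({"LCA", "LCB"})


@dataclass(frozen=True)
class Fix:
    """One timestamped location of one individual."""
    individual_id: str
    timestamp: datetime
    lon: float
    lat: float
    quality: str = "GPS"
    altitude_amsl: float | None = None

    def __post_init__(self):
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValidationError(
                f"fix coordinate out of range: {self.lon}, {self.lat}")
        if self.timestamp.tzinfo is None:
            object.__setattr__(self, "timestamp",
                               self.timestamp.replace(tzinfo=timezone.utc))

    @property
    def lonlat(self) -> tuple[float, float]:
        return (self.lon, self.lat)


@dataclass
class MigrationTrack:
    individual_id: str
    season: str  # "spring" | "autumn"
    year: int
    fixes: list[Fix]

    def __post_init__(self):
        if self.season not in ("spring", "autumn"):
            raise ValidationError(f"unknown season {self.season!r}")
        ts = [f.timestamp for f in self.fixes]
        if any(b <= a for a, b in zip(ts[:-1], ts[1:])):
            raise ValidationError("fix timestamps must strictly increase")

    @property
    def start_fix(self) -> Fix:
        return self.fixes[0]

    @property
    def end_fix(self) -> Fix:
        return self.fixes[-1]

    def position_at(self, t: datetime) -> tuple[float, float]:
        """Position at time t, great-circle interpolated between the
        bracketing fixes; clamped to the track's span."""
        fx = self.fixes
        if t <= fx[0].timestamp:
            return fx[0].lonlat
        if t >= fx[-1].timestamp:
            return fx[-1].lonlat
        times = [f.timestamp for f in fx]
        i = _bisect(times, t)
        a, b = fx[i - 1], fx[i]
        span = (b.timestamp - a.timestamp).total_seconds()
        if span <= 0:
            return a.lonlat
        frac = (t - a.timestamp).total_seconds() / span
        if a.lonlat == b.lonlat:
            return a.lonlat
        return geodesy.gc_interpolate(a.lonlat, b.lonlat, [frac])[0]


def _bisect(times: list[datetime], t: datetime) -> int:
    lo, hi = 0, len(times)
    while lo < hi:
        mid = (lo + hi) // 2
        if times[mid] < t:
            lo = mid + 1
        else:
            hi = mid
    return lo


@dataclass
class Stopover:
    center_lon: float
    center_lat: float
    arrival: datetime
    departure: datetime
    duration_days: float
    fixes: list[Fix] = field(default_factory=list)


@dataclass
class Segment:
    """A directed movement step used by the wind analysis."""
    onset: Fix
    midpoint: Fix
    end: Fix
    displacement_km: float
    duration_h: float
    source: str  # "ptt_rule" | "gps_daily"

    @property
    def daily_displacement_km_per_day(self) -> float:
        return self.displacement_km / (self.duration_h / 24.0)


@dataclass
class RoutePair:
    amr: MigrationTrack
    gcr_points: list[tuple[float, float]]
    amr_length_km: float
    gcr_length_km: float

    @property
    def detour_extent(self) -> float:
        return detour_extent(self.amr_length_km, self.gcr_length_km)


@dataclass(frozen=True)
class QualityPolicy:
    """Which ARGOS location classes survive filtering.

    LC0 fixes are kept only when their cross-track distance to the
    great circle through the nearest retained neighbours stays below
    ``lc0_cross_track_km`` — an operational stand-in for the manual
    "no significant deviation from the route" screening applied to
    duty-cycled tags.
    """
    keep: frozenset = ALWAYS_KEEP
    drop: frozenset = ALWAYS_DROP
    lc0_cross_track_km: float = 100.0


def filter_fixes(fixes: Sequence[Fix],
                 policy: QualityPolicy = QualityPolicy()) -> list[Fix]:
    """Quality-filter an ordered fix record.

    GPS and LC1–LC3 are always retained, LCA/LCB always dropped, LC0
    conditionally retained (see :class:`QualityPolicy`).  Unknown
    quality codes raise :class:`UnknownQualityError`.
    """
    for f in fixes:
        if f.quality not in QUALITY_CODES:
            raise UnknownQualityError(f"unknown quality code {f.quality!r}")
    kept = [f for f in fixes if f.quality in policy.keep]
    out = list(kept)
    for idx, f in enumerate(fixes):
        if f.quality != "LC0" or "LC0" in policy.drop:
            continue
        before = next((g for g in reversed(fixes[:idx])
                       if g.quality in policy.keep), None)
        after = next((g for g in fixes[idx + 1:]
                      if g.quality in policy.keep), None)
        if before is None or after is None:
            continue  # cannot assess deviation; drop conservatively
        if before.lonlat == after.lonlat:
            dist = geodesy.vincenty_km(*f.lonlat, *before.lonlat)
        else:
            dist = geodesy.cross_track_km(f.lonlat, before.lonlat,
                                          after.lonlat)
        if dist < policy.lc0_cross_track_km:
            out.append(f)
    out.sort(key=lambda f: f.timestamp)
    return out


def _day_range(track: MigrationTrack) -> list[datetime]:
    t0 = track.start_fix.timestamp
    t1 = track.end_fix.timestamp
    day0 = t0.replace(hour=0, minute=0, second=0, microsecond=0)
    days = []
    d = day0
    while d < t1:
        days.append(d)
        d += timedelta(days=1)
    return days


def daily_displacements(track: MigrationTrack) -> pd.DataFrame:
    """Net displacement (km) of each UTC calendar day spanned by the
    track, between interpolated day-boundary positions."""
    days = _day_range(track)
    rows = []
    for d in days:
        a = track.position_at(max(d, track.start_fix.timestamp))
        b = track.position_at(min(d + timedelta(days=1),
                                  track.end_fix.timestamp))
        rows.append({"day": d, "net_km": geodesy.vincenty_km(*a, *b)})
    return pd.DataFrame(rows)


def detect_stopovers(track: MigrationTrack,
                     threshold_km_per_day: float = 50.0,
                     min_days: int = 3) -> list[Stopover]:
    """Stopovers: maximal runs of consecutive days each with net travel
    below ``threshold_km_per_day``, kept only when strictly longer than
    ``min_days`` days.  Returns disjoint, chronologically ordered
    intervals; empty list for tracks shorter than one day."""
    if len(track.fixes) < 2:
        return []
    if (track.end_fix.timestamp - track.start_fix.timestamp) < timedelta(days=1):
        return []
    dd = daily_displacements(track)
    slow = (dd["net_km"] < threshold_km_per_day).to_numpy()
    out: list[Stopover] = []
    i = 0
    n = len(slow)
    while i < n:
        if not slow[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and slow[j + 1]:
            j += 1
        run_len = j - i + 1
        if run_len > min_days:
            arrival = max(dd["day"].iloc[i], track.start_fix.timestamp)
            departure = min(dd["day"].iloc[j] + timedelta(days=1),
                            track.end_fix.timestamp)
            fx = [f for f in track.fixes
                  if arrival <= f.timestamp < departure]
            if fx:
                clon = float(np.mean([f.lon for f in fx]))
                clat = float(np.mean([f.lat for f in fx]))
            else:
                clon, clat = track.position_at(arrival)
            out.append(Stopover(
                center_lon=clon, center_lat=clat,
                arrival=arrival, departure=departure,
                duration_days=(departure - arrival) / timedelta(days=1),
                fixes=fx))
        i = j + 1
    return out


def geodesic_length(points: Sequence[tuple[float, float]]) -> float:
    """WGS84 geodesic length (km) of an ordered (lon, lat) polyline."""
    return geodesy.geodesic_length_km(points)


def migration_fixes(track: MigrationTrack,
                    stopovers: Sequence[Stopover]) -> list[Fix]:
    """Fixes outside every stopover interval ("only migrating movement
    points")."""
    return [f for f in track.fixes
            if not any(s.arrival <= f.timestamp < s.departure
                       for s in stopovers)]


def migration_track(track: MigrationTrack,
                    stopovers: Sequence[Stopover]) -> MigrationTrack:
    """Copy of the track with stopover fixes removed — the record of
    actual migratory movement used for route lengths and for movement
    segments (stationary stopover days would otherwise contribute
    spurious near-zero segments)."""
    fx = migration_fixes(track, stopovers)
    if len(fx) < 2:
        raise DegenerateTrackError("fewer than 2 fixes outside stopovers")
    return MigrationTrack(individual_id=track.individual_id,
                          season=track.season, year=track.year, fixes=fx)


def amr_length(track: MigrationTrack,
               stopovers: Sequence[Stopover]) -> float:
    """Length (km) of the actual migration route with stopover fixes
    removed, so within-site wander does not inflate travel distance."""
    fx = migration_fixes(track, stopovers)
    if len(fx) < 2:
        raise DegenerateTrackError(
            "fewer than 2 fixes outside stopovers; no route remains")
    return geodesic_length([f.lonlat for f in fx])


def detour_extent(amr_km: float, gcr_km: float) -> float:
    """Relative detour: (AMR − GCR) / GCR."""
    if gcr_km <= 0:
        raise ValidationError("gcr_km must be positive")
    return (amr_km - gcr_km) / gcr_km


def route_pair(track: MigrationTrack, stopovers: Sequence[Stopover],
               spacing_km: float = 100.0) -> RoutePair:
    """AMR plus its great-circle reference route between the same
    endpoints, sampled every ``spacing_km``."""
    gcr = geodesy.great_circle_route(track.start_fix.lonlat,
                                     track.end_fix.lonlat, spacing_km)
    return RoutePair(
        amr=track, gcr_points=gcr,
        amr_length_km=amr_length(track, stopovers),
        gcr_length_km=geodesic_length(gcr))


@dataclass
class TravelSpeeds:
    total_days: float
    traveling_days: float
    speed_km_per_day: float
    active_speed_km_per_day: float


def travel_speeds(track: MigrationTrack, stopovers: Sequence[Stopover],
                  amr_km: float) -> TravelSpeeds:
    """Overall speed (over all migration days, stopovers included) and
    active speed (over traveling days only)."""
    total = (track.end_fix.timestamp - track.start_fix.timestamp) \
        / timedelta(days=1)
    if total <= 0:
        raise ValidationError("track must span at least part of a day")
    stop_days = sum(s.duration_days for s in stopovers)
    traveling = total - stop_days
    if traveling <= 0:
        raise DegenerateTrackError("zero traveling days")
    return TravelSpeeds(total, traveling, amr_km / total, amr_km / traveling)


def _nearest_mid_fix(fixes: Sequence[Fix]) -> Fix:
    t0, t1 = fixes[0].timestamp, fixes[-1].timestamp
    mid = t0 + (t1 - t0) / 2
    best = min(fixes, key=lambda f: (abs((f.timestamp - mid).total_seconds()),
                                     f.timestamp))
    return best


def build_segments(track: MigrationTrack, mode: str,
                   daytime_window: tuple[int, int] = (0, 14),
                   min_km: float = 50.0,
                   min_hours: float = 4.0) -> list[Segment]:
    """Movement segments for the wind analysis.

    ``mode='ptt'``: maximal runs of daytime fixes within one UTC day
    form a candidate step; kept when its displacement exceeds
    ``min_km`` and its duration is at least ``min_hours``.
    ``mode='gps'``: one segment per UTC day from the day's first to
    last fix; days with fewer than two fixes are skipped.
    The segment midpoint is the fix nearest the temporal middle (ties
    toward the earlier fix)."""
    if mode not in ("ptt", "gps"):
        raise ValidationError(f"unknown segment mode {mode!r}")
    segs: list[Segment] = []
    fixes = track.fixes
    if mode == "gps":
        groups: dict = {}
        for f in fixes:
            groups.setdefault(f.timestamp.date(), []).append(f)
        for day in sorted(groups):
            fx = groups[day]
            if len(fx) < 2:
                continue
            seg = _make_segment(fx, "gps_daily")
            if seg is not None:
                segs.append(seg)
    else:
        h0, h1 = daytime_window
        day_fixes = [f for f in fixes if h0 <= f.timestamp.hour < h1]
        groups = {}
        for f in day_fixes:
            groups.setdefault(f.timestamp.date(), []).append(f)
        for day in sorted(groups):
            fx = groups[day]
            if len(fx) < 2:
                continue
            disp = geodesy.vincenty_km(*fx[0].lonlat, *fx[-1].lonlat)
            dur = (fx[-1].timestamp - fx[0].timestamp).total_seconds() / 3600
            if disp > min_km and dur >= min_hours:
                segs.append(_make_segment(fx, "ptt_rule"))
    return segs


def _make_segment(fx: Sequence[Fix], source: str) -> Segment | None:
    disp = geodesy.vincenty_km(*fx[0].lonlat, *fx[-1].lonlat)
    dur = (fx[-1].timestamp - fx[0].timestamp).total_seconds() / 3600
    if dur <= 0:
        return None
    return Segment(onset=fx[0], midpoint=_nearest_mid_fix(fx), end=fx[-1],
                   displacement_km=disp, duration_h=dur, source=source)


def project_track_onto_gcr(track: MigrationTrack,
                           gcr_points: Sequence[tuple[float, float]]) -> list[Fix]:
    """Map each fix to the point at the same fraction of cumulative
    route distance along the great-circle reference route, keeping the
    original timestamp — the "same wind clock, direct route" control
    used for the tailwind comparison."""
    amr_pts = [f.lonlat for f in track.fixes]
    seg = [geodesy.vincenty_km(*p, *q)
           for p, q in zip(amr_pts[:-1], amr_pts[1:])]
    total = sum(seg)
    cum = [0.0]
    for d in seg:
        cum.append(cum[-1] + d)
    out = []
    for f, c in zip(track.fixes, cum):
        frac = c / total if total > 0 else 0.0
        lon, lat = geodesy.interpolate_along(list(gcr_points), frac)
        out.append(replace(f, lon=lon, lat=lat))
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O

_COLUMN_ALIASES = {
    "individual_id": ["individual_id", "individual-local-identifier", "id"],
    "timestamp": ["timestamp", "study-local-timestamp", "time"],
    "lon": ["lon", "longitude", "location-long"],
    "lat": ["lat", "latitude", "location-lat"],
    "altitude": ["altitude", "altitude_amsl", "height-above-msl"],
    "quality": ["quality", "argos-lc", "lc"],
}


def read_fixes(path, aliases: dict | None = None) -> list[Fix]:
    """Read a delimited-text fix table (Movebank-style aliases accepted)."""
    df = pd.read_csv(path)
    amap = dict(_COLUMN_ALIASES)
    if aliases:
        for k, v in aliases.items():
            amap[k] = [v] + amap.get(k, [])
    cols = {}
    for key, names in amap.items():
        for name in names:
            if name in df.columns:
                cols[key] = name
                break
    for req in ("individual_id", "timestamp", "lon", "lat"):
        if req not in cols:
            raise ValidationError(f"missing required column {req!r}")
    fixes = []
    for _, r in df.iterrows():
        ts = pd.Timestamp(r[cols["timestamp"]])
        if ts.tzinfo is None:
            ts = ts.tz_localize("UTC")
        alt = None
        if "altitude" in cols and pd.notna(r[cols["altitude"]]):
            alt = float(r[cols["altitude"]])
        fixes.append(Fix(
            individual_id=str(r[cols["individual_id"]]),
            timestamp=ts.to_pydatetime(),
            lon=float(r[cols["lon"]]), lat=float(r[cols["lat"]]),
            quality=str(r[cols["quality"]]) if "quality" in cols else "GPS",
            altitude_amsl=alt))
    return fixes


def write_fixes(fixes: Iterable[Fix], path) -> None:
    pd.DataFrame([{
        "individual_id": f.individual_id,
        "timestamp": f.timestamp.isoformat(),
        "lon": f.lon, "lat": f.lat,
        "altitude": f.altitude_amsl, "quality": f.quality,
    } for f in fixes]).to_csv(path, index=False)
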