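"""Raster sampling along routes, barrier extent, land-cover
reclassification, stopover footprints (100% MCP) and NDVI extraction.

Rasters are regular geographic (lon/lat) grids; sampling is
nearest-cell with no interpolation, matching the point-sampling
convention of desktop GIS tools.  File I/O uses the plain-text ESRI
ASCII grid format (readable by QGIS/GDAL), which keeps synthetic
fixtures human-inspectable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient
from statsmodels.stats.proportion import proportions_ztest

from . import geodesy
from .errors import (DegenerateGeometryError, OutOfBoundsError,
                     ValidationError)

LANDCOVER_CLASSES = (
    "Cropland", "Cropland mosaic", "Forest", "Open natural ecosystem",
    "Urban areas", "Bare areas", "Water body", "Permanent snow and ice")

#: latitudinal bands (degrees N) used for elevation summaries
DEFAULT_BANDS = ((8, 18), (18, 28), (28, 38), (38, 48), (48, 58))


@dataclass
class Raster:
    """Single-band regular lon/lat grid.

    ``values`` is [nrows, ncols] with row 0 the NORTHERNMOST row (the
    ASCII-grid convention); (xll, yll) is the lower-left corner of the
    lower-left cell.
    """
    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0
    semantics: str = "elevation_m"

    def __post_init__(self):
        if self.cellsize <= 0:
            raise ValidationError("cellsize must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("raster values must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.xll, self.yll,
                self.xll + self.ncols * self.cellsize,
                self.yll + self.nrows * self.cellsize)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (np.arange(self.nrows) + 0.5) * self.cellsize
        return xs, ys[::-1]  # y ordered like rows (north to south)

    def to_ascii(self, path) -> None:
        header = (f"ncols {self.ncols}\nnrows {self.nrows}\n"
                  f"xllcorner {self.xll}\nyllcorner {self.yll}\n"
                  f"cellsize {self.cellsize}\nNODATA_value {self.nodata}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, np.where(np.isnan(self.values), self.nodata,
                                    self.values), fmt="%.6g")

    @classmethod
    def from_ascii(cls, path, semantics: str = "elevation_m") -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        for line in lines[:6]:
            key, val = line.split()
            header[key.lower()] = float(val)
        values = np.loadtxt(lines[6:])
        return cls(values=np.atleast_2d(values),
                   xll=header["xllcorner"], yll=header["yllcorner"],
                   cellsize=header["cellsize"],
                   nodata=header.get("nodata_value", -9999.0),
                   semantics=semantics)


def sample_raster(points, raster: Raster,
                  out_of_bounds: str = "warn") -> np.ndarray:
    """Nearest-cell value for each (lon, lat) point.

    Nodata cells and (by default) out-of-extent points yield NaN; set
    ``out_of_bounds='error'`` to raise instead."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cols = np.floor((pts[:, 0] - raster.xll) / raster.cellsize).astype(int)
    rows_from_bottom = np.floor(
        (pts[:, 1] - raster.yll) / raster.cellsize).astype(int)
    rows = raster.nrows - 1 - rows_from_bottom
    inside = ((cols >= 0) & (cols < raster.ncols)
              & (rows >= 0) & (rows < raster.nrows))
    if not inside.all():
        if out_of_bounds == "error":
            raise OutOfBoundsError(
                f"{(~inside).sum()} point(s) outside raster extent")
        warnings.warn(f"{(~inside).sum()} point(s) outside raster extent; "
                      "returned as missing", stacklevel=2)
    out = np.full(len(pts), np.nan)
    vals = raster.values[rows[inside], cols[inside]]
    vals = np.where(vals == raster.nodata, np.nan, vals)
    out[inside] = vals
    return out


def altitude_above_ground(altitude_amsl: float | np.ndarray,
                          ground_elevation_m: float | np.ndarray):
    """Flight altitude above ground: tag altitude minus ground
    elevation.  Negative values (GPS error) are preserved, not clipped."""
    alt = np.asarray(altitude_amsl, dtype=float)
    if np.isnan(alt).any():
        raise ValidationError("altitude_amsl missing for some fixes")
    return alt - np.asarray(ground_elevation_m, dtype=float)


@dataclass
class BandSummary:
    band: tuple[float, float]
    n_amr: int
    n_gcr: int
    mean_amr: float
    mean_gcr: float
    se_amr: float
    se_gcr: float
    max_amr: float
    max_gcr: float
    statistic: float
    p: float
    test: str


def _band_stats(v: np.ndarray) -> tuple[float, float, float]:
    if len(v) == 0:
        return (np.nan, np.nan, np.nan)
    se = float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else np.nan
    return float(np.mean(v)), se, float(np.max(v))


def elevation_band_summary(amr_lats, amr_values, gcr_lats, gcr_values,
                           bands=DEFAULT_BANDS) -> list[BandSummary]:
    """Per-latitude-band elevation statistics for the actual and the
    great-circle route, with an unpaired rank-sum test per band (the
    two routes sample different numbers of points, so samples are not
    paired)."""
    amr_lats = np.asarray(amr_lats, float)
    gcr_lats = np.asarray(gcr_lats, float)
    amr_values = np.asarray(amr_values, float)
    gcr_values = np.asarray(gcr_values, float)
    out = []
    for lo, hi in bands:
        a = amr_values[(amr_lats >= lo) & (amr_lats < hi)]
        g = gcr_values[(gcr_lats >= lo) & (gcr_lats < hi)]
        a, g = a[~np.isnan(a)], g[~np.isnan(g)]
        mean_a, se_a, max_a = _band_stats(a)
        mean_g, se_g, max_g = _band_stats(g)
        if len(a) > 0 and len(g) > 0:
            if np.array_equal(np.sort(a), np.sort(g)):
                stat, p = float(len(a) * len(g) / 2.0), 1.0
            else:
                stat, p = stats.mannwhitneyu(a, g, alternative="two-sided")
        else:
            stat, p = np.nan, np.nan
        out.append(BandSummary(band=(lo, hi), n_amr=len(a), n_gcr=len(g),
                               mean_amr=mean_a, mean_gcr=mean_g,
                               se_amr=se_a, se_gcr=se_g,
                               max_amr=max_a, max_gcr=max_g,
                               statistic=float(stat), p=float(p),
                               test="mann-whitney-u"))
    return out


def barrier_extent(gcr_points, elevation_raster: Raster,
                   threshold_m: float = 3500.0) -> float:
    """Along-route extent (km) of terrain above ``threshold_m`` on a
    sampled route — the operational barrier distance Yb.

    Each maximal run of consecutive above-threshold samples contributes
    the route length between the midpoints of its flanking sample
    intervals (clipped at the route ends); runs are summed."""
    pts = list(gcr_points)
    if len(pts) == 0:
        raise ValidationError("empty route")
    elev = sample_raster(pts, elevation_raster)
    above = np.nan_to_num(elev, nan=-np.inf) > threshold_m
    if not above.any():
        return 0.0
    seg = [geodesy.vincenty_km(*p, *q) for p, q in zip(pts[:-1], pts[1:])]
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = 0.0
    i, n = 0, len(pts)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        start = cum[0] if i == 0 else 0.5 * (cum[i - 1] + cum[i])
        end = cum[-1] if j == n - 1 else 0.5 * (cum[j] + cum[j + 1])
        total += end - start
        i = j + 1
    return float(total)


@dataclass
class ReclassMap:
    """Total mapping from source land-cover codes to the 8 thematic
    classes; unmapped codes are an error, never silently dropped."""
    mapping: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = set(self.mapping.values()) - set(LANDCOVER_CLASSES)
        if bad:
            raise ValidationError(f"unknown thematic classes: {sorted(bad)}")

    def __getitem__(self, code: int) -> str:
        try:
            return self.mapping[int(code)]
        except KeyError:
            raise ValidationError(
                f"land-cover code {code} not in reclassification map") from None


def load_reclass_toml(path) -> ReclassMap:
    """Load a [mapping] table of source code -> thematic class."""
    import tomllib
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return ReclassMap(mapping={int(k): v for k, v in raw["mapping"].items()})


def esa_cci_reclass() -> ReclassMap:
    """The shipped default aggregation of the 37 ESA-CCI land-cover
    codes into the 8 thematic classes (editable config file under
    ``detourkit/data/``)."""
    from importlib.resources import files
    return load_reclass_toml(files("detourkit") / "data"
                             / "esa_cci_reclass.toml")


def reclassify_landcover(codes, reclass_map: ReclassMap) -> list[str]:
    """Map raw land-cover codes to the 8 thematic classes."""
    return [reclass_map[c] for c in np.asarray(codes).ravel()]


def landcover_proportions(amr_classes, gcr_classes
                          ) -> pd.DataFrame:
    """Per-class shares of points on each route, with a pooled
    two-proportion z test per class; z is reported NaN where the test
    is undefined (class absent from both or present in all points)."""
    a = pd.Series(list(amr_classes))
    g = pd.Series(list(gcr_classes))
    n_a, n_g = len(a), len(g)
    rows = []
    for cls in LANDCOVER_CLASSES:
        ca, cg = int((a == cls).sum()), int((g == cls).sum())
        if 0 < ca + cg < n_a + n_g:
            z, p = proportions_ztest([ca, cg], [n_a, n_g])
        else:
            z, p = np.nan, np.nan
        rows.append({"class": cls, "count_amr": ca, "count_gcr": cg,
                     "prop_amr": ca / n_a if n_a else np.nan,
                     "prop_gcr": cg / n_g if n_g else np.nan,
                     "z": float(z) if np.isfinite(z) else np.nan,
                     "p": float(p) if np.isfinite(p) else np.nan})
    return pd.DataFrame(rows).set_index("class")


def mcp100(points) -> Polygon:
    """100% minimum convex polygon (plain convex hull, no peeling) of a
    point set, as a counter-clockwise closed ring.

    Planar hull on lon/lat degrees — adequate at stopover scales
    (< 200 km), where the metric distortion is well below cell size."""
    pts = [(float(x), float(y)) for x, y in points]
    if len(set(pts)) < 3:
        raise DegenerateGeometryError("MCP needs at least 3 distinct points")
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon":
        raise DegenerateGeometryError("points are collinear; no polygon")
    return orient(hull, sign=1.0)


def monthly_ndvi(polygon: Polygon, ndvi_stack: dict[str, Raster]
                 ) -> pd.Series:
    """Mean NDVI of in-polygon cells per month.

    The cell-in-polygon test uses cell centres (boundary inclusive);
    nodata cells are excluded.  Raises when no cell centre falls inside
    the polygon."""
    out = {}
    for month, raster in ndvi_stack.items():
        xs, ys = raster.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.intersects_xy(polygon, gx.ravel(), gy.ravel())
        if not inside.any():
            raise ValidationError(
                f"polygon overlaps no raster cells (month {month})")
        vals = raster.values.ravel()[inside]
        vals = vals[(vals != raster.nodata) & ~np.isnan(vals)]
        if len(vals) == 0:
            raise ValidationError(
                f"polygon covers only nodata cells (month {month})")
        out[month] = float(np.mean(vals))
    return pd.Series(out, name="mean_ndvi")
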