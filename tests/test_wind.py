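"""Wind interpolation, segment weighting, drift decomposition and
classification, band tables, regressions and the route comparison."""

import math
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from detourkit import geodesy, tracks, wind
from detourkit.errors import (NumericalError, OutOfBoundsError,
                              ValidationError)
from detourkit.tracks import Fix, MigrationTrack, Segment
from detourkit.wind import WindGrid, WindVector

from conftest import make_daily_track

UTC = timezone.utc
T0 = datetime(2020, 3, 1, tzinfo=UTC)


def small_grid(u_fn=None, v_fn=None):
    lons = np.array([60.0, 62.5, 65.0])
    lats = np.array([10.0, 12.5, 15.0])
    times = (np.datetime64("2020-03-01T00:00", "ns")
             + np.arange(4) * np.timedelta64(6 * 3600, "s"))
    shape = (4, 3, 3)
    u = np.zeros(shape)
    v = np.zeros(shape)
    for it in range(4):
        for ila, la in enumerate(lats):
            for ilo, lo in enumerate(lons):
                u[it, ila, ilo] = u_fn(lo, la, it) if u_fn else 0.0
                v[it, ila, ilo] = v_fn(lo, la, it) if v_fn else 0.0
    return WindGrid(lons=lons, lats=lats, times=times, u=u, v=v)


def make_segment(lon0, lat0, lon1, lat1, hours=24.0, t0=T0):
    f0 = Fix("b", t0, lon0, lat0)
    f1 = Fix("b", t0 + timedelta(hours=hours), lon1, lat1)
    mid = Fix("b", t0 + timedelta(hours=hours / 2),
              (lon0 + lon1) / 2, (lat0 + lat1) / 2)
    return Segment(onset=f0, midpoint=mid, end=f1,
                   displacement_km=geodesy.vincenty_km(lon0, lat0, lon1, lat1),
                   duration_h=hours, source="gps_daily")


class TestInterpolation:
    def test_node_exactness(self):
        g = small_grid(u_fn=lambda lo, la, it: lo + la + it)
        w = wind.interpolate_wind(g, 62.5, 12.5,
                                  datetime(2020, 3, 1, 6, tzinfo=UTC))
        assert w.u == pytest.approx(62.5 + 12.5 + 1, rel=1e-12)
        assert w.v == 0.0

    def test_midway_linearity(self):
        g = small_grid(u_fn=lambda lo, la, it: 2.0 if lo == 60.0 else
                       (6.0 if lo == 62.5 else 6.0))
        w = wind.interpolate_wind(g, 61.25, 10.0, T0)
        assert w.u == pytest.approx(4.0, rel=1e-12)

    def test_brute_force_corner_weight_oracle(self):
        rng = np.random.default_rng(5)
        g = small_grid(u_fn=lambda lo, la, it: math.sin(lo) + la * it,
                       v_fn=lambda lo, la, it: lo - la + it ** 2)
        taxis = g.times.astype("datetime64[s]").astype(float)
        for _ in range(50):
            lon = rng.uniform(60, 65)
            lat = rng.uniform(10, 15)
            # whole seconds: datetime carries microsecond precision
            tf = float(rng.integers(int(taxis[0]), int(taxis[-1]) + 1))
            t = datetime.fromtimestamp(tf, tz=UTC)
            # independent trilinear weight sum over the 8 corners
            def brute(arr):
                i = np.searchsorted(taxis, tf, side="right") - 1
                i = min(i, len(taxis) - 2)
                j = np.searchsorted(g.lats, lat, side="right") - 1
                j = min(j, len(g.lats) - 2)
                k = np.searchsorted(g.lons, lon, side="right") - 1
                k = min(k, len(g.lons) - 2)
                wt = (tf - taxis[i]) / (taxis[i + 1] - taxis[i])
                wy = (lat - g.lats[j]) / (g.lats[j + 1] - g.lats[j])
                wx = (lon - g.lons[k]) / (g.lons[k + 1] - g.lons[k])
                total = 0.0
                for dt in (0, 1):
                    for dy in (0, 1):
                        for dx in (0, 1):
                            w8 = ((wt if dt else 1 - wt)
                                  * (wy if dy else 1 - wy)
                                  * (wx if dx else 1 - wx))
                            total += w8 * arr[i + dt, j + dy, k + dx]
                return total
            got = wind.interpolate_wind(g, lon, lat, t)
            assert got.u == pytest.approx(brute(g.u), abs=1e-10)
            assert got.v == pytest.approx(brute(g.v), abs=1e-10)

    def test_out_of_bounds_raises(self):
        g = small_grid()
        with pytest.raises(OutOfBoundsError):
            wind.interpolate_wind(g, 59.0, 12.0, T0)
        with pytest.raises(OutOfBoundsError):
            wind.interpolate_wind(g, 62.0, 12.0,
                                  T0 - timedelta(hours=1))

    def test_netcdf_roundtrip(self, tmp_path):
        g = small_grid(u_fn=lambda lo, la, it: lo - la,
                       v_fn=lambda lo, la, it: it * 1.0)
        path = tmp_path / "uv.nc"
        g.to_netcdf(path)
        back = WindGrid.from_netcdf(path)
        np.testing.assert_allclose(back.u, g.u)
        np.testing.assert_allclose(back.v, g.v)
        np.testing.assert_allclose(back.lats, g.lats)
        assert back.pressure_level == g.pressure_level


class TestWindVector:
    @pytest.mark.parametrize("u,v,speed,direction", [
        (0.0, 5.0, 5.0, 0.0),       # blowing toward north
        (5.0, 0.0, 5.0, 90.0),      # toward east
        (0.0, -5.0, 5.0, 180.0),
        (-3.0, -4.0, 5.0, 216.869897645844),
    ])
    def test_speed_and_direction(self, u, v, speed, direction):
        w = WindVector(u, v)
        assert w.speed == pytest.approx(speed)
        assert w.direction_deg == pytest.approx(direction)
        assert w.direction_from_deg \
            == pytest.approx((direction + 180.0) % 360.0)


class TestSegmentWind:
    def test_identical_vectors(self):
        w = wind.segment_wind(WindVector(3, 0), WindVector(3, 0),
                              WindVector(3, 0))
        assert (w.u, w.v) == (3.0, 0.0)

    def test_midpoint_double_weight(self):
        w = wind.segment_wind(WindVector(0, 0), WindVector(2, 0),
                              WindVector(0, 0))
        assert w.u == pytest.approx(1.0)

    def test_onset_single_weight(self):
        w = wind.segment_wind(WindVector(4, 0), WindVector(0, 0),
                              WindVector(0, 0))
        assert w.u == pytest.approx(1.0)


class TestGoalDirection:
    def test_cardinal_directions(self):
        north = make_daily_track([200] * 3, bearing=0.0)
        assert wind.goal_direction(north) == pytest.approx(0.0, abs=1e-9)
        fixes = [Fix("b", T0, 0, 0), Fix("b", T0 + timedelta(days=1), 10, 0)]
        east = MigrationTrack("b", "spring", 2020, fixes)
        assert wind.goal_direction(east) == pytest.approx(90.0)

    def test_matches_bearing_formula(self):
        fixes = [Fix("b", T0, 74.43, 27.81),
                 Fix("b", T0 + timedelta(days=1), 66.85, 37.11)]
        t = MigrationTrack("b", "spring", 2020, fixes)
        assert wind.goal_direction(t) == pytest.approx(
            geodesy.initial_bearing_deg(74.43, 27.81, 66.85, 37.11),
            abs=1e-9)

    def test_identical_endpoints_rejected(self):
        fixes = [Fix("b", T0, 70, 10), Fix("b", T0 + timedelta(days=1), 70, 10)]
        t = MigrationTrack("b", "spring", 2020, fixes)
        with pytest.raises(ValidationError):
            wind.goal_direction(t)


class TestDecompose:
    def test_pure_tailwind(self):
        seg = make_segment(70, 10, 70, 12)
        r = wind.decompose(seg, WindVector(0, 5), 0.0)
        assert r.tailwind_ms == pytest.approx(5.0)
        assert r.crosswind_ms == pytest.approx(0.0, abs=1e-12)

    def test_pure_crosswind_right_positive(self):
        seg = make_segment(70, 10, 70, 12)
        r = wind.decompose(seg, WindVector(5, 0), 0.0)
        assert r.tailwind_ms == pytest.approx(0.0, abs=1e-12)
        assert r.crosswind_ms == pytest.approx(5.0)

    def test_rotation_matrix_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            u, v = rng.normal(0, 5, 2)
            goal = rng.uniform(0, 360)
            g = math.radians(goal)
            rot = np.array([[math.sin(g), math.cos(g)],
                            [math.cos(g), -math.sin(g)]])
            tail, cross = rot @ np.array([u, v])
            seg = make_segment(70, 10, 70.5, 12)
            r = wind.decompose(seg, WindVector(u, v), goal)
            assert r.tailwind_ms == pytest.approx(tail, abs=1e-10)
            assert r.crosswind_ms == pytest.approx(cross, abs=1e-10)

    def test_movement_decomposition_conserves_magnitude(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            lon0 = rng.uniform(60, 80)
            lat0 = rng.uniform(5, 45)
            brg = rng.uniform(0, 360)
            dist = rng.uniform(30, 500)
            lon1, lat1 = geodesy.destination(lon0, lat0, brg, dist)
            seg = make_segment(lon0, lat0, lon1, lat1,
                               hours=rng.uniform(4, 30))
            r = wind.decompose(seg, WindVector(1, 1), rng.uniform(0, 360))
            rate = seg.daily_displacement_km_per_day
            assert r.forward_move_kmday ** 2 + r.perp_move_kmday ** 2 \
                == pytest.approx(rate ** 2, rel=1e-6)

    def test_equivariance_under_frame_rotation(self):
        """Rotating goal, wind and movement bearing together leaves
        all four components unchanged."""
        rng = np.random.default_rng(17)
        for delta in (37.0, 123.0, 291.0):
            u, v = 3.0, -2.0
            goal = 20.0
            seg = make_segment(0, 0, *geodesy.destination(0, 0, 45.0, 200.0))
            base = wind.decompose(seg, WindVector(u, v), goal)
            g = math.radians(delta)
            u2 = u * math.cos(g) + v * math.sin(g)
            v2 = -u * math.sin(g) + v * math.cos(g)
            seg2 = make_segment(0, 0, *geodesy.destination(
                0, 0, 45.0 + delta, 200.0))
            rot = wind.decompose(seg2, WindVector(u2, v2), goal + delta)
            assert rot.tailwind_ms == pytest.approx(base.tailwind_ms,
                                                    abs=1e-9)
            assert rot.crosswind_ms == pytest.approx(base.crosswind_ms,
                                                     abs=1e-9)
            # movement components compared as direction cosines: the
            # geodesic length of a fixed spherical step varies slightly
            # with bearing on the ellipsoid
            r1 = base.segment.daily_displacement_km_per_day
            r2 = rot.segment.daily_displacement_km_per_day
            assert rot.forward_move_kmday / r2 == pytest.approx(
                base.forward_move_kmday / r1, abs=1e-9)
            assert rot.perp_move_kmday / r2 == pytest.approx(
                base.perp_move_kmday / r1, abs=1e-9)

    def test_zero_length_segment_unclassified(self):
        f0 = Fix("b", T0, 70, 10)
        f1 = Fix("b", T0 + timedelta(hours=10), 70, 10)
        seg = Segment(f0, f0, f1, 0.0, 10.0, "gps_daily")
        r = wind.decompose(seg, WindVector(5, 5), 0.0)
        assert r.behaviour == "unclassified"


class TestClassifyDrift:
    @pytest.mark.parametrize("perp,cross,expected", [
        (80.0, 3.0, "drift"),
        (-80.0, -3.0, "drift"),
        (0.0, 5.0, "compensation"),
        (49.9, -5.0, "compensation"),
        (-80.0, 3.0, "overcompensation"),
        (80.0, -3.0, "overcompensation"),
        (80.0, 0.0, "unclassified"),
    ])
    def test_rules(self, perp, cross, expected):
        assert wind.classify_drift(perp, cross) == expected

    def test_truth_table_oracle(self):
        """Exhaustive agreement with an independently written rule."""
        def oracle(pm, cw, thr=50.0):
            if -thr <= pm <= thr:
                return "compensation"
            if cw == 0.0:
                return "unclassified"
            same = (pm > 0) == (cw > 0)
            return "drift" if same else "overcompensation"
        for pm in range(-100, 101):
            for cw in (-5.0, -0.1, 0.0, 0.1, 5.0):
                assert wind.classify_drift(float(pm), cw) == oracle(pm, cw)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            wind.classify_drift(float("nan"), 1.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(pm=st.floats(-500, 500), cw=st.floats(-30, 30),
           thr=st.floats(1.0, 100.0))
    def test_total_and_band_property(self, pm, cw, thr):
        label = wind.classify_drift(pm, cw, thr)
        assert label in ("drift", "compensation", "overcompensation",
                         "unclassified")
        if abs(pm) <= thr:
            assert label == "compensation"
        else:
            assert label != "compensation"


class TestBandFrequencies:
    def _record(self, perp, cross, lat, season="spring"):
        seg = make_segment(70, lat - 0.5, 70, lat + 0.5)
        return self._manual(seg, perp, cross, season)

    @staticmethod
    def _manual(seg, perp, cross, season):
        return wind.DriftRecord(
            segment=seg, goal_bearing_deg=0.0, tailwind_ms=0.0,
            crosswind_ms=cross, forward_move_kmday=150.0,
            perp_move_kmday=perp,
            behaviour=wind.classify_drift(perp, cross),
            lat_band=wind.latitude_band(seg.midpoint.lat), season=season)

    def test_counts_and_total_preserved(self):
        recs = [self._record(80, 3, 20), self._record(0, 3, 20),
                self._record(-80, 3, 35), self._record(80, 3, 45),
                self._record(60, 0, 45)]          # last one unclassified
        table, chi2, dof, p = wind.band_frequencies(recs)
        assert table.to_numpy().sum() == 4
        assert table.loc["south_of_30", "drift"] == 1
        assert table.loc["south_of_30", "compensation"] == 1
        assert table.loc["band_30_40", "overcompensation"] == 1

    def test_identical_bands_chi2_zero(self):
        recs = [self._record(80, 3, lat) for lat in (20, 35, 45)] * 5
        table, chi2, dof, p = wind.band_frequencies(recs)
        assert chi2 == 0.0

    def test_hand_built_table_matches_textbook_formula(self):
        recs = ([self._record(80, 3, 20)] * 10
                + [self._record(0, 3, 20)] * 5
                + [self._record(80, 3, 35)] * 4
                + [self._record(0, 3, 35)] * 11
                + [self._record(80, 3, 45)] * 7
                + [self._record(-80, 3, 45)] * 3)
        table, chi2, dof, p = wind.band_frequencies(recs)
        obs = table.loc[:, table.sum(axis=0) > 0].to_numpy().astype(float)
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        exp = row @ col / obs.sum()
        assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(),
                                     rel=1e-12)
        assert dof == (obs.shape[0] - 1) * (obs.shape[1] - 1)


class TestDriftRegression:
    def _rec(self, perp, cross, fwd=150.0, tail=1.0, season="spring"):
        seg = make_segment(70, 20, 70, 21)
        return wind.DriftRecord(
                segment=seg, goal_bearing_deg=0.0, tailwind_ms=tail,
                crosswind_ms=cross, forward_move_kmday=fwd,
                perp_move_kmday=perp,
                behaviour=wind.classify_drift(perp, cross),
                lat_band="south_of_30", season=season)

    def test_collinear_slope_exact(self):
        recs = [self._rec(24.7 * c, c, fwd=23.2 * c + 150.0, tail=c)
                for c in (-3.0, -1.0, 0.5, 2.0, 4.0)]
        res = wind.drift_regression(recs)["perp_on_crosswind"]
        assert res.slope == pytest.approx(24.7, rel=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(23)
        recs = [self._rec(20 * c + rng.normal(0, 5), c, tail=c)
                for c in rng.normal(0, 2, 30)]
        a = wind.drift_regression(recs)["perp_on_crosswind"].slope
        b = wind.drift_regression(recs[::-1])["perp_on_crosswind"].slope
        assert a == pytest.approx(b, rel=1e-12)

    def test_constant_predictor_raises(self):
        recs = [self._rec(10.0, 2.0)] * 5
        with pytest.raises(NumericalError):
            wind.drift_regression(recs)

    def test_season_filter(self):
        recs = ([self._rec(10 * c, c, tail=c, season="spring")
                 for c in (-2, -1, 1, 2)]
                + [self._rec(30 * c, c, tail=c, season="autumn")
                   for c in (-2, -1, 1, 2)])
        sp = wind.drift_regression(recs, "spring")["perp_on_crosswind"]
        au = wind.drift_regression(recs, "autumn")["perp_on_crosswind"]
        assert sp.slope == pytest.approx(10.0, rel=1e-9)
        assert au.slope == pytest.approx(30.0, rel=1e-9)


class TestTailwindComparison:
    def _rec(self, tail):
        seg = make_segment(70, 20, 70, 21)
        return wind.DriftRecord(
            segment=seg, goal_bearing_deg=0.0, tailwind_ms=tail,
            crosswind_ms=0.0, forward_move_kmday=100.0,
            perp_move_kmday=0.0, behaviour="compensation",
            lat_band="south_of_30")

    def test_identical_inputs_zero_difference(self):
        recs = [self._rec(t) for t in (1.0, -2.0, 3.0)]
        cmp = wind.tailwind_amr_vs_gcr(recs, list(recs))
        assert cmp.mean_difference == 0.0
        assert cmp.t == 0.0

    def test_constructed_offset_recovered(self):
        rng = np.random.default_rng(31)
        base = rng.normal(0, 1, 40)
        amr = [self._rec(b + 2.0) for b in base]
        gcr = [self._rec(b) for b in base]
        cmp = wind.tailwind_amr_vs_gcr(amr, gcr)
        assert cmp.mean_difference == pytest.approx(2.0, abs=1e-9)
        assert cmp.p < 1e-6

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValidationError):
            wind.tailwind_amr_vs_gcr([self._rec(1.0)], [])
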