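"""Shared fixtures: synthetic wind, tracks and rasters, built once."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from detourkit import synthetic, tracks

UTC = timezone.utc


def make_daily_track(daily_km, individual_id="b1", season="spring",
                     start=(70.0, 10.0), bearing=0.0,
                     t0=datetime(2020, 3, 1, tzinfo=UTC)):
    """Track with two fixes per day (00:00 and 12:00) advancing the
    given net distance each day on a fixed bearing."""
    from detourkit import geodesy
    fixes = []
    pos = start
    for i, km in enumerate(daily_km):
        day = t0 + timedelta(days=i)
        half = geodesy.destination(*pos, bearing, km / 2.0)
        fixes.append(tracks.Fix(individual_id, day, *pos))
        fixes.append(tracks.Fix(individual_id, day + timedelta(hours=12),
                                *half))
        pos = geodesy.destination(*pos, bearing, km)
    fixes.append(tracks.Fix(individual_id, t0 + timedelta(days=len(daily_km)),
                            *pos))
    return tracks.MigrationTrack(individual_id, season, 2020, fixes)


@pytest.fixture(scope="session")
def wind_setup():
    """Zero-noise zonal wind grid plus its analytic function."""
    grid, fn = synthetic.make_wind_grid(
        synthetic.WindSpec(noise_sd=0.0), seed=7)
    return grid, fn


@pytest.fixture(scope="session")
def sim_track(wind_setup):
    """One simulated spring track with ground truth."""
    _, fn = wind_setup
    cfg = synthetic.SimConfig(seed=11)
    return synthetic.simulate_track(cfg, fn, seed=11, season="spring")


@pytest.fixture(scope="session")
def dem():
    return synthetic.make_elevation()
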