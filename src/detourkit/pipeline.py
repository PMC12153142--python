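"""End-to-end report assembly: tracks -> terrain -> wind -> energetics.

``run_pipeline`` drives the whole analysis over a cohort (synthetic by
default, so a run needs no external data) and emits one
machine-readable JSON report: per-track route geometry and stopovers,
the drift/compensation tables and regressions, the barrier extent, the
transport-cost model and the detour-optimality verdict.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import energetics, synthetic, terrain, tracks, wind
from .config import PipelineConfig

log = logging.getLogger("detourkit")


def _track_report(track, cfg: PipelineConfig) -> dict:
    stopovers = tracks.detect_stopovers(
        track, cfg.stopover_threshold_kmday, cfg.stopover_min_days)
    pair = tracks.route_pair(track, stopovers, cfg.gcr_spacing_km)
    speeds = tracks.travel_speeds(track, stopovers, pair.amr_length_km)
    return {
        "individual_id": track.individual_id,
        "season": track.season,
        "year": track.year,
        "n_fixes": len(track.fixes),
        "amr_length_km": pair.amr_length_km,
        "gcr_length_km": pair.gcr_length_km,
        "detour_extent": pair.detour_extent,
        "detour_km": pair.amr_length_km - pair.gcr_length_km,
        "n_stopovers": len(stopovers),
        "stopover_days": sum(s.duration_days for s in stopovers),
        "speed_km_per_day": speeds.speed_km_per_day,
        "active_speed_km_per_day": speeds.active_speed_km_per_day,
        "stopovers": [{
            "center_lon": s.center_lon, "center_lat": s.center_lat,
            "arrival": s.arrival.isoformat(),
            "departure": s.departure.isoformat(),
            "duration_days": s.duration_days} for s in stopovers],
        "_pair": pair, "_stopovers": stopovers,
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis on a seeded synthetic cohort and write
    ``report.json`` (plus a config echo) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)

    # cohort routed around the ridge through a western waypoint, the
    # geometry the detour analysis is about
    sim = synthetic.SimConfig(seed=config.seed, n_tracks=config.n_tracks,
                              waypoints=((56.0, 29.0),))
    grid, analytic = synthetic.make_wind_grid(
        synthetic.WindSpec(noise_sd=0.0), config.seed)
    cohort = synthetic.simulate_cohort(sim, analytic)
    log.info("simulated %d tracks", len(cohort))

    track_reports = [_track_report(t, config) for t, _ in cohort]

    # terrain: barrier extent along each direct route
    barrier = synthetic.BarrierSpec()
    dem = synthetic.make_elevation(barrier)
    extents = [terrain.barrier_extent(r["_pair"].gcr_points, dem,
                                      config.elevation_threshold_m)
               for r in track_reports]

    # wind: drift records over all tracks
    records: list[wind.DriftRecord] = []
    paired_amr: list[wind.DriftRecord] = []
    paired_gcr: list[wind.DriftRecord] = []
    for (full_track, _), rep in zip(cohort, track_reports):
        track = tracks.migration_track(full_track, rep["_stopovers"]) \
            if rep["_stopovers"] else full_track
        segs = tracks.build_segments(track, sim.tag, config.daytime_window)
        recs = wind.analyse_track(track, segs, grid,
                                  config.drift_threshold_kmday,
                                  config.band_edges)
        records.extend(recs)
        gcr_fixes = tracks.project_track_onto_gcr(track,
                                                  rep["_pair"].gcr_points)
        gcr_track = tracks.MigrationTrack(
            individual_id=track.individual_id, season=track.season,
            year=track.year, fixes=gcr_fixes)
        gcr_segs = tracks.build_segments(gcr_track, sim.tag,
                                         config.daytime_window)
        if len(gcr_segs) == len(segs):
            paired_amr.extend(recs)
            paired_gcr.extend(wind.analyse_track(
                gcr_track, gcr_segs, grid, config.drift_threshold_kmday,
                config.band_edges))
        else:  # unpaired day -> excluded, logged, reported
            log.warning("track %s: %d AMR vs %d GCR segments; excluded "
                        "from paired tailwind comparison",
                        track.individual_id, len(segs), len(gcr_segs))

    table, chi2, dof, chi_p = wind.band_frequencies(records,
                                                    config.band_edges)
    regressions = {
        season: {name: asdict(res) for name, res in
                 wind.drift_regression(records, season).items()}
        for season in ("spring", "autumn")}
    paired = wind.tailwind_amr_vs_gcr(paired_amr, paired_gcr)

    # energetics: the detour-optimality verdict
    perf = energetics.flight_performance(config.morphometrics,
                                         config.flight_constants)
    costs = energetics.transport_costs(perf)
    yb = float(np.mean(extents)) if np.mean(extents) > 0 else config.yb_km
    dmax = energetics.max_detour(yb, costs)
    observed = float(np.mean([r["detour_km"] for r in track_reports]))
    verdict = energetics.assess_detour(observed, dmax, yb)

    wind.records_frame(records).to_csv(outdir / "drift_records.csv",
                                       index=False)
    table.to_csv(outdir / "band_frequencies.csv")

    report = {
        "n_tracks": len(track_reports),
        "tracks": [{k: v for k, v in r.items() if not k.startswith("_")}
                   for r in track_reports],
        "mean_detour_extent": float(np.mean(
            [r["detour_extent"] for r in track_reports])),
        "mean_detour_km": observed,
        "barrier_extent_km": {"per_track": extents, "mean": yb},
        "wind": {
            "n_segments": len(records),
            "n_paired_segments": paired.n,
            "band_frequencies": {b: table.loc[b].to_dict()
                                 for b in table.index},
            "chi2": chi2, "dof": dof, "chi2_p": chi_p,
            "regressions": regressions,
            "tailwind_amr_vs_gcr": asdict(paired),
        },
        "energetics": {
            "bmr_w": perf.bmr_w, "ps_w": perf.ps_w,
            "vmp_ms": perf.vmp_ms, "vmr_ms": perf.vmr_ms,
            "pmr_w": perf.pmr_w, "vcc_ms": perf.vcc_ms,
            "c1_j_per_m": costs.c1_j_per_m, "c2_j_per_m": costs.c2_j_per_m,
            "cost_ratio": costs.ratio,
            "yb_km": yb, "dmax_km": dmax,
            "observed_detour_km": observed,
            "optimal": verdict.optimal,
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   sort_keys=True))
    return report
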