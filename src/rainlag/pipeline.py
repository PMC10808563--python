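"""End-to-end orchestration: krige -> realign -> screen -> model -> moran -> threshold -> summarize.

Every stage writes its artifact under the configured output directory and
the run ends with a machine-readable manifest listing the artifacts, the
seeds used, and a hash of the configuration, so identical configs produce
byte-identical result JSON.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import datamodel, geostat, lags, models, screening, spatial, summaries

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    stations_path: str
    elevation_path: str
    traps_path: str
    out_dir: str
    start_date: _dt.date | None = None
    end_date: _dt.date | None = None
    thin: bool = True
    seed: int = 0
    min_events: int = 60
    threshold_tolerance: float = 0.05
    max_neighbors: int = 64
    exclude_bg: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("start_date", "end_date"):
            if raw.get(key):
                raw[key] = _dt.date.fromisoformat(str(raw[key]))
        return cls(**raw)

    def validate(self) -> None:
        for key in ("stations_path", "elevation_path", "traps_path"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")

    def digest(self) -> str:
        """Hash of the analytic configuration (the output location is not
        part of what determines the results)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the manifest dict (also written)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.digest(), "seed": config.seed,
                      "stages": {}, "counts": {}}
    stage = "load"
    try:
        station_days = datamodel.read_stations(config.stations_path)
        grid, elevation = datamodel.read_elevation_grid(config.elevation_path)
        events = datamodel.read_traps(config.traps_path)
        manifest["counts"]["events_read"] = len(events)
        if config.exclude_bg:
            events = datamodel.filter_trap_type(events, keep="CO2")
            manifest["counts"]["events_after_bg_filter"] = len(events)

        stage = "krige"
        surfaces = _krige_stage(config, station_days, grid, elevation, out)
        manifest["stages"]["krige"] = {"n_surfaces": len(surfaces),
                                       "dir": str(out / "surfaces")}

        stage = "align"
        lagrows = []
        skipped = 0
        for ev in events:
            try:
                lagrows.append(lags.extract_lags(ev, surfaces))
            except (lags.MissingSurfaceError, ValueError):
                skipped += 1
        manifest["counts"]["events_without_full_history"] = skipped
        full_matrix = lags.build_lag_matrix(lagrows)
        matrix = lags.thin_lag_matrix(full_matrix) if config.thin else full_matrix
        manifest["counts"]["lag_rows"] = len(full_matrix)
        manifest["counts"]["thinned_rows"] = len(matrix)
        matrix_path = out / "lagmatrix.csv"
        matrix.to_csv(matrix_path, index=False)
        manifest["stages"]["align"] = {"path": str(matrix_path)}

        stage = "screen"
        pres = screening.screen_to_frame(screening.per_lag_presence_screen(matrix))
        abund = screening.screen_to_frame(screening.per_lag_abundance_screen(matrix))
        pres.to_csv(out / "screen_presence.csv", index=False)
        abund.to_csv(out / "screen_abundance.csv", index=False)
        manifest["stages"]["screen"] = {"presence": str(out / "screen_presence.csv"),
                                        "abundance": str(out / "screen_abundance.csv")}

        stage = "model"
        comparison = {}
        for outcome in ("presence", "abundance"):
            fits = models.fit_model_suite(matrix, outcome, seed=config.seed)
            comparison[outcome] = [
                {"spec": f.spec, "metric": f.metric_name,
                 "estimate": round(f.estimate, 6), "penalty": f.penalty,
                 "n_train": f.n_train, "n_test": f.n_test} for f in fits]
        cmp_path = out / "model_comparison.json"
        _write_json(comparison, cmp_path)
        manifest["stages"]["model"] = {"path": str(cmp_path)}

        stage = "moran"
        agg = spatial.equal_sample(events, min_events=min(config.min_events,
                                                          _max_events_per_trap(events)),
                                   seed=config.seed)
        proj = geostat.LocalProjection(grid.bbox)
        coords = proj.to_xy(agg["lon"].to_numpy(), agg["lat"].to_numpy())
        moran = spatial.morans_i(agg["female_total"].to_numpy(), coords)
        moran_path = out / "moran.json"
        _write_json({k: _jsonable(v) for k, v in dataclasses.asdict(moran).items()},
                    moran_path)
        manifest["stages"]["moran"] = {"path": str(moran_path)}

        stage = "threshold"
        thr = summaries.find_low_precip_threshold(
            matrix, tolerance=config.threshold_tolerance)
        thr_path = out / "threshold.json"
        _write_json({k: _jsonable(v) for k, v in dataclasses.asdict(thr).items()},
                    thr_path)
        manifest["stages"]["threshold"] = {"path": str(thr_path)}

        stage = "summarize"
        table = summaries.summarize_effort(events)
        table_path = out / "effort_summary.csv"
        table.to_csv(table_path, index=False)
        manifest["stages"]["summarize"] = {"path": str(table_path)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    _write_json(manifest, out / "manifest.json")
    return manifest


def _krige_stage(config, station_days, grid, elevation, out: Path):
    surf_dir = out / "surfaces"
    surf_dir.mkdir(exist_ok=True)
    by_date: dict[_dt.date, list] = {}
    for s in station_days:
        if config.start_date and s.date < config.start_date:
            continue
        if config.end_date and s.date > config.end_date:
            continue
        by_date.setdefault(s.date, []).append(s)
    surfaces = {}
    for date in sorted(by_date):
        surf = geostat.make_daily_surface(by_date[date], elevation, grid,
                                          max_neighbors=config.max_neighbors)
        datamodel.write_surface(surf, surf_dir / f"precip_{date.isoformat()}.csv")
        surfaces[date] = surf
    return surfaces


def _max_events_per_trap(events) -> int:
    counts: dict[str, int] = {}
    for e in events:
        if e.trap_type == "CO2":
            counts[e.trap_id] = counts.get(e.trap_id, 0) + 1
    return max(counts.values(), default=0)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def _write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
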