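"""Canonical data types, CSV readers, surface I/O, and the precipitation cleaning rule.

Precipitation is carried in inches throughout (the unit of the source gauge
network and of both analysis thresholds); :func:`inches_to_mm` is the single
conversion helper.  Daily precipitation surfaces are stored as plain-text CSV
grids with a small ``# key=value`` comment header, one file per day.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import io
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Gauge readings below this are not measurable precipitation (inches).
MEASURABLE_PRECIP_IN = 0.01

MM_PER_INCH = 25.4

TRAP_TYPES = ("CO2", "BG")


class SchemaError(ValueError):
    """A required column is missing or a file is structurally malformed."""


class RowError(ValueError):
    """One or more data rows failed validation; message lists line numbers."""


def inches_to_mm(values):
    """Convert precipitation from inches to millimeters."""
    return np.asarray(values, dtype=float) * MM_PER_INCH


@dataclasses.dataclass(frozen=True)
class StationDay:
    """One weather station's precipitation observation on one calendar date."""

    station_id: str
    lon: float
    lat: float
    elevation: float  # meters
    date: _dt.date
    precip: float  # inches/day


@dataclasses.dataclass(frozen=True)
class TrapEvent:
    """One trap-collection record.

    Presence is defined as at least one female in the trap; it is derived,
    never stored independently of the count.
    """

    trap_id: str
    lon: float
    lat: float
    trap_type: str  # "CO2" or "BG"
    collection_date: _dt.date
    female_count: int
    male_count: int

    @property
    def presence(self) -> bool:
        return self.female_count >= 1

    @property
    def total_count(self) -> int:
        return self.female_count + self.male_count


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid with cell-center registration.

    Cells tile the bounding box exactly with half-open intervals (closed on
    the left/bottom edge), so every interior point maps to a unique cell.
    Row 0 is the southernmost row.
    """

    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("empty bounding box")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return (self.lon_min, self.lat_min, self.lon_max, self.lat_max)

    @property
    def cell_width(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_cols

    @property
    def cell_height(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_rows

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lon, lat) arrays of shape (n_rows, n_cols)."""
        lons = self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_width
        lats = self.lat_min + (np.arange(self.n_rows) + 0.5) * self.cell_height
        return np.meshgrid(lons, lats)

    def contains(self, lon: float, lat: float) -> bool:
        return (self.lon_min <= lon < self.lon_max + 1e-12
                and self.lat_min <= lat < self.lat_max + 1e-12)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing a point.

        Half-open cells; points on the top/right boundary of the bbox are
        assigned to the last row/column so the box is fully covered.
        """
        if not self.contains(lon, lat):
            raise ValueError(f"point ({lon}, {lat}) outside grid bbox {self.bbox}")
        col = min(int((lon - self.lon_min) / self.cell_width), self.n_cols - 1)
        row = min(int((lat - self.lat_min) / self.cell_height), self.n_rows - 1)
        return row, col


@dataclasses.dataclass
class PrecipSurface:
    """One date's interpolated precipitation grid (inches/day)."""

    grid: GridSpec
    date: _dt.date
    values: np.ndarray
    variance: np.ndarray | None = None  # kriging variance, (inches)^2

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_rows}, {self.grid.n_cols})")
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=float)
            if self.variance.shape != self.values.shape:
                raise ValueError("variance shape does not match values")

    def value_at(self, lon: float, lat: float) -> float:
        row, col = self.grid.cell_of(lon, lat)
        return float(self.values[row, col])


def clean_precip(values):
    """Zero out non-measurable precipitation.

    Kriging output may be slightly negative or vanishingly small; negatives
    and values in (0, 0.01) inches are set to 0.  Values >= 0.01 in pass
    through unchanged.  Idempotent; preserves shape; scalar in, scalar out.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("clean_precip requires finite input")
    out = np.where(arr < MEASURABLE_PRECIP_IN, 0.0, arr)
    if np.ndim(values) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# CSV readers

_STATION_COLUMNS = ["station_id", "lon", "lat", "elevation_m", "date", "precip_in"]
_TRAP_COLUMNS = ["trap_id", "lon", "lat", "trap_type", "collection_date",
                 "female_count", "male_count"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_stations(path) -> list[StationDay]:
    """Read a station-day CSV into typed records.

    Malformed rows are collected and reported together with their line
    numbers (header is line 1).
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    _require_columns(df, _STATION_COLUMNS, path)
    if df.empty:
        logger.warning("%s: no data rows", path)
        return []
    records, bad = [], []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            precip = float(row["precip_in"])
            if not math.isfinite(precip):
                raise ValueError("non-finite precip")
            records.append(StationDay(
                station_id=str(row["station_id"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                elevation=float(row["elevation_m"]),
                date=_parse_date(row["date"]),
                precip=precip,
            ))
        except (ValueError, TypeError) as exc:
            bad.append(f"line {line}: {exc}")
    if bad:
        raise RowError(f"{path}: {len(bad)} malformed row(s): " + "; ".join(bad))
    return records


def read_traps(path) -> list[TrapEvent]:
    """Read a trap-event CSV into typed, validated records.

    BG-Sentinel rows are accepted here; downstream stages exclude them via
    :func:`filter_trap_type` (the default analysis uses CO2 traps only).
    """
    df = pd.read_csv(path, dtype={"trap_id": str, "trap_type": str})
    _require_columns(df, _TRAP_COLUMNS, path)
    records, bad = [], []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            trap_type = str(row["trap_type"]).strip()
            if trap_type not in TRAP_TYPES:
                raise ValueError(f"unknown trap_type {trap_type!r}")
            females = int(row["female_count"])
            males = int(row["male_count"])
            if females < 0 or males < 0:
                raise ValueError("negative count")
            records.append(TrapEvent(
                trap_id=str(row["trap_id"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                trap_type=trap_type,
                collection_date=_parse_date(row["collection_date"]),
                female_count=females,
                male_count=males,
            ))
        except (ValueError, TypeError) as exc:
            bad.append(f"line {line}: {exc}")
    if bad:
        raise RowError(f"{path}: {len(bad)} invalid row(s): " + "; ".join(bad))
    return records


def filter_trap_type(events: Iterable[TrapEvent],
                     keep: str = "CO2") -> list[TrapEvent]:
    """Keep only events of one trap type (default: the CO2-baited network)."""
    events = list(events)
    kept = [e for e in events if e.trap_type == keep]
    if len(kept) < len(events):
        logger.info("excluded %d events of other trap types", len(events) - len(kept))
    return kept


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value).strip())


# ---------------------------------------------------------------------------
# Surface I/O (plain-text CSV grid with a key=value comment header)

_SURFACE_MAGIC = "rainlag-surface"


def write_surface(surface: PrecipSurface, path) -> None:
    """Write a surface (and its variance layer, if present) as a CSV grid."""
    g = surface.grid
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_SURFACE_MAGIC} 1\n")
        fh.write(f"# date={surface.date.isoformat()}\n")
        fh.write(f"# bbox={g.lon_min!r},{g.lat_min!r},{g.lon_max!r},{g.lat_max!r}\n")
        fh.write(f"# shape={g.n_rows},{g.n_cols}\n")
        fh.write(f"# bands={'values,variance' if surface.variance is not None else 'values'}\n")
        np.savetxt(fh, surface.values, fmt="%.10g", delimiter=",")
        if surface.variance is not None:
            np.savetxt(fh, surface.variance, fmt="%.10g", delimiter=",")


def read_surface(path) -> PrecipSurface:
    """Read a surface written by :func:`write_surface`; validates band count."""
    header: dict[str, str] = {}
    body_lines = []
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if _SURFACE_MAGIC not in first:
            raise SchemaError(f"{path}: not a rainlag surface file")
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    try:
        lon_min, lat_min, lon_max, lat_max = (float(x) for x in header["bbox"].split(","))
        n_rows, n_cols = (int(x) for x in header["shape"].split(","))
        date = _dt.date.fromisoformat(header["date"])
        bands = header["bands"].split(",")
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed surface header: {exc}") from exc
    grid = GridSpec(lon_min, lat_min, lon_max, lat_max, n_rows, n_cols)
    data = np.loadtxt(io.StringIO("".join(body_lines)), delimiter=",", ndmin=2)
    expected_rows = n_rows * len(bands)
    if data.shape != (expected_rows, n_cols):
        raise SchemaError(
            f"{path}: expected {len(bands)} band(s) of {n_rows}x{n_cols} "
            f"values, found array of shape {data.shape}")
    values = data[:n_rows]
    variance = data[n_rows:] if len(bands) == 2 else None
    return PrecipSurface(grid=grid, date=date, values=values, variance=variance)


def write_elevation_grid(grid: GridSpec, values: np.ndarray, path) -> None:
    """Write an elevation grid (meters) using the surface container format."""
    surf = PrecipSurface(grid=grid, date=_dt.date(1970, 1, 1), values=values)
    write_surface(surf, path)


def read_elevation_grid(path) -> tuple[GridSpec, np.ndarray]:
    surf = read_surface(path)
    return surf.grid, surf.values


def events_to_frame(events: Iterable[TrapEvent]) -> pd.DataFrame:
    """Tabular view of trap events (one row per event, presence derived)."""
    rows = [{
        "trap_id": e.trap_id, "lon": e.lon, "lat": e.lat,
        "trap_type": e.trap_type, "collection_date": e.collection_date,
        "female_count": e.female_count, "male_count": e.male_count,
        "presence": e.presence,
    } for e in events]
    return pd.DataFrame(rows)
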