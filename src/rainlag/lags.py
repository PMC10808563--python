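"""Per-event 20-day precipitation histories, cumulative sums, and thinning.

Each trapping event is joined to the interpolated precipitation at its own
location for each of the 20 days before collection (day k = collection date
minus k days; the collection day itself is not a predictor).  Cumulative
10- and 20-day sums are derived from the same values.  Thinning keeps one
event per trap per calendar month — the earliest — so that overlapping
20-day windows from weekly sampling cannot induce artificial 7-day
autocorrelation in the predictors.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import PrecipSurface, TrapEvent

logger = logging.getLogger(__name__)

N_LAGS = 20
LAG_COLUMNS = [f"lag{k}" for k in range(1, N_LAGS + 1)]


@dataclasses.dataclass
class LagRow:
    """A trap event joined to its 20 prior daily precipitation values."""

    trap_id: str
    collection_date: _dt.date
    female_count: int
    lag: np.ndarray  # lag[k-1] = precipitation k days before collection

    def __post_init__(self):
        self.lag = np.asarray(self.lag, dtype=float)
        if self.lag.shape != (N_LAGS,):
            raise ValueError(f"lag vector must have length {N_LAGS}")
        if np.any(self.lag < 0):
            raise ValueError("lag values must be non-negative (cleaned)")

    @property
    def presence(self) -> bool:
        return self.female_count >= 1

    @property
    def cum10(self) -> float:
        return float(self.lag[:10].sum())

    @property
    def cum20(self) -> float:
        return float(self.lag.sum())


class MissingSurfaceError(KeyError):
    """One or more required daily surfaces are absent from the store."""


def extract_lags(event: TrapEvent,
                 surfaces: Mapping[_dt.date, PrecipSurface]) -> LagRow:
    """Build an event's lag vector from a store of dated surfaces.

    The value for day k is read from the grid cell containing the trap on
    date ``collection_date - k`` (point-in-cell; no smoothing).
    """
    needed = [event.collection_date - _dt.timedelta(days=k)
              for k in range(1, N_LAGS + 1)]
    missing = [d for d in needed if d not in surfaces]
    if missing:
        raise MissingSurfaceError(
            "missing precipitation surface(s) for: "
            + ", ".join(d.isoformat() for d in sorted(missing)))
    lag = np.array([surfaces[d].value_at(event.lon, event.lat) for d in needed])
    return LagRow(trap_id=event.trap_id, collection_date=event.collection_date,
                  female_count=event.female_count, lag=lag)


def thin_events(rows: Sequence) -> list:
    """Keep one event per (trap, calendar month): the earliest-dated.

    Works on any records exposing ``trap_id`` and a date attribute
    (``collection_date``).  Ties on date break by trap_id then input order,
    so the result is deterministic.  Idempotent.
    """
    best: dict[tuple[str, int, int], tuple] = {}
    for order, row in enumerate(rows):
        d = row.collection_date
        key = (row.trap_id, d.year, d.month)
        cand = (d, row.trap_id, order)
        if key not in best or cand < best[key]:
            best[key] = cand
    keep = sorted(best.values(), key=lambda t: t[2])
    return [rows[order] for _, _, order in keep]


def build_lag_matrix(rows: Iterable[LagRow]) -> pd.DataFrame:
    """Assemble the analysis table: presence, female_count, lag1..lag20, cum10, cum20.

    Rows with non-finite lags are excluded (count logged).  Row order is
    stable by (trap_id, collection_date).
    """
    records, dropped = [], 0
    for row in rows:
        if not np.all(np.isfinite(row.lag)):
            dropped += 1
            continue
        rec = {"trap_id": row.trap_id, "collection_date": row.collection_date,
               "presence": row.presence, "female_count": row.female_count}
        rec.update({col: row.lag[i] for i, col in enumerate(LAG_COLUMNS)})
        rec["cum10"] = row.cum10
        rec["cum20"] = row.cum20
        records.append(rec)
    if dropped:
        logger.info("excluded %d row(s) with missing lag values", dropped)
    df = pd.DataFrame(records)
    if df.empty:
        return df
    return df.sort_values(["trap_id", "collection_date"], kind="stable").reset_index(drop=True)


def thin_lag_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Thin an already-built lag matrix to one row per trap-month."""
    if df.empty:
        return df
    dates = pd.to_datetime(df["collection_date"])
    key = pd.DataFrame({"trap_id": df["trap_id"],
                        "year": dates.dt.year, "month": dates.dt.month,
                        "date": dates})
    order = key.sort_values(["date", "trap_id"], kind="stable").index
    seen, keep = set(), []
    for idx in order:
        k = (key.at[idx, "trap_id"], key.at[idx, "year"], key.at[idx, "month"])
        if k not in seen:
            seen.add(k)
            keep.append(idx)
    return df.loc[sorted(keep)].reset_index(drop=True)
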