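"""Trapping-effort summaries, monthly activity, and the low-precipitation threshold.

The threshold analysis bounds the mosquito fraction that anthropogenic
water alone can support: events whose 20-day cumulative interpolated
precipitation never exceeded a "low precipitation threshold" could not have
met the inundation requirement for egg development, so any females trapped
there developed in human-created water.  The threshold is found by scanning
a candidate grid of cumulative precipitation values for the widest initial
plateau over which the maximum trap count does not grow.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import TrapEvent

logger = logging.getLogger(__name__)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (presentation rounding for percentages)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _pct(numer: int, denom: int) -> float:
    if denom == 0:
        return float("nan")
    return round_half_away(100.0 * numer / denom, 1)


def summarize_effort(events: Sequence[TrapEvent]) -> pd.DataFrame:
    """Per year x trap-type effort summary plus a grand-totals row.

    Columns: year, trap_type, n_traps, n_surveys, n_nonzero, pct_nonzero,
    n_mosquitoes, n_females, pct_females, n_female_positive,
    pct_female_positive.  "Nonzero" means at least one mosquito of either
    sex; "female positive" means at least one female.  The totals row uses
    unique traps across all groups and re-derives every percentage from the
    summed integers.
    """
    df = pd.DataFrame([{
        "year": e.collection_date.year, "trap_type": e.trap_type,
        "trap_id": e.trap_id, "females": e.female_count,
        "males": e.male_count, "total": e.total_count,
        "nonzero": e.total_count > 0, "fpos": e.female_count > 0,
    } for e in events])
    rows = []
    if df.empty:
        return pd.DataFrame(columns=[
            "year", "trap_type", "n_traps", "n_surveys", "n_nonzero",
            "pct_nonzero", "n_mosquitoes", "n_females", "pct_females",
            "n_female_positive", "pct_female_positive"])
    for (year, ttype), g in df.groupby(["year", "trap_type"], sort=True):
        rows.append(_effort_row(str(year), ttype, g))
    rows.append(_effort_row("Totals", "all", df))
    return pd.DataFrame(rows)


def _effort_row(year: str, ttype: str, g: pd.DataFrame) -> dict:
    n_surveys = len(g)
    n_nonzero = int(g["nonzero"].sum())
    n_mosq = int(g["total"].sum())
    n_fem = int(g["females"].sum())
    n_fpos = int(g["fpos"].sum())
    return {
        "year": year, "trap_type": ttype,
        "n_traps": g["trap_id"].nunique(),
        "n_surveys": n_surveys,
        "n_nonzero": n_nonzero, "pct_nonzero": _pct(n_nonzero, n_surveys),
        "n_mosquitoes": n_mosq,
        "n_females": n_fem, "pct_females": _pct(n_fem, n_mosq),
        "n_female_positive": n_fpos,
        "pct_female_positive": _pct(n_fpos, n_surveys),
    }


def monthly_activity(events: Iterable[TrapEvent]) -> dict[int, dict]:
    """Per calendar month (pooled across years): nonzero female counts + zero tally.

    Returns {month: {"nonzero_counts": sorted list, "n_zero": int}} for
    months 1..12; supports log-scale seasonal-activity displays without
    doing any plotting here.
    """
    out = {m: {"nonzero_counts": [], "n_zero": 0} for m in range(1, 13)}
    for e in events:
        m = e.collection_date.month
        if e.female_count > 0:
            out[m]["nonzero_counts"].append(e.female_count)
        else:
            out[m]["n_zero"] += 1
    for m in out:
        out[m]["nonzero_counts"].sort()
    return out


@dataclasses.dataclass
class ThresholdResult:
    threshold: float  # inches, on the cum20 scale
    pct_events_below: float  # % of all events with cum20 <= threshold
    pct_females_below: float  # % of all trapped females in those events
    max_count_below: int
    tolerance: float
    pct_female_positive_below: float  # alt. denominator: female-positive events


DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.01, 0.51, 0.01), 2))


def find_low_precip_threshold(lagmatrix: pd.DataFrame,
                              candidate_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
                              tolerance: float = 0.05) -> ThresholdResult:
    """Find the widest initial plateau of the running maximum count.

    Let M(t) be the maximum female count among events with cum20 <= t.  The
    threshold t* is the largest candidate such that M is constant, within a
    relative ``tolerance``, over all candidates up to t*.  Above t*,
    additional precipitation raises the attainable count, i.e. precipitation
    starts to matter.
    """
    grid = sorted(float(t) for t in candidate_grid)
    if not grid:
        raise ValueError("empty candidate grid")
    cum20 = lagmatrix["cum20"].to_numpy(dtype=float)
    counts = lagmatrix["female_count"].to_numpy(dtype=float)
    if not np.any(cum20 <= grid[0]):
        raise ValueError("no events at or below the smallest candidate threshold")
    m_first = None
    t_star, m_star = grid[0], None
    for t in grid:
        below = cum20 <= t
        if not below.any():
            continue
        m_t = counts[below].max()
        if m_first is None:
            m_first = m_t if m_t > 0 else 1.0
        if (m_t - m_first) / m_first > tolerance:
            break
        t_star, m_star = t, m_t
    pct_events = 100.0 * np.mean(cum20 <= t_star)
    total_females = counts.sum()
    if total_females == 0:
        raise ValueError("no females trapped; fractions undefined")
    pct_females = 100.0 * counts[cum20 <= t_star].sum() / total_females
    fpos = counts > 0
    pct_fpos = (100.0 * np.mean(cum20[fpos] <= t_star)) if fpos.any() else float("nan")
    logger.info("threshold %.2f in: %.1f%% of all events, %.1f%% of female-positive "
                "events, %.1f%% of females", t_star, pct_events, pct_fpos, pct_females)
    return ThresholdResult(threshold=t_star, pct_events_below=float(pct_events),
                           pct_females_below=float(pct_females),
                           max_count_below=int(m_star),
                           tolerance=tolerance,
                           pct_female_positive_below=float(pct_fpos))


def anthropogenic_fraction(lagmatrix: pd.DataFrame, threshold: float) -> float:
    """Percent of all trapped females caught in events with cum20 <= threshold.

    This is the minimum share of the population that precipitation cannot
    account for — a lower bound on support by anthropogenic water sources.
    """
    cum20 = lagmatrix["cum20"].to_numpy(dtype=float)
    counts = lagmatrix["female_count"].to_numpy(dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("zero total females")
    return float(100.0 * counts[cum20 <= threshold].sum() / total)
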