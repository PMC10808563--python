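"""Per-lag univariate screens: logistic slopes for presence, correlations for counts.

These single-predictor screens establish that individual prior days carry
differing (sign and magnitude) associations with trap outcomes, the
precursor justifying the joint regularized models.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lags import N_LAGS

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class LagScreenResult:
    lag_day: int
    effect: float  # logistic slope (presence) or Pearson r (abundance)
    ci_low: float
    ci_high: float
    n: int
    flag: str | None = None  # "separation", "zero-variance", ...


def per_lag_presence_screen(lagmatrix: pd.DataFrame) -> list[LagScreenResult]:
    """Fit an independent intercept+slope logistic model per lag day.

    Returns the slope with its Wald 95% CI.  Complete separation yields a
    flagged result with an infinite-slope sentinel; a zero-variance lag
    column yields a flagged NaN.
    """
    y = lagmatrix["presence"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("presence outcome has a single class; cannot screen")
    out = []
    for k in range(1, N_LAGS + 1):
        x = lagmatrix[f"lag{k}"].to_numpy(dtype=float)
        n = len(x)
        if np.ptp(x) == 0.0:
            out.append(LagScreenResult(k, np.nan, np.nan, np.nan, n, "zero-variance"))
            logger.warning("lag%d has zero variance; screen skipped", k)
            continue
        X = sm.add_constant(x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            slope = float(fit.params[1])
            se = float(fit.bse[1])
            if not np.isfinite(se) or se > 1e6:
                raise sm.tools.sm_exceptions.PerfectSeparationError("huge SE")
            out.append(LagScreenResult(k, slope, slope - 1.96 * se,
                                       slope + 1.96 * se, n))
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                np.linalg.LinAlgError):
            sign = np.sign(np.corrcoef(x, y)[0, 1]) or 1.0
            out.append(LagScreenResult(k, sign * np.inf, np.nan, np.nan, n,
                                       "separation"))
    return out


def per_lag_abundance_screen(lagmatrix: pd.DataFrame,
                             scope: str = "all",
                             method: str = "pearson") -> list[LagScreenResult]:
    """Correlate female counts with each lag day's precipitation.

    ``scope="positive-only"`` restricts to rows with at least one female
    (zeros separated from non-zero counts).  CIs are Fisher-z 95%.
    """
    if scope not in ("all", "positive-only"):
        raise ValueError("scope must be 'all' or 'positive-only'")
    df = lagmatrix if scope == "all" else lagmatrix[lagmatrix["female_count"] > 0]
    counts = df["female_count"].to_numpy(dtype=float)
    n = len(counts)
    if n < 3:
        raise ValueError("need at least 3 rows in scope")
    out = []
    for k in range(1, N_LAGS + 1):
        x = df[f"lag{k}"].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(counts) == 0.0:
            out.append(LagScreenResult(k, np.nan, np.nan, np.nan, n, "zero-variance"))
            logger.warning("lag%d: zero variance in scope; correlation undefined", k)
            continue
        if method == "pearson":
            r = float(stats.pearsonr(x, counts).statistic)
        elif method == "spearman":
            r = float(stats.spearmanr(x, counts).statistic)
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
        lo, hi = _fisher_ci(r, n)
        out.append(LagScreenResult(k, r, lo, hi, n))
    return out


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def screen_to_frame(results: list[LagScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
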