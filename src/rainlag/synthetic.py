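"""Seeded generator of the study's statistical structure, end to end.

Emulates a clustered weather-station network over an arid-county bounding
box, a smooth elevation surface, zero-inflated daily precipitation (dry days
interleaved with wet days drawn from a Gaussian random field with a known
variogram, truncated at zero), a regular grid of weekly-serviced traps at
roughly one per square mile, and female trap counts driven by known
daily-lag coefficients through a hurdle model:

* presence ~ Bernoulli(logit^-1(b0p + sum_k beta_k * lag_k + cum terms))
* count | presence ~ 1 + NB(mean = exp(b0a + sum_k beta_k * lag_k) - adjusted)

so that presence == (count >= 1) holds exactly, the presence logit carries
the planted presence coefficients, and counts carry the planted abundance
coefficients.  Every output is a pure function of the config (seed included).

The defaults mirror the study conditions: ~8 inches of rain per year
arriving in a minority of wet days, station clustering, 1-mile trap
spacing, weekly collections, and a strong negative planted effect two days
before collection with a positive effect at day 10.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .datamodel import GridSpec, TrapEvent, clean_precip
from .geostat import LocalProjection, VariogramModel, gamma
from .lags import N_LAGS, LagRow

MILES_TO_DEG_LAT = 1.0 / 69.0  # ~1 mile in degrees of latitude


def default_lag_effects() -> np.ndarray:
    """Planted daily presence/abundance coefficients (per inch of rain).

    Strong suppression 2 days before collection, mild suppression at day 8,
    a positive peak at day 10, and zero effect on days 1, 5, 9, 13, 20 —
    the qualitative pattern the screening and model stages must recover.
    """
    beta = np.zeros(N_LAGS)
    beta[1] = -6.0   # day 2
    beta[7] = -2.0   # day 8
    beta[9] = 4.0    # day 10
    for day in (3, 4, 6, 7, 11, 12, 14, 15, 16, 17, 18, 19):
        beta[day - 1] = 1.0
    return beta


@dataclasses.dataclass
class SyntheticConfig:
    seed: int = 0
    n_stations: int = 60
    bbox: tuple[float, float, float, float] = (-112.6, 33.0, -111.6, 33.9)
    n_days: int = 60
    start_date: _dt.date = _dt.date(2015, 6, 1)
    wet_day_prob: float = 0.08  # ~29 wet days/yr: an arid two-season climate
    true_variogram: VariogramModel = dataclasses.field(
        default_factory=lambda: VariogramModel("exponential", nugget=0.0,
                                               partial_sill=0.04,
                                               range_=15_000.0))
    wet_day_mean: float = 0.25  # inches; with wet_day_prob gives ~7-8 in/yr
    elevation_effect: float = 0.05  # inches per km of elevation
    trap_spacing_miles: float = 1.0
    n_traps: int | None = 100  # cap on the trap grid (None = fill the bbox)
    presence_intercept: float = -0.5
    abundance_intercept: float = 1.0
    lag_effects_presence: np.ndarray = dataclasses.field(default_factory=default_lag_effects)
    lag_effects_abundance: np.ndarray = dataclasses.field(default_factory=default_lag_effects)
    cum10_effect: float = 0.0
    cum20_effect: float = 0.0
    cum10_effect_abundance: float = 0.0
    cum20_effect_abundance: float = 0.0
    dispersion: float = 2.0  # NB size; np.inf -> Poisson

    def __post_init__(self):
        if not 0.0 <= self.wet_day_prob <= 1.0:
            raise ValueError("wet_day_prob must lie in [0, 1]")
        if self.trap_spacing_miles <= 0:
            raise ValueError("trap_spacing must be positive")
        self.lag_effects_presence = np.asarray(self.lag_effects_presence, float)
        self.lag_effects_abundance = np.asarray(self.lag_effects_abundance, float)


def _rng(cfg: SyntheticConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def gen_stations_and_elevation(cfg: SyntheticConfig,
                               grid: GridSpec | None = None
                               ) -> tuple[list[dict], GridSpec, np.ndarray]:
    """Clustered station locations plus a smooth elevation grid.

    Stations are drawn around a handful of cluster centers (mimicking a
    flood-control gauge network concentrated in urban basins).  Elevation is
    a low-order trend plus smooth sinusoidal relief, in meters.  Returns
    (stations, grid, elevation) where stations are dicts with station_id,
    lon, lat, elevation.
    """
    if cfg.n_stations < 3:
        raise ValueError("need at least 3 stations")
    rng = _rng(cfg, 1)
    lon_min, lat_min, lon_max, lat_max = cfg.bbox
    n_clusters = max(3, cfg.n_stations // 12)
    centers = np.column_stack([
        rng.uniform(lon_min, lon_max, n_clusters),
        rng.uniform(lat_min, lat_max, n_clusters)])
    which = rng.integers(0, n_clusters, cfg.n_stations)
    scatter = 0.12 * min(lon_max - lon_min, lat_max - lat_min)
    pts = centers[which] + rng.normal(0.0, scatter, (cfg.n_stations, 2))
    pts[:, 0] = np.clip(pts[:, 0], lon_min + 1e-6, lon_max - 1e-6)
    pts[:, 1] = np.clip(pts[:, 1], lat_min + 1e-6, lat_max - 1e-6)

    if grid is None:
        grid = GridSpec(lon_min, lat_min, lon_max, lat_max, n_rows=30, n_cols=30)
    elevation = _elevation_field(grid.cell_centers()[0], grid.cell_centers()[1], cfg)
    stn_elev = _elevation_field(pts[:, 0], pts[:, 1], cfg)
    stations = [{"station_id": f"S{i:03d}", "lon": float(pts[i, 0]),
                 "lat": float(pts[i, 1]), "elevation": float(stn_elev[i])}
                for i in range(cfg.n_stations)]
    return stations, grid, elevation


def _elevation_field(lon, lat, cfg: SyntheticConfig) -> np.ndarray:
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    lon_min, lat_min, lon_max, lat_max = cfg.bbox
    u = (lon - lon_min) / (lon_max - lon_min)
    v = (lat - lat_min) / (lat_max - lat_min)
    # basin floor ~300 m rising toward the box edges with gentle relief
    return (300.0 + 250.0 * (u + 0.5 * v)
            + 60.0 * np.sin(3.1 * math.pi * u) * np.cos(2.3 * math.pi * v))


def trap_grid(cfg: SyntheticConfig) -> np.ndarray:
    """Regular trap locations at cfg.trap_spacing_miles, row-major order."""
    lon_min, lat_min, lon_max, lat_max = cfg.bbox
    dlat = cfg.trap_spacing_miles * MILES_TO_DEG_LAT
    dlon = dlat / math.cos(math.radians(0.5 * (lat_min + lat_max)))
    lats = np.arange(lat_min + dlat / 2, lat_max, dlat)
    lons = np.arange(lon_min + dlon / 2, lon_max, dlon)
    pts = np.array([(lo, la) for la in lats for lo in lons])
    if cfg.n_traps is not None and len(pts) > cfg.n_traps:
        # keep an evenly thinned subset so coverage stays spatially spread
        idx = np.linspace(0, len(pts) - 1, cfg.n_traps).astype(int)
        pts = pts[idx]
    return pts


def gen_precip_days(cfg: SyntheticConfig, stations: Sequence[dict],
                    extra_points: np.ndarray | None = None
                    ) -> tuple[dict, np.ndarray]:
    """Daily station observations plus the true field at extra points.

    Returns ``(obs, truth)`` where ``obs[date]`` is an array of cleaned
    station precipitation (inches) and ``truth`` has shape
    (n_days, n_extra) holding the true (cleaned) field at ``extra_points``
    (e.g. trap locations).  Dry days are all zero; wet days draw a Gaussian
    random field with the configured variogram at stations+extras jointly
    (dense Cholesky), shift by the wet-day mean and the elevation effect,
    and truncate at zero (natural within-wet-day zero inflation).
    """
    proj = LocalProjection(cfg.bbox)
    st_xy = proj.to_xy([s["lon"] for s in stations], [s["lat"] for s in stations])
    st_elev_km = np.array([s["elevation"] for s in stations]) / 1000.0
    if extra_points is not None and len(extra_points):
        ex_xy = proj.to_xy(extra_points[:, 0], extra_points[:, 1])
        ex_elev_km = _elevation_field(extra_points[:, 0], extra_points[:, 1], cfg) / 1000.0
    else:
        ex_xy = np.zeros((0, 2))
        ex_elev_km = np.zeros(0)
    all_xy = np.vstack([st_xy, ex_xy])
    all_elev = np.concatenate([st_elev_km, ex_elev_km])
    n_st = len(st_xy)

    vg = cfg.true_variogram
    sill = vg.sill
    d = cdist(all_xy, all_xy)
    cov = sill - gamma(d, vg)
    np.fill_diagonal(cov, sill)
    cov += 1e-10 * sill * np.eye(len(cov))  # numerical jitter
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("variogram covariance not positive definite; "
                         "increase the jitter or adjust parameters") from exc

    rng = _rng(cfg, 2)
    obs: dict[_dt.date, np.ndarray] = {}
    truth = np.zeros((cfg.n_days, len(ex_xy)))
    mean = cfg.wet_day_mean + cfg.elevation_effect * all_elev
    for day in range(cfg.n_days):
        date = cfg.start_date + _dt.timedelta(days=day)
        if rng.random() >= cfg.wet_day_prob:
            obs[date] = np.zeros(n_st)
            continue
        field = mean + chol @ rng.standard_normal(len(cov))
        field = clean_precip(np.maximum(field, 0.0))
        obs[date] = field[:n_st]
        truth[day] = field[n_st:]
    return obs, truth


def gen_trap_events(cfg: SyntheticConfig, truth: np.ndarray,
                    traps: np.ndarray) -> tuple[list[TrapEvent], list[LagRow]]:
    """Weekly trap events with hurdle-model counts driven by the true lags.

    ``truth`` is the (n_days, n_traps) true precipitation at trap locations
    from :func:`gen_precip_days`.  Collections start once every trap has a
    full 20-day history; each trap keeps a fixed, jittered weekday.  Returns
    the events plus the matching truth lag rows (the oracle table).
    """
    if cfg.n_days < N_LAGS + 1:
        raise ValueError("need at least 21 generated days")
    rng = _rng(cfg, 3)
    weekday_offset = rng.integers(0, 7, size=len(traps))
    events: list[TrapEvent] = []
    lagrows: list[LagRow] = []
    bp, ba = cfg.lag_effects_presence, cfg.lag_effects_abundance
    for t_idx, (lon, lat) in enumerate(traps):
        trap_id = f"T{t_idx:04d}"
        day = N_LAGS + int(weekday_offset[t_idx])
        while day < cfg.n_days:
            lag = truth[day - np.arange(1, N_LAGS + 1), t_idx]
            cum10, cum20 = lag[:10].sum(), lag.sum()
            eta_p = (cfg.presence_intercept + bp @ lag
                     + cfg.cum10_effect * cum10 + cfg.cum20_effect * cum20)
            p_present = 1.0 / (1.0 + math.exp(-np.clip(eta_p, -30, 30)))
            present = rng.random() < p_present
            if present:
                eta_a = (cfg.abundance_intercept + ba @ lag
                         + cfg.cum10_effect_abundance * cum10
                         + cfg.cum20_effect_abundance * cum20)
                mu = math.exp(np.clip(eta_a, -20, 10))
                count = 1 + _draw_count(rng, mu, cfg.dispersion)
            else:
                count = 0
            date = cfg.start_date + _dt.timedelta(days=day)
            events.append(TrapEvent(trap_id=trap_id, lon=float(lon), lat=float(lat),
                                    trap_type="CO2", collection_date=date,
                                    female_count=count,
                                    male_count=int(rng.poisson(0.5 * count))))
            lagrows.append(LagRow(trap_id=trap_id, collection_date=date,
                                  female_count=count, lag=lag))
            day += 7
    return events, lagrows


def _draw_count(rng: np.random.Generator, mu: float, dispersion: float) -> int:
    if not np.isfinite(dispersion):
        return int(rng.poisson(mu))
    # negative binomial with mean mu and size (dispersion) r
    r = dispersion
    p = r / (r + mu)
    return int(rng.negative_binomial(r, p))


def gen_lag_matrix(cfg: SyntheticConfig) -> "pd.DataFrame":
    """One-call generator of a thinned truth-based lag matrix.

    Convenience wrapper running stations -> precipitation -> trap events ->
    thinning -> lag matrix entirely from the true fields (no kriging), the
    standard input for screening/model tests.
    """
    from .lags import build_lag_matrix, thin_events

    stations, _, _ = gen_stations_and_elevation(cfg)
    traps = trap_grid(cfg)
    _, truth = gen_precip_days(cfg, stations, extra_points=traps)
    _, lagrows = gen_trap_events(cfg, truth, traps)
    return build_lag_matrix(thin_events(lagrows))
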