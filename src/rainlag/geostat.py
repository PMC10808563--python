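"""Variogram estimation and fitting, and kriging with an elevation drift.

The interpolation model is kriging with external drift (KED): the mean of the
precipitation field at a point is ``b0 + b1 * elevation``, and residual
spatial structure is captured by a semivariogram fitted automatically each
day.  The automatic fit follows the convention of treating the initial sill
as the mean of the maximum and median binned semivariance, the initial range
as one tenth of the bounding-box diagonal, and the initial nugget as the
minimum binned semivariance, then refining each candidate family (spherical,
exponential, Gaussian, Matern) by weighted least squares and keeping the
family with the smallest weighted residual sum of squares.

All distances are planar: lon/lat are projected to a local
transverse-Mercator-style system centered on the study bounding box before
any variogram or kriging computation (the study area is small enough that
the planar approximation error is negligible relative to station spacing).
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Sequence

import numpy as np
from scipy import optimize, special
from scipy.spatial.distance import cdist, pdist, squareform

from .datamodel import GridSpec, PrecipSurface, StationDay, clean_precip

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

VARIOGRAM_FAMILIES = ("spherical", "exponential", "gaussian", "matern")

#: Candidate Matern smoothness values; a free smoothness is nearly
#: unidentifiable from binned semivariances, so it is fitted over this set.
MATERN_SMOOTHNESS_GRID = (0.5, 1.0, 2.0)


class LocalProjection:
    """Planar projection centered on a bounding box (meters).

    Equirectangular about the box center with the x-scale locked to the
    central parallel — the same small-area approximation a local transverse
    Mercator gives to first order.
    """

    def __init__(self, bbox: tuple[float, float, float, float]):
        lon_min, lat_min, lon_max, lat_max = bbox
        self.lon0 = 0.5 * (lon_min + lon_max)
        self.lat0 = 0.5 * (lat_min + lat_max)
        self._coslat0 = math.cos(math.radians(self.lat0))

    def to_xy(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = np.radians(lon - self.lon0) * self._coslat0 * EARTH_RADIUS_M
        y = np.radians(lat - self.lat0) * EARTH_RADIUS_M
        return np.column_stack([np.ravel(x), np.ravel(y)])


@dataclasses.dataclass
class EmpiricalVariogram:
    """Binned semivariance estimates: mean of 0.5*(zi - zj)^2 per distance bin."""

    bin_center: np.ndarray  # meters; mean pair distance per retained bin
    semivariance: np.ndarray  # (inches)^2
    pair_count: np.ndarray

    def __post_init__(self):
        self.bin_center = np.asarray(self.bin_center, dtype=float)
        self.semivariance = np.asarray(self.semivariance, dtype=float)
        self.pair_count = np.asarray(self.pair_count, dtype=int)
        if not np.all(np.diff(self.bin_center) > 0):
            raise ValueError("bin centers must be strictly increasing")


@dataclasses.dataclass
class VariogramModel:
    """Fitted semivariogram: gamma(h) = nugget + psill * structure(h / range)."""

    family: str
    nugget: float
    partial_sill: float
    range_: float  # meters
    smoothness: float | None = None  # matern only
    fit_sse: float = float("nan")

    def __post_init__(self):
        if self.family not in VARIOGRAM_FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("require nugget >= 0, partial_sill >= 0, range > 0")
        if self.family == "matern" and self.smoothness is None:
            raise ValueError("matern model requires a smoothness")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


@dataclasses.dataclass
class KrigeResult:
    prediction: float  # inches (before cleaning)
    variance: float  # (inches)^2
    weights: np.ndarray  # per-station; sums to 1


def empirical_semivariogram(points: np.ndarray, values: np.ndarray,
                            n_bins: int = 15,
                            cutoff: float | None = None) -> EmpiricalVariogram:
    """Estimate the semivariogram from point data by distance binning.

    ``points`` are planar coordinates in meters, shape (n, 2).  Pairs beyond
    ``cutoff`` (default: a third of the maximum pair distance, the common
    automatic-fitting default) are discarded; empty bins are dropped.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    d = pdist(points)
    if np.all(d == 0):
        raise ValueError("all points identical in location: no pairs at distance > 0")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    if cutoff is None:
        cutoff = d.max() / 3.0
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    keep = (d > 0) & (d <= cutoff)
    d, sq = d[keep], sq[keep]
    if d.size == 0:
        raise ValueError("no pairs within cutoff")
    edges = np.linspace(0.0, cutoff, n_bins + 1)
    # right-closed bins (lo, hi] so a pair exactly at a bin edge stays there
    which = np.clip(np.digitize(d, edges, right=True) - 1, 0, n_bins - 1)
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        centers.append(d[mask].mean())
        gammas.append(sq[mask].mean())
        counts.append(int(mask.sum()))
    return EmpiricalVariogram(np.array(centers), np.array(gammas), np.array(counts))


def initial_params(emp: EmpiricalVariogram,
                   bbox_diagonal: float) -> tuple[float, float, float]:
    """Automatic-fit starting values: (sill0, range0, nugget0).

    sill0 = mean of the max and median binned semivariance; range0 = 0.1 x
    the bounding-box diagonal; nugget0 = minimum binned semivariance.
    """
    sv = emp.semivariance
    if sv.size == 0:
        raise ValueError("empty empirical variogram")
    sill0 = 0.5 * (sv.max() + float(np.median(sv)))
    range0 = 0.1 * bbox_diagonal
    nugget0 = float(sv.min())
    return sill0, range0, nugget0


def _matern_correlation(h: np.ndarray, range_: float, nu: float) -> np.ndarray:
    hr = np.asarray(h, dtype=float) / range_
    out = np.ones_like(hr)
    pos = hr > 0
    x = hr[pos]
    with np.errstate(over="ignore"):
        out[pos] = (2.0 ** (1.0 - nu) / special.gamma(nu)) * (x ** nu) * special.kv(nu, x)
    # kv underflows to 0 for large x, which is the correct limit
    return np.nan_to_num(out, nan=0.0)


def gamma(h, model: VariogramModel):
    """Evaluate the model semivariance at separation distance(s) h (meters)."""
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ValueError("distance must be non-negative")
    a, c0, c1 = model.range_, model.nugget, model.partial_sill
    if model.family == "spherical":
        hr = np.minimum(h_arr / a, 1.0)
        struct = 1.5 * hr - 0.5 * hr ** 3
    elif model.family == "exponential":
        struct = 1.0 - np.exp(-h_arr / a)
    elif model.family == "gaussian":
        struct = 1.0 - np.exp(-((h_arr / a) ** 2))
    else:  # matern
        struct = 1.0 - _matern_correlation(h_arr, a, model.smoothness)
    out = np.where(h_arr == 0.0, c0, c0 + c1 * struct)
    # gamma(0) = nugget by definition; for h > 0 the nugget is fully present
    if np.ndim(h) == 0:
        return float(out)
    return out


def fit_variogram(emp: EmpiricalVariogram,
                  families: Sequence[str] = VARIOGRAM_FAMILIES,
                  init: tuple[float, float, float] | None = None,
                  bbox_diagonal: float | None = None) -> VariogramModel:
    """Fit each candidate family by weighted least squares; keep the best.

    Residuals are weighted by sqrt(pair_count) / distance (i.e. squared
    weights N_j / h_j^2, the common automatic-fitting default).  Families
    that fail to converge are skipped with a warning; if none converge a
    ``RuntimeError`` is raised.
    """
    if emp.bin_center.size < 3:
        raise ValueError("need at least 3 variogram bins to fit")
    if init is None:
        if bbox_diagonal is None:
            bbox_diagonal = 10.0 * emp.bin_center.max()  # fallback scale
        init = initial_params(emp, bbox_diagonal)
    sill0, range0, nugget0 = init
    psill0 = max(sill0 - nugget0, 1e-12)
    h, g_emp = emp.bin_center, emp.semivariance
    w = np.sqrt(emp.pair_count) / h

    scale = max(g_emp.max(), 1e-30)

    def residuals(theta, family, nu):
        nugget, psill, rng = theta
        model = VariogramModel(family, max(nugget, 0.0), max(psill, 0.0),
                               max(rng, 1e-9), smoothness=nu)
        return w * (gamma(h, model) - g_emp)

    best: VariogramModel | None = None
    for family in families:
        nus = MATERN_SMOOTHNESS_GRID if family == "matern" else (None,)
        for nu in nus:
            try:
                res = optimize.least_squares(
                    residuals, x0=[nugget0, psill0, range0],
                    args=(family, nu),
                    bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                    x_scale=[scale, scale, range0], max_nfev=2000)
            except Exception as exc:  # pragma: no cover - scipy internals
                logger.warning("variogram fit failed for %s: %s", family, exc)
                continue
            if not res.success or not np.all(np.isfinite(res.x)):
                logger.warning("variogram fit did not converge for %s", family)
                continue
            sse = float(np.sum(res.fun ** 2))
            model = VariogramModel(family, float(res.x[0]), float(res.x[1]),
                                   float(max(res.x[2], 1e-9)), smoothness=nu,
                                   fit_sse=sse)
            if best is None or sse < best.fit_sse:
                best = model
    if best is None:
        raise RuntimeError("no variogram family converged")
    return best


def krige_points(station_xy: np.ndarray, station_values: np.ndarray,
                 station_drift: np.ndarray, target_xy: np.ndarray,
                 target_drift: np.ndarray, model: VariogramModel,
                 max_neighbors: int | None = 64) -> tuple[np.ndarray, np.ndarray]:
    """Kriging with external (elevation) drift at arbitrary target points.

    Solves the augmented semivariance system per target: unknown constant
    mean plus a linear elevation term.  Duplicate station locations must be
    resolved (averaged) by the caller; :func:`dedupe_stations` does this.

    Returns (predictions, variances); predictions are raw (not cleaned).
    With ``max_neighbors`` set, each target uses only its nearest stations,
    bounding cost on dense days.
    """
    station_xy = np.asarray(station_xy, dtype=float)
    target_xy = np.asarray(target_xy, dtype=float)
    z = np.asarray(station_values, dtype=float)
    drift_s = np.asarray(station_drift, dtype=float)
    drift_t = np.asarray(target_drift, dtype=float)
    n = len(station_xy)
    if n < 3:
        raise ValueError("kriging with drift requires at least 3 stations")

    use_all = max_neighbors is None or n <= max_neighbors
    if use_all:
        lhs, use_drift = _ked_lhs(station_xy, drift_s, model)
        try:
            lu = np.linalg.inv(lhs)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular kriging system: {exc}") from exc
        d0 = cdist(target_xy, station_xy)
        preds = np.empty(len(target_xy))
        varis = np.empty(len(target_xy))
        for i in range(len(target_xy)):
            rhs = _ked_rhs(d0[i], drift_t[i], model, use_drift)
            sol = lu @ rhs
            lam, mu = sol[:n], sol[n:]
            preds[i] = lam @ z
            varis[i] = max(float(lam @ rhs[:n] + mu @ rhs[n:]), 0.0)
        return preds, varis

    # local neighborhoods: solve a small system per target
    d_all = cdist(target_xy, station_xy)
    preds = np.empty(len(target_xy))
    varis = np.empty(len(target_xy))
    for i in range(len(target_xy)):
        idx = np.argpartition(d_all[i], max_neighbors - 1)[:max_neighbors]
        sub_xy, sub_z, sub_dr = station_xy[idx], z[idx], drift_s[idx]
        lhs, use_drift = _ked_lhs(sub_xy, sub_dr, model)
        m = len(idx)
        rhs = _ked_rhs(d_all[i][idx], drift_t[i], model, use_drift)
        try:
            sol = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular kriging system: {exc}") from exc
        lam, mu = sol[:m], sol[m:]
        preds[i] = lam @ sub_z
        varis[i] = max(float(lam @ rhs[:m] + mu @ rhs[m:]), 0.0)
    return preds, varis


def krige_point_detail(station_xy, station_values, station_drift,
                       target_xy, target_drift,
                       model: VariogramModel) -> KrigeResult:
    """Single-target kriging returning the weight vector (for diagnostics)."""
    station_xy = np.asarray(station_xy, dtype=float)
    z = np.asarray(station_values, dtype=float)
    n = len(station_xy)
    lhs, use_drift = _ked_lhs(station_xy, np.asarray(station_drift, float), model)
    d0 = cdist(np.atleast_2d(np.asarray(target_xy, float)), station_xy)[0]
    rhs = _ked_rhs(d0, float(target_drift), model, use_drift)
    sol = np.linalg.solve(lhs, rhs)
    lam, mu = sol[:n], sol[n:]
    return KrigeResult(prediction=float(lam @ z),
                       variance=max(float(lam @ rhs[:n] + mu @ rhs[n:]), 0.0),
                       weights=lam)


def _ked_lhs(station_xy: np.ndarray, drift: np.ndarray,
             model: VariogramModel) -> tuple[np.ndarray, bool]:
    """Augmented semivariance system; the elevation column is dropped when it
    is constant (collinear with the intercept), reducing to ordinary kriging."""
    n = len(station_xy)
    gm = gamma(squareform(pdist(station_xy)), model)
    np.fill_diagonal(gm, 0.0)
    use_drift = bool(np.ptp(drift) > 1e-9 * (abs(np.mean(drift)) + 1.0))
    k = 2 if use_drift else 1
    lhs = np.zeros((n + k, n + k))
    lhs[:n, :n] = gm
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0
    if use_drift:
        lhs[:n, n + 1] = drift
        lhs[n + 1, :n] = drift
    return lhs, use_drift


def _ked_rhs(d0: np.ndarray, drift_t: float, model: VariogramModel,
             use_drift: bool) -> np.ndarray:
    g0 = gamma(d0, model)
    # exact coincidence: gamma(0) on the rhs must be 0, not nugget, so that
    # kriging honors the observation at a station location
    g0 = np.where(d0 == 0.0, 0.0, g0)
    tail = [1.0, drift_t] if use_drift else [1.0]
    return np.concatenate([g0, tail])


def dedupe_stations(xy: np.ndarray, values: np.ndarray,
                    drift: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average observations sharing a location (avoids singular systems)."""
    xy = np.asarray(xy, dtype=float)
    key = np.round(xy, 6)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    if np.all(counts == 1):
        return xy, np.asarray(values, float), np.asarray(drift, float)
    k = counts.size
    out_xy = np.zeros((k, 2))
    out_v = np.zeros(k)
    out_d = np.zeros(k)
    np.add.at(out_xy, inv, xy)
    np.add.at(out_v, inv, np.asarray(values, float))
    np.add.at(out_d, inv, np.asarray(drift, float))
    out_xy /= counts[:, None]
    out_v /= counts
    out_d /= counts
    return out_xy, out_v, out_d


def bilinear_resample(src_grid: GridSpec, src_values: np.ndarray,
                      dst_grid: GridSpec) -> np.ndarray:
    """Resample a grid onto another grid by bilinear interpolation of cell centers."""
    from scipy.interpolate import RegularGridInterpolator
    src_lon = src_grid.lon_min + (np.arange(src_grid.n_cols) + 0.5) * src_grid.cell_width
    src_lat = src_grid.lat_min + (np.arange(src_grid.n_rows) + 0.5) * src_grid.cell_height
    interp = RegularGridInterpolator((src_lat, src_lon), np.asarray(src_values, float),
                                     bounds_error=False, fill_value=None)
    lon_g, lat_g = dst_grid.cell_centers()
    pts = np.column_stack([lat_g.ravel(), lon_g.ravel()])
    return interp(pts).reshape(dst_grid.n_rows, dst_grid.n_cols)


def fit_day_variogram(stations: Sequence[StationDay],
                      bbox: tuple[float, float, float, float],
                      n_bins: int = 15) -> VariogramModel:
    """Project one day's stations and run the automatic variogram fit."""
    proj = LocalProjection(bbox)
    xy = proj.to_xy([s.lon for s in stations], [s.lat for s in stations])
    values = np.array([s.precip for s in stations])
    emp = empirical_semivariogram(xy, values, n_bins=n_bins)
    corners = proj.to_xy([bbox[0], bbox[2]], [bbox[1], bbox[3]])
    diag = float(np.hypot(*(corners[1] - corners[0])))
    return fit_variogram(emp, init=initial_params(emp, diag))


def make_daily_surface(stations: Sequence[StationDay],
                       elevation_grid: np.ndarray,
                       grid: GridSpec,
                       model: VariogramModel | None = None,
                       max_neighbors: int | None = 64,
                       with_variance: bool = False) -> PrecipSurface:
    """Krige one day's station observations onto every cell center.

    ``model=None`` triggers a per-day automatic variogram fit.  Days whose
    reporting stations all share one value (including all-zero days) return
    that uniform surface directly — any unbiased predictor reproduces a
    constant field exactly, so no system is solved.  Days with fewer than 3
    stations yield an all-NaN surface with a warning.
    """
    if len(stations) == 0:
        raise ValueError("no station observations supplied")
    date = stations[0].date
    if any(s.date != date for s in stations):
        raise ValueError("make_daily_surface expects a single date")
    values = np.array([clean_precip(s.precip) for s in stations])
    shape = (grid.n_rows, grid.n_cols)

    if len(stations) < 3:
        warnings.warn(f"{date}: fewer than 3 reporting stations; surface is all-missing")
        return PrecipSurface(grid=grid, date=date, values=np.full(shape, np.nan))

    if np.ptp(values) == 0.0:
        return PrecipSurface(grid=grid, date=date,
                             values=np.full(shape, values[0]),
                             variance=np.zeros(shape) if with_variance else None)

    if model is None:
        model = fit_day_variogram(stations, grid.bbox)

    proj = LocalProjection(grid.bbox)
    st_xy = proj.to_xy([s.lon for s in stations], [s.lat for s in stations])
    st_drift = np.array([s.elevation for s in stations])
    st_xy, values, st_drift = dedupe_stations(st_xy, values, st_drift)

    lon_g, lat_g = grid.cell_centers()
    tgt_xy = proj.to_xy(lon_g.ravel(), lat_g.ravel())
    tgt_drift = np.asarray(elevation_grid, dtype=float).ravel()
    if tgt_drift.size != tgt_xy.shape[0]:
        raise ValueError("elevation grid does not match the analysis grid")

    try:
        preds, varis = krige_points(st_xy, values, st_drift, tgt_xy, tgt_drift,
                                    model, max_neighbors=max_neighbors)
    except RuntimeError as exc:
        raise RuntimeError(f"kriging failed on {date}: {exc}") from exc
    return PrecipSurface(grid=grid, date=date,
                         values=clean_precip(preds).reshape(shape),
                         variance=varis.reshape(shape) if with_variance else None)
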