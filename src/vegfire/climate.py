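"""Climate transforms: humidity, pseudo-daily interpolation, detrending,
biogeography smoothing, and delta-method anomaly downscaling.

Gridded monthly climate is carried as an :class:`xarray.Dataset` with
dimensions ``(time, y, x)`` and variables

* ``ppt``  -- precipitation, cm month^-1
* ``tmax`` -- mean daily maximum temperature, deg C
* ``tmin`` -- mean daily minimum temperature, deg C
* ``vpr``  -- mean vapor pressure, Pa

with integer auxiliary coordinates ``year`` and ``month`` along ``time``
(a 365-day, no-leap calendar).  Anomaly trajectories use dimensions
``(time, yc, xc)`` on a coarse lattice whose ``yc``/``xc`` coordinates are
positions in fine-grid index space.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

__all__ = [
    "MONTH_LENGTHS",
    "saturation_vapor_pressure",
    "derive_humidity",
    "pseudo_daily",
    "pseudo_daily_year",
    "detrend_for_spinup",
    "ClimateSmoother",
    "bilinear_interpolate",
    "downscale_anomaly",
    "baseline_means",
]

#: Days per month in the model's no-leap calendar.
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

# Magnus saturation-vapor-pressure constants (hPa, -, deg C).
_MAGNUS_A = 6.1094
_MAGNUS_B = 17.625
_MAGNUS_C = 243.04

#: Anomaly ratios for precipitation and vapor pressure are capped here.
RATIO_CAP = 5.0


def saturation_vapor_pressure(t_c):
    """Saturation vapor pressure in Pa at temperature ``t_c`` (deg C)."""
    t_c = np.asarray(t_c, dtype=float)
    return 100.0 * _MAGNUS_A * np.exp(_MAGNUS_B * t_c / (_MAGNUS_C + t_c))


def derive_humidity(tmax, tmin, vpr, rh_floor: float = 1.0):
    """Relative humidity (%) and vapor pressure deficit (Pa) for a month.

    RH is vapor pressure over saturation at the daily-mean temperature,
    clipped to ``(rh_floor, 100]``; VPD is ``max(es - vpr, 0)``.
    """
    tmean = 0.5 * (np.asarray(tmax, float) + np.asarray(tmin, float))
    es = saturation_vapor_pressure(tmean)
    rh = np.clip(100.0 * np.asarray(vpr, float) / es, rh_floor, 100.0)
    vpd = np.maximum(es - np.asarray(vpr, float), 0.0)
    return rh, vpd


# ---------------------------------------------------------------------------
# pseudo-daily interpolation
# ---------------------------------------------------------------------------

def _midpoints(ndays: int) -> float:
    # mid-month anchor as a (1-based) fractional day
    return 0.5 * (ndays + 1)


def pseudo_daily(prev, cur, nxt, ndays_prev: int, ndays: int, ndays_next: int,
                 conserve_total: bool = False) -> np.ndarray:
    """Daily values for one month, linear between mid-month anchors.

    ``prev``/``cur``/``nxt`` are the monthly values of the neighboring months
    (scalars or arrays broadcast along a trailing cell axis); the mid-month
    day equals the monthly value exactly.  With ``conserve_total`` the daily
    series is rescaled so it sums to ``cur * ndays`` (used for precipitation,
    where monthly totals must be conserved).

    Returns an array of shape ``(ndays,) + shape(cur)``.
    """
    prev = np.asarray(prev, float)
    cur = np.asarray(cur, float)
    nxt = np.asarray(nxt, float)
    mid = _midpoints(ndays)
    days = np.arange(1, ndays + 1, dtype=float)
    out = np.empty((ndays,) + cur.shape, dtype=float)

    first = days <= mid
    # distance between previous month's mid and this month's mid
    span_prev = (ndays_prev - _midpoints(ndays_prev)) + mid
    frac = (days[first] - mid) / span_prev  # in [-1, 0]
    out[first] = cur + frac.reshape((-1,) + (1,) * cur.ndim) * (cur - prev)

    last = ~first
    span_next = (ndays - mid) + _midpoints(ndays_next)
    frac = (days[last] - mid) / span_next  # in (0, 1)
    out[last] = cur + frac.reshape((-1,) + (1,) * cur.ndim) * (nxt - cur)

    if conserve_total:
        out = np.maximum(out, 0.0)
        total = out.sum(axis=0)
        target = cur * ndays
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(total > 0, target / np.where(total > 0, total, 1.0), 0.0)
        out = out * scale
    return out


def pseudo_daily_year(monthly: np.ndarray, prev_dec: np.ndarray,
                      next_jan: np.ndarray, conserve_total: bool = False) -> np.ndarray:
    """Pseudo-daily series for a whole year.

    ``monthly`` has shape ``(12,) + cell_shape``; ``prev_dec`` / ``next_jan``
    supply the edge anchors (replicated at series ends by the caller).
    Returns shape ``(365,) + cell_shape``.
    """
    monthly = np.asarray(monthly, float)
    parts = []
    for m in range(12):
        prev = prev_dec if m == 0 else monthly[m - 1]
        nxt = next_jan if m == 11 else monthly[m + 1]
        nd_prev = MONTH_LENGTHS[(m - 1) % 12]
        nd_next = MONTH_LENGTHS[(m + 1) % 12]
        parts.append(pseudo_daily(prev, monthly[m], nxt,
                                  nd_prev, MONTH_LENGTHS[m], nd_next,
                                  conserve_total=conserve_total))
    return np.concatenate(parts, axis=0)


# ---------------------------------------------------------------------------
# detrending for spinup
# ---------------------------------------------------------------------------

def detrend_for_spinup(grid: xr.Dataset) -> xr.Dataset:
    """Remove per-cell linear trends over years from a historical grid.

    Temperature variables are detrended additively; precipitation and vapor
    pressure multiplicatively (trend line of annual values divided out and
    the long-term mean restored).  Precipitation is floored at zero.
    """
    years = np.unique(grid["year"].values)
    if years.size < 2:
        raise ValueError("detrending requires at least 2 years of data")
    out = grid.copy(deep=True)
    yr = grid["year"].values.astype(float)
    t = yr - yr.mean()

    for var in ("tmax", "tmin"):
        annual = grid[var].groupby(grid["year"]).mean("time")
        ya = annual["year"].values.astype(float) - yr.mean()
        slope = np.polyfit(ya, annual.values.reshape(len(years), -1), 1)[0]
        slope = slope.reshape(annual.shape[1:])
        out[var] = grid[var] - xr.DataArray(
            t[:, None, None] * slope[None, :, :], dims=("time", "y", "x"))

    for var in ("ppt", "vpr"):
        annual = grid[var].groupby(grid["year"]).mean("time")
        ya = annual["year"].values.astype(float) - yr.mean()
        flat = annual.values.reshape(len(years), -1)
        slope, intercept = np.polyfit(ya, flat, 1)
        trend = (t[:, None] * slope[None, :] + intercept[None, :])
        mean = flat.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(trend > 0, mean[None, :] / np.where(trend > 0, trend, 1.0), 1.0)
        factor = factor.reshape((len(yr),) + grid[var].shape[1:])
        out[var] = xr.DataArray(
            np.maximum(grid[var].values * factor, 0.0), dims=("time", "y", "x"))
    return out


# ---------------------------------------------------------------------------
# biogeography smoothing
# ---------------------------------------------------------------------------

class ClimateSmoother:
    """Exponential running means of the two biogeography climate drivers.

    Tracks (a) minimum temperature of the coldest month and (b) growing-season
    (April-September) precipitation, updated once per year.  The first update
    initializes the smoothed values to that year's values; afterwards

        s <- s + alpha * (x - s),  alpha = 1 - exp(-1 / tau)

    with e-folding time ``tau`` in years.
    """

    def __init__(self, efold_years: float = 10.0):
        self.alpha = 1.0 - float(np.exp(-1.0 / efold_years))
        self.min_temp: np.ndarray | None = None
        self.gs_precip: np.ndarray | None = None

    def update(self, tmin_monthly: np.ndarray, ppt_monthly: np.ndarray):
        """Advance one year.  Inputs have shape ``(12,) + cell_shape``."""
        coldest = np.min(tmin_monthly, axis=0)
        gsp = np.sum(ppt_monthly[3:9], axis=0)  # April..September
        if self.min_temp is None:
            self.min_temp = np.array(coldest, dtype=float, copy=True)
            self.gs_precip = np.array(gsp, dtype=float, copy=True)
        else:
            self.min_temp += self.alpha * (coldest - self.min_temp)
            self.gs_precip += self.alpha * (gsp - self.gs_precip)
        return self.min_temp, self.gs_precip


# ---------------------------------------------------------------------------
# delta-method downscaling
# ---------------------------------------------------------------------------

def bilinear_interpolate(coarse: np.ndarray, yc: np.ndarray, xc: np.ndarray,
                         yf: np.ndarray, xf: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of ``coarse`` (..., yc, xc) onto fine points.

    ``yf``/``xf`` are 1-D fine-grid coordinates in the same space as the
    coarse lattice coordinates; the lattice must cover the fine grid.
    """
    yc = np.asarray(yc, float)
    xc = np.asarray(xc, float)
    if yf.min() < yc.min() - 1e-9 or yf.max() > yc.max() + 1e-9 \
            or xf.min() < xc.min() - 1e-9 or xf.max() > xc.max() + 1e-9:
        raise ValueError("anomaly lattice does not cover the fine grid")
    iy = np.clip(np.searchsorted(yc, yf, side="right") - 1, 0, len(yc) - 2)
    ix = np.clip(np.searchsorted(xc, xf, side="right") - 1, 0, len(xc) - 2)
    wy = (yf - yc[iy]) / (yc[iy + 1] - yc[iy])
    wx = (xf - xc[ix]) / (xc[ix + 1] - xc[ix])
    wy = np.clip(wy, 0.0, 1.0)[:, None]
    wx = np.clip(wx, 0.0, 1.0)[None, :]
    c00 = coarse[..., iy[:, None], ix[None, :]]
    c01 = coarse[..., iy[:, None], ix[None, :] + 1]
    c10 = coarse[..., iy[:, None] + 1, ix[None, :]]
    c11 = coarse[..., iy[:, None] + 1, ix[None, :] + 1]
    return ((1 - wy) * (1 - wx) * c00 + (1 - wy) * wx * c01
            + wy * (1 - wx) * c10 + wy * wx * c11)


def baseline_means(grid: xr.Dataset, year_start: int = 1971,
                   year_end: int = 2000) -> xr.Dataset:
    """Per-month climatological means over a baseline window (inclusive)."""
    sel = grid.sel(time=(grid["year"] >= year_start) & (grid["year"] <= year_end))
    return sel.groupby(sel["month"]).mean("time")


def downscale_anomaly(anomalies: xr.Dataset, baseline: xr.Dataset) -> xr.Dataset:
    """Apply coarse GCM-style anomalies to a fine-grid monthly baseline.

    Temperature anomalies (``dtemp``, deg C) are added; precipitation and
    vapor-pressure ratios (``pratio``, ``vratio``) are multiplied after
    capping at :data:`RATIO_CAP`.  Anomalies are bilinearly interpolated from
    the coarse ``(yc, xc)`` lattice to the fine grid first.

    ``baseline`` is the output of :func:`baseline_means` (dims month, y, x);
    returns a future grid with dims ``(time, y, x)``.
    """
    pratio = anomalies["pratio"].values
    vratio = anomalies["vratio"].values
    if np.any(pratio <= 0) or np.any(vratio <= 0):
        raise ValueError("multiplicative anomalies must be positive")
    ny = baseline.sizes["y"]
    nx = baseline.sizes["x"]
    yf = np.arange(ny, dtype=float)
    xf = np.arange(nx, dtype=float)
    yc = anomalies["yc"].values
    xc = anomalies["xc"].values

    dtemp = bilinear_interpolate(anomalies["dtemp"].values, yc, xc, yf, xf)
    prat = bilinear_interpolate(np.minimum(pratio, RATIO_CAP), yc, xc, yf, xf)
    vrat = bilinear_interpolate(np.minimum(vratio, RATIO_CAP), yc, xc, yf, xf)

    years = anomalies["year"].values
    months = anomalies["month"].values
    midx = months - 1
    base_ppt = baseline["ppt"].values[midx]
    base_tmax = baseline["tmax"].values[midx]
    base_tmin = baseline["tmin"].values[midx]
    base_vpr = baseline["vpr"].values[midx]

    tmax = base_tmax + dtemp
    tmin = base_tmin + dtemp
    ppt = np.maximum(base_ppt * np.minimum(prat, RATIO_CAP), 0.0)
    vpr = base_vpr * np.minimum(vrat, RATIO_CAP)
    # keep vapor pressure physically consistent (RH <= 100%)
    es = saturation_vapor_pressure(0.5 * (tmax + tmin))
    vpr = np.minimum(vpr, es)

    time = np.arange(len(years))
    return xr.Dataset(
        {v: (("time", "y", "x"), d) for v, d in
         (("ppt", ppt), ("tmax", tmax), ("tmin", tmin), ("vpr", vpr))},
        coords={"time": time, "year": ("time", years), "month": ("time", months),
                "y": np.arange(ny), "x": np.arange(nx)},
    )
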