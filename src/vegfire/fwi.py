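"""Canadian Forest Fire Weather Index System moisture codes.

Vectorized daily updates of the Fine Fuel Moisture Code (FFMC), Duff
Moisture Code (DMC), and Drought Code (DC), plus the Build-Up Index (BUI)
and the mapping from codes to dead-fuel moisture contents by timelag class.
The update equations are the published standard daily equations of the FWI
System; inputs are noon-equivalent temperature (deg C), relative humidity
(%), wind speed (km h^-1) and 24-h rain (mm).

All functions accept scalars or equal-shaped numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ffmc_update",
    "dmc_update",
    "dc_update",
    "bui",
    "update_codes",
    "fuel_moistures",
    "DMC_DAY_LENGTH",
    "DC_DAY_FACTOR",
]

#: DMC effective day-length factors by month (46N standard table).
DMC_DAY_LENGTH = np.array([6.5, 7.5, 9.0, 12.8, 13.9, 13.9,
                           12.4, 10.9, 9.4, 8.0, 7.0, 6.0])
#: DC day-length adjustment by month.
DC_DAY_FACTOR = np.array([-1.6, -1.6, -1.6, 0.9, 3.8, 5.8,
                          6.4, 5.0, 2.4, 0.4, -1.6, -1.6])


def ffmc_update(ffmc_prev, temp, rh, wind, rain):
    """One-day FFMC update.  ``wind`` km h^-1, ``rain`` mm."""
    f0 = np.asarray(ffmc_prev, float)
    t = np.asarray(temp, float)
    h = np.clip(np.asarray(rh, float), 0.0, 100.0)
    w = np.asarray(wind, float)
    r = np.asarray(rain, float)

    mo = 147.2 * (101.0 - f0) / (59.5 + f0)

    # rainfall phase
    rf = np.maximum(r - 0.5, 0.0)
    wet = rf > 0
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        mr = mo + 42.5 * rf * np.exp(-100.0 / (251.0 - np.minimum(mo, 250.0))) \
            * (1.0 - np.exp(-6.93 / np.where(wet, rf, 1.0)))
        mr = mr + np.where(mo > 150.0,
                           0.0015 * (mo - 150.0) ** 2 * np.sqrt(rf), 0.0)
    mo = np.where(wet, np.minimum(mr, 250.0), mo)

    ed = (0.942 * h ** 0.679 + 11.0 * np.exp((h - 100.0) / 10.0)
          + 0.18 * (21.1 - t) * (1.0 - np.exp(-0.115 * h)))
    ew = (0.618 * h ** 0.753 + 10.0 * np.exp((h - 100.0) / 10.0)
          + 0.18 * (21.1 - t) * (1.0 - np.exp(-0.115 * h)))

    # drying toward Ed
    ko = (0.424 * (1.0 - (h / 100.0) ** 1.7)
          + 0.0694 * np.sqrt(np.maximum(w, 0.0)) * (1.0 - (h / 100.0) ** 8))
    kd = ko * 0.581 * np.exp(0.0365 * t)
    m_dry = ed + (mo - ed) * 10.0 ** (-kd)

    # wetting toward Ew
    kl = (0.424 * (1.0 - ((100.0 - h) / 100.0) ** 1.7)
          + 0.0694 * np.sqrt(np.maximum(w, 0.0)) * (1.0 - ((100.0 - h) / 100.0) ** 8))
    kw = kl * 0.581 * np.exp(0.0365 * t)
    m_wet = ew - (ew - mo) * 10.0 ** (-kw)

    m = np.where(mo > ed, m_dry, np.where(mo < ew, m_wet, mo))
    return np.clip(59.5 * (250.0 - m) / (147.2 + m), 0.0, 101.0)


def dmc_update(dmc_prev, temp, rh, rain, month):
    """One-day DMC update.  ``month`` is 1..12 (scalar)."""
    p0 = np.asarray(dmc_prev, float)
    t = np.asarray(temp, float)
    h = np.clip(np.asarray(rh, float), 0.0, 100.0)
    r = np.asarray(rain, float)

    wet = r > 1.5
    re = 0.92 * r - 1.27
    mo = 20.0 + np.exp(5.6348 - p0 / 43.43)
    b = np.where(p0 <= 33.0, 100.0 / (0.5 + 0.3 * p0),
                 np.where(p0 <= 65.0, 14.0 - 1.3 * np.log(np.maximum(p0, 1e-9)),
                          6.2 * np.log(np.maximum(p0, 1e-9)) - 17.2))
    mr = mo + 1000.0 * re / (48.77 + b * re)
    pr = np.maximum(244.72 - 43.43 * np.log(np.maximum(mr - 20.0, 1e-9)), 0.0)
    p = np.where(wet, pr, p0)

    le = DMC_DAY_LENGTH[month - 1]
    k = 1.894 * (np.maximum(t, -1.1) + 1.1) * (100.0 - h) * le * 1e-6
    return p + 100.0 * k


def dc_update(dc_prev, temp, rain, month):
    """One-day DC update.  ``month`` is 1..12 (scalar)."""
    d0 = np.asarray(dc_prev, float)
    t = np.asarray(temp, float)
    r = np.asarray(rain, float)

    wet = r > 2.8
    rd = 0.83 * r - 1.27
    q0 = 800.0 * np.exp(-d0 / 400.0)
    qr = q0 + 3.937 * rd
    dr = np.maximum(400.0 * np.log(800.0 / np.maximum(qr, 1e-9)), 0.0)
    d = np.where(wet, dr, d0)

    lf = DC_DAY_FACTOR[month - 1]
    v = np.maximum(0.36 * (np.maximum(t, -2.8) + 2.8) + lf, 0.0)
    return d + 0.5 * v


def bui(dmc, dc):
    """Build-Up Index from DMC and DC."""
    p = np.asarray(dmc, float)
    d = np.asarray(dc, float)
    denom = p + 0.4 * d
    with np.errstate(invalid="ignore", divide="ignore"):
        lo = np.where(denom > 0, 0.8 * p * d / np.where(denom > 0, denom, 1.0), 0.0)
        hi = p - (1.0 - 0.8 * d / np.where(denom > 0, denom, 1.0)) \
            * (0.92 + (0.0114 * p) ** 1.7)
    return np.maximum(np.where(p <= 0.4 * d, lo, hi), 0.0)


def update_codes(ffmc, dmc, dc, temp, rh, wind, rain, month: int):
    """One-day update of all three moisture codes plus the BUI.

    Convenience wrapper over the individual updates; returns
    ``(ffmc, dmc, dc, bui)``.
    """
    f = ffmc_update(ffmc, temp, rh, wind, rain)
    p = dmc_update(dmc, temp, rh, rain, month)
    d = dc_update(dc, temp, rain, month)
    return f, p, d, bui(p, d)


def fuel_moistures(ffmc, dmc, dc):
    """Dead-fuel moisture fractions by timelag class from the codes.

    1-h moisture is the FFMC fine-fuel moisture content; 10-h lags it
    slightly; 100-h follows the DMC duff moisture and 1000-h the DC
    moisture equivalent.  Returned as fractions (0.1 == 10%).
    """
    f = np.asarray(ffmc, float)
    m1 = 147.2 * (101.0 - f) / (59.5 + f) / 100.0
    m10 = 1.25 * m1 + 0.01
    m100 = (20.0 + np.exp(5.6348 - np.asarray(dmc, float) / 43.43)) / 100.0 * 0.6
    m1000 = 800.0 * np.exp(-np.asarray(dc, float) / 400.0) / 100.0 * 0.4
    return {"1h": m1, "10h": m10, "100h": np.minimum(m100, 2.0),
            "1000h": np.minimum(m1000, 2.0)}
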