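"""Independent scalar transcription of the Canadian FWI daily equations.

Used as the oracle for the vectorized implementation in vegfire.fwi; written
separately as plain scalar functions following the published equation
numbering, and deliberately not shared with the package code.
"""

import math

EL = [6.5, 7.5, 9.0, 12.8, 13.9, 13.9, 12.4, 10.9, 9.4, 8.0, 7.0, 6.0]
FL = [-1.6, -1.6, -1.6, 0.9, 3.8, 5.8, 6.4, 5.0, 2.4, 0.4, -1.6, -1.6]


def ffmc(f_prev, t, h, w, r):
    mo = 147.2 * (101.0 - f_prev) / (59.5 + f_prev)
    if r > 0.5:
        rf = r - 0.5
        if mo <= 150.0:
            mo = mo + 42.5 * rf * math.exp(-100.0 / (251.0 - mo)) \
                * (1.0 - math.exp(-6.93 / rf))
        else:
            mo = mo + 42.5 * rf * math.exp(-100.0 / (251.0 - mo)) \
                * (1.0 - math.exp(-6.93 / rf)) \
                + 0.0015 * (mo - 150.0) ** 2 * math.sqrt(rf)
        if mo > 250.0:
            mo = 250.0
    ed = 0.942 * h ** 0.679 + 11.0 * math.exp((h - 100.0) / 10.0) \
        + 0.18 * (21.1 - t) * (1.0 - math.exp(-0.115 * h))
    if mo > ed:
        ko = 0.424 * (1.0 - (h / 100.0) ** 1.7) \
            + 0.0694 * math.sqrt(w) * (1.0 - (h / 100.0) ** 8)
        kd = ko * 0.581 * math.exp(0.0365 * t)
        m = ed + (mo - ed) * 10.0 ** (-kd)
    else:
        ew = 0.618 * h ** 0.753 + 10.0 * math.exp((h - 100.0) / 10.0) \
            + 0.18 * (21.1 - t) * (1.0 - math.exp(-0.115 * h))
        if mo < ew:
            kl = 0.424 * (1.0 - ((100.0 - h) / 100.0) ** 1.7) \
                + 0.0694 * math.sqrt(w) * (1.0 - ((100.0 - h) / 100.0) ** 8)
            kw = kl * 0.581 * math.exp(0.0365 * t)
            m = ew - (ew - mo) * 10.0 ** (-kw)
        else:
            m = mo
    f = 59.5 * (250.0 - m) / (147.2 + m)
    return max(0.0, min(f, 101.0))


def dmc(p_prev, t, h, r, month):
    p = p_prev
    if r > 1.5:
        re = 0.92 * r - 1.27
        mo = 20.0 + math.exp(5.6348 - p_prev / 43.43)
        if p_prev <= 33.0:
            b = 100.0 / (0.5 + 0.3 * p_prev)
        elif p_prev <= 65.0:
            b = 14.0 - 1.3 * math.log(p_prev)
        else:
            b = 6.2 * math.log(p_prev) - 17.2
        mr = mo + 1000.0 * re / (48.77 + b * re)
        p = 244.72 - 43.43 * math.log(mr - 20.0)
        if p < 0.0:
            p = 0.0
    t_eff = max(t, -1.1)
    k = 1.894 * (t_eff + 1.1) * (100.0 - h) * EL[month - 1] * 1.0e-6
    return p + 100.0 * k


def dc(d_prev, t, r, month):
    d = d_prev
    if r > 2.8:
        rd = 0.83 * r - 1.27
        qo = 800.0 * math.exp(-d_prev / 400.0)
        qr = qo + 3.937 * rd
        d = 400.0 * math.log(800.0 / qr)
        if d < 0.0:
            d = 0.0
    t_eff = max(t, -2.8)
    v = 0.36 * (t_eff + 2.8) + FL[month - 1]
    if v < 0.0:
        v = 0.0
    return d + 0.5 * v


def bui(p, d):
    if p <= 0.4 * d:
        if p + 0.4 * d <= 0:
            return 0.0
        u = 0.8 * p * d / (p + 0.4 * d)
    else:
        u = p - (1.0 - 0.8 * d / (p + 0.4 * d)) \
            * (0.92 + (0.0114 * p) ** 1.7)
    return max(u, 0.0)
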