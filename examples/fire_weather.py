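"""Daily fire-weather codes through a drought year.

Feeds pseudo-daily weather (interpolated from monthly values) through the
Canadian fire-weather index chain for the warm-dry corner cell in a severe
drought year, and prints the month-end codes.  Natural ignition needs
FFMC > 90.4 and BUI > 80 on a day with a positive spread rate, so the dry
late summer is when fires happen.
"""

import numpy as np

import vegfire as vf
from vegfire import fwi
from vegfire.climate import MONTH_LENGTHS, derive_humidity, pseudo_daily_year

climate, _ = vf.generate_grid(vf.SyntheticConfig(seed=0))
year = 1936  # deep in the 1930s-analogue drought
sel = climate.sel(time=climate.year == year).isel(y=-1, x=-1)

rh_m, _ = derive_humidity(sel.tmax.values, sel.tmin.values, sel.vpr.values)
daily_t = pseudo_daily_year(sel.tmax.values, sel.tmax.values[11:12],
                            sel.tmax.values[0:1])
daily_rh = np.clip(pseudo_daily_year(rh_m, rh_m[11:12], rh_m[0:1]), 1, 100)
rates = sel.ppt.values / MONTH_LENGTHS
daily_rain = pseudo_daily_year(rates, rates[11:12], rates[0:1],
                               conserve_total=True) * 10.0  # mm

ffmc, dmc, dc = 85.0, 6.0, 15.0
day = 0
print(f"{'month':>5} {'FFMC':>6} {'DMC':>6} {'DC':>6} {'BUI':>6}")
for m in range(12):
    for _ in range(MONTH_LENGTHS[m]):
        ffmc = float(fwi.ffmc_update(ffmc, daily_t[day], daily_rh[day],
                                     6 * 3.6, daily_rain[day]))
        dmc = float(fwi.dmc_update(dmc, daily_t[day], daily_rh[day],
                                   daily_rain[day], m + 1))
        dc = float(fwi.dc_update(dc, daily_t[day], daily_rain[day], m + 1))
        day += 1
    bui = float(fwi.bui(dmc, dc))
    flag = "  <- ignition window" if ffmc > 90.4 and bui > 80 else ""
    print(f"{m + 1:5d} {ffmc:6.1f} {dmc:6.1f} {dc:6.1f} {bui:6.1f}{flag}")
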