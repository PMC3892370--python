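"""Generate the synthetic landscape and inspect its climate gradient.

Builds the default 12x12 grid of monthly climate (1895-2008) whose mean
annual temperature rises and precipitation falls from the NW to the SE
corner, spanning the prairie-woodland ecotone boundary climate
(7.6 degC / 48.5 cm), with half of the precipitation falling May-July.
"""

import numpy as np

import vegfire as vf

climate, soils = vf.generate_grid(vf.SyntheticConfig(seed=0))

tmean = 0.5 * (climate.tmax + climate.tmin)
annual_ppt = climate.ppt.groupby(climate.year).sum()

print("grid:", dict(climate.sizes))
for name, iy, ix in (("NW corner (cool/wet)", 0, 0),
                     ("center", 5, 5),
                     ("SE corner (warm/dry)", -1, -1)):
    t = float(tmean.isel(y=iy, x=ix).mean())
    p = float(annual_ppt.isel(y=iy, x=ix).mean())
    print(f"{name:22s} Tmean {t:5.2f} degC   PPT {p:5.1f} cm/yr")

months = climate.month.values
mjj = climate.ppt.values[np.isin(months, [5, 6, 7])].sum() / climate.ppt.values.sum()
print(f"fraction of precipitation falling May-July: {mjj:.3f}")

drought = annual_ppt.sel(year=slice(1933, 1938)).mean("year")
normal = annual_ppt.mean("year")
print(f"1930s drought precipitation, fraction of normal: "
      f"{float((drought / normal).mean()):.2f}")
# The gradient brackets the ecotone boundary (7.6 degC / 48.5 cm): cells on
# the cool-wet side will support forest under natural fire, cells on the
# warm-dry side will not.
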