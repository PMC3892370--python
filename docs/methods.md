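# Methods

`vegfire` is a desk-scale dynamic vegetation model of a prairie–woodland
ecotone: a lattice of independent cells, each carrying CENTURY-style carbon
pools for one evergreen needleleaf tree type and a C3/C4 grass stratum,
driven by monthly climate, with a daily fire subsystem built on the
Canadian Fire Weather Index (FWI) System and the Rothermel surface spread
model.  The question the model is built to answer is mechanistic: where,
along a gradient of warming temperature and declining precipitation, does
fire frequency flip the stable vegetation from forest to grassland — and
how does that boundary respond to 21st-century climate under natural-fire,
fire-suppression, and prescribed-fire management?

## Model structure

**Cells are independent.**  Each cell is a point model; "maps" are
collections of point runs.  Drought, and therefore fire danger, is
region-wide by construction of the climate generator, which is what makes
contiguous blocks of cells burn in the same years.

**Monthly biogeochemistry.**  Maximum monthly production rates for trees
and grasses are scaled by multiplicative factors: a Gaussian temperature
response (hard zero below freezing); a water scalar that is a saturating
power of the ratio of available water (monthly precipitation plus
plant-available soil water) to Penman potential evapotranspiration, with
the tree curve less steep than the grass curve (drought-tolerant pine); a
logarithmic CO2 factor (+15 % production and −25 % transpiration per
doubling); for trees a light-capture factor and a grass-competition
factor (below); for grasses, shading by tree canopy and standing dead.
NPP is allocated with fixed fractions (tree: 25 % leaf, 15 % fine branch,
35 % large wood, 25 % roots; grass: 60/40 shoot/root).  Turnover routes
live carbon to dead pools by fuel timelag class (leaf → 1-h/10-h litter,
fine branch → 100-h, large wood → 1000-h, roots → soil), and dead and soil
pools decay first-order down a litter → active → slow → passive chain with
Q10 temperature and available-water moisture modifiers.  Only a tenth of
decayed slow carbon is stabilized into the passive pool.  Nitrogen is not
cycled; nutrient limitation is folded into the calibrated maximum
production rates.  Carbon is conserved exactly: at every step the change
in total carbon equals NPP plus establishment inflow minus heterotrophic
respiration, grazing offtake, and fire emissions.

**Water.**  Two soil buckets (0–30 cm and 30 cm–profile depth) with
plant-available capacity from a pedotransfer constant (0.13 cm water per
cm soil).  PET uses the Penman combination equation with a
Hargreaves-type radiation estimate from the diurnal temperature range and
the classical linear wind function.  AET is the lesser of demand
(0.8 × PET, times the CO2 transpiration multiplier) and stored water.

**Tree geometry.**  Height is a power law of aboveground tree carbon
(`0.25 · C^0.45` m, ≈14 m for the calibrated old forest), crown base
height is height times one minus a crown ratio that declines from 0.9 in
saplings to 0.4 in tall stands, bark is 0.15 cm per meter of height, and
LAI saturates in leaf carbon at an asymptote of 2.5 — half the generic
closed-forest default, reflecting the open canopies of a shade-intolerant
pine.

**Fire.**  Pseudo-daily weather is linearly interpolated between mid-month
anchors (daily precipitation rescaled to conserve monthly totals), and the
published FWI daily equations update FFMC/DMC/DC (startup values 85/6/15
each year in the first month above 0 °C; no overwintering of the drought
code).  Natural ignition is deterministic: the first day of the year on
which the spread rate is positive, FFMC > 90.4 and BUI > 80 — at most one
fire per cell-year.  Behavior comes from a Rothermel surface-spread core
over the cell's fuel bed (1-h/10-h/100-h dead classes plus live fine
fuel; carbon-to-dry-matter factor 2.0), with vegetation-class wind (6 m/s
grassland, 3 m/s forest) and moistures of extinction (30 % / 25 %).
Fireline intensity is Byram's `H·w·R`; the energy-release component is
the flaming-front energy of the consumed fuel per unit area over a fixed
60 s residence time, in kW m⁻² to match the SI suppression thresholds.
Crown fire initiates when intensity reaches the critical value
`(0.01·CBH·(460+25.9·FMC))^1.5` (foliar moisture fixed at 100 %), and
kills all live tree carbon.  Surface-fire stem kill is a sharp logistic
(scale 0.8 m) in scorch height (`0.1483·I^(2/3)`) versus crown base
height, times a bark survival factor (e-folding 3 cm): what protects a
stand is above all being *tall*.  The fraction of the cell burned is
`min(years-since-fire/10, 1)` — fine fuels take a decade to rebuild — and
all pool effects scale with it.  Killed live carbon moves to the matching
dead pools except for an emitted fraction of fine material; consumed dead
fuel leaves as emission; grass shoots are mostly consumed, roots survive.

**Management policies.**  Suppression (from 1941) contains every potential
natural fire unless it exceeds 45 % of the severity thresholds
0.51 m s⁻¹ ROS / 3.1 MW m⁻¹ FLI / 0.68 MW m⁻² ERC.  With this fuel and
wind parameterization, surface fires are slow but intense, so the default
escape rule is *all three* thresholds (configurable to *any*): under
"any" every fire escapes through one gate or another and the policy does
nothing.  Prescribed fire sets a September-15 burn every 11 years from
2001 with a fixed 20 % live-tree kill, full grass top-kill and burn
fraction 1, and vetoes all natural ignitions.

**Phases.**  Equilibrium runs averaged 1895–1950 climate with scheduled
fires at fixed return intervals (10 yr grassland, 30 yr wooded; the first
after a ~100-yr establishment window) until the passive soil pool changes
less than 1 g C m⁻² per century, capped at 3000 yr (the cap binds on the
wettest cells of the full grid; single-cell runs converge in ≈2000–2600
yr).  Spinup loops a detrended 1895–2008 series ten times (1140 yr) with
dynamic fire; the default run ends with |grid-mean NBP| < 1 g C m⁻² yr⁻¹
over the final cycle.  Historical (1895–2008) and future (2001–2100) runs
are transient; futures apply the evergreen-needleleaf constraint and
delta-method anomalies — temperature added, precipitation and vapor
pressure multiplied after capping ratios at five, bilinearly interpolated
from the coarse anomaly lattice onto the cell grid over the 1971–2000
baseline means.

## The ecotone mechanism and its calibration

Two ingredients create the bistable forest/grassland landscape:

1. **Tree establishment is a bottleneck.**  The tree light scalar is a
   Beer-law saturating function of own LAI raised to the 1.25 power, and
   tree production is further damped by `exp(−0.012 · grass-root C ·
   open-canopy fraction)`.  Sparse seedling cohorts facing an intact grass
   sod (roots survive fire, so burns do not clear the competition) grow
   very slowly for decades, then accelerate: bare ground reaches woodland
   biomass only after roughly half a century without fire.
2. **Fire resets establishment but spares mature stands.**  In
   grass-dominated cells, fires are fast and intense and crown any young
   trees; in forest cells they are slow surface fires whose scorch height
   straddles the crown-base-height gradient.

The equilibrium phase initializes each cell's vegetation type from a
climatic moisture index (annual precipitation over annual PET, ramping
from grassland below 0.37 to woodland above 0.43), standing in for the
Holocene history that put forest on the cool-wet side; the fire regime
then keeps every cell on the attractor its climate supports.  Under
natural fire the warm-dry cells burn every ~8–15 years (drought-year FFMC
exceedances) and stay grassland; the cool-wet cells burn about 0–3 times
per century and carry self-maintaining forest; the boundary between them
is one cell wide.  Without fire the whole gradient converges to forest,
and tree carbon then correlates almost perfectly (negatively) with
temperature and (positively) with precipitation, because nothing but
climate shapes it.

The single calibrated rate is maximum tree NPP, bisected so that the
coolest-wettest cell run without fire through equilibrium, spinup and the
historical period reaches the old-unburned-forest target band of
7500–9000 g C m⁻² aboveground live tree carbon (default 172 g C m⁻²
month⁻¹, landing near 8250).

## Synthetic climate

The generator replaces the observational archives with fields that carry
the statistical structure the analysis needs — it makes no attempt to
reproduce real weather sequences.  Mean annual temperature and
precipitation vary linearly along the NW→SE diagonal (defaults 6.0→9.2 °C
and 58→38 cm yr⁻¹, bracketing the 7.6 °C / 48.5 cm ecotone boundary);
monthly fractions put half the annual precipitation in May–July; the
seasonal temperature cycle has a 15 °C half-range with a larger summer
diurnal range.  Interannual variability is region-wide: a lognormal
annual precipitation multiplier (σ = 0.18), lognormal month-scale noise
(σ = 0.25), and an AR(1) temperature anomaly (sd 0.7 °C, ρ = 0.5), plus
two scheduled severe droughts (1933–38 at 55 % precipitation, +1.2 °C;
1953–57 at 60 %) that anchor the fire history the way the 1930s and 1950s
droughts do in the observed record.  Vapor pressure is generated from a
seasonal relative-humidity target (72 % winter, 52 % summer) evaluated at
the *domain-mean* temperature and scaled by the precipitation multiplier
to the 0.35 power — so the warm-dry corner is also the low-humidity
corner, and dry years are dry in the atmosphere as well as the soil.
That coupling, not any fire-parameter difference, is what makes fire
frequency rise along the gradient.

Future trajectories are monthly anomaly series on a 2×2 coarse lattice:
a common warming ramp to +1.2 °C at 2040, then style-specific divergence
to +2.8 °C (wetter-warm, precipitation ×1.18), +5.8 °C (hot-flat-precip,
precipitation ×1.0; the 2090s decadal mean exceeds +5 °C), and +6.8 °C
(hottest-driest, ×0.72) at 2100.  Vapor-pressure ratios grow with warming
at per-style rates below the saturation-curve slope, so relative humidity
declines modestly under every style and most under the hottest-driest
one.  On top of the smooth trends ride historical-like interannual
variability and large month-scale precipitation-ratio noise (lognormal
σ = 0.45): single-month anomaly ratios from a coarse climate model are
individually erratic, which is exactly why the downscaling caps them at
five.  Without this variability the future runs produce almost no
ignitions and the fire-frequency signal disappears.

The CO2 path rises monotonically from 294 ppm (1895) through 370 (2000)
to 856 ppm (2100); a flat effects-off variant holds the 350 ppm
reference.

## What the synthetic data do and do not show

Passing tests on this generator demonstrate the *mechanism*: that the
coupled fire-vegetation dynamics produce a sharp, fire-maintained ecotone
with the right sensitivities (fire frequency rising along the dryness
gradient and under every warming trajectory, mature forests persisting,
grasslands not invading without suppression).  They do not validate the
model against real landscapes: the synthetic gradient is noiseless in
space, so climate–biomass correlations are near ±1 rather than the ±0.9
of heterogeneous terrain; there is no topography, no spatial fire spread,
no wind variability, and the pseudo-daily interpolation smears rain over
whole months, which inflates the absolute count of high-BUI days (their
trends and ordering across scenarios are meaningful, their level is not).
Class-area percentages depend on where the synthetic gradient is cut and
should not be compared to observed tables.

## Numerical choices and degenerate inputs

Monthly biogeochemistry, daily fire, 365-day calendar.  All state is
float64; runs are bit-reproducible for a given configuration and seed
(the simulator itself draws no random numbers; only the generator does).
Establishment floors (1 g C m⁻² tree leaf, 2 g C m⁻² grass shoot) keep a
propagule pool so vegetation can recover after fire; the floor inflow is
booked as an input in the carbon balance.  Pool updates clamp at zero;
burn fractions require at least one year since the last fire (a cell
cannot reburn within its fire year); frozen months have zero production,
zero decomposition and zero evaporative demand.  Degenerate climates
(permanently frozen) equilibrate to bare cells at the propagule floors.
Suppressed ignitions still consume the cell's single annual ignition
slot.  Scenario runs on the default 12×12 grid complete in minutes on one
CPU; the test suite uses that grid for the integration checks and smaller
grids (2×2–6×6) elsewhere.

## Known limitations

No nitrogen or phosphorus cycling; no individual-tree demography, bark
beetles, or drought mortality (drought only reduces production); no
deciduous-broadleaf dynamics (the lifeform mix is reported, but
production uses the evergreen parameter set and future runs force the
evergreen constraint); no cell-to-cell fire spread; one fire per
cell-year at most.  The equilibrium-phase initialization from a moisture
index means the *location* of the ecotone partly reflects that index's
ramp; the dynamics determine whether each side is stable, which is the
property the analyses rely on.
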