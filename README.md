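# vegfire

A desk-scale dynamic vegetation model of a fire-maintained prairie–woodland
ecotone, for ecologists and fire managers who want to experiment with the
mechanism rather than run a full-size DGVM: a lattice of independent cells,
each simulating competition between an evergreen needleleaf tree type
(ponderosa-pine-like) and C3/C4 grasses with CENTURY-style carbon
biogeochemistry, mechanistic wildfire (Canadian FWI System danger codes,
Rothermel surface spread, Van Wagner crown-fire initiation), and
delta-method climate downscaling for 21st-century scenarios under
natural-fire, fire-suppression, and prescribed-fire management.

The core state of each cell is its carbon-pool vector **C** (tree leaf,
branch, wood, roots; grass shoot/root; 1-h…1000-h dead fuels; three soil
pools).  Monthly production is

&nbsp;&nbsp;&nbsp;&nbsp;NPP = NPPmax · f(T) · g(W/PET) · h(CO₂) · ℓ(LAI) · c(grass),

fire danger follows the FWI codes from pseudo-daily weather, ignition is
deterministic (first day with spread rate > 0, FFMC > 90.4, BUI > 80),
fireline intensity is Byram's I = H·w·R, crown fire initiates at
I ≥ (0.01·CBH·(460+25.9·FMC))^1.5, and the burned cell fraction is
min(years-since-fire/10, 1).  Tall trees survive surface fire (scorch
height 0.1483·I^⅔ versus crown base height); young trees do not — which is
the whole story of the ecotone.  Details and all parameter defaults are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
>>> import vegfire as vf
>>> from vegfire.simulator import Simulator
>>> clim, soils = vf.generate_grid(vf.SyntheticConfig(nx=6, ny=6, seed=0))
>>> sim = Simulator(clim, soils, scenario=vf.ScenarioConfig())
>>> state, _ = sim.run_equilibrium()
>>> state, info = sim.run_spinup(state, vf.detrend_for_spinup(clim), "natural")
>>> vf.vegetation_fractions(state.veg_class)
{'grassland': 8.33..., 'shrubland': 0.0, 'woodland': 0.0, 'forest': 91.66...}
```

After the 1140-year spinup with dynamic fire, the warm-dry corner of the
gradient is grassland (fires every ~8–15 years keep trees from
establishing) and the cool-wet side carries forest with ~0–3 fires per
century — a sharp boundary one cell wide.  Re-running `run_spinup` with
`fire_mode="none"` turns the entire grid to forest: fire, not climate,
draws the line.  The `examples/` scripts walk through each capability:

| script | what it shows |
|---|---|
| `synthetic_climate.py` | the climate gradient, seasonality, droughts |
| `fire_weather.py` | FWI codes through a drought year; the ignition window |
| `ecotone_spinup.py` | natural-fire vs no-fire spinup maps |
| `future_scenarios.py` | 2001–2100 ignition rise; forest persistence |
| `co2_effects.py` | CO₂ production/transpiration scalars |

A thin CLI wraps the same workflows:
`vegfire generate`, `vegfire run --fire-mode natural --style hottest-driest`,
`vegfire report`.

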