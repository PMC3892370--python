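"""Phase orchestration: equilibrium, spinup, historical and future runs.

Cells are simulated independently but advanced together as flat arrays; the
biogeochemistry runs on a monthly step and the fire subsystem on a daily
step inside each month, using pseudo-daily weather interpolated from the
monthly inputs.  Fire-weather codes are started each year in the first
snow-free month and the whole chain is deterministic: a given configuration
and seed reproduce outputs bit-for-bit.

Phases:

* equilibrium -- averaged monthly climate, fixed class-dependent fire
  return intervals, run until the passive soil pool converges (or a year
  cap is reached);
* spinup -- a detrended historical series looped (default 10 x 114 yr)
  with dynamic fire, to quasi-equilibrium in net biome production;
* historical -- transient climate; under the suppression policy natural
  fire runs through the year before the suppression start year;
* future -- downscaled anomaly climate with the evergreen constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import biogeochem as bgc
from . import fire as fire_mod
from . import fwi
from .biogeography import VegClass, classify_vegetation, lifeform_mix
from .climate import (ClimateSmoother, MONTH_LENGTHS, derive_humidity,
                      pseudo_daily_year)
from .fire import FireEvent
from .params import ModelParams, ScenarioConfig

__all__ = ["GridState", "RunOutput", "Simulator", "calibrate_max_tree_npp"]

_DAY0 = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)[:-1]])  # first doy per month

#: Reference dry dead-fuel moistures for equilibrium-phase scheduled fires.
_EQ_MOISTURES = {"1h": 0.07, "10h": 0.09, "100h": 0.14, "1000h": 0.20}

#: Establishment floors, g C m^-2: seed/resprout inflow keeps a minimal
#: propagule pool so vegetation can recover after fire.
_MIN_TREE_LEAF = 1.0
_MIN_GRASS_SHOOT = 2.0


@dataclass
class GridState:
    """State of all cells: carbon pools, water, fire memory, smoothed climate."""

    pools: dict
    sw1: np.ndarray
    sw2: np.ndarray
    years_since_fire: np.ndarray
    smooth_min_temp: np.ndarray | None = None
    smooth_gs_precip: np.ndarray | None = None
    veg_class: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.pools["tree_leaf"].size

    def total_carbon(self) -> np.ndarray:
        return sum(self.pools[p] for p in bgc.ALL_POOLS)

    def copy(self) -> "GridState":
        return GridState(
            pools={k: v.copy() for k, v in self.pools.items()},
            sw1=self.sw1.copy(), sw2=self.sw2.copy(),
            years_since_fire=self.years_since_fire.copy(),
            smooth_min_temp=None if self.smooth_min_temp is None else self.smooth_min_temp.copy(),
            smooth_gs_precip=None if self.smooth_gs_precip is None else self.smooth_gs_precip.copy(),
            veg_class=None if self.veg_class is None else self.veg_class.copy(),
        )

    @classmethod
    def initial(cls, n: int, woody_weight=1.0) -> "GridState":
        """Starting state for the equilibrium phase.

        ``woody_weight`` in [0, 1] sets the initial vegetation type per
        cell: 1 starts a cell as young woodland, 0 as grassland.  The
        equilibrium phase derives it from a climatic moisture index (the
        standard way a vegetation type is initialized before the carbon
        pools are equilibrated); the fire regime then maintains each cell
        on the attractor its climate supports.
        """
        w = np.broadcast_to(np.asarray(woody_weight, float), (n,))
        pools = {p: np.zeros(n) for p in bgc.ALL_POOLS}
        pools.update({
            "tree_leaf": np.maximum(150.0 * w, _MIN_TREE_LEAF),
            "tree_fine_branch": 450.0 * w,
            "tree_large_wood": 1500.0 * w,
            "tree_fine_root": 100.0 * w,
            "tree_coarse_root": 150.0 * w,
            "grass_shoot": 30.0 + 50.0 * (1.0 - w),
            "grass_root": 60.0 + 100.0 * (1.0 - w),
            "litter_1h": np.full(n, 50.0),
            "soil_active": np.full(n, 200.0),
            "soil_slow": np.full(n, 1000.0),
        })
        # the first scheduled equilibrium fire arrives only after stands
        # have had decades to approach their climatic steady state, so the
        # crown-fire test probes mature rather than juvenile geometry
        return cls(pools=pools, sw1=np.zeros(n), sw2=np.zeros(n),
                   years_since_fire=np.full(n, -70.0),
                   veg_class=np.where(w > 0.3, 2, 0).astype(np.int8))


@dataclass
class RunOutput:
    """Per-cell annual outputs of one phase."""

    years: np.ndarray
    shape: tuple                      # (ny, nx)
    tree_c: np.ndarray                # live aboveground tree C, (nyr, n)
    grass_c: np.ndarray               # live shoot C, (nyr, n)
    npp: np.ndarray                   # g C m^-2 yr^-1
    nbp: np.ndarray
    veg_class: np.ndarray
    bui_days: np.ndarray
    events: list = field(default_factory=list)

    def events_frame(self) -> pd.DataFrame:
        cols = ["year", "doy", "cell", "ros", "fli", "erc", "crown",
                "burn_fraction", "suppressed", "prescribed"]
        if not self.events:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([vars(e) for e in self.events])[cols]

    def fire_counts(self, effective: bool = False) -> np.ndarray:
        """Per-cell fire counts (or summed burned fractions) over the run."""
        out = np.zeros(self.tree_c.shape[1])
        for e in self.events:
            if not e.suppressed:
                out[e.cell] += e.burn_fraction if effective else 1.0
        return out


class Simulator:
    """Runs the model over a climate grid under one parameter set."""

    def __init__(self, climate: xr.Dataset, soils: xr.Dataset,
                 params: ModelParams | None = None,
                 scenario: ScenarioConfig | None = None,
                 lat_deg: float = 43.5):
        self.params = params or ModelParams()
        self.scenario = scenario or ScenarioConfig()
        self.lat_deg = lat_deg
        self.shape = (climate.sizes["y"], climate.sizes["x"])
        self.n = self.shape[0] * self.shape[1]
        self.climate = climate
        depth = soils["depth_cm"].values.ravel()
        awc = soils["awc_per_cm"].values.ravel()
        sp = self.params.soil
        self.cap1 = np.minimum(depth, sp.layer1_depth_cm) * awc
        self.cap2 = np.maximum(depth - sp.layer1_depth_cm, 0.0) * awc

    # -- climate helpers ---------------------------------------------------

    def _flat(self, ds: xr.Dataset) -> dict:
        out = {v: ds[v].values.reshape(ds[v].shape[0], -1) for v in
               ("ppt", "tmax", "tmin", "vpr")}
        out["year"] = ds["year"].values
        return out

    def climatology(self, year_start: int = 1895, year_end: int = 1950) -> dict:
        """Monthly means over a window, flattened to (12, n)."""
        ds = self.climate
        sel = ds.sel(time=(ds["year"] >= year_start) & (ds["year"] <= year_end))
        clim = sel.groupby(sel["month"]).mean("time")
        return {v: clim[v].values.reshape(12, -1) for v in
                ("ppt", "tmax", "tmin", "vpr")}

    # -- monthly biogeochemistry ------------------------------------------

    def _step_month(self, state: GridState, month: int, ppt, tmax, tmin, vpr,
                    co2_prod, co2_transp, grazing: bool) -> dict:
        p = self.params
        tmean = 0.5 * (tmax + tmin)
        rh, vpd = derive_humidity(tmax, tmin, vpr)
        pet = bgc.penman_pet(tmean, vpd, 3.0, month, tmax=tmax, tmin=tmin,
                             lat_deg=self.lat_deg)

        geom = bgc.allometry(state.pools, p.allometry)
        available = ppt + state.sw1 + state.sw2
        ws_tree = bgc.water_scalar(available, pet, p.production, tree=True)
        ws_grass = bgc.water_scalar(available, pet, p.production, tree=False)
        ts_tree = bgc.temperature_scalar(tmean, p.production, tree=True)
        ts_grass = bgc.temperature_scalar(tmean, p.production, tree=False)

        npp_tree = bgc.tree_production(p.production, ts_tree, ws_tree,
                                       co2_prod, geom["lai"],
                                       grass_root=state.pools["grass_root"])
        npp_grass = bgc.grass_production(p.production, ts_grass, ws_grass,
                                         co2_prod, geom["lai"],
                                         state.pools["grass_standing_dead"])

        shoot_npp = p.allocation.grass_alloc["shoot"] * npp_grass
        grazed = bgc.graze(shoot_npp, month, enabled=grazing)
        bgc.allocate_and_turnover(state.pools, npp_tree, npp_grass, p.allocation)
        state.pools["grass_shoot"] = state.pools["grass_shoot"] - grazed

        # establishment / resprout inflow keeps minimal propagule pools
        est = (np.maximum(_MIN_TREE_LEAF - state.pools["tree_leaf"], 0.0)
               + np.maximum(_MIN_GRASS_SHOOT - state.pools["grass_shoot"], 0.0))
        state.pools["tree_leaf"] = np.maximum(state.pools["tree_leaf"], _MIN_TREE_LEAF)
        state.pools["grass_shoot"] = np.maximum(state.pools["grass_shoot"],
                                                _MIN_GRASS_SHOOT)

        moisture_ratio = available / np.maximum(pet, 1e-6)
        rh_flux = bgc.decompose(state.pools, tmean, moisture_ratio,
                                p.decomposition)

        state.sw1, state.sw2, aet, _ = bgc.soil_water_update(
            state.sw1, state.sw2, self.cap1, self.cap2, ppt, pet,
            transp_mult=co2_transp, demand_factor=p.soil.demand_factor)

        return {"npp": npp_tree + npp_grass, "rh": rh_flux, "grazed": grazed,
                "establishment": est, "aet": aet, "pet": pet}

    # -- daily fire loop for one month ------------------------------------

    def _fire_month(self, state, fstate, year: int, month: int, fire_mode: str,
                    daily_t, daily_rh, daily_rain, events, burned_mask):
        p = self.params.fire
        grass_dom = state.veg_class <= VegClass.SHRUBLAND
        wind_ms = np.where(grass_dom, p.wind_grass, p.wind_forest)
        wind_kmh = wind_ms * 3.6
        fuels = fire_mod.fuel_loads(state.pools, p)
        geom = bgc.allometry(state.pools, self.params.allometry)

        suppress_active = (fire_mode == "suppression"
                           and year >= self.scenario.suppression_start_year)
        allow_natural = fire_mode in ("natural", "suppression")

        d0 = _DAY0[month - 1]
        for d in range(MONTH_LENGTHS[month - 1]):
            doy = d0 + d
            active = fstate["startup_day"] <= doy
            if not active.any():
                continue
            ffmc = fwi.ffmc_update(fstate["ffmc"], daily_t[doy], daily_rh[doy],
                                   wind_kmh, daily_rain[doy])
            dmc = fwi.dmc_update(fstate["dmc"], daily_t[doy], daily_rh[doy],
                                 daily_rain[doy], month)
            dc = fwi.dc_update(fstate["dc"], daily_t[doy], daily_rain[doy], month)
            fstate["ffmc"] = np.where(active, ffmc, fstate["ffmc"])
            fstate["dmc"] = np.where(active, dmc, fstate["dmc"])
            fstate["dc"] = np.where(active, dc, fstate["dc"])
            bui_val = fwi.bui(fstate["dmc"], fstate["dc"])
            fstate["bui_days"] += (active & (bui_val > p.bui_threshold))

            if not allow_natural:
                continue
            cand = (active & ~fstate["fire_done"]
                    & (fstate["ffmc"] > p.ffmc_threshold)
                    & (bui_val > p.bui_threshold))
            if not cand.any():
                continue
            moist = fwi.fuel_moistures(fstate["ffmc"], fstate["dmc"], fstate["dc"])
            ros, fli, erc = fire_mod.fire_behavior(fuels, moist, grass_dom, p)
            ignite = fire_mod.ignition_test(ros, fstate["ffmc"], bui_val,
                                            fstate["fire_done"], p) & cand
            if not ignite.any():
                continue
            fstate["fire_done"] |= ignite
            suppressed = np.zeros(self.n, bool)
            if suppress_active:
                suppressed = fire_mod.suppression_policy(ros, fli, erc, p)
            burn = ignite & ~suppressed
            crown = fire_mod.crown_fire_test(fli, geom["cbh"],
                                             p.foliar_moisture_pct) & burn
            bf = np.where(burn,
                          fire_mod.burn_fraction(
                              np.maximum(state.years_since_fire, 1.0),
                              p.burn_fraction_ramp_years),
                          0.0)
            res = fire_mod.fire_effects(state.pools, fli, crown, bf,
                                        cbh=geom["cbh"], bark_cm=geom["bark_cm"],
                                        params=p)
            fstate["emissions"] += res["emissions"]
            burned_mask |= burn
            for i in np.nonzero(ignite)[0]:
                events.append(FireEvent(
                    year=year, doy=int(doy + 1), cell=int(i),
                    ros=float(ros[i]), fli=float(fli[i]), erc=float(erc[i]),
                    crown=bool(crown[i]), burn_fraction=float(bf[i]),
                    suppressed=bool(suppressed[i])))
            # fuels change after a burn
            fuels = fire_mod.fuel_loads(state.pools, p)
            geom = bgc.allometry(state.pools, self.params.allometry)

    # -- one simulated year -------------------------------------------------

    def _run_year(self, state: GridState, year: int, monthly: dict,
                  edge_prev: dict, edge_next: dict, co2_ppm: float,
                  fire_mode: str, smoother: ClimateSmoother,
                  grazing: bool, evergreen_constraint: bool,
                  events: list | None = None) -> dict:
        """Advance the grid one year; returns annual fluxes and diagnostics."""
        p = self.params
        co2_prod, co2_transp = bgc.co2_scalars(
            co2_ppm, p.production, effects_on=self.scenario.co2_effects)

        run_fire = fire_mode != "none"
        fstate = None
        daily_t = daily_rh = daily_rain = None
        if run_fire:
            tmean_m = 0.5 * (monthly["tmax"] + monthly["tmin"])
            warm = tmean_m > p.fire.snow_free_tmean
            first_warm = np.argmax(warm, axis=0)
            has_warm = warm.any(axis=0)
            startup_day = np.where(has_warm, _DAY0[first_warm], 10_000)
            rh_m = np.stack([derive_humidity(monthly["tmax"][m], monthly["tmin"][m],
                                             monthly["vpr"][m])[0]
                             for m in range(12)])
            rh_prev, _ = derive_humidity(edge_prev["tmax"], edge_prev["tmin"],
                                         edge_prev["vpr"])
            rh_next, _ = derive_humidity(edge_next["tmax"], edge_next["tmin"],
                                         edge_next["vpr"])
            daily_t = pseudo_daily_year(monthly["tmax"], edge_prev["tmax"],
                                        edge_next["tmax"])
            daily_rh = np.clip(pseudo_daily_year(rh_m, rh_prev, rh_next), 1.0, 100.0)
            # precip anchors are daily rates (cm d^-1); the interpolated
            # series is rescaled so each month's sum equals its total
            daily_rain = pseudo_daily_year(
                monthly["ppt"] / MONTH_LENGTHS[:, None],
                edge_prev["ppt"] / MONTH_LENGTHS[11],
                edge_next["ppt"] / MONTH_LENGTHS[0],
                conserve_total=True) * 10.0  # mm d^-1
            fstate = {
                "ffmc": np.full(self.n, p.fire.ffmc_start),
                "dmc": np.full(self.n, p.fire.dmc_start),
                "dc": np.full(self.n, p.fire.dc_start),
                "fire_done": np.zeros(self.n, bool),
                "bui_days": np.zeros(self.n, int),
                "emissions": np.zeros(self.n),
                "startup_day": startup_day,
            }

        if events is None:
            events = []
        burned_mask = np.zeros(self.n, bool)
        totals = {k: np.zeros(self.n) for k in ("npp", "rh", "grazed",
                                                "establishment")}
        for m in range(1, 13):
            fx = self._step_month(state, m, monthly["ppt"][m - 1],
                                  monthly["tmax"][m - 1], monthly["tmin"][m - 1],
                                  monthly["vpr"][m - 1], co2_prod, co2_transp,
                                  grazing)
            for k in totals:
                totals[k] += fx[k]
            if run_fire:
                self._fire_month(state, fstate, year, m, fire_mode,
                                 daily_t, daily_rh, daily_rain, events,
                                 burned_mask)

        # prescribed burns: September 15 of event years, natural fire vetoed
        if fire_mode == "prescribed" and (
                year >= p.fire.prescribed_start_year
                and (year - p.fire.prescribed_start_year)
                % p.fire.prescribed_interval_years == 0):
            geom = bgc.allometry(state.pools, p.allometry)
            res = fire_mod.fire_effects(
                state.pools, 0.0, np.zeros(self.n, bool), np.ones(self.n),
                cbh=geom["cbh"], bark_cm=geom["bark_cm"], params=p.fire,
                tree_mortality_override=p.fire.prescribed_tree_mortality,
                grass_consumption=1.0)
            emissions = res["emissions"] + (fstate["emissions"] if run_fire
                                            else np.zeros(self.n))
            burned_mask |= True
            events.append(FireEvent(year=year, doy=258 + 1, cell=-1, ros=0.0,
                                    fli=0.0, erc=0.0, crown=False,
                                    burn_fraction=1.0, prescribed=True))
        else:
            emissions = fstate["emissions"] if run_fire else np.zeros(self.n)

        # annual biogeography update
        smin, sgsp = smoother.update(monthly["tmin"], monthly["ppt"])
        state.smooth_min_temp, state.smooth_gs_precip = smin, sgsp
        gs_temp = 0.5 * (monthly["tmax"][3:9] + monthly["tmin"][3:9]).mean(axis=0)
        mix = lifeform_mix(smin, sgsp, p.biogeography,
                           evergreen_constraint=evergreen_constraint,
                           gs_temp=gs_temp)
        tree_c = bgc.aboveground_tree_c(state.pools)
        state.veg_class = classify_vegetation(tree_c, p.biogeography)
        state.years_since_fire = np.where(burned_mask, 1.0,
                                          state.years_since_fire + 1.0)

        return {
            "npp": totals["npp"], "rh": totals["rh"], "grazed": totals["grazed"],
            "establishment": totals["establishment"],
            "fire_emissions": emissions,
            "nbp": totals["npp"] + totals["establishment"] - totals["rh"]
                   - totals["grazed"] - emissions,
            "tree_c": tree_c, "grass_c": state.pools["grass_shoot"].copy(),
            "bui_days": fstate["bui_days"].copy() if run_fire else np.zeros(self.n, int),
            "mix": mix, "events": events, "burned": burned_mask,
        }

    # -- phases -------------------------------------------------------------

    def run_equilibrium(self, state: GridState | None = None,
                        clim_year_start: int = 1895,
                        clim_year_end: int = 1950) -> tuple:
        """Equilibrate carbon pools under averaged climate and fixed FRIs.

        Iterates years of mean monthly climate with scheduled fires at the
        class-dependent fire return interval until the passive soil pool
        changes less than the tolerance per century (or the year cap).
        Returns ``(state, info)`` with ``info['converged']``.
        """
        sc = self.scenario
        monthly = self.climatology(clim_year_start, clim_year_end)
        if state is None:
            state = GridState.initial(self.n, self._initial_woody_weight(monthly))
        edge_prev = {v: monthly[v][11] for v in ("ppt", "tmax", "tmin", "vpr")}
        edge_next = {v: monthly[v][0] for v in ("ppt", "tmax", "tmin", "vpr")}
        smoother = ClimateSmoother(self.params.biogeography.smoothing_efold_years)
        co2 = sc.co2_ppm_1895
        pf = self.params.fire

        passive_checkpoint = state.pools["soil_passive"].copy()
        converged = False
        years_run = 0
        for yr in range(sc.equilibrium_max_years):
            self._run_year(state, 0, monthly, edge_prev, edge_next, co2,
                           "none", smoother, grazing=sc.grazing,
                           evergreen_constraint=sc.evergreen_constraint)
            # scheduled fire at the fixed class FRI
            fri = np.where(state.veg_class <= VegClass.SHRUBLAND,
                           pf.fri_grassland, pf.fri_wooded)
            due = state.years_since_fire >= fri
            if due.any():
                fuels = fire_mod.fuel_loads(state.pools, pf)
                geom = bgc.allometry(state.pools, self.params.allometry)
                grass_dom = state.veg_class <= VegClass.SHRUBLAND
                ros, fli, erc = fire_mod.fire_behavior(fuels, _EQ_MOISTURES,
                                                       grass_dom, pf)
                crown = fire_mod.crown_fire_test(fli, geom["cbh"],
                                                 pf.foliar_moisture_pct) & due
                bf = np.where(due, 1.0, 0.0)
                fire_mod.fire_effects(state.pools, fli, crown, bf,
                                      cbh=geom["cbh"], bark_cm=geom["bark_cm"],
                                      params=pf)
                state.years_since_fire = np.where(due, 1.0,
                                                  state.years_since_fire)
            years_run += 1
            if years_run % 100 == 0:
                delta = np.max(np.abs(state.pools["soil_passive"]
                                      - passive_checkpoint))
                passive_checkpoint = state.pools["soil_passive"].copy()
                if delta < sc.equilibrium_tol:
                    converged = True
                    break
        return state, {"converged": converged, "years": years_run}

    def _initial_woody_weight(self, monthly: dict) -> np.ndarray:
        """Initial woodland fraction from the climatic moisture index.

        Annual precipitation over annual PET (a standard aridity index)
        ramps the initial type from pure grassland below ``init_aridity_lo``
        to young woodland above ``init_aridity_hi``.
        """
        p = self.params.biogeography
        ppt = np.sum(monthly["ppt"], axis=0)
        pet = np.zeros(self.n)
        for m in range(1, 13):
            tmax = monthly["tmax"][m - 1]
            tmin = monthly["tmin"][m - 1]
            _, vpd = derive_humidity(tmax, tmin, monthly["vpr"][m - 1])
            pet += bgc.penman_pet(0.5 * (tmax + tmin), vpd, 3.0, m,
                                  tmax=tmax, tmin=tmin, lat_deg=self.lat_deg)
        ai = ppt / np.maximum(pet, 1e-6)
        return np.clip((ai - p.init_aridity_lo)
                       / (p.init_aridity_hi - p.init_aridity_lo), 0.0, 1.0)

    def _year_arrays(self, flat: dict, iy: int, nyr: int) -> tuple:
        sl = slice(iy * 12, (iy + 1) * 12)
        monthly = {v: flat[v][sl] for v in ("ppt", "tmax", "tmin", "vpr")}
        if iy > 0:
            edge_prev = {v: flat[v][iy * 12 - 1] for v in monthly}
        else:
            edge_prev = {v: monthly[v][0] for v in monthly}
        if iy < nyr - 1:
            edge_next = {v: flat[v][(iy + 1) * 12] for v in monthly}
        else:
            edge_next = {v: monthly[v][11] for v in monthly}
        return monthly, edge_prev, edge_next

    def run_spinup(self, state: GridState, detrended: xr.Dataset,
                   fire_mode: str = "natural") -> tuple:
        """Loop the detrended series to quasi-equilibrium in NBP.

        Returns ``(state, info)`` where ``info['final_cycle_nbp']`` is the
        grid-mean annual NBP over the last cycle.
        """
        sc = self.scenario
        flat = self._flat(detrended)
        years = np.unique(flat["year"])
        nyr = len(years)
        smoother = ClimateSmoother(self.params.biogeography.smoothing_efold_years)
        co2 = sc.co2_ppm_1895
        nbp_last = []
        for cycle in range(sc.spinup_cycles):
            for iy, year in enumerate(years):
                monthly, ep, en = self._year_arrays(flat, iy, nyr)
                out = self._run_year(state, int(year), monthly, ep, en, co2,
                                     fire_mode, smoother, grazing=sc.grazing,
                                     evergreen_constraint=sc.evergreen_constraint)
                if cycle == sc.spinup_cycles - 1:
                    nbp_last.append(out["nbp"].mean())
        info = {"final_cycle_nbp": float(np.mean(nbp_last)),
                "quasi_equilibrium": abs(float(np.mean(nbp_last)))
                < sc.nbp_tolerance}
        return state, info

    def _run_transient(self, state: GridState, climate: xr.Dataset,
                       fire_mode: str, co2_series: pd.Series,
                       grazing: bool) -> RunOutput:
        flat = self._flat(climate)
        years = np.unique(flat["year"])
        nyr = len(years)
        smoother = ClimateSmoother(self.params.biogeography.smoothing_efold_years)
        out = RunOutput(
            years=years, shape=self.shape,
            tree_c=np.zeros((nyr, self.n)), grass_c=np.zeros((nyr, self.n)),
            npp=np.zeros((nyr, self.n)), nbp=np.zeros((nyr, self.n)),
            veg_class=np.zeros((nyr, self.n), np.int8),
            bui_days=np.zeros((nyr, self.n), int))
        for iy, year in enumerate(years):
            monthly, ep, en = self._year_arrays(flat, iy, nyr)
            co2 = float(co2_series.loc[int(year)]) if co2_series is not None \
                else self.scenario.co2_ppm_1895
            res = self._run_year(state, int(year), monthly, ep, en, co2,
                                 fire_mode, smoother, grazing=grazing,
                                 evergreen_constraint=self.scenario.evergreen_constraint,
                                 events=out.events)
            out.tree_c[iy] = res["tree_c"]
            out.grass_c[iy] = res["grass_c"]
            out.npp[iy] = res["npp"]
            out.nbp[iy] = res["nbp"]
            out.veg_class[iy] = state.veg_class
            out.bui_days[iy] = res["bui_days"]
        return out

    def run_historical(self, state: GridState, fire_mode: str = "natural",
                       co2_series: pd.Series | None = None) -> RunOutput:
        """Transient 1895-2008 run (suppression switches on at its start year)."""
        return self._run_transient(state, self.climate, fire_mode, co2_series,
                                   grazing=self.scenario.grazing)

    def run_future(self, state: GridState, future_climate: xr.Dataset,
                   fire_mode: str = "natural",
                   co2_series: pd.Series | None = None) -> RunOutput:
        """2001-2100 run under a management scenario (evergreen constraint on)."""
        return self._run_transient(state, future_climate, fire_mode, co2_series,
                                   grazing=self.scenario.grazing)


def calibrate_max_tree_npp(make_sim, target: float = 8250.0,
                           lo: float = 40.0, hi: float = 220.0,
                           tol: float = 150.0, max_iter: int = 12) -> float:
    """Calibrate the maximum tree NPP against the old-forest carbon target.

    ``make_sim(max_tree_npp)`` must run the no-fire protocol on a cool-wet
    cell and return year-2000 aboveground live tree carbon (g C m^-2).
    Bisects until within ``tol`` of the target (default: the middle of the
    7500-9000 g C m^-2 old-unburned-forest band).  Returns the calibrated
    rate (g C m^-2 month^-1).
    """
    f_lo, f_hi = make_sim(lo), make_sim(hi)
    if not (f_lo < target < f_hi):
        raise ValueError(
            f"target {target} not bracketed: f({lo})={f_lo:.0f}, f({hi})={f_hi:.0f}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = make_sim(mid)
        if abs(f_mid - target) < tol:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
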