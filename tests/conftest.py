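"""Shared fixtures.

The heavy fixture here is ``pipeline``: one complete run of the default
protocol (equilibrium, both spinups, the three historical management modes,
and the natural-fire futures) on the default synthetic grid, computed once
per session and shared by the integration and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import vegfire as vf

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from vegfire.climate import baseline_means, downscale_anomaly
from vegfire.simulator import Simulator

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def default_grid():
    """Default synthetic climate and soils (seed 0)."""
    return vf.generate_grid(vf.SyntheticConfig())


@pytest.fixture(scope="session")
def small_grid():
    """A cheap 3x3 grid for unit-level runs."""
    cfg = vf.SyntheticConfig(nx=3, ny=3, seed=1)
    return vf.generate_grid(cfg), cfg


@pytest.fixture(scope="session")
def co2_path():
    return vf.generate_co2_path()


@pytest.fixture(scope="session")
def pipeline(default_grid, co2_path):
    """Full default-protocol run shared across integration tests."""
    clim, soils = default_grid
    det = vf.detrend_for_spinup(clim)
    sc = vf.ScenarioConfig()
    sim = Simulator(clim, soils, scenario=sc)

    st_eq, eq_info = sim.run_equilibrium()
    st_nat, nat_info = sim.run_spinup(st_eq.copy(), det, fire_mode="natural")
    st_nf, nf_info = sim.run_spinup(st_eq.copy(), det, fire_mode="none")

    hist_nat = sim.run_historical(st_nat.copy(), "natural", co2_path)
    hist_sup = sim.run_historical(st_nat.copy(), "suppression", co2_path)
    hist_nf = sim.run_historical(st_nf.copy(), "none", co2_path)

    # state at end of 2000 for the future phase
    clim2000 = clim.sel(time=clim.year <= 2000)
    st_2000 = st_nat.copy()
    Simulator(clim2000, soils, scenario=sc).run_historical(st_2000, "natural",
                                                           co2_path)
    base = baseline_means(clim)
    futures = {}
    for style in ("wetter-warm", "hot-flat-precip", "hottest-driest"):
        anoms = vf.generate_future_anomalies(style)
        fut_clim = downscale_anomaly(anoms, base)
        fsim = Simulator(fut_clim, soils, scenario=sc)
        futures[style] = fsim.run_future(st_2000.copy(), fut_clim,
                                         "natural", co2_path)

    return {
        "climate": clim, "soils": soils, "detrended": det, "scenario": sc,
        "sim": sim, "eq": st_eq, "eq_info": eq_info,
        "nat": st_nat, "nat_info": nat_info,
        "nf": st_nf, "nf_info": nf_info,
        "hist_nat": hist_nat, "hist_sup": hist_sup, "hist_nf": hist_nf,
        "state_2000": st_2000, "futures": futures,
    }


def aboveground(state):
    return (state.pools["tree_leaf"] + state.pools["tree_fine_branch"]
            + state.pools["tree_large_wood"])


@pytest.fixture(scope="session")
def nw_cell_protocol(default_grid, co2_path):
    """No-fire protocol on the coolest-wettest cell of the default grid."""
    clim, soils = default_grid
    tmean = (0.5 * (clim.tmax + clim.tmin)).mean("time")
    iy, ix = np.unravel_index(int(tmean.values.argmin()), tmean.shape)
    cell_clim = clim.isel(y=[iy], x=[ix])
    cell_soil = soils.isel(y=[iy], x=[ix])
    det = vf.detrend_for_spinup(cell_clim)
    sc = vf.ScenarioConfig(fire_mode="none")
    sim = Simulator(cell_clim, cell_soil, scenario=sc)
    st, eq_info = sim.run_equilibrium()
    st, sp_info = sim.run_spinup(st, det, fire_mode="none")
    out = sim.run_historical(st, fire_mode="none", co2_series=co2_path)
    return {"out": out, "eq_info": eq_info, "spinup_info": sp_info,
            "cell": (iy, ix)}
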