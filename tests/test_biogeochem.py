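"""Carbon/water process functions: PET, scalars, allocation, decay, allometry."""

import numpy as np
import pytest

from vegfire import biogeochem as bgc
from vegfire.params import (AllocationParams, AllometryParams,
                            DecompositionParams, ProductionParams)


class TestPenmanPET:
    def test_zero_vpd_and_radiation_gives_zero(self):
        pet = bgc.penman_pet(15.0, 0.0, 3.0, 6, rn=0.0)
        assert pet == pytest.approx(0.0, abs=1e-9)

    def test_increases_with_temperature_at_fixed_rh(self):
        from vegfire.climate import saturation_vapor_pressure
        temps = np.arange(5.0, 30.0, 5.0)
        pets = []
        for t in temps:
            vpd = saturation_vapor_pressure(t) * 0.4  # RH 60%
            pets.append(float(bgc.penman_pet(t, vpd, 3.0, 7,
                                             tmax=t + 6, tmin=t - 6)))
        assert np.all(np.diff(pets) > 0)

    def test_matches_independent_combination_equation(self):
        """Reference month: 15 degC, RH 60%, wind 3 m/s, fixed radiation."""
        t, rn, u = 15.0, 10.0, 3.0
        from vegfire.climate import saturation_vapor_pressure
        es_pa = saturation_vapor_pressure(t)
        vpd_pa = es_pa * 0.4
        got = float(bgc.penman_pet(t, vpd_pa, u, 6, rn=rn))
        # independent transcription of the combination equation
        es = 0.6108 * np.exp(17.27 * t / (t + 237.3))       # kPa
        delta = 4098.0 * es / (t + 237.3) ** 2
        gamma, lam = 0.066, 2.45
        e_rad = delta / (delta + gamma) * rn / lam
        e_aero = gamma / (delta + gamma) * 6.43 * (1 + 0.536 * u) \
            * (vpd_pa / 1000.0) / lam
        expected = (e_rad + e_aero) * 30 / 10.0            # cm for June
        assert got == pytest.approx(expected, rel=0.01)


class TestWaterScalar:
    def test_saturates_at_one(self):
        p = ProductionParams()
        assert bgc.water_scalar(10.0, 5.0, p, tree=True) == pytest.approx(1.0)

    def test_zero_water_gives_floor(self):
        p = ProductionParams()
        assert bgc.water_scalar(0.0, 5.0, p, tree=True) == pytest.approx(p.water_floor)

    def test_tree_curve_less_steep_than_grass(self):
        p = ProductionParams()
        half = 0.5 * p.water_sat_ratio * 5.0
        tree = bgc.water_scalar(half, 5.0, p, tree=True)
        grass = bgc.water_scalar(half, 5.0, p, tree=False)
        assert tree > grass


class TestCO2Scalars:
    def test_doubling_effects(self):
        p = ProductionParams()
        prod, transp = bgc.co2_scalars(2 * p.co2_ref, p)
        assert prod == pytest.approx(1.15)
        assert transp == pytest.approx(0.75)

    def test_reference_identity(self):
        p = ProductionParams()
        prod, transp = bgc.co2_scalars(p.co2_ref, p)
        assert prod == pytest.approx(1.0)
        assert transp == pytest.approx(1.0)

    def test_effects_off(self):
        p = ProductionParams()
        prod, transp = bgc.co2_scalars(900.0, p, effects_on=False)
        assert prod == 1.0 and transp == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bgc.co2_scalars(-10.0, ProductionParams())


class TestProduction:
    def test_zero_scalar_zeroes_npp(self):
        p = ProductionParams()
        assert bgc.tree_production(p, 0.0, 1.0, 1.0, 2.0) == 0.0
        assert bgc.grass_production(p, 1.0, 0.0, 1.0, 0.0, 0.0) == 0.0

    def test_npp_is_product_of_scalars(self):
        p = ProductionParams()
        lai = 2.0
        light = (1 - np.exp(-p.light_k * lai)) ** p.light_power
        got = bgc.tree_production(p, 0.8, 0.5, 1.1, lai)
        assert got == pytest.approx(p.max_tree_npp * 0.8 * 0.5 * 1.1 * light)

    def test_grass_shaded_by_tree_canopy(self):
        p = ProductionParams()
        shaded = bgc.grass_production(p, 1.0, 1.0, 1.0, tree_lai=2.0,
                                      standing_dead=0.0)
        open_ = bgc.grass_production(p, 1.0, 1.0, 1.0, tree_lai=0.0,
                                     standing_dead=0.0)
        assert shaded < open_

    def test_grass_roots_suppress_tree_seedlings_not_canopies(self):
        p = ProductionParams()
        seedling_clear = bgc.tree_production(p, 1.0, 1.0, 1.0, 0.05, grass_root=0.0)
        seedling_sod = bgc.tree_production(p, 1.0, 1.0, 1.0, 0.05, grass_root=150.0)
        assert seedling_sod < 0.5 * seedling_clear
        canopy_clear = bgc.tree_production(p, 1.0, 1.0, 1.0, 2.5, grass_root=0.0)
        canopy_sod = bgc.tree_production(p, 1.0, 1.0, 1.0, 2.5, grass_root=150.0)
        # a closed canopy is barely touched; a seedling is crushed
        assert canopy_sod > 0.7 * canopy_clear


def _zero_pools(n=1):
    return {k: np.zeros(n) for k in bgc.ALL_POOLS}


class TestAllocationTurnover:
    def test_no_npp_no_turnover_leaves_pools_unchanged(self):
        p = AllocationParams()
        for k in p.tree_turnover:
            p.tree_turnover[k] = 0.0
        for k in p.grass_turnover:
            p.grass_turnover[k] = 0.0
        p.standing_dead_fall = 0.0
        pools = _zero_pools()
        pools["tree_leaf"] += 10.0
        before = {k: v.copy() for k, v in pools.items()}
        bgc.allocate_and_turnover(pools, 0.0, 0.0, p)
        for k in pools:
            assert np.allclose(pools[k], before[k])

    def test_year_of_constant_npp_matches_fractions(self):
        p = AllocationParams()
        for k in p.tree_turnover:
            p.tree_turnover[k] = 0.0
        for k in p.grass_turnover:
            p.grass_turnover[k] = 0.0
        p.standing_dead_fall = 0.0
        pools = _zero_pools()
        for _ in range(12):
            bgc.allocate_and_turnover(pools, 10.0, 5.0, p)
        for part, frac in p.tree_alloc.items():
            assert pools[f"tree_{part}"][0] == pytest.approx(frac * 120.0)
        for part, frac in p.grass_alloc.items():
            assert pools[f"grass_{part}"][0] == pytest.approx(frac * 60.0)

    def test_bad_fractions_rejected(self):
        p = AllocationParams()
        p.tree_alloc["leaf"] = 0.9
        with pytest.raises(ValueError, match="sum to 1"):
            bgc.allocate_and_turnover(_zero_pools(), 1.0, 1.0, p)

    def test_turnover_conserves_carbon(self):
        p = AllocationParams()
        pools = _zero_pools()
        for k in pools:
            pools[k] += 100.0
        total_before = sum(v.sum() for v in pools.values())
        bgc.allocate_and_turnover(pools, 7.0, 3.0, p)
        total_after = sum(v.sum() for v in pools.values())
        assert total_after - total_before == pytest.approx(10.0, abs=1e-9)


class TestDecomposition:
    def test_frozen_month_no_decay(self):
        p = DecompositionParams()
        pools = _zero_pools()
        pools["litter_1h"] += 50.0
        rh = bgc.decompose(pools, -5.0, 1.0, p)
        assert np.all(rh == 0.0)
        assert pools["litter_1h"][0] == 50.0

    def test_single_pool_exponential_decay(self):
        p = DecompositionParams()
        rate = p.base_rates["soil_passive"]
        pools = _zero_pools()
        pools["soil_passive"] += 1000.0
        months = 120
        for _ in range(months):
            bgc.decompose(pools, p.t_ref, p.moisture_half, p)
        expected = 1000.0 * (1 - rate) ** months
        assert pools["soil_passive"][0] == pytest.approx(expected, rel=1e-9)

    def test_steady_litter_converges_to_input_over_rate(self):
        p = DecompositionParams()
        rate = p.base_rates["litter_1h"]
        pools = _zero_pools()
        inflow = 2.0
        for _ in range(3000):
            pools["litter_1h"] += inflow
            bgc.decompose(pools, p.t_ref, p.moisture_half, p)
        assert pools["litter_1h"][0] == pytest.approx(
            inflow * (1 - rate) / rate, rel=1e-3)

    def test_respired_plus_transferred_balances(self):
        p = DecompositionParams()
        pools = _zero_pools()
        for k in p.base_rates:
            pools[k] += 100.0
        before = sum(v.sum() for v in pools.values())
        rh = bgc.decompose(pools, 25.0, 1.0, p)
        after = sum(v.sum() for v in pools.values())
        assert before - after == pytest.approx(float(rh.sum()), rel=1e-12)


class TestSoilWater:
    def test_no_water_no_aet(self):
        sw1, sw2, aet, dr = bgc.soil_water_update(0.0, 0.0, 5.0, 8.0, 0.0, 10.0)
        assert aet == 0.0 and dr == 0.0

    def test_saturating_precip_fills_and_drains(self):
        sw1, sw2, aet, dr = bgc.soil_water_update(0.0, 0.0, 5.0, 8.0, 30.0, 0.0)
        assert sw1 == pytest.approx(5.0)
        assert sw2 == pytest.approx(8.0)
        assert dr == pytest.approx(30.0 - 13.0)

    def test_reduced_transpiration_leaves_more_soil_water(self):
        a = bgc.soil_water_update(3.0, 5.0, 5.0, 8.0, 2.0, 8.0, transp_mult=0.75)
        b = bgc.soil_water_update(3.0, 5.0, 5.0, 8.0, 2.0, 8.0, transp_mult=1.0)
        assert a[0] + a[1] > b[0] + b[1]

    def test_aet_never_exceeds_pet(self):
        _, _, aet, _ = bgc.soil_water_update(5.0, 8.0, 5.0, 8.0, 10.0, 3.0,
                                             transp_mult=2.0, demand_factor=2.0)
        assert aet <= 3.0 + 1e-12


class TestGrazing:
    @pytest.mark.parametrize("month,npp,expected", [
        (6, 100.0, 30.0),
        (12, 100.0, 0.0),
        (6, 0.0, 0.0),
        (4, 50.0, 15.0),
        (9, 50.0, 15.0),
        (10, 50.0, 0.0),
    ])
    def test_window_and_fraction(self, month, npp, expected):
        assert bgc.graze(npp, month) == pytest.approx(expected)

    def test_disabled(self):
        assert bgc.graze(100.0, 6, enabled=False) == 0.0


class TestAllometry:
    def test_zero_pools_zero_geometry(self):
        g = bgc.allometry(_zero_pools(), AllometryParams())
        for v in g.values():
            assert np.all(v == 0.0)

    def test_monotone_in_wood(self):
        p = AllometryParams()
        pools = _zero_pools()
        pools["tree_leaf"] += 100.0
        pools["tree_large_wood"] += 1000.0
        g1 = bgc.allometry(pools, p)
        pools["tree_large_wood"] *= 2
        g2 = bgc.allometry(pools, p)
        for k in ("height", "cbh", "bark_cm"):
            assert g2[k][0] > g1[k][0]

    def test_lai_saturates_at_halved_asymptote(self):
        p = AllometryParams()
        pools = _zero_pools()
        pools["tree_leaf"] += 1e7
        g = bgc.allometry(pools, p)
        assert g["lai"][0] == pytest.approx(p.lai_max)
        assert g["cbh"][0] < g["height"][0]
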