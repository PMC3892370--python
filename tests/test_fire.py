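"""Fire behavior, ignition, crown initiation, effects, and policies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegfire import fire as fm
from vegfire.biogeochem import ALL_POOLS
from vegfire.params import FireParams


def _pools(n=1, **overrides):
    pools = {k: np.zeros(n) for k in ALL_POOLS}
    for k, v in overrides.items():
        pools[k] = pools[k] + v
    return pools


def _bed(one=300.0, ten=100.0, hundred=200.0, live=300.0):
    return {"1h": np.array([one]), "10h": np.array([ten]),
            "100h": np.array([hundred]), "1000h": np.array([500.0]),
            "live": np.array([live])}


_DRY = {"1h": np.array([0.06]), "10h": np.array([0.08]),
        "100h": np.array([0.12])}


class TestFuelLoads:
    def test_zero_pools_zero_loads(self):
        loads = fm.fuel_loads(_pools())
        for v in loads.values():
            assert np.all(v == 0.0)

    def test_carbon_to_dry_matter_mapping(self):
        p = FireParams()
        pools = _pools(litter_1h=10.0, grass_standing_dead=5.0,
                       litter_10h=7.0, litter_100h=3.0, litter_1000h=2.0,
                       grass_shoot=4.0, tree_leaf=6.0)
        loads = fm.fuel_loads(pools, p)
        assert loads["1h"][0] == pytest.approx((10 + 5) * 2.0)
        assert loads["10h"][0] == pytest.approx(14.0)
        assert loads["100h"][0] == pytest.approx(6.0)
        assert loads["1000h"][0] == pytest.approx(4.0)
        assert loads["live"][0] == pytest.approx((4 + 6) * 2.0)

    def test_grass_cell_dominated_by_fine_fuel(self):
        pools = _pools(grass_shoot=60.0, grass_standing_dead=40.0,
                       litter_1h=50.0)
        loads = fm.fuel_loads(pools)
        fine = loads["1h"][0] + loads["live"][0]
        coarse = loads["10h"][0] + loads["100h"][0] + loads["1000h"][0]
        assert fine > 10 * max(coarse, 1e-9)


class TestBehavior:
    def test_moisture_above_extinction_stops_spread(self):
        p = FireParams()
        wet = {"1h": np.array([p.mx_dead_grass + 0.05]),
               "10h": np.array([p.mx_dead_grass + 0.05]),
               "100h": np.array([p.mx_dead_grass + 0.05])}
        ros, fli, erc = fm.fire_behavior(_bed(), wet, np.array([True]), p)
        assert ros[0] == 0.0
        assert erc[0] == 0.0

    def test_wind_speeds_spread(self):
        p = FireParams()
        slow = fm.fire_behavior(_bed(), _DRY, np.array([True]), p,
                                wind_m_s=2.0)[0]
        fast = fm.fire_behavior(_bed(), _DRY, np.array([True]), p,
                                wind_m_s=4.0)[0]
        assert fast[0] > slow[0]

    def test_grassland_spreads_at_least_as_fast_as_forest(self):
        p = FireParams()
        g = fm.fire_behavior(_bed(), _DRY, np.array([True]), p)[0]
        f = fm.fire_behavior(_bed(), _DRY, np.array([False]), p)[0]
        assert g[0] >= f[0]

    def test_intensity_scales_with_spread(self):
        p = FireParams()
        ros, fli, erc = fm.fire_behavior(_bed(), _DRY, np.array([True]), p)
        assert ros[0] > 0
        assert fli[0] > 0
        # FLI = heat yield x consumed fuel x ROS
        cons = p.consumption
        w = (cons["litter_1h"] * 0.3 + cons["litter_10h"] * 0.1
             + cons["litter_100h"] * 0.2 + p.grass_shoot_consumption * 0.3)
        assert fli[0] == pytest.approx(p.heat_yield_kj_kg * w * ros[0], rel=1e-9)


class TestIgnition:
    def test_gate_requires_all_conditions(self):
        p = FireParams()
        assert fm.ignition_test(1.0, 91.0, 90.0, False, p)
        assert not fm.ignition_test(0.0, 91.0, 90.0, False, p)
        assert not fm.ignition_test(1.0, 89.0, 120.0, False, p)   # FFMC gate
        assert not fm.ignition_test(1.0, 91.0, 70.0, False, p)    # BUI gate
        assert not fm.ignition_test(1.0, 91.0, 90.0, True, p)     # one per year

    def test_threshold_is_strict(self):
        p = FireParams()
        assert not fm.ignition_test(1.0, 90.4, 90.0, False, p)
        assert fm.ignition_test(1.0, 90.4 + 1e-9, 90.0, False, p)


class TestCrownFire:
    def test_zero_cbh_crowns_at_any_intensity(self):
        assert fm.crown_fire_test(1.0, 0.0)
        assert fm.crown_fire_test(1e-6, 0.0)

    def test_critical_intensity_formula(self):
        cbh, fmc = 4.0, 100.0
        i0 = (0.01 * cbh * (460.0 + 25.9 * fmc)) ** 1.5
        assert fm.crown_fire_test(i0, cbh, fmc)          # >= convention
        assert not fm.crown_fire_test(i0 * 0.999, cbh, fmc)

    def test_tall_stand_resists_moderate_intensity(self):
        # mature open pine: CBH ~8 m resists a 600 kW/m surface fire
        assert not fm.crown_fire_test(600.0, 8.0, 100.0)


class TestBurnFraction:
    @pytest.mark.parametrize("years,expected", [
        (1, 0.1), (5, 0.5), (10, 1.0), (25, 1.0),
    ])
    def test_ramp(self, years, expected):
        assert fm.burn_fraction(years) == pytest.approx(expected)

    def test_reburn_within_fire_year_rejected(self):
        with pytest.raises(ValueError):
            fm.burn_fraction(0)


class TestEffects:
    def test_crown_fire_full_burn_removes_live_trees(self):
        p = FireParams()
        pools = _pools(tree_leaf=100.0, tree_fine_branch=200.0,
                       tree_large_wood=900.0, tree_fine_root=80.0,
                       tree_coarse_root=120.0, grass_shoot=30.0,
                       litter_1h=40.0)
        before = sum(v.sum() for v in pools.values())
        res = fm.fire_effects(pools, 5000.0, np.array([True]), 1.0, params=p)
        for pool in ("tree_leaf", "tree_fine_branch", "tree_large_wood"):
            assert pools[pool][0] == pytest.approx(0.0)
        after = sum(v.sum() for v in pools.values())
        # killed live C = transfers + emission, exactly
        assert before - after == pytest.approx(float(res["emissions"][0]))
        assert res["killed_live"][0] == pytest.approx(1400.0)

    def test_zero_burn_fraction_changes_nothing(self):
        pools = _pools(tree_leaf=50.0, litter_1h=20.0, grass_shoot=10.0)
        before = {k: v.copy() for k, v in pools.items()}
        fm.fire_effects(pools, 0.0, np.array([False]), 0.0)
        for k in pools:
            assert np.allclose(pools[k], before[k])

    def test_thicker_bark_lowers_stem_mortality(self):
        p = FireParams()
        out = []
        for bark in (0.5, 2.5):
            pools = _pools(tree_leaf=100.0, tree_large_wood=900.0)
            fm.fire_effects(pools, 800.0, np.array([False]), 1.0,
                            cbh=4.0, bark_cm=bark, params=p)
            out.append(pools["tree_large_wood"][0])
        assert out[1] > out[0]

    def test_grass_roots_survive(self):
        pools = _pools(grass_shoot=50.0, grass_root=80.0)
        fm.fire_effects(pools, 2000.0, np.array([False]), 1.0, cbh=0.0)
        assert pools["grass_root"][0] == pytest.approx(80.0)
        assert pools["grass_shoot"][0] < 10.0


class TestPolicies:
    def test_scaled_ros_threshold_value(self):
        p = FireParams()
        assert p.suppression_scale * p.ros_threshold_m_s == pytest.approx(0.2295)

    def test_mild_fire_suppressed(self):
        assert fm.suppression_policy(0.1, 500.0, 100.0)
        assert fm.suppression_policy(0.0, 0.0, 0.0)

    def test_severe_fire_escapes(self):
        p = FireParams()
        s = p.suppression_scale
        assert not fm.suppression_policy(2 * s * p.ros_threshold_m_s,
                                         2 * s * p.fli_threshold_kw_m,
                                         2 * s * p.erc_threshold_kw_m2, p)

    def test_any_rule_escapes_on_single_exceedance(self):
        p = FireParams(escape_rule="any")
        assert not fm.suppression_policy(1.0, 0.0, 0.0, p)
        p_all = FireParams(escape_rule="all")
        assert fm.suppression_policy(1.0, 0.0, 0.0, p_all)

    def test_escape_monotone_in_scaling_factor(self):
        ros, fli, erc = 0.3, 1600.0, 350.0
        escaped = []
        for scale in (0.3, 0.45, 0.6, 1.0, 2.0):
            p = FireParams(suppression_scale=scale)
            escaped.append(not fm.suppression_policy(ros, fli, erc, p))
        assert np.all(np.diff(np.array(escaped).astype(int)) <= 0)

    def test_prescribed_event_years(self):
        years = fm.prescribed_event_years(2001, 2100)
        assert years[0] == 2001 and years[1] == 2012
        assert len(years) == 10
        assert np.all(np.diff(years) == 11)

    def test_prescribed_mortality_fraction(self):
        p = FireParams()
        pools = _pools(tree_leaf=100.0, tree_fine_branch=200.0,
                       tree_large_wood=700.0)
        fm.fire_effects(pools, 0.0, np.array([False]), 1.0, params=p,
                        tree_mortality_override=p.prescribed_tree_mortality,
                        grass_consumption=1.0)
        live = (pools["tree_leaf"] + pools["tree_fine_branch"]
                + pools["tree_large_wood"])[0]
        assert live == pytest.approx(800.0)


@given(st.floats(0.0, 0.4), st.floats(0.0, 0.4), st.floats(0.0, 0.5))
@settings(max_examples=50, deadline=None)
def test_behavior_outputs_nonnegative(m1, m10, m100):
    moist = {"1h": np.array([m1]), "10h": np.array([m10]),
             "100h": np.array([m100])}
    ros, fli, erc = fm.fire_behavior(_bed(), moist, np.array([True]))
    assert ros[0] >= 0 and fli[0] >= 0 and erc[0] >= 0
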