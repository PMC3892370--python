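"""Climate transforms: downscaling, detrending, smoothing, pseudo-daily."""

import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

import vegfire as vf
from vegfire.climate import (ClimateSmoother, MONTH_LENGTHS,
                             bilinear_interpolate, baseline_means,
                             downscale_anomaly, pseudo_daily,
                             pseudo_daily_year, saturation_vapor_pressure)


def _flat_anomalies(nyr, dtemp=0.0, pratio=1.0, vratio=1.0, ny=4, nx=4):
    n = nyr * 12
    return xr.Dataset(
        {
            "dtemp": (("time", "yc", "xc"), np.full((n, 2, 2), dtemp)),
            "pratio": (("time", "yc", "xc"), np.full((n, 2, 2), pratio)),
            "vratio": (("time", "yc", "xc"), np.full((n, 2, 2), vratio)),
        },
        coords={"time": np.arange(n),
                "year": ("time", np.repeat(np.arange(2001, 2001 + nyr), 12)),
                "month": ("time", np.tile(np.arange(1, 13), nyr)),
                "yc": np.array([0.0, ny - 1.0]), "xc": np.array([0.0, nx - 1.0])})


class TestDownscaling:
    def test_precipitation_ratio_capped_at_five(self, small_grid):
        (clim, _), cfg = small_grid
        base = baseline_means(clim, cfg.year_start, cfg.year_end)
        an = _flat_anomalies(2, pratio=7.0, ny=cfg.ny, nx=cfg.nx)
        fut = downscale_anomaly(an, base)
        jan_base = base["ppt"].sel(month=1).values
        jan_fut = fut["ppt"].values[0]
        assert np.allclose(jan_fut, 5.0 * jan_base)

    def test_identity_anomalies_reproduce_baseline(self, small_grid):
        (clim, _), cfg = small_grid
        base = baseline_means(clim, cfg.year_start, cfg.year_end)
        an = _flat_anomalies(1, ny=cfg.ny, nx=cfg.nx)
        fut = downscale_anomaly(an, base)
        for m in range(12):
            assert np.allclose(fut["tmax"].values[m],
                               base["tmax"].sel(month=m + 1).values)
            assert np.allclose(fut["ppt"].values[m],
                               base["ppt"].sel(month=m + 1).values)

    def test_bilinear_exact_at_lattice_nodes(self):
        coarse = np.array([[1.0, 2.0], [3.0, 5.0]])
        out = bilinear_interpolate(coarse, np.array([0.0, 3.0]),
                                   np.array([0.0, 3.0]),
                                   np.array([0.0, 3.0]), np.array([0.0, 3.0]))
        assert np.allclose(out, coarse)
        # center point is the mean of the four corners
        mid = bilinear_interpolate(coarse, np.array([0.0, 3.0]),
                                   np.array([0.0, 3.0]),
                                   np.array([1.5]), np.array([1.5]))
        assert mid[0, 0] == pytest.approx(coarse.mean())

    def test_lattice_must_cover_grid(self):
        coarse = np.ones((2, 2))
        with pytest.raises(ValueError, match="cover"):
            bilinear_interpolate(coarse, np.array([0.0, 2.0]),
                                 np.array([0.0, 2.0]),
                                 np.array([0.0, 3.0]), np.array([0.0, 1.0]))

    def test_nonpositive_ratio_rejected(self, small_grid):
        (clim, _), cfg = small_grid
        base = baseline_means(clim, cfg.year_start, cfg.year_end)
        an = _flat_anomalies(1, pratio=-1.0, ny=cfg.ny, nx=cfg.nx)
        with pytest.raises(ValueError, match="positive"):
            downscale_anomaly(an, base)


class TestDetrending:
    def test_trendless_input_unchanged(self, small_grid):
        (clim, _), _ = small_grid
        flat = clim.copy(deep=True)
        # replace with an exactly cyclic (trendless) series
        one_year = clim.ppt.values[:12]
        nyr = len(np.unique(clim.year.values))
        for v in ("ppt", "tmax", "tmin", "vpr"):
            flat[v].values = np.tile(clim[v].values[:12], (nyr, 1, 1))
        det = vf.detrend_for_spinup(flat)
        for v in ("ppt", "tmax", "tmin", "vpr"):
            assert np.allclose(det[v].values, flat[v].values, atol=1e-8)

    def test_imposed_temperature_trend_removed(self, small_grid):
        (clim, _), _ = small_grid
        trended = clim.copy(deep=True)
        years = trended.year.values
        ramp = 0.01 * (years - years.min())
        for v in ("tmax", "tmin"):
            trended[v].values = trended[v].values + ramp[:, None, None]
        det = vf.detrend_for_spinup(trended)
        ann = det.tmax.groupby(det.year).mean("time").isel(y=0, x=0).values
        yrs = np.unique(years).astype(float)
        slope = np.polyfit(yrs, ann, 1)[0]
        assert abs(slope) < 2e-3  # residual interannual noise only

    def test_mean_precipitation_preserved(self, small_grid):
        (clim, _), _ = small_grid
        det = vf.detrend_for_spinup(clim)
        before = clim.ppt.values.sum(axis=0)
        after = det.ppt.values.sum(axis=0)
        assert np.allclose(after, before, rtol=1e-3)

    def test_short_series_rejected(self, small_grid):
        (clim, _), _ = small_grid
        one_year = clim.sel(time=clim.year == clim.year.values[0])
        with pytest.raises(ValueError, match="2 years"):
            vf.detrend_for_spinup(one_year)


class TestSmoothing:
    def test_constant_climate_is_fixed_point(self):
        sm = ClimateSmoother(10.0)
        tmin = np.full((12, 3), -8.0)
        ppt = np.full((12, 3), 4.0)
        for _ in range(50):
            mt, gp = sm.update(tmin, ppt)
        assert np.allclose(mt, -8.0)
        assert np.allclose(gp, 6 * 4.0)

    def test_first_year_initializes_to_inputs(self):
        sm = ClimateSmoother(10.0)
        tmin = np.linspace(-20, 0, 12).reshape(12, 1)
        ppt = np.ones((12, 1))
        mt, gp = sm.update(tmin, ppt)
        assert mt[0] == pytest.approx(tmin.min())
        assert gp[0] == pytest.approx(ppt[3:9].sum())

    def test_step_change_follows_geometric_series(self):
        """After a step, the residual decays like (1-alpha)^k."""
        tau = 10.0
        sm = ClimateSmoother(tau)
        cold = np.full((12, 1), -10.0)
        warm = np.full((12, 1), -2.0)
        ppt = np.ones((12, 1))
        sm.update(cold, ppt)
        alpha = sm.alpha
        values = []
        for k in range(1, 31):
            mt, _ = sm.update(warm, ppt)
            values.append(float(mt[0]))
            expected = -2.0 + (-10.0 - -2.0) * (1 - alpha) ** k
            assert mt[0] == pytest.approx(expected, abs=1e-10)
        # monotone approach; residual still >10% after 1 year, <10% later
        assert np.all(np.diff(values) > 0)
        resid = (np.array(values) + 2.0) / -8.0
        assert resid[0] > 0.1
        assert resid[-1] < 0.1


class TestPseudoDaily:
    def test_equal_months_give_constant_days(self):
        days = pseudo_daily(5.0, 5.0, 5.0, 31, 30, 31)
        assert np.allclose(days, 5.0)

    def test_mid_month_day_equals_monthly_value(self):
        days = pseudo_daily(2.0, 8.0, 4.0, 31, 31, 30)
        assert days[15] == pytest.approx(8.0)  # day 16 is mid-month of 31

    def test_halfway_point_is_arithmetic_mean(self):
        # equal 30-day months: anchors sit at day 15.5 of each month, so the
        # halfway point between the two mid-months falls at the month
        # boundary; the last day of the month is within half a day of it
        days = pseudo_daily(2.0, 8.0, 4.0, 30, 30, 30)
        assert days[-1] == pytest.approx(0.5 * (8.0 + 4.0), abs=0.1)

    @given(st.lists(st.floats(0.0, 20.0), min_size=12, max_size=12))
    @settings(max_examples=25, deadline=None)
    def test_precipitation_conserved_exactly(self, monthly):
        monthly = np.asarray(monthly)
        rates = monthly / MONTH_LENGTHS
        daily = pseudo_daily_year(rates, rates[11:12], rates[0:1],
                                  conserve_total=True)
        assert daily.shape[0] == 365
        d0 = 0
        for m in range(12):
            nd = MONTH_LENGTHS[m]
            total = daily[d0:d0 + nd].sum()
            assert total == pytest.approx(monthly[m], abs=1e-9)
            d0 += nd


class TestHumidity:
    def test_saturated_air(self):
        es = saturation_vapor_pressure(15.0)
        rh, vpd = vf.derive_humidity(15.0, 15.0, es)
        assert rh == pytest.approx(100.0)
        assert vpd == pytest.approx(0.0)

    def test_dry_air_clipped_to_floor(self):
        rh, vpd = vf.derive_humidity(25.0, 15.0, 0.0)
        assert rh == pytest.approx(1.0)
        assert vpd == pytest.approx(saturation_vapor_pressure(20.0))

    def test_vpd_increases_with_temperature_at_fixed_vapor(self):
        vpr = 800.0
        temps = np.arange(5.0, 35.0, 1.0)
        _, vpd = vf.derive_humidity(temps + 5, temps - 5, vpr)
        assert np.all(np.diff(vpd) > 0)
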