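"""Energy-balance melt model: fluxes, melt conversion, attribution."""

import numpy as np
import pandas as pd
import pytest

from bioalbedo import (
    IRFRegression,
    SurfaceParams,
    WeatherSeries,
    extrapolate_volume,
    melt_from_energy,
    melt_uncertainty,
    percent_contribution,
    run_melt_model,
    sensible_heat_flux,
    shortwave_net,
)
from bioalbedo.errors import WeatherError
from bioalbedo.melt import PhysicalConstants

LF = 3.34e5


def constant_weather(par, temp, wind=5.0, rh=80.0, n=288, start="2023-02-06"):
    return WeatherSeries(
        timestamps=pd.date_range(start, periods=n, freq="5min"),
        par=np.full(n, float(par)),
        air_temp=np.full(n, float(temp)),
        wind=np.full(n, float(wind)),
        rh=np.full(n, float(rh)),
    )


class TestSensibleHeatFlux:
    def test_zero_air_temperature(self):
        assert sensible_heat_flux(0.0, 5.0, 80.0) == 0.0

    def test_zero_wind(self):
        assert sensible_heat_flux(3.0, 0.0, 80.0) == 0.0

    def test_bulk_formula_default_constants(self):
        # 1.29 * 1005 * 1.5e-3 * 0.8 * 5 * 3.15
        assert sensible_heat_flux(3.15, 5.0, 80.0) == pytest.approx(24.50, abs=0.005)

    def test_negative_for_subzero_air(self):
        assert sensible_heat_flux(-2.0, 5.0, 80.0) < 0.0

    def test_humidity_scales_transfer_coefficient(self):
        full = sensible_heat_flux(3.0, 5.0, 100.0)
        half = sensible_heat_flux(3.0, 5.0, 50.0)
        assert half == pytest.approx(0.5 * full)

    def test_out_of_range_humidity_rejected(self):
        with pytest.raises(ValueError):
            sensible_heat_flux(3.0, 5.0, 120.0)


class TestShortwaveNet:
    def test_high_albedo_limit(self):
        assert shortwave_net(300.0, 0.999999) == pytest.approx(0.0, abs=1e-3)

    def test_arithmetic(self):
        assert shortwave_net(300.0, 0.8) == pytest.approx(60.0)

    def test_irf_is_additive(self):
        assert shortwave_net(300.0, 0.8, 10.0) == pytest.approx(
            shortwave_net(300.0, 0.8) + 10.0
        )

    def test_albedo_bounds(self):
        with pytest.raises(ValueError):
            shortwave_net(300.0, 1.0)
        with pytest.raises(ValueError):
            shortwave_net(300.0, 0.0)


class TestMeltFromEnergy:
    def test_latent_heat_definition(self):
        assert melt_from_energy(LF) == pytest.approx(1.0)

    def test_zero(self):
        assert melt_from_energy(0.0) == 0.0

    def test_negative_energy_clamped_no_refreezing(self):
        assert melt_from_energy(-1e5) == 0.0


class TestRunMeltModel:
    def test_dark_cold_day_melts_nothing(self, field_regression):
        weather = constant_weather(par=0.0, temp=-5.0)
        surface = SurfaceParams(albedo=0.6, density=500.0)
        res = run_melt_model(weather, surface, field_regression, 2.5e5)
        assert res.total_melt_mm == 0.0
        assert res.algal_melt_mm == 0.0
        assert res.percent_contribution == 0.0

    def test_constant_forcing_closed_form(self):
        """(E_sw*(1-albedo) + Q_h) * 86400 / L_f under constant forcing."""
        # no algae: zero-residual regression with huge negative intercept
        reg = IRFRegression(0.0, -1.0, 0.0, 0.0, reference_par=351.0)
        par = 100.0 * 4.57  # 100 W m-2 irradiance
        weather = constant_weather(par=par, temp=3.15, wind=5.0, rh=80.0)
        surface = SurfaceParams(albedo=0.6, density=500.0)
        res = run_melt_model(weather, surface, reg, 2.5e5)
        qh = 1.29 * 1005 * 1.5e-3 * 0.8 * 5 * 3.15
        expected = (100.0 * 0.4 + qh) * 86400 / LF
        assert res.total_melt_mm == pytest.approx(expected, rel=1e-9)
        assert res.algal_melt_mm == pytest.approx(0.0, abs=1e-12)

    def test_example_closed_form_with_qh_10(self):
        reg = IRFRegression(0.0, -1.0, 0.0, 0.0)
        # choose wind so that Q_h = 10 W m-2 at 3.15 degC, rh 80%
        wind = 10.0 / (1.29 * 1005 * 1.5e-3 * 0.8 * 3.15)
        weather = constant_weather(par=100.0 * 4.57, temp=3.15, wind=wind)
        res = run_melt_model(weather, SurfaceParams(albedo=0.6, density=500.0),
                             reg, 1.0)
        assert res.total_melt_mm == pytest.approx((100 * 0.4 + 10) * 86400 / LF,
                                                  rel=1e-9)

    def test_algal_run_never_melts_less(self, field_regression):
        rng = np.random.default_rng(5)
        weather = WeatherSeries(
            timestamps=pd.date_range("2023-02-01", periods=288, freq="5min"),
            par=rng.uniform(0, 800, 288),
            air_temp=rng.uniform(-3, 5, 288),
            wind=rng.uniform(0, 12, 288),
            rh=rng.uniform(40, 100, 288),
        )
        res = run_melt_model(weather, SurfaceParams(albedo=0.55, density=500.0),
                             field_regression, 2.5e5)
        assert res.total_melt_mm >= res.clean_melt_mm
        assert 0.0 <= res.percent_contribution <= 100.0

    def test_energy_closure_per_run(self, field_regression):
        rng = np.random.default_rng(9)
        weather = WeatherSeries(
            timestamps=pd.date_range("2023-02-01", periods=288, freq="5min"),
            par=rng.uniform(0, 800, 288),
            air_temp=rng.uniform(-3, 5, 288),
            wind=rng.uniform(0, 12, 288),
            rh=rng.uniform(40, 100, 288),
        )
        res = run_melt_model(weather, SurfaceParams(albedo=0.55, density=500.0),
                             field_regression, 2.5e5)
        steps = res.steps
        dt = weather.step_seconds
        net = (steps["shortwave_net_algal_w_m2"] + steps["sensible_w_m2"]) * dt
        assert (steps["melt_algal_mm"] * LF).sum() == pytest.approx(
            net.clip(lower=0).sum(), rel=1e-12
        )

    def test_half_day_additivity(self, field_regression):
        rng = np.random.default_rng(3)
        ts = pd.date_range("2023-02-01", periods=288, freq="5min")
        par = rng.uniform(0, 800, 288)
        temp = rng.uniform(-3, 5, 288)
        wind = rng.uniform(0, 12, 288)
        rh = rng.uniform(40, 100, 288)
        surface = SurfaceParams(albedo=0.55, density=500.0)

        def run(sl):
            w = WeatherSeries(ts[sl], par[sl], temp[sl], wind[sl], rh[sl])
            return run_melt_model(w, surface, field_regression, 2.5e5)

        full = run(slice(None))
        first, second = run(slice(0, 144)), run(slice(144, 288))
        assert first.total_melt_mm + second.total_melt_mm == pytest.approx(
            full.total_melt_mm, rel=1e-12
        )
        assert first.algal_melt_mm + second.algal_melt_mm == pytest.approx(
            full.algal_melt_mm, rel=1e-12
        )

    def test_percent_contribution_stable_under_finer_discretisation(
        self, field_regression
    ):
        """5-min vs 1-min steps change smooth-forcing percentages < 0.1%."""
        from bioalbedo.synthetic import make_weather_series

        surface = SurfaceParams(albedo=0.55, density=500.0)
        w5 = make_weather_series(seed=0)
        res5 = run_melt_model(w5, surface, field_regression, 2.5e5)

        hours = np.arange(288 * 5) / 60.0
        rise, dl = 12.0 - 8.0, 16.0
        phase = (hours - rise) / dl
        par = np.where((phase > 0) & (phase < 1), np.sin(np.pi * phase), 0.0)
        par *= w5.par.mean() / par.mean()
        w1 = WeatherSeries(
            pd.date_range("2023-02-06", periods=288 * 5, freq="1min"),
            par,
            2.42 + 1.5 * np.cos(2 * np.pi * (hours - 15.0) / 24.0),
            np.full(288 * 5, 8.0),
            np.full(288 * 5, 85.0),
        )
        res1 = run_melt_model(w1, surface, field_regression, 2.5e5)
        assert res1.percent_contribution == pytest.approx(
            res5.percent_contribution, rel=1e-3
        )

    def test_irregular_timestamps_rejected(self, field_regression):
        ts = pd.DatetimeIndex(
            ["2023-02-01 00:00", "2023-02-01 00:05", "2023-02-01 00:15"]
        )
        with pytest.raises(WeatherError, match="regular"):
            WeatherSeries(ts, [0.0] * 3, [0.0] * 3, [0.0] * 3, [50.0] * 3)

    def test_empty_series_rejected(self):
        with pytest.raises(WeatherError, match="empty"):
            WeatherSeries(pd.DatetimeIndex([]), [], [], [], [])

    def test_surface_lowering_uses_bulk_density(self, field_regression):
        weather = constant_weather(par=457.0, temp=2.0)
        res = run_melt_model(weather, SurfaceParams(albedo=0.6, density=500.0),
                             field_regression, 2.5e5)
        assert res.lowering_mm == pytest.approx(res.total_melt_mm * 2.0)


class TestMeltUncertainty:
    def test_zero_residual_sd_gives_zero(self):
        reg = IRFRegression(5.52, -24.03, 1.0, 0.0)
        weather = constant_weather(par=400.0, temp=2.0)
        res = run_melt_model(weather, SurfaceParams(albedo=0.6, density=500.0),
                             reg, 2.5e5)
        unc = melt_uncertainty(res, density_sd=0.0)
        assert unc.residual_sd_mm == pytest.approx(0.0, abs=1e-12)
        assert unc.density_sd_mm == pytest.approx(0.0, abs=1e-12)

    def test_constant_forcing_linear_propagation(self, field_regression):
        """SD = residual_sd * (par/ref) * 86400 / L_f when nothing clamps."""
        par = 351.0
        weather = constant_weather(par=par, temp=3.0)
        res = run_melt_model(weather, SurfaceParams(albedo=0.6, density=500.0),
                             field_regression, 2.5e5)
        unc = melt_uncertainty(res)
        expected = field_regression.residual_sd * (par / 351.0) * 86400 / LF
        assert unc.residual_sd_mm == pytest.approx(expected, rel=1e-9)

    def test_sd_nondecreasing_in_residual_sd(self):
        weather = constant_weather(par=400.0, temp=2.0)
        surface = SurfaceParams(albedo=0.6, density=500.0)
        sds = []
        for rsd in (0.0, 5.0, 10.0):
            reg = IRFRegression(5.52, -24.03, 0.41, rsd)
            res = run_melt_model(weather, surface, reg, 2.5e5)
            sds.append(melt_uncertainty(res).residual_sd_mm)
        assert sds == sorted(sds)


class TestPercentContribution:
    def test_zero_algal(self):
        assert percent_contribution(0.0, 10.0) == 0.0

    def test_consistent_with_printed_melt_table(self):
        # printed 0.51 mm of 21.4 mm was reported as 2.36%
        assert percent_contribution(0.51, 21.4) == pytest.approx(2.36, abs=0.05)

    def test_all_algal(self):
        assert percent_contribution(5.0, 5.0) == 100.0

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            percent_contribution(0.0, 0.0)


class TestExtrapolateVolume:
    def test_unit_identity(self):
        assert extrapolate_volume(1.0, 1.0) == pytest.approx(1e6)

    def test_bloom_scale(self):
        assert extrapolate_volume(0.51, 2.7) == pytest.approx(1.377e6)

    def test_zero_area(self):
        assert extrapolate_volume(0.51, 0.0) == 0.0

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_volume(1.0, -1.0)


def test_physical_constants_are_configurable():
    pc = PhysicalConstants(latent_heat_fusion=2 * LF)
    assert melt_from_energy(LF, pc) == pytest.approx(0.5)
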