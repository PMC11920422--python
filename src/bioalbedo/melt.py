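"""Five-minute surface energy-balance melt model with and without algae.

The model sums two fluxes at a melting (0 degC) snow or weathering-crust
surface at each weather-station step:

* net shortwave: PAR converted to energy (4.57 umol J-1), reduced by the
  broadband surface albedo, plus the algal radiative forcing predicted from
  the density-IRF regression and scaled with instantaneous PAR;
* turbulent sensible heat: a bulk formula
  ``Q_h = rho_air * c_p * C_h0 * (rh/100) * wind * (T_air - 0)``,
  with the transfer coefficient modulated multiplicatively by relative
  humidity.

Positive net energy melts at the latent heat of fusion; negative net energy
produces no melt (no cold content or refreezing is modelled).  Longwave,
latent and ground heat fluxes are deliberately excluded.  Running the model
twice — with the algal forcing and with it zeroed — attributes the melt
difference to the algae.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import WeatherError
from .forcing import IRFRegression, PAR_QUANTUM_TO_ENERGY, predict_irf

__all__ = [
    "PhysicalConstants",
    "WeatherSeries",
    "SurfaceParams",
    "MeltResult",
    "MeltUncertainty",
    "sensible_heat_flux",
    "shortwave_net",
    "melt_from_energy",
    "run_melt_model",
    "melt_uncertainty",
    "percent_contribution",
    "extrapolate_volume",
]

SNOW = "snow"
WEATHERING_CRUST = "weathering_crust"


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the energy-balance model (SI units)."""

    rho_air: float = 1.29  # air density, kg m-3
    cp_air: float = 1005.0  # specific heat of air, J kg-1 K-1
    ch0: float = 1.5e-3  # base bulk heat-transfer coefficient
    latent_heat_fusion: float = 3.34e5  # J kg-1
    water_density: float = 1000.0  # kg m-3
    par_conversion: float = PAR_QUANTUM_TO_ENERGY  # umol J-1
    surface_temp: float = 0.0  # degC, melting surface


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class WeatherSeries:
    """Regular (default 5-minute) weather-station records.

    Fields are aligned 1-D arrays: PAR (umol m-2 s-1, >= 0), air temperature
    (degC), wind speed (m s-1, >= 0) and relative humidity (%, 0-100).
    """

    timestamps: pd.DatetimeIndex
    par: np.ndarray
    air_temp: np.ndarray
    wind: np.ndarray
    rh: np.ndarray

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        object.__setattr__(self, "timestamps", ts)
        for name in ("par", "air_temp", "wind", "rh"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (len(ts),):
                raise WeatherError(f"{name} length does not match timestamps")
            if np.any(~np.isfinite(arr)):
                raise WeatherError(f"{name} contains missing/non-finite values")
        if len(ts) == 0:
            raise WeatherError("empty weather series")
        if len(ts) > 1:
            deltas = np.diff(ts.asi8) / 1e9
            if np.ptp(deltas) > 1e-6 or deltas[0] <= 0:
                raise WeatherError(
                    "weather series must have regular, positive time spacing"
                )
        if np.any(self.par < 0):
            raise WeatherError("PAR must be >= 0")
        if np.any(self.wind < 0):
            raise WeatherError("wind speed must be >= 0")
        if np.any((self.rh < 0) | (self.rh > 100)):
            raise WeatherError("relative humidity must lie in [0, 100] %")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def step_seconds(self) -> float:
        if len(self.timestamps) < 2:
            return 300.0
        return float((self.timestamps[1] - self.timestamps[0]).total_seconds())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "par_umol_m2_s": self.par,
                "air_temp_c": self.air_temp,
                "wind_m_s": self.wind,
                "rh_pct": self.rh,
            }
        )


@dataclass(frozen=True)
class SurfaceParams:
    """Bulk properties of the melting surface."""

    albedo: float  # broadband HDRF, (0, 1)
    density: float  # kg m-3
    label: str = SNOW

    def __post_init__(self) -> None:
        if not (0.0 < self.albedo < 1.0):
            raise ValueError("albedo must lie strictly in (0, 1)")
        if not (50.0 <= self.density <= 917.0):
            raise ValueError("surface density must lie in [50, 917] kg m-3")


@dataclass(frozen=True)
class MeltUncertainty:
    """Melt-attribution uncertainties, mm w.e. per model period."""

    residual_sd_mm: float
    density_sd_mm: float | None = None


@dataclass(frozen=True)
class MeltResult:
    """Per-step fluxes and melt for the algal and algae-free runs.

    ``steps`` columns: par, irradiance W m-2, algal_irf, shortwave_net_algal,
    shortwave_net_clean, sensible, melt_algal_mm, melt_clean_mm.
    Totals are sums over the full series (one day for a 288-step input).
    Surface lowering converts w.e. through the bulk surface density.
    """

    steps: pd.DataFrame
    total_melt_mm: float  # algal run
    clean_melt_mm: float  # algae-free run
    algal_melt_mm: float  # difference
    percent_contribution: float
    surface: SurfaceParams
    cell_density: float
    regression: IRFRegression
    weather: WeatherSeries
    constants: PhysicalConstants = DEFAULT_CONSTANTS
    algal_melt_sd_mm: float | None = None

    @property
    def lowering_mm(self) -> float:
        """Total surface lowering of the algal run, mm of surface material."""
        return self.total_melt_mm * self.constants.water_density / self.surface.density


def sensible_heat_flux(
    air_temp, wind, rh, constants: PhysicalConstants = DEFAULT_CONSTANTS
):
    """Bulk sensible heat flux into a melting surface, W m-2.

    ``Q_h = rho_air * c_p * C_h0 * (rh / 100) * wind * (T_air - T_surf)``
    with the surface held at 0 degC.  Negative for sub-zero air.  Accepts
    scalars or aligned arrays.
    """
    air_temp = np.asarray(air_temp, dtype=float)
    wind = np.asarray(wind, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(wind < 0):
        raise ValueError("wind speed must be >= 0")
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    q = (
        constants.rho_air
        * constants.cp_air
        * constants.ch0
        * (rh / 100.0)
        * wind
        * (air_temp - constants.surface_temp)
    )
    return float(q) if q.ndim == 0 else q


def shortwave_net(irr_total, albedo: float, algal_irf=0.0):
    """Net shortwave flux absorbed by the surface, W m-2.

    ``irr_total * (1 - albedo) + algal_irf``: the albedo-reduced PAR-derived
    irradiance plus the additional absorption attributed to algae.
    """
    if not (0.0 < albedo < 1.0):
        raise ValueError("albedo must lie strictly in (0, 1)")
    irr_total = np.asarray(irr_total, dtype=float)
    algal_irf = np.asarray(algal_irf, dtype=float)
    if np.any(irr_total < 0):
        raise ValueError("irradiance must be >= 0")
    if np.any(algal_irf < 0):
        raise ValueError("algal IRF entering the melt model must be >= 0")
    out = irr_total * (1.0 - albedo) + algal_irf
    return float(out) if out.ndim == 0 else out


def melt_from_energy(energy, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Meltwater equivalent (mm w.e.) from net surface energy (J m-2).

    Negative energy produces zero melt (no refreezing is modelled).  With
    water at 1000 kg m-3, 1 kg m-2 of melt is exactly 1 mm w.e.
    """
    energy = np.asarray(energy, dtype=float)
    out = np.maximum(energy, 0.0) / constants.latent_heat_fusion
    return float(out) if out.ndim == 0 else out


def _run(
    weather: WeatherSeries,
    surface: SurfaceParams,
    reg: IRFRegression,
    density: float,
    constants: PhysicalConstants,
    irf_offset: float = 0.0,
) -> pd.DataFrame:
    """One model pass; irf_offset shifts the reference-PAR IRF (error runs)."""
    dt = weather.step_seconds
    irr = weather.par / constants.par_conversion
    raw = reg.slope_a * np.log(density) + reg.intercept_b + irf_offset
    irf = np.maximum(raw * (weather.par / reg.reference_par), 0.0)
    qh = sensible_heat_flux(weather.air_temp, weather.wind, weather.rh, constants)
    sw_algal = shortwave_net(irr, surface.albedo, irf)
    sw_clean = shortwave_net(irr, surface.albedo, 0.0)
    melt_algal = melt_from_energy((sw_algal + qh) * dt, constants)
    melt_clean = melt_from_energy((sw_clean + qh) * dt, constants)
    return pd.DataFrame(
        {
            "timestamp": weather.timestamps,
            "par_umol_m2_s": weather.par,
            "irradiance_w_m2": irr,
            "algal_irf_w_m2": irf,
            "sensible_w_m2": qh,
            "shortwave_net_algal_w_m2": sw_algal,
            "shortwave_net_clean_w_m2": sw_clean,
            "melt_algal_mm": melt_algal,
            "melt_clean_mm": melt_clean,
        }
    )


def run_melt_model(
    weather: WeatherSeries,
    surface: SurfaceParams,
    reg: IRFRegression,
    density: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> MeltResult:
    """Run the energy-balance model with and without algal forcing.

    Parameters
    ----------
    weather : WeatherSeries
        Regular 5-minute (or other regular cadence) forcing series.
    surface : SurfaceParams
        Broadband albedo and bulk density of the melting surface.
    reg : IRFRegression
        Fitted density-IRF relation; its prediction at ``density`` is scaled
        with instantaneous PAR at every step and clamped at zero.
    density : float
        Algal cell density applied uniformly, cells ml-1, > 0.
    """
    if not density > 0:
        raise ValueError("cell density must be > 0")
    steps = _run(weather, surface, reg, density, constants)
    total = float(steps["melt_algal_mm"].sum())
    clean = float(steps["melt_clean_mm"].sum())
    algal = total - clean
    percent = 0.0 if total == 0 else 100.0 * algal / total
    return MeltResult(
        steps=steps,
        total_melt_mm=total,
        clean_melt_mm=clean,
        algal_melt_mm=algal,
        percent_contribution=percent,
        surface=surface,
        cell_density=density,
        regression=reg,
        weather=weather,
        constants=constants,
    )


def melt_uncertainty(
    result: MeltResult, density_sd: float | None = None
) -> MeltUncertainty:
    """Propagate regression scatter (and optionally density spread) to melt.

    The model is re-run with the reference-PAR IRF shifted by +/- one
    residual standard deviation of the density-IRF fit (the shift scales
    with PAR exactly like the IRF itself); the reported SD is half the
    spread of the algal melt between the two runs.  If ``density_sd`` is
    given, an analogous +/- one-SD density perturbation is reported
    separately (the low side is floored just above zero since density
    enters through its log).
    """
    reg = result.regression
    if reg.residual_sd < 0:
        raise ValueError("residual_sd must be >= 0")

    def algal_melt(irf_offset: float = 0.0, density: float | None = None) -> float:
        d = result.cell_density if density is None else density
        steps = _run(
            result.weather, result.surface, reg, d, result.constants, irf_offset
        )
        return float(steps["melt_algal_mm"].sum() - steps["melt_clean_mm"].sum())

    hi = algal_melt(irf_offset=+reg.residual_sd)
    lo = algal_melt(irf_offset=-reg.residual_sd)
    residual_sd_mm = 0.5 * (hi - lo)

    density_sd_mm = None
    if density_sd is not None:
        d_hi = result.cell_density + density_sd
        d_lo = max(result.cell_density - density_sd, 1.0)
        density_sd_mm = 0.5 * abs(algal_melt(density=d_hi) - algal_melt(density=d_lo))
    return MeltUncertainty(residual_sd_mm=residual_sd_mm, density_sd_mm=density_sd_mm)


def percent_contribution(algal_melt: float, total_melt: float) -> float:
    """Algal share of total melt, percent."""
    if not total_melt > 0:
        raise ValueError("total melt must be > 0")
    if not (0.0 <= algal_melt <= total_melt):
        raise ValueError("algal melt must lie in [0, total melt]")
    return 100.0 * algal_melt / total_melt


def extrapolate_volume(algal_melt_mm: float, area_km2: float) -> float:
    """Meltwater volume (litres) of a melt depth over a bloom area.

    1 mm w.e. over 1 m2 is 1 litre, so mm * km2 * 1e6 gives litres.
    """
    if area_km2 < 0:
        raise ValueError("area must be >= 0")
    return float(algal_melt_mm * area_km2 * 1e6)
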