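"""Seeded generators for every input the pipeline consumes.

The module emulates the statistical structure of field data from an
algae-bloomed ice cap without any radiative-transfer modelling:

* phenomenological snow and weathering-crust reflectance spectra — a bright
  visible plateau with a gentle tilt, a broad red reflectance maximum and a
  near-infrared absorption falloff; snow is constructed brighter than crust;
* an algal pigment signal subtracted from a base spectrum — a Gaussian
  chlorophyll-a dip at 680 nm, carotenoid absorption within 400-550 nm
  (strongest for red-cell communities) and a broadband VNIR quench for
  communities containing dark-pigmented *Ancylonema* — with depths growing
  as ``ln(1 + density / d0)``;
* paired density-IRF samples scattered about a log-linear relation, with the
  noise level calibrated analytically to a target coefficient of
  determination;
* diurnal weather series: a half-sine PAR curve over the daylight window
  normalised so the 24-h mean is exact, and a sinusoidal temperature cycle;
* labelled multiband scenes with an exactly-sized bloom mask.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcing import DensityIRFSample, ANCYLONEMA_PRESENT, RED_DOMINATED
from .mapping import BandDef, DEFAULT_BANDS, Scene
from .melt import WeatherSeries
from .spectra import Spectrum, band_reflectance

__all__ = [
    "PigmentModel",
    "make_surface_spectrum",
    "apply_algal_signal",
    "make_density_irf_dataset",
    "noise_sd_for_target_r2",
    "make_weather_series",
    "make_scene",
]

log = logging.getLogger("bioalbedo")

#: Wavelength grid of generated field spectra, nm (VNIR).
SPECTRUM_GRID = np.arange(350.0, 1000.5, 1.0)

SNOW = "snow"
WEATHERING_CRUST = "weathering_crust"

#: Published log-linear density-IRF coefficients used as generator defaults.
DEFAULT_SLOPE = 5.52
DEFAULT_INTERCEPT = -24.03
#: Observed density range (cells ml-1) spanned by the default IRF dataset.
DEFAULT_DENSITY_RANGE = (5e3, 1.4e6)
#: Variance fraction the log-linear relation explains in the field data.
DEFAULT_R_SQUARED = 0.41


@dataclass(frozen=True)
class PigmentModel:
    """Parameters of the subtractive algal pigment signal.

    Depths scale with ``ln(1 + density / d0)``; ``d0`` softens the response
    so densities near the detection floor (~5e3 cells ml-1) produce shallow
    dips.  ``broadband_quench`` is the extra flat VNIR darkening per unit
    ln-density applied when *Ancylonema* is present.
    """

    chl_center: float = 680.0  # nm
    chl_width: float = 12.0  # Gaussian sigma, nm
    carotenoid_band: tuple[float, float] = (400.0, 550.0)  # nm
    carotenoid_width: float = 37.5  # Gaussian sigma, nm
    depth_per_lndensity: float = 0.05
    carotenoid_ratio_red: float = 0.6  # carotenoid depth vs chl depth, red cells
    carotenoid_ratio_ancylonema: float = 0.3
    broadband_quench: float = 0.012  # per unit ln-density
    d0: float = 1e3  # density softening constant, cells ml-1

    def __post_init__(self) -> None:
        if self.chl_width <= 0 or self.carotenoid_width <= 0:
            raise ValueError("pigment feature widths must be > 0")
        if min(self.depth_per_lndensity, self.broadband_quench) < 0:
            raise ValueError("pigment depths must be >= 0")

    @property
    def carotenoid_center(self) -> float:
        return 0.5 * (self.carotenoid_band[0] + self.carotenoid_band[1])

    def depth_scale(self, density) -> np.ndarray:
        """Dimensionless ln(1 + density/d0) depth multiplier."""
        return np.log1p(np.asarray(density, dtype=float) / self.d0)


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def make_surface_spectrum(kind: str = SNOW, seed: int = 0) -> Spectrum:
    """A smooth parametric clean-surface reflectance spectrum on 350-1000 nm.

    Snow draws a bright plateau (~0.86), weathering crust a darker one
    (~0.55); both get a seeded downward tilt, a broad reflectance maximum in
    the red and a near-infrared absorption falloff.  Snow's broadband mean
    exceeds crust's for every seed by construction; identical seeds give
    bitwise-identical spectra.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(-1.0, 1.0, size=4)
    if kind == SNOW:
        level = 0.86 + 0.015 * u[0]
        tilt = 0.02 + 0.02 * u[1]
        nir_depth = 0.33 + 0.03 * u[2]
    elif kind == WEATHERING_CRUST:
        level = 0.55 + 0.02 * u[0]
        tilt = 0.015 + 0.015 * u[1]
        nir_depth = 0.24 + 0.02 * u[2]
    else:
        raise ValueError(f"unknown surface kind {kind!r}")
    red_bump = 0.05 + 0.01 * u[3]
    wl = SPECTRUM_GRID
    values = (
        level
        - tilt * (wl - wl[0]) / (wl[-1] - wl[0])
        + red_bump * _gauss(wl, 665.0, 60.0)
        - nir_depth * _gauss(wl, 1005.0, 165.0)
    )
    return Spectrum(wl, values, kind="reflectance")


def _pigment_features(pm: PigmentModel, community: str, wl: np.ndarray):
    """Unit pigment shapes (before the density depth scale) on grid ``wl``."""
    chl = pm.depth_per_lndensity * _gauss(wl, pm.chl_center, pm.chl_width)
    car_shape = _gauss(wl, pm.carotenoid_center, pm.carotenoid_width)
    if community == RED_DOMINATED:
        car = pm.carotenoid_ratio_red * pm.depth_per_lndensity * car_shape
        quench = np.zeros_like(wl)
    elif community == ANCYLONEMA_PRESENT:
        car = pm.carotenoid_ratio_ancylonema * pm.depth_per_lndensity * car_shape
        quench = np.full_like(wl, pm.broadband_quench)
    else:
        raise ValueError(f"unknown community {community!r}")
    return chl + car + quench


def apply_algal_signal(
    base: Spectrum,
    density: float,
    pm: PigmentModel | None = None,
    community: str = RED_DOMINATED,
    seed: int | None = None,
) -> Spectrum:
    """Darken a clean-surface spectrum with an algal pigment signal.

    Subtractive by construction (output <= base pointwise); density 0
    returns the base unchanged.  If the requested depth would drive any
    reflectance to or below zero, the depth is floored so the minimum stays
    just above zero and a warning is logged.  ``seed`` is accepted for
    interface symmetry; the signal itself is deterministic.
    """
    del seed  # deterministic; kept for generator interface symmetry
    if density < 0:
        raise ValueError("cell density must be >= 0")
    if pm is None:
        pm = PigmentModel()
    if density == 0:
        return base
    unit = _pigment_features(pm, community, base.wavelengths)
    scale = float(pm.depth_scale(density))
    dip = scale * unit
    headroom = base.values - 1e-3
    excess = dip > headroom
    if np.any(excess & (unit > 0)):
        limit = float(np.min(headroom[unit > 0] / unit[unit > 0]))
        log.warning(
            "DEPTHFLOOR: pigment depth floored (scale %.3g -> %.3g) to keep "
            "reflectance positive",
            scale,
            limit,
        )
        dip = min(scale, limit) * unit
    return Spectrum(base.wavelengths, base.values - dip, kind="reflectance")


def noise_sd_for_target_r2(
    slope: float = DEFAULT_SLOPE,
    density_range: tuple[float, float] = DEFAULT_DENSITY_RANGE,
    r_squared: float = DEFAULT_R_SQUARED,
) -> float:
    """Residual SD giving a population R^2 under log-uniform density sampling.

    With ln-density uniform over [ln lo, ln hi], the signal variance is
    ``slope^2 * span^2 / 12`` and ``R^2 = var_signal / (var_signal + sd^2)``,
    hence ``sd = |slope| * span / sqrt(12) * sqrt((1 - R^2) / R^2)``.
    """
    lo, hi = density_range
    span = np.log(hi / lo)
    if not (0 < r_squared < 1):
        raise ValueError("target r_squared must lie in (0, 1)")
    return float(abs(slope) * span / np.sqrt(12.0) * np.sqrt((1 - r_squared) / r_squared))


def make_density_irf_dataset(
    n: int = 41,
    a: float = DEFAULT_SLOPE,
    b: float = DEFAULT_INTERCEPT,
    noise_sd: float | None = None,
    density_range: tuple[float, float] = DEFAULT_DENSITY_RANGE,
    seed: int = 0,
) -> list[DensityIRFSample]:
    """Paired density-IRF samples scattered about ``a*ln(d) + b``.

    Densities are log-uniform over ``density_range`` (mirroring heavy-tailed
    field counts); Gaussian noise of SD ``noise_sd`` is added to the IRF.
    ``noise_sd=None`` selects the level that makes the log-linear relation
    explain ~41% of the variance, matching the field relationship.
    """
    if n < 3:
        raise ValueError("need n >= 3 samples")
    lo, hi = density_range
    if lo <= 0:
        raise ValueError("density_range lower bound must be > 0")
    if noise_sd is None:
        noise_sd = noise_sd_for_target_r2(a, density_range)
    rng = np.random.default_rng(seed)
    densities = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    irf = a * np.log(densities) + b + rng.normal(0.0, noise_sd, size=n)
    groups = rng.choice([RED_DOMINATED, ANCYLONEMA_PRESENT], size=n)
    return [
        DensityIRFSample(cell_density=float(d), irf=float(f), group_label=str(g))
        for d, f, g in zip(densities, irf, groups)
    ]


def make_weather_series(
    date: str = "2023-02-06",
    mean_par: float = 399.0,
    mean_temp: float = 2.42,
    daylight_hours: float = 16.0,
    wind: float = 8.0,
    rh: float = 85.0,
    temp_amplitude: float = 1.5,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> WeatherSeries:
    """One day of synthetic 5-minute weather records (288 steps).

    PAR follows a half-sine over a daylight window centred on local noon and
    is exactly zero at night; the curve is rescaled so the 24-h mean equals
    ``mean_par`` (to within float rounding).  Temperature is a sinusoid about
    ``mean_temp`` peaking mid-afternoon.  Optional multiplicative jitter on
    PAR is seeded and followed by a re-normalisation preserving the mean.
    Default means correspond to a bright summer day on a maritime Antarctic
    ice cap.
    """
    if mean_par < 0:
        raise ValueError("mean_par must be >= 0")
    if not (0 < daylight_hours <= 24):
        raise ValueError("daylight_hours must lie in (0, 24]")
    rng = np.random.default_rng(seed)
    timestamps = pd.date_range(start=date, periods=288, freq="5min")
    hours = np.arange(288) * 300.0 / 3600.0
    rise = 12.0 - daylight_hours / 2.0
    phase = (hours - rise) / daylight_hours
    par = np.where((phase > 0) & (phase < 1), np.sin(np.pi * phase), 0.0)
    if jitter_sd > 0:
        day = par > 0
        par[day] *= np.clip(1.0 + rng.normal(0.0, jitter_sd, day.sum()), 0.0, None)
    m = par.mean()
    par = par * (mean_par / m) if m > 0 else np.zeros_like(par)
    temp = mean_temp + temp_amplitude * np.cos(2 * np.pi * (hours - 15.0) / 24.0)
    return WeatherSeries(
        timestamps=timestamps,
        par=par,
        air_temp=temp,
        wind=np.full(288, float(wind)),
        rh=np.full(288, float(rh)),
    )


def _band_means(shape_values: np.ndarray, band_defs) -> np.ndarray:
    """Trapezoidal band means of a spectral shape defined on SPECTRUM_GRID."""
    s = Spectrum(SPECTRUM_GRID, np.asarray(shape_values, float), kind="radiance")
    return np.array([band_reflectance(s, b) for b in band_defs])


def make_scene(
    shape: tuple[int, int] = (60, 60),
    bloom_fraction: float = 0.2,
    density_range: tuple[float, float] = (1e4, 1e6),
    band_defs: tuple[BandDef, ...] = DEFAULT_BANDS,
    noise_sd: float = 0.0,
    pixel_size: float = 1.6,
    surface: str = WEATHERING_CRUST,
    pm: PigmentModel | None = None,
    invalid_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[Scene, np.ndarray]:
    """A labelled multiband scene with exactly ``round(fraction * pixels)``
    algae pixels.

    Each pixel's band values are the band-convolved clean-surface spectrum;
    algae pixels additionally carry the band-convolved pigment signal at a
    log-uniform density drawn from ``density_range`` (floored at 1e4 by
    default so the noiseless classification is not run at the numerical
    knife-edge) and a community drawn 50/50 red-dominated vs
    *Ancylonema*-containing.  Band convolution is linear, so the vectorised
    construction is exactly the per-pixel
    ``band_reflectance(apply_algal_signal(base, d))`` path.  Optional
    Gaussian band noise of SD ``noise_sd`` is added per pixel and band.

    Returns the scene and the ground-truth algae mask.
    """
    if not (0.0 <= bloom_fraction <= 1.0):
        raise ValueError("bloom_fraction must lie in [0, 1]")
    if pm is None:
        pm = PigmentModel()
    rng = np.random.default_rng(seed)
    rows, cols = shape
    n_pixels = rows * cols
    n_algae = int(round(bloom_fraction * n_pixels))

    base = make_surface_spectrum(surface, seed=int(rng.integers(2**31)))
    base_bands = _band_means(base.values, band_defs)
    unit_bands = {
        c: _band_means(_pigment_features(pm, c, SPECTRUM_GRID), band_defs)
        for c in (RED_DOMINATED, ANCYLONEMA_PRESENT)
    }

    grid = np.tile(base_bands[:, None], (1, n_pixels))
    truth = np.zeros(n_pixels, dtype=bool)
    algae_idx = rng.choice(n_pixels, size=n_algae, replace=False)
    truth[algae_idx] = True
    if n_algae:
        lo, hi = density_range
        dens = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_algae))
        comm = rng.choice([RED_DOMINATED, ANCYLONEMA_PRESENT], size=n_algae)
        scale = pm.depth_scale(dens)
        for c in (RED_DOMINATED, ANCYLONEMA_PRESENT):
            sel = comm == c
            if sel.any():
                grid[:, algae_idx[sel]] -= unit_bands[c][:, None] * scale[sel][None, :]
    if noise_sd > 0:
        grid = grid + rng.normal(0.0, noise_sd, size=grid.shape)
        grid = np.clip(grid, 0.0, None)

    validity = np.ones(n_pixels, dtype=bool)
    if invalid_fraction > 0:
        clean_idx = np.flatnonzero(~truth)
        n_invalid = min(int(round(invalid_fraction * n_pixels)), clean_idx.size)
        validity[rng.choice(clean_idx, size=n_invalid, replace=False)] = False

    scene = Scene(
        bands=tuple(band_defs),
        grid=grid.reshape(len(band_defs), rows, cols),
        pixel_size=pixel_size,
        validity_mask=validity.reshape(rows, cols),
    )
    return scene, truth.reshape(rows, cols)
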