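"""Instantaneous radiative forcing (IRF) of algal patches and its
relationship to cell density.

The IRF of a darkened patch is the extra radiative power it absorbs relative
to a clean reference surface, integrated over the photosynthetically active
range (400-700 nm):

    IRF = integral_400^700  E_e(lambda) * (rho_clean(lambda) - rho_algae(lambda)) dlambda

with E_e the downwelling spectral irradiance.  E_e is derived from a
broadband PAR measurement using the daylight quantum-to-energy conversion
4.57 umol J^-1 and is taken spectrally uniform over 400-700 nm, because a
quantum PAR sensor carries no spectral information.

Across sampled patches, IRF rises roughly linearly with the natural log of
algal cell density; that relation is captured by an ordinary least squares
fit ``IRF = a * ln(density) + b`` evaluated at a fixed reference PAR, and
predictions at other irradiances are scaled linearly in PAR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import CoverageError, RegressionError
from .spectra import Spectrum, resample

__all__ = [
    "PAR_QUANTUM_TO_ENERGY",
    "PAR_BAND_NM",
    "DEFAULT_REFERENCE_PAR",
    "IrradianceSpectral",
    "DensityIRFSample",
    "IRFRegression",
    "IRFDensityRegressor",
    "par_to_irradiance",
    "compute_irf",
    "fit_irf_density",
    "predict_irf",
]

#: Daylight quantum-to-energy conversion for PAR (umol photons per joule).
PAR_QUANTUM_TO_ENERGY = 4.57

#: Photosynthetically active range, nm.
PAR_BAND_NM = (400.0, 700.0)

#: Median daylight PAR during the field campaign, umol m-2 s-1; the density-IRF
#: regression is referenced to this irradiance.
DEFAULT_REFERENCE_PAR = 351.0


@dataclass(frozen=True)
class IrradianceSpectral:
    """Downwelling irradiance over 400-700 nm on the 1-nm working grid.

    ``total`` (W m-2) is by construction the trapezoidal integral of
    ``spectral_density`` (W m-2 nm-1) over the band.
    """

    wavelengths: np.ndarray
    spectral_density: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        dens = np.asarray(self.spectral_density, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "spectral_density", dens)
        if np.any(dens < 0):
            raise ValueError("spectral irradiance density must be >= 0")
        total = float(np.trapezoid(dens, wl))
        object.__setattr__(self, "_total", total)

    @property
    def total(self) -> float:
        """Band-integrated irradiance, W m-2."""
        return self._total


def par_to_irradiance(
    par: float, conversion: float = PAR_QUANTUM_TO_ENERGY
) -> IrradianceSpectral:
    """Convert a quantum PAR reading to spectrally uniform irradiance.

    Parameters
    ----------
    par : float
        PAR in umol photons m-2 s-1, >= 0.
    conversion : float
        Quantum-to-energy factor in umol J-1 (daylight default 4.57).
    """
    if par < 0:
        raise ValueError(f"PAR must be >= 0 (got {par:g})")
    lo, hi = PAR_BAND_NM
    wl = np.arange(lo, hi + 0.5, 1.0)
    total = par / conversion
    density = np.full(wl.shape, total / (hi - lo))
    return IrradianceSpectral(wl, density)


def compute_irf(
    clean: Spectrum, algal: Spectrum, irr: IrradianceSpectral
) -> float:
    """Instantaneous radiative forcing of an algal patch, W m-2.

    Trapezoidal integral over 400-700 nm of
    ``E_e(lambda) * (rho_clean - rho_algae)``.  The result may be negative if
    the algal patch is brighter than the reference; it is returned as-is
    (clamping is a melt-model concern).
    """
    lo, hi = float(irr.wavelengths[0]), float(irr.wavelengths[-1])
    for name, s in (("clean", clean), ("algal", algal)):
        if not s.covers(lo, hi):
            raise CoverageError(
                f"{name} spectrum [{s.wl_min:g}, {s.wl_max:g}] nm does not cover "
                f"the irradiance band [{lo:g}, {hi:g}] nm"
            )
    rho_clean = resample(clean, irr.wavelengths).values
    rho_algae = resample(algal, irr.wavelengths).values
    integrand = irr.spectral_density * (rho_clean - rho_algae)
    return float(np.trapezoid(integrand, irr.wavelengths))


# ---------------------------------------------------------------------------
# Density-IRF regression
# ---------------------------------------------------------------------------

RED_DOMINATED = "red_dominated"
ANCYLONEMA_PRESENT = "ancylonema_present"


@dataclass(frozen=True)
class DensityIRFSample:
    """One paired observation of algal cell density and measured IRF."""

    cell_density: float  # cells ml-1, > 0
    irf: float  # W m-2
    group_label: str = RED_DOMINATED

    def __post_init__(self) -> None:
        if not self.cell_density > 0:
            raise ValueError("cell_density must be > 0 (its log is taken)")


@dataclass(frozen=True)
class IRFRegression:
    """Fitted coefficients of ``IRF = a * ln(density) + b`` at a reference PAR."""

    slope_a: float  # W m-2 per unit ln(cells ml-1)
    intercept_b: float  # W m-2
    r_squared: float
    residual_sd: float  # W m-2, n-2 denominator
    reference_par: float = DEFAULT_REFERENCE_PAR
    n_samples: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if not self.reference_par > 0:
            raise ValueError("reference_par must be > 0")

    @property
    def detection_floor(self) -> float:
        """Density at which the regression crosses zero IRF, cells ml-1."""
        return float(np.exp(-self.intercept_b / self.slope_a))


class IRFDensityRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares of IRF on the natural log of cell density.

    scikit-learn style estimator: ``fit(X, y)`` with ``X`` the cell densities
    (cells ml-1, shape ``(n,)`` or ``(n, 1)``) and ``y`` the measured IRF
    (W m-2) at the reference irradiance.  ``predict(X, par=...)`` applies the
    fitted log-linear relation, scales it linearly with PAR relative to
    ``reference_par``, and clamps negative predictions to zero (algae are not
    modelled as brightening a surface).

    Attributes
    ----------
    slope_ : float
        Fitted slope a, W m-2 per unit ln(cells ml-1).
    intercept_ : float
        Fitted intercept b, W m-2.
    r_squared_ : float
        Coefficient of determination of the fit.
    residual_sd_ : float
        Residual standard deviation with n-2 denominator, W m-2.
    slope_stderr_ : float
        Standard error of the slope (for confidence intervals).
    """

    def __init__(self, reference_par: float = DEFAULT_REFERENCE_PAR):
        self.reference_par = reference_par

    @staticmethod
    def _as_density(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("X must be a 1-D density vector or an (n, 1) column")
        if np.any(x <= 0):
            raise ValueError("cell densities must be > 0 (their log is taken)")
        return x

    def fit(self, X, y):
        if not self.reference_par > 0:
            raise ValueError("reference_par must be > 0")
        density = self._as_density(X)
        y = np.asarray(y, dtype=float)
        if y.shape != density.shape:
            raise ValueError("X and y have mismatched lengths")
        if density.size < 3:
            raise RegressionError(
                f"need at least 3 samples to fit the density-IRF relation "
                f"(got {density.size})"
            )
        logd = np.log(density)
        if np.ptp(logd) == 0:
            raise RegressionError("all cell densities are equal — degenerate design")
        res = stats.linregress(logd, y)
        fitted = res.slope * logd + res.intercept
        sse = float(np.sum((y - fitted) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
        self.residual_sd_ = float(np.sqrt(sse / (density.size - 2)))
        self.slope_stderr_ = float(res.stderr)
        self.n_features_in_ = 1
        self.n_samples_ = int(density.size)
        return self

    def predict(self, X, par: float | np.ndarray | None = None) -> np.ndarray:
        check_is_fitted(self, "slope_")
        density = self._as_density(X)
        if par is None:
            par = self.reference_par
        par = np.asarray(par, dtype=float)
        if np.any(par < 0):
            raise ValueError("PAR must be >= 0")
        raw = self.slope_ * np.log(density) + self.intercept_
        return np.maximum(raw * (par / self.reference_par), 0.0)

    def slope_confint(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided (1-alpha) confidence interval for the slope."""
        check_is_fitted(self, "slope_")
        tcrit = stats.t.ppf(1 - alpha / 2, self.n_samples_ - 2)
        half = tcrit * self.slope_stderr_
        return self.slope_ - half, self.slope_ + half

    def to_regression(self) -> IRFRegression:
        check_is_fitted(self, "slope_")
        return IRFRegression(
            slope_a=self.slope_,
            intercept_b=self.intercept_,
            r_squared=self.r_squared_,
            residual_sd=self.residual_sd_,
            reference_par=self.reference_par,
            n_samples=self.n_samples_,
        )

    @classmethod
    def from_regression(cls, reg: IRFRegression) -> "IRFDensityRegressor":
        est = cls(reference_par=reg.reference_par)
        est.slope_ = reg.slope_a
        est.intercept_ = reg.intercept_b
        est.r_squared_ = reg.r_squared
        est.residual_sd_ = reg.residual_sd
        est.slope_stderr_ = float("nan")
        est.n_features_in_ = 1
        est.n_samples_ = reg.n_samples or 0
        return est


def fit_irf_density(
    samples: Sequence[DensityIRFSample],
    reference_par: float = DEFAULT_REFERENCE_PAR,
) -> IRFRegression:
    """OLS fit of IRF on ln(cell density) across paired samples.

    Pools both community groups (red-dominated and *Ancylonema*-containing)
    into a single regression; stratified fits can be obtained by filtering on
    ``group_label`` before calling.
    """
    densities = [s.cell_density for s in samples]
    irfs = [s.irf for s in samples]
    est = IRFDensityRegressor(reference_par=reference_par).fit(densities, irfs)
    return est.to_regression()


def predict_irf(density, reg: IRFRegression, par: float | None = None):
    """Predicted IRF (W m-2) at a given cell density and instantaneous PAR.

    The raw log-linear prediction is scaled by ``par / reference_par`` and
    clamped at zero from below.  ``par`` defaults to the regression's
    reference PAR.  Accepts scalar or array density/PAR.
    """
    est = IRFDensityRegressor.from_regression(reg)
    scalar = np.isscalar(density) and (par is None or np.isscalar(par))
    out = est.predict(np.atleast_1d(np.asarray(density, dtype=float)), par=par)
    return float(out[0]) if scalar and out.size == 1 else out
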