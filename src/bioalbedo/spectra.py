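"""Field-spectra handling: HDRF computation, resampling, band averaging.

Field spectroscopy of snow and ice surfaces records target radiance bracketed
by scans of a calibrated Spectralon reference panel.  The hemispherical
directional reflectance factor (HDRF) of the target is the ratio of target
radiance to the bracketing-mean panel radiance, scaled by the panel's
calibrated reflectance ``beta``:

    rho(lambda) = L_target(lambda) / mean(L_panel_before, L_panel_after) * beta(lambda)

All spectral arithmetic happens on a common 1-nm working grid; spectra on
instrument grids are linearly resampled onto it first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import CoverageError, GridMismatchError, PanelError, SpectrumError

__all__ = [
    "Spectrum",
    "PanelCalibration",
    "WORKING_GRID_STEP_NM",
    "working_grid",
    "compute_hdrf",
    "resample",
    "broadband_mean",
    "band_reflectance",
    "average_spectra",
]

#: Step of the common working grid all spectra are resampled to (nm).
WORKING_GRID_STEP_NM = 1.0

#: HDRF may mildly exceed 1 over bright snow; values beyond this cap are
#: treated as unit errors and rejected for reflectance-kind spectra.
REFLECTANCE_CAP = 1.5

RADIANCE = "radiance"
REFLECTANCE = "reflectance"
_KINDS = (RADIANCE, REFLECTANCE)


def working_grid(lo: float = 350.0, hi: float = 2500.0) -> np.ndarray:
    """Return the 1-nm working grid covering ``[lo, hi]`` inclusive."""
    return np.arange(lo, hi + 0.5 * WORKING_GRID_STEP_NM, WORKING_GRID_STEP_NM)


@dataclass(frozen=True)
class Spectrum:
    """A 1-D spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array-like of float
        Wavelengths in nm, strictly increasing, length >= 2.
    values : array-like of float
        Spectral values: dimensionless for ``kind="reflectance"`` (HDRF),
        instrument-proportional units for ``kind="radiance"``.
    kind : {"radiance", "reflectance"}
        Physical quantity carried by ``values``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = REFLECTANCE

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in _KINDS:
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise SpectrumError("wavelengths and values must be 1-D of equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least 2 samples")
        if not np.all(np.isfinite(wl)):
            raise SpectrumError("non-finite wavelength")
        if np.any(np.diff(wl) <= 0):
            bad = int(np.flatnonzero(np.diff(wl) <= 0)[0])
            raise SpectrumError(
                f"wavelengths must be strictly increasing "
                f"(violated between {wl[bad]:g} and {wl[bad + 1]:g} nm)"
            )
        if not np.all(np.isfinite(vals)):
            raise SpectrumError("non-finite spectral value")
        if self.kind == REFLECTANCE:
            if np.any(vals < 0):
                raise SpectrumError("reflectance values must be >= 0")
            if np.any(vals > REFLECTANCE_CAP):
                raise SpectrumError(
                    f"reflectance above {REFLECTANCE_CAP} — likely a unit error "
                    f"(max value {vals.max():g})"
                )

    # -- convenience ---------------------------------------------------
    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def wl_min(self) -> float:
        return float(self.wavelengths[0])

    @property
    def wl_max(self) -> float:
        return float(self.wavelengths[-1])

    def covers(self, lo: float, hi: float) -> bool:
        return self.wl_min <= lo and hi <= self.wl_max

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of values onto ``grid`` (no extrapolation check)."""
        return np.interp(np.asarray(grid, dtype=float), self.wavelengths, self.values)


@dataclass(frozen=True)
class PanelCalibration:
    """Per-wavelength calibrated reflectance ``beta`` of the reference panel.

    A nominal "98% Spectralon" panel corresponds to a constant beta of 0.98,
    which is the default when no per-wavelength calibration file is supplied.
    """

    calibration: Spectrum | None = None
    constant: float = 0.98

    def __post_init__(self) -> None:
        if self.calibration is not None:
            beta = self.calibration.values
            if np.any(beta <= 0) or np.any(beta > 1.1):
                raise SpectrumError("panel calibration beta must lie in (0, 1.1]")
        else:
            if not (0 < self.constant <= 1.1):
                raise SpectrumError("panel calibration beta must lie in (0, 1.1]")

    def beta(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        if self.calibration is None:
            return np.full(grid.shape, self.constant)
        if not self.calibration.covers(grid[0], grid[-1]):
            raise CoverageError(
                "panel calibration does not cover the target wavelength range"
            )
        return self.calibration.interp(grid)


def resample(s: Spectrum, grid: Sequence[float] | np.ndarray) -> Spectrum:
    """Linearly resample a spectrum onto ``grid``.

    ``grid`` must lie inside the spectrum's wavelength range; extrapolation is
    refused because instrument noise at the range edges makes it meaningless.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid[0] < s.wl_min or grid[-1] > s.wl_max):
        raise CoverageError(
            f"resample grid [{grid[0]:g}, {grid[-1]:g}] nm extends beyond the "
            f"data range [{s.wl_min:g}, {s.wl_max:g}] nm (no extrapolation)"
        )
    return Spectrum(grid, s.interp(grid), kind=s.kind)


def _common_grid(target: Spectrum, others: Iterable[Spectrum]) -> list[Spectrum]:
    """Resample ``others`` onto the target grid; error if coverage is short."""
    out = []
    for s in others:
        if np.array_equal(s.wavelengths, target.wavelengths):
            out.append(s)
            continue
        if not s.covers(target.wl_min, target.wl_max):
            raise GridMismatchError(
                f"spectrum on [{s.wl_min:g}, {s.wl_max:g}] nm cannot be resampled "
                f"onto the target grid [{target.wl_min:g}, {target.wl_max:g}] nm"
            )
        out.append(resample(s, target.wavelengths))
    return out


def compute_hdrf(
    target: Spectrum,
    panel_before: Spectrum,
    panel_after: Spectrum,
    cal: PanelCalibration | None = None,
) -> Spectrum:
    """HDRF of a target from its two bracketing reference-panel scans.

    The panel radiance assigned to the target is the arithmetic mean, per
    wavelength, of the scans taken before and after the target measurement.

    Raises
    ------
    PanelError
        If the bracketing-mean panel radiance is <= 0 at any wavelength (the
        message names the first offending wavelength).
    GridMismatchError
        If the panel/calibration spectra cannot be placed on the target grid.
    """
    if cal is None:
        cal = PanelCalibration()
    panel_before, panel_after = _common_grid(target, [panel_before, panel_after])
    panel = 0.5 * (panel_before.values + panel_after.values)
    if np.any(panel <= 0):
        wl = target.wavelengths[np.flatnonzero(panel <= 0)[0]]
        raise PanelError(
            f"mean panel radiance <= 0 at {wl:g} nm — cannot divide"
        )
    beta = cal.beta(target.wavelengths)
    rho = target.values / panel * beta
    return Spectrum(target.wavelengths, rho, kind=REFLECTANCE)


def _window_values(s: Spectrum, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Wavelengths/values restricted to [lo, hi], endpoints interpolated in."""
    if lo >= hi:
        raise SpectrumError(f"window bounds must satisfy lo < hi (got {lo:g} >= {hi:g})")
    if not s.covers(lo, hi):
        raise CoverageError(
            f"window [{lo:g}, {hi:g}] nm not covered by data "
            f"[{s.wl_min:g}, {s.wl_max:g}] nm"
        )
    inside = (s.wavelengths > lo) & (s.wavelengths < hi)
    wl = np.concatenate(([lo], s.wavelengths[inside], [hi]))
    vals = np.concatenate(([s.interp([lo])[0]], s.values[inside], [s.interp([hi])[0]]))
    return wl, vals


def broadband_mean(s: Spectrum, lo: float, hi: float) -> float:
    """Wavelength-weighted (trapezoidal) mean of a spectrum over ``[lo, hi]`` nm."""
    wl, vals = _window_values(s, lo, hi)
    return float(np.trapezoid(vals, wl) / (hi - lo))


def band_reflectance(s: Spectrum, band) -> float:
    """Boxcar (trapezoidal mean) reflectance of ``s`` over a sensor band.

    ``band`` is any object with ``lower`` and ``upper`` attributes in nm
    (e.g. :class:`bioalbedo.mapping.BandDef`).
    """
    return broadband_mean(s, float(band.lower), float(band.upper))


def average_spectra(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra sharing one grid and kind.

    Used for triplicate target scans; the default pipeline order averages the
    per-replicate HDRFs, but averaging radiances first is equally supported by
    calling this before :func:`compute_hdrf`.
    """
    if not spectra:
        raise SpectrumError("cannot average an empty list of spectra")
    first = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, first.wavelengths):
            raise GridMismatchError("replicate spectra must share one wavelength grid")
        if s.kind != first.kind:
            raise SpectrumError("replicate spectra must share one quantity kind")
    stack = np.vstack([s.values for s in spectra])
    return Spectrum(first.wavelengths, stack.mean(axis=0), kind=first.kind)
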