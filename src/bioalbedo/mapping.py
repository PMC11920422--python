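"""Multispectral bloom mapping via the scaled chlorophyll band-depth integral.

Glacier algae depress reflectance in the red through chlorophyll-a absorption
near 680 nm.  In a multispectral scene this appears as the centre band of a
yellow / red / red-edge triple sitting below the linear continuum spanned by
its neighbours.  The scaled Band-5 integral is the continuum-relative depth

    I_B5 = (C - R_B5) / C,
    C = (R_B4 * (l6 - l5) + R_B6 * (l5 - l4)) / (l6 - l4)

with l_n the band-centre wavelengths.  A pixel is classified as containing
algae iff I_B5 > 0 (strict).  Per-pixel cell-density estimation is
deliberately refused: band depth correlates too weakly with density to
support more than presence/absence, so maps are binary and carry the
documented detection floor (~5452 cells ml-1) only as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import SceneError

__all__ = [
    "BandDef",
    "Scene",
    "BloomMap",
    "ChlorophyllBandDepthClassifier",
    "DEFAULT_BANDS",
    "DETECTION_FLOOR_CELLS_PER_ML",
    "scaled_band_integral",
    "classify_scene",
    "bloom_extent",
]

#: Documented density floor of the band-depth detection method, cells ml-1.
#: Recorded as map metadata only; never used in computation.
DETECTION_FLOOR_CELLS_PER_ML = 5452.0


@dataclass(frozen=True)
class BandDef:
    """A sensor band: name, centre wavelength and band edges, nm."""

    name: str
    center: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower < self.center < self.upper):
            raise SceneError(
                f"band {self.name!r}: need lower < center < upper "
                f"(got {self.lower:g}, {self.center:g}, {self.upper:g})"
            )


#: Default yellow / red / red-edge triple (published WorldView-2 band centres).
DEFAULT_BANDS = (
    BandDef("B4", center=605.0, lower=585.0, upper=625.0),
    BandDef("B5", center=660.0, lower=630.0, upper=690.0),
    BandDef("B6", center=725.0, lower=705.0, upper=745.0),
)


@dataclass(frozen=True)
class Scene:
    """A multiband reflectance grid.

    ``grid`` has shape ``(n_bands, rows, cols)`` aligned with ``bands``;
    ``validity_mask`` marks usable pixels (e.g. the digitised ice-cap area).
    ``geo`` carries opaque georeferencing tags passed through untouched.
    """

    bands: tuple[BandDef, ...]
    grid: np.ndarray
    pixel_size: float  # m
    validity_mask: np.ndarray | None = None
    geo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "bands", tuple(self.bands))
        if grid.ndim != 3 or grid.shape[0] != len(self.bands):
            raise SceneError(
                f"grid must be (n_bands, rows, cols) with n_bands == "
                f"{len(self.bands)} (got shape {grid.shape})"
            )
        if len(self.bands) < 3:
            raise SceneError("a scene needs at least three bands")
        if not self.pixel_size > 0:
            raise SceneError("pixel_size must be > 0")
        if self.validity_mask is None:
            mask = np.ones(grid.shape[1:], dtype=bool)
        else:
            mask = np.asarray(self.validity_mask, dtype=bool)
            if mask.shape != grid.shape[1:]:
                raise SceneError("validity_mask shape does not match the grid")
        object.__setattr__(self, "validity_mask", mask)
        if np.any(grid[:, mask] < 0):
            raise SceneError("reflectance must be >= 0 on valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape[1:]

    def band(self, name: str) -> np.ndarray:
        for b, arr in zip(self.bands, self.grid):
            if b.name == name:
                return arr
        raise SceneError(
            f"scene has no band named {name!r} "
            f"(available: {[b.name for b in self.bands]})"
        )

    def band_def(self, name: str) -> BandDef:
        for b in self.bands:
            if b.name == name:
                return b
        raise SceneError(f"scene has no band named {name!r}")


@dataclass(frozen=True)
class BloomMap:
    """Binary algae presence map with per-pixel band depth and extent."""

    algae_mask: np.ndarray  # bool, True = algae
    i_b5: np.ndarray  # float, NaN where undefined/invalid
    extent_km2: float
    fraction: float
    pixel_size: float
    n_valid: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_algae(self) -> int:
        return int(self.algae_mask.sum())


def scaled_band_integral(r_b4, r_b5, r_b6, centers=(605.0, 660.0, 725.0)):
    """Continuum-relative depth of the centre band (scaled Band-5 integral).

    Positive iff ``r_b5`` lies below the linear continuum between the
    neighbouring bands.  Accepts scalars or arrays (elementwise).  Pixels
    with non-positive continuum are undefined and returned as NaN rather
    than raising.
    """
    l4, l5, l6 = (float(c) for c in centers)
    if not (l4 < l5 < l6):
        raise SceneError(f"band centres must be strictly increasing (got {centers})")
    r4 = np.asarray(r_b4, dtype=float)
    r5 = np.asarray(r_b5, dtype=float)
    r6 = np.asarray(r_b6, dtype=float)
    continuum = (r4 * (l6 - l5) + r6 * (l5 - l4)) / (l6 - l4)
    with np.errstate(divide="ignore", invalid="ignore"):
        depth = np.where(continuum > 0, (continuum - r5) / continuum, np.nan)
    if depth.ndim == 0:
        return float(depth)
    return depth


class ChlorophyllBandDepthClassifier(ClassifierMixin, BaseEstimator):
    """Binary algae presence classifier on (B4, B5, B6) band reflectances.

    A fixed-rule scikit-learn classifier: ``decision_function`` returns the
    scaled band-depth integral I_B5 and ``predict`` thresholds it strictly
    above ``threshold`` (default 0).  ``fit`` only records the class labels;
    there are no free parameters to estimate.
    """

    def __init__(self, centers=(605.0, 660.0, 725.0), threshold: float = 0.0):
        self.centers = centers
        self.threshold = threshold

    def fit(self, X=None, y=None):
        l4, l5, l6 = (float(c) for c in self.centers)
        if not (l4 < l5 < l6):
            raise SceneError(
                f"band centres must be strictly increasing (got {self.centers})"
            )
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 3
        return self

    @staticmethod
    def _as_bands(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim != 2 or x.shape[1] != 3:
            raise ValueError("X must have shape (n_pixels, 3): columns B4, B5, B6")
        return x

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        x = self._as_bands(X)
        return np.asarray(
            scaled_band_integral(x[:, 0], x[:, 1], x[:, 2], self.centers)
        )

    def predict(self, X) -> np.ndarray:
        depth = self.decision_function(X)
        # NaN (undefined continuum) compares False -> classified "no algae";
        # scene-level code excludes those pixels from counts entirely.
        with np.errstate(invalid="ignore"):
            return depth > self.threshold


def classify_scene(
    scene: Scene, band_names: tuple[str, str, str] = ("B4", "B5", "B6")
) -> BloomMap:
    """Classify every valid pixel of a scene and compute bloom extent.

    A pixel is algae-containing iff its band-depth integral is strictly
    positive.  Invalid pixels and pixels with a non-positive continuum are
    excluded from both the algae count and the valid-pixel denominator.
    """
    defs = tuple(scene.band_def(n) for n in band_names)
    arrs = tuple(scene.band(n) for n in band_names)
    centers = tuple(d.center for d in defs)
    depth = scaled_band_integral(arrs[0], arrs[1], arrs[2], centers)
    depth = np.where(scene.validity_mask, depth, np.nan)
    defined = scene.validity_mask & np.isfinite(depth)
    with np.errstate(invalid="ignore"):
        algae = defined & (depth > 0)
    n_valid = int(defined.sum())
    extent_km2, fraction = bloom_extent(algae, scene.pixel_size, n_valid)
    return BloomMap(
        algae_mask=algae,
        i_b5=depth,
        extent_km2=extent_km2,
        fraction=fraction,
        pixel_size=scene.pixel_size,
        n_valid=n_valid,
        metadata={
            "detection_floor_cells_per_ml": DETECTION_FLOOR_CELLS_PER_ML,
            "band_names": list(band_names),
            "band_centers_nm": list(centers),
            "n_undefined": int((scene.validity_mask & ~defined).sum()),
        },
    )


def bloom_extent(algae_mask, pixel_size: float, valid_count: int | None = None):
    """Bloom extent (km2) and areal fraction from a binary algae mask.

    ``valid_count`` defaults to the mask size; it must be > 0 since the
    fraction is undefined over an empty valid area.
    """
    if isinstance(algae_mask, BloomMap):
        mask = algae_mask.algae_mask
    else:
        mask = np.asarray(algae_mask, dtype=bool)
    if not pixel_size > 0:
        raise SceneError("pixel_size must be > 0")
    n_algae = int(mask.sum())
    if valid_count is None:
        valid_count = int(mask.size)
    if valid_count <= 0:
        raise SceneError("fraction undefined: zero valid pixels")
    if n_algae > valid_count:
        raise SceneError("algae count exceeds valid-pixel count")
    extent_km2 = n_algae * pixel_size**2 / 1e6
    return float(extent_km2), float(n_algae / valid_count)
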