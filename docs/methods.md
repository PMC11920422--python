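# Methods

## Reflectance processing

Field spectra are treated as hemispherical directional reflectance factors
(HDRF): the ratio of target radiance to the radiance of a calibrated
Spectralon reference panel, scaled by the panel's calibrated reflectance
β_λ. Because the panel is scanned immediately before and after each target,
the panel radiance assigned to a target is the **arithmetic mean per
wavelength** of the two bracketing scans; this choice (rather than, say,
time-weighted interpolation) is the package's own, made because bracketing
scans are seconds apart and illumination drift within a bracket is
unresolvable anyway. When no per-wavelength calibration is supplied, β is a
constant 0.98 (a nominal 98% panel).

All spectral arithmetic happens on a **1-nm working grid**; instrument grids
are linearly resampled onto it first, and extrapolation beyond the recorded
range is refused. Reflectance values are validated to [0, 1.5]: HDRF over
bright snow can mildly exceed 1, but values beyond 1.5 indicate unit errors.
Replicate target scans are averaged **after** HDRF computation by default
(averaging radiances first is also exposed); with stable panel brackets the
two orders differ only at rounding level.

Broadband and band reflectances are trapezoidal means over a window, with
window endpoints interpolated in, so a window not aligned to the grid is
still handled exactly for piecewise-linear data.

## Irradiance and radiative forcing

A quantum PAR reading (µmol photons m⁻² s⁻¹) is converted to energy with the
daylight constant **4.57 µmol J⁻¹** and spread **uniformly** over
400–700 nm (total/300 per nm). A broadband quantum sensor carries no
spectral shape; a uniform density is the assumption-free choice and, because
the forcing integral is linear in E_e, any fixed shape with the same total
would change patch IRF only through its covariance with the reflectance
difference.

IRF is the trapezoidal integral over 400–700 nm of
`E_e(λ)·(ρ_clean − ρ_algae)`. It is signed: a patch brighter than the
reference yields negative forcing, which is reported as-is at this layer and
clamped only where it enters the melt model.

Numerically, the 1-nm trapezoid agrees with a 0.01-nm brute-force quadrature
to ~1e-15 relative for Gaussian absorption features that decay to negligible
amplitude at the integration limits. Features truncated at 400 or 700 nm
leave a boundary (Euler–Maclaurin) term of order 1e-4 relative at 1-nm
sampling; the numerical-equivalence test suite therefore draws its dip
centres in 480–640 nm with σ ≤ 10 nm, which is a property of the check, not
of the physics.

## Density–IRF regression

Across patches, IRF rises approximately linearly in ln(cell density). The
relation `IRF = a·ln(d) + b` is fitted by ordinary least squares
(`scipy.stats.linregress` inside a scikit-learn estimator), pooling the
red-cell-dominated and *Ancylonema*-containing communities into a single
fit; group labels are retained for optional stratified fits. Reported
diagnostics: R², residual SD with n−2 denominator, and the slope's standard
error for confidence intervals.

The regression is anchored to a **reference PAR** (default 351 µmol m⁻² s⁻¹,
a field median of daylight conditions). Predictions at other irradiance are
scaled **linearly in PAR** relative to that reference — radiative forcing is
proportional to incident flux for fixed spectral contrast — and clamped at
zero from below, since biological brightening is not modelled and the
log-linear form is not evaluated below its zero crossing (~5.4 × 10³
cells ml⁻¹ for the default coefficients). At PAR = 0 the prediction is 0.

## Bloom mapping

A multiband scene is classified per pixel with the scaled band-depth
integral of the centre (red) band of a yellow / red / red-edge triple:
`I_B5 = (C − R_B5)/C` with `C` the linear continuum between the outer bands
evaluated at the centre band's wavelength. Chlorophyll-a absorption near
680 nm depresses the red band below the continuum, so `I_B5 > 0` (strict)
marks an algae-containing pixel. Default band centres are 605/660/725 nm
(published WorldView-2 yellow/red/red-edge centres); they are configurable
because other sensors place the triple differently.

The map is deliberately **binary**. Band depth correlates too weakly with
cell density to support per-pixel density estimates, so none are made; the
approximate detection floor (5452 cells ml⁻¹) travels as map metadata only.
Pixels with a non-positive continuum are undefined and excluded from both
the algae count and the valid-pixel denominator. Extent is
`n_algae · pixel_size² / 10⁶` km² (default pixel 1.6 m); the areal fraction
uses the defined-and-valid pixel count.

Raster I/O uses multiband float TIFF via `tifffile`, with band definitions
and pixel size in a JSON ImageDescription and GeoTIFF georeferencing tags
passed through untouched; masks are byte rasters (1 algae / 0 clean /
255 invalid). Full CRS-aware geospatial handling is out of scope.

## Energy-balance melt model

A deliberately minimal two-flux model at a melting surface, per 5-minute
step:

* net shortwave `E_sw = (PAR/4.57)·(1 − α) + IRF(density, PAR_t)`, with α
  the broadband surface albedo;
* bulk sensible heat `Q_h = ρ_air·c_p·C_h0·(rh/100)·u·(T_air − 0 °C)`, with
  ρ_air = 1.29 kg m⁻³, c_p = 1005 J kg⁻¹ K⁻¹ and C_h0 = 1.5 × 10⁻³. The
  multiplicative rh/100 modulation of the transfer coefficient is a simple,
  configurable stand-in for humidity dependence of turbulent exchange over
  melting snow.

Longwave, latent and ground fluxes are excluded by design. The surface is
pinned at 0 °C; positive net energy melts at L_f = 3.34 × 10⁵ J kg⁻¹ and
negative net energy produces no melt (no cold content, no refreezing), so
melt per step is `max(E_net, 0)·Δt / L_f` in mm w.e. Energy closure
(Σ melt·L_f = Σ max(E_net,0)·Δt) and additivity over split series hold
exactly by construction. All constants live in the run configuration, none
at call sites. An auxiliary output converts w.e. to surface lowering via the
bulk density of the surface material, since that conversion is the ambiguous
step when comparing melt "depths" between snow and crust.

The **algal attribution** is the difference between a run with the
density-IRF forcing (at one uniform cell density, default the observed mean
2.5 × 10⁵ cells ml⁻¹) and a run with it zeroed. Uncertainty re-runs the
model with the reference-PAR IRF shifted by ±1 residual SD of the
regression (the shift scales with PAR exactly like the IRF); the reported
SD is half the spread of the algal melt, which reduces to
`residual_sd·(PAR/ref)·Δt/L_f` summed over steps when nothing clamps. A
separate ±1 SD cell-density perturbation is available because density
spread and regression scatter are different error sources and should not be
merged silently. Meltwater volume over a bloom is `mm × km² × 10⁶` litres.

Under the default coefficients the predicted forcing at the mean density
(≈ 44.6 W m⁻² at the reference PAR) is a large fraction of a bright day's
albedo-reduced shortwave, so percentage contributions on synthetic days are
tens of percent; the model reports exactly what its inputs imply.

## Synthetic data

The generators emulate the statistical structure of field data, not its
physics — no radiative-transfer snow optics.

* **Surface spectra** (350–1000 nm): a visible plateau (snow ~0.86, crust
  ~0.55), a gentle seeded downward tilt, a broad reflectance maximum near
  665 nm and a Gaussian near-infrared falloff centred at 1005 nm. Snow's
  broadband mean exceeds crust's for every seed by construction. The red
  maximum plus NIR falloff make clean surfaces slightly **convex-up** across
  the classifier's band triple, so clean pixels sit strictly below the
  detection threshold rather than at it.
* **Algal signal**: subtractive features whose depths grow as
  `ln(1 + d/d0)` with d0 = 10³ cells ml⁻¹ (so densities near the detection
  floor give shallow dips): a chlorophyll-a Gaussian dip at 680 nm
  (σ = 12 nm, 0.05 per unit ln-density), carotenoid absorption centred in
  the 400–550 nm band (stronger for red-cell communities), and a flat VNIR
  quench (0.012 per unit ln-density) when *Ancylonema* is present. Depths
  are floored with a logged warning if they would drive reflectance to zero.
* **Density–IRF datasets**: densities log-uniform over 5 × 10³–1.4 × 10⁶
  cells ml⁻¹ (mirroring heavy-tailed field counts, mean 2.5 × 10⁵ with SD
  2.7 × 10⁵), IRF on the line a = 5.52, b = −24.03 plus Gaussian noise. The
  default noise SD (≈ 10.8 W m⁻²) is derived in closed form so the relation
  explains ~41% of variance, the level observed in the field data.
* **Weather**: 288 five-minute steps; PAR a half-sine over a 16-h daylight
  window (typical of a maritime Antarctic February) rescaled so the 24-h
  mean is exact and nights are exactly zero; temperature a ±1.5 °C sinusoid
  peaking mid-afternoon; wind 8 m s⁻¹ and rh 85% constant by default
  (windy, humid maritime conditions). Day defaults 399 µmol m⁻² s⁻¹ and
  2.42 °C, a bright field day.
* **Scenes**: one base surface spectrum per scene, band-convolved; exactly
  `round(fraction · pixels)` algae pixels at log-uniform densities ≥ 10⁴
  cells ml⁻¹ (keeping the noiseless classifier test off the numerical
  knife-edge) with 50/50 community draws; optional per-band Gaussian noise.
  Band convolution is linear, so the vectorised construction is exactly the
  per-pixel spectrum route.

Every generator is a pure function of its arguments including the seed.

**What passing tests do and do not show.** The generators have a single base
spectrum per scene, no mixed pixels, no mineral dust, no spatial
autocorrelation, and noise that is independent per band and pixel; real
scenes violate all of these (dust in particular can mimic or mask the
chlorophyll signal). Recovery results on synthetic scenes therefore
demonstrate correctness of the algorithms, not field-accuracy of the
classification.

## Numerical and design notes

* OLS via `scipy.stats.linregress`; an independent statsmodels OLS serves as
  a cross-check in the test suite only.
* Strict inequality at the classification threshold means exactly-collinear
  bands are "no algae"; undefined-continuum pixels are excluded from counts
  entirely rather than defaulted.
* Weather ingestion enforces a regular cadence; gaps of ≤ 2 steps are filled
  by linear interpolation with a machine-greppable `GAPFILL` warning, longer
  gaps are an error.
* Melt percentages are invariant to discretisation for smooth forcing
  (5-min vs 1-min agree to < 0.1%).
* Problem sizes in the test and acceptance runs (40×40–100×100 scenes,
  100–200 replicates, single synthetic days) were chosen as the smallest
  sizes at which the statistical checks are stable; all complete in seconds.

## Known limitations

* No albedo (cosine-collector) computation: HDRF is directional, and the
  melt model uses broadband HDRF as a stand-in for albedo.
* No atmospheric correction, no diffuse/direct partitioning, no spectral
  shape for E_e.
* Shortwave energy is PAR-band only; near-infrared irradiance absorption is
  not represented, so absolute melt totals underestimate full-spectrum
  forcing while the *algal* attribution (a 400–700 nm effect) is less
  affected.
* One cell density and one surface per melt run; no distributed modelling.
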