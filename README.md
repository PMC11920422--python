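# bioalbedo

Analysis toolkit for the **bioalbedo effect** of glacier-algae blooms: how
photosynthetic microorganisms (red snow algae, dark-pigmented *Ancylonema*)
darken snow and ice surfaces and thereby enhance melt.

It is written for cryosphere field scientists who collect ground spectra,
weather-station records and multispectral imagery over bloomed ice and want a
tested, reproducible pipeline from raw scans to "how much melt did the algae
cause".

## What it computes

1. **HDRF** — hemispherical directional reflectance factors from target
   radiance scans bracketed by calibrated Spectralon panel scans:
   `ρ_λ = L_target / mean(L_panel_before, L_panel_after) · β_λ`.
2. **Instantaneous radiative forcing (IRF)** of an algal patch, the extra
   power it absorbs relative to clean snow/ice,
   `IRF = ∫₄₀₀⁷⁰⁰ E_e(λ) (ρ_clean − ρ_algae) dλ` (W m⁻²), with E_e derived
   from a quantum PAR reading at 4.57 µmol J⁻¹ and taken spectrally uniform.
3. **Density–IRF regression** — ordinary least squares of IRF on the natural
   log of cell density, `IRF = a·ln(density) + b` at a reference PAR, as a
   scikit-learn estimator (`IRFDensityRegressor`).
4. **Bloom mapping** — per-pixel chlorophyll band-depth classification of
   multiband scenes: a pixel contains algae iff its centre (red) band sits
   strictly below the linear continuum between the yellow and red-edge bands
   (`I_B5 = (C − R_B5)/C > 0`), plus bloom extent in km².
5. **Melt attribution** — a 5-minute energy-balance model (net shortwave +
   bulk sensible heat over a 0 °C surface) run with and without the algal
   forcing; the difference is the algal melt, with uncertainty propagated
   from the regression's residual scatter.
6. **Synthetic data** — seeded generators for all of the above inputs
   (parametric snow/crust spectra with chlorophyll and carotenoid features,
   scattered density–IRF datasets, diurnal weather, labelled scenes), so the
   entire pipeline is testable without field data.

## Worked example

```python
import bioalbedo as ba

# the field density-IRF relation at the campaign's median daylight PAR
reg = ba.IRFRegression(slope_a=5.52, intercept_b=-24.03,
                       r_squared=0.41, residual_sd=10.77, reference_par=351.0)
print(ba.predict_irf(2.5e5, reg, par=351.0))   # 44.57927340658098 W m-2

# a synthetic sunny summer day, weathering-crust surface, mean cell density
weather = ba.make_weather_series(mean_par=399.0, mean_temp=2.42, seed=0)
crust = ba.SurfaceParams(albedo=0.55, density=500.0, label="weathering_crust")
result = ba.run_melt_model(weather, crust, reg, density=2.5e5)
print(round(result.total_melt_mm, 2))          # 31.55 mm w.e. (algal run)
print(round(result.algal_melt_mm, 2))          # 13.11 mm w.e. from algae
print(round(result.percent_contribution, 1))   # 41.5 %

# a labelled synthetic scene, classified back
scene, truth = ba.make_scene(shape=(100, 100), bloom_fraction=0.2, seed=1)
bloom = ba.classify_scene(scene)
print(bloom.fraction, bloom.extent_km2)        # 0.2 0.00512 (km2 at 1.6 m pixels)
```

The first number is the regression evaluated at the mean observed density
(2.5 × 10⁵ cells ml⁻¹). The melt run shows algal forcing at that density more
than doubling a crust surface's shortwave absorption on a bright day. The
scene round-trip shows the band-depth classifier recovering a noiseless
synthetic bloom mask exactly.

A command-line interface mirrors the library (`bioalbedo hdrf | irf | fit |
classify | melt | simulate ...`); every run writes a metadata sidecar from
which it can be reproduced.

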