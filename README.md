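# defocarb

**Biophysical carbon cost of tropical deforestation.**

Deforestation removes carbon directly, but it also changes the regional
climate: less evapotranspiration and surface roughness mean warming and, in
the tropics, less rainfall. Remaining forests then grow under hotter, drier
conditions and store less aboveground biomass (AGB). `defocarb` estimates
this *biophysical* carbon cost — the extra AGB loss in forests that were not
cleared — and compares it with the direct loss of the cleared biomass. It is
aimed at carbon-cycle and land-use researchers who work with multimodel
deforestation experiments and gridded biomass/climate observations, and at
anyone quantifying the additionality of avoided-deforestation projects.

## Method

1. **Climate response.** For each Earth system model, the deforestation
   signal is the last-30-year mean of the deforested run minus the control
   run: ΔT (°C) and ΔP. Relative rainfall change is taken against each
   model's own control climatology (so model rainfall biases divide out) and
   converted to mm yr⁻¹ with the *observed* climatology:
   ΔP_mm = (ΔP_rel/100)·P_obs. The ensemble summary carries the multimodel
   mean, cross-model SD (ddof = 1) and a sign-agreement count per cell
   (robust where ≥ 6 of 8 models agree).
2. **AGB–climate sensitivity.** A spatial regression across tropical 1° land
   cells (|lat| ≤ 23°, MAP ≥ 100 mm yr⁻¹, land fraction ≥ 0.5),

       AGB = intercept + a·MAP + b·MAT + ε,

   fitted globally and inside moving rainfall windows of ±500 mm yr⁻¹
   centered at each level from 600 to 3100 mm yr⁻¹. A window is significant
   when both climate coefficients have two-sided *P* < 0.001; the wettest
   windows lose significance (biomass saturates at high rainfall) and
   contribute zero sensitivity.
3. **Carbon cost.** Each cell's sensitivities (s_P, s_T) are interpolated
   from the curve at its background rainfall (climatology adjusted by the
   deforestation-induced relative change); the biophysical AGB change is
   ΔAGB = s_P·ΔP_mm + s_T·ΔT. The direct loss is the tree-cover change
   times the observed tree-cover/AGB slope (~20 Mg C ha⁻¹ per 10 % cover),
   and the percent additionality is 100·ΔAGB_biophys/ΔAGB_direct.
   Uncertainty is propagated in quadrature:
   σ = sqrt((a·σ_ΔP)² + (b·σ_ΔT)²).
4. **Feedback and history.** The deforestation-driven carbon–climate
   feedback parameter γ = ΔC_AGB/ΔT (Mg C ha⁻¹ °C⁻¹) is compared with the
   CO₂-driven γ = (ΔC′ − ΔC*)/ΔT′ from fully coupled vs
   biogeochemistry-only CO₂-ramp experiments. Historical attribution scales
   the idealized-experiment deltas linearly by the 1850–2015 primary-forest
   loss fraction and prices them with the observational sensitivity.

A synthetic-data module generates observation-like grids and a pseudo
multimodel ensemble with exactly the statistical structure the analysis
relies on, so the full pipeline runs and is tested offline; real gridded
data in CF-style NetCDF (fields named `MAP`, `MAT`, `AGB`, `tree_cover`,
`land_fraction`, run series `P`, `T`) can be substituted at any stage.

## Worked example

```python
import defocarb as dc

cfg = dc.SyntheticConfig(seed=0)
bundle = dc.generate_observation_bundle(cfg)
model = dc.AGBClimateModel.from_bundle(bundle, max_map=cfg.saturation_map)
print(model.fit().summary())
```

```
AGB ~ MAP + MAT spatial regression
n_cells = 4068   R2 = 0.924   RMSE = 6.12 Mg C ha-1
term                                      coef        se           p
a*100 (Mg C ha-1 / 100 mm yr-1)         3.3978    0.0174           0
b (Mg C ha-1 / degC)                   -0.3194    0.0340    9.55e-21
intercept = 19.902 Mg C ha-1
delta_MAP = 5.53 % / 100 mm yr-1   delta_MAT = -0.52 % / degC
```

The fit recovers the configured tropical sensitivities (AGB rises
3.4 Mg C ha⁻¹ per 100 mm yr⁻¹ of rainfall and falls 0.32 Mg C ha⁻¹ per °C)
within their standard errors. Running every stage,

```python
out = dc.run_all(dc.PipelineConfig(outdir="run0", seed=0))
```

writes the delta maps, sensitivity curve, regional summary and feedback
tables. The regional summary for seed 0 reads (losses negative, ± one SD):

```
       region  dp_rel   dp_mm    dt  direct  biophys  pct  pct_sd
       amazon   -5.54 -111.07  0.57  -88.27    -3.42 3.87    3.08
        congo   -3.61  -56.18  0.04  -57.79    -1.91 3.30    2.45
tropical_asia   -0.87  -22.14 -0.17  -45.00    -0.20 0.45    2.95
```

i.e. in the Amazon-analog region deforestation-driven drying (−111 mm yr⁻¹)
and warming (+0.6 °C) cost an extra 3.4 Mg C ha⁻¹ on top of the 88 Mg C ha⁻¹
cleared — a 3.9 % additionality, within the 1.4–8.8 % range expected for
this region; the wet tropical-Asia analog shows essentially none because its
background rainfall sits in the saturated, insensitive regime. The same
stages are available from a shell as `defocarb synth | climate |
sensitivity | cost | history | all`.

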