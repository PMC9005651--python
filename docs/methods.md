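# Methods

## The estimator

The quantity of interest is the *biophysical* AGB change of deforestation:
the carbon that remaining forests fail to store because deforestation made
the regional climate hotter and drier. It is built from two independent
ingredients:

1. a multimodel estimate of the deforestation-induced climate change
   (ΔP, ΔT), taken as last-30-year means of paired deforested/control runs;
2. an observational estimate of how AGB varies with mean annual
   precipitation (MAP) and temperature (MAT) across space,
   AGB = intercept + a·MAP + b·MAT + ε, fitted by OLS both globally and in
   overlapping ±500 mm yr⁻¹ rainfall windows centered at 600…3100 mm yr⁻¹.

The space-for-time substitution in (2) is the key assumption: the spatial
climate–biomass gradient is read as the long-term equilibrium response of
biomass to a changed climate. It inherits everything that covaries with
climate across space (fire regime, soils, land use) and says nothing about
transient dynamics; the moving window softens it by letting the sensitivity
depend on the local rainfall regime.

Per cell, ΔAGB = s_P·ΔP_mm + s_T·ΔT, with (s_P, s_T) interpolated from the
window curve at the cell's *background* rainfall — the observed climatology
adjusted by the deforestation-induced relative change. Windows whose fit is
not jointly significant (two-sided P < 0.001 on both climate coefficients)
contribute zero sensitivity: where biomass has saturated in rainfall, no
loss is attributed. This is deliberately conservative and is what produces
zero predicted loss in the wettest regions.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| averaging window | 30 | yr | run-pair delta estimator |
| window levels | 600–3100 step 100 | mm yr⁻¹ | sensitivity curve support |
| window half-width | 500 | mm yr⁻¹ | bias/variance of local fits |
| significance alpha | 0.001 | – | joint two-sided t-tests, no correction |
| min cells per window | 30 | – | below this a window is flagged |
| agreement fraction | 0.75 | – | robust-sign mask (6 of 8 models) |
| γ warming threshold | 0.1 | °C | masks tiny denominators in γ maps |
| domain filters | MAP ≥ 100, land ≥ 0.5, lat ≤ 23° | – | analysis cell set |

Design choices where the procedure was genuinely open:

* **Intercept.** The regression includes an intercept (configurable). A
  no-intercept fit would make R² non-comparable across models and inflate
  the climate coefficients.
* **Weighting.** Regression cells are unweighted; regional statistics are
  cos(latitude) area-weighted. Near the equator the distinction is almost
  neutral.
* **Cross-model SD** uses ddof = 1, computed on per-model *regional means*
  (not cellwise SDs averaged), which is the construction the quadrature
  propagation needs. The mm yr⁻¹ rainfall SD is taken across per-model
  products of relative change with the observed climatology.
* **Zero deltas** count as agreeing with neither sign in the agreement
  tally — with a finite ensemble this can only lower agreement.
* **Regional additionality** divides the regional-mean biophysical loss by
  the regional-mean direct loss (not the mean of cellwise ratios), so the
  printed regional pairs reproduce it exactly.
* **Regional direct loss** uses a region-specific tree-cover/AGB slope
  fitted within the region; the global ~19–22 Mg C ha⁻¹ per 10 % band is a
  sanity check, not the estimator.
* **Historical warming term.** The global temperature coefficient
  (b = −0.32) makes the scaled Amazon warming a small loss
  (−0.041 Mg C ha⁻¹), while the window-local coefficient at Amazon
  background rainfall makes it a small gain (+0.04 Mg C ha⁻¹). Both
  variants are computed and stored on the scenario record; the headline
  total uses the window-local variant, which is the one consistent with the
  published basin total the package reproduces (≈ 743 Tg C). The two differ
  by ~6 % of the total — the rainfall term dominates either way.
* **γ regionalisation.** Regional γ is (regional ΔC)/(regional ΔT), not the
  mean of cellwise ratios, which would be dominated by near-zero warming
  cells even after masking.

## The synthetic world

The generator reproduces the statistical structure the analysis exploits —
nothing more. On a 1° grid inside 23°S–23°N, three idealized land bands
("south_america", "africa", "asia") carry linear west–east rainfall ramps
(300–3300, 200–2600, 1800–3400 mm yr⁻¹) modulated by latitude, with ~5200
analysis cells after filtering. Within them sit an Amazon-analog box
(climatology ≈ 2000 mm yr⁻¹, partly saturated in the east), a Congo-analog
box (≈ 1550 mm yr⁻¹) and the 10°S–10°N, 95°E–155°E tropical-Asia box
(mostly saturated).

* **AGB**: intercept 20 + 0.034·MAP − 0.32·MAT (Mg C ha⁻¹), blended toward
  a constant over 2400–2700 mm yr⁻¹ so both climate slopes vanish in the
  wet regime; Gaussian noise with SD 6 Mg C ha⁻¹ in the linear regime
  rising to 14 in the saturated regime (mimicking radar-retrieval
  saturation error at high biomass); clipped at zero. The intercept and
  noise scale are chosen so the zero clip essentially never binds inside
  the analysis domain — the refit is then unbiased and 2-SE coverage of the
  injected coefficients is nominal. A consequence of that choice is a
  cleaner world than reality (R² ≈ 0.92 vs ~0.5, relative sensitivity
  δ_MAP ≈ 5.5 %/100 mm vs ~8 %): real dry-land biomass sits near zero,
  which a strictly linear unclipped surface cannot produce.
* **MAT** = 22 + 7·(1 − MAP-normalised) plus noise of SD 2.0 (wet) to 3.5
  (dry) °C: anticorrelated with MAP, more variable where dry.
* **Tree cover** = 0.95·(1 − exp(−MAP/1200)) plus 1 pp noise: monotone and
  saturating in MAP; the implied AGB/cover slope in the wet-region boxes is
  ~19–22 Mg C ha⁻¹ per 10 % cover.
* **Ensemble**: per model and region, (ΔP_rel %, ΔT °C, Δcover pp) are
  drawn from Normal(mean, SD) distributions whose defaults are the
  published eight-model regional statistics (e.g. Amazon −6.7 ± 4.7 %,
  +0.5 ± 0.5 °C, −44.7 ± 6.0 pp); the response is applied uniformly over
  the region box on top of the shared control climatology, with 4 %
  interannual rainfall noise and 0.3 °C temperature noise so the windowed
  delta estimator is exercised. Runs are 35 years — only the last-30 mean
  enters the estimator. One RNG stream per model member is derived from
  the master seed, so adding members never perturbs earlier ones.
* **CO₂-ramp pseudo-experiment**: 140-year pairs sharing a fertilization
  trend; only the coupled run warms (3.5 ± 0.5 °C at ramp end across
  models) and responds with injected regional feedbacks of −2.5 / −1.2 /
  −0.6 Mg C ha⁻¹ °C⁻¹ (most negative in the Amazon-analog, magnitudes in
  the range of AGB-only tropical feedback estimates). Pairs are generated
  one model at a time to bound memory.

What passing tests on this world do **not** show: realism of monthly
weather, ENSO-like variability, spatially correlated noise, geographic
basin shapes, or any nonlinearity of the climate response in deforestation
level. They do show that the estimator chain — windowed deltas, moving
window fits with significance masking, background-rainfall lookup, the
product estimator, quadrature propagation and linear historical scaling —
is implemented correctly and recovers injected truth.

## Numerical notes

* Fits go through statsmodels OLS; tests cross-check coefficients against
  hand-solved normal equations.
* Window membership uses closed intervals [L − 500, L + 500]; cells belong
  to many windows by construction. Windows with < 30 cells or a degenerate
  design are reported with NaN/flagged, never fatal.
* Curve lookup interpolates linearly between levels, treats non-significant
  levels as zero, and clamps to the nearest endpoint outside 600–3100.
* Area weights are cos(latitude) of the cell center; cell areas use the
  spherical formula with R = 6371 km. Basin totals computed from regional
  per-ha means agree with cellwise integration to < 1 % on these grids.
* Belsley collinearity diagnostics are computed from the SVD of the
  unit-column-scaled design; a condition index > 30 carrying > 0.5 of the
  variance of two or more columns flags a dependency.
* NetCDF I/O uses the classic format (scipy backend); boolean masks are
  stored as int8 with a dtype attribute and restored on read.
* Statistical tests of stochastic behaviour use fixed seed lists and
  binomial acceptance bounds (e.g. 2-SE coverage over 100 seeds is asserted
  at ≥ 91/100, the one-sided 95 % bound for a true rate of 0.95).

## Problem sizes

Default analyses run on the 46 × 241 grid (~5200 analysis cells), 8-member
ensembles of 35-year runs, and 100-seed recovery / 10-seed end-to-end
repetitions; the full suite completes in well under a minute on one core.

## Known limitations

* The sensitivity curve is a descriptive OLS object: no spatial
  autocorrelation correction, so printed p-values on real data would be
  anti-conservative; the P < 0.001 threshold and the joint test are partly
  compensating conventions.
* VPD is accepted only as a precomputed covariate; deriving it would
  require humidity inputs the pipeline does not model.
* Historical attribution assumes strict linearity in deforestation level
  and equilibrium response; the Congo basin area is not part of the
  published inputs, so only its per-hectare quantities are robust.
* Edge-effect percentages in the combined-additionality table are
  literature constants, not computed by this package.
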