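"""Reference constants of the analysis.

These are the published multimodel regional statistics of the idealized
global-deforestation experiment (mean and one cross-model SD of tree-cover
change, relative precipitation change, absolute precipitation change against
observed climatology, and temperature change) together with the tropical
observational AGB-climate regression coefficients. They serve two roles:

* defaults for the synthetic-data generator, which draws per-model regional
  responses around them so the pseudo-ensemble has the statistical structure
  of the real one;
* printed inputs for the desk-scale worked examples (uncertainty propagation,
  historical attribution, additionality arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass

# Tropical observational AGB = a*MAP + b*MAT + eps fit
# (Mg C ha-1 per mm yr-1 and per degC)
OBS_A = 0.034
OBS_B = -0.32
OBS_R2 = 0.49
OBS_RMSE = 32.0  # Mg C ha-1

# Literature mean local edge-effect additionality (percent of direct loss)
EDGE_EFFECT_PCT = {"amazon": 36.0, "congo": 19.0, "tropical_asia": 10.0}


@dataclass(frozen=True)
class RegionalResponse:
    """Ensemble mean and cross-model SD of the regional deforestation
    response (units: percentage points of tree cover; percent precipitation;
    mm yr-1; degC; Mg C ha-1)."""
    dcover: tuple[float, float]
    dp_rel: tuple[float, float]
    dp_mm: tuple[float, float]
    dt: tuple[float, float]
    direct_loss: tuple[float, float]
    biophys_loss: tuple[float, float]


REGION_RESPONSES: dict[str, RegionalResponse] = {
    "amazon": RegionalResponse(
        dcover=(-44.7, 6.0), dp_rel=(-6.7, 4.7), dp_mm=(-150.0, 105.0),
        dt=(0.5, 0.5), direct_loss=(-98.3, 13.2), biophys_loss=(-5.0, 3.6)),
    "congo": RegionalResponse(
        dcover=(-38.7, 8.8), dp_rel=(-2.7, 3.7), dp_mm=(-41.0, 56.0),
        dt=(0.1, 0.5), direct_loss=(-75.5, 16.7), biophys_loss=(-2.9, 1.9)),
    "tropical_asia": RegionalResponse(
        dcover=(-31.2, 8.9), dp_rel=(-1.3, 2.0), dp_mm=(-38.0, 58.0),
        dt=(-0.1, 0.2), direct_loss=(-62.4, 17.8), biophys_loss=(-0.3, 2.0)),
}

# Historical (1850-2015) primary-forest fraction losses and basin geometry
AMAZON_HIST_LOSS_PCT = 11.5
CONGO_HIST_LOSS_PCT = 8.4
AMAZON_AREA_KM2 = 5.84e6
# Per-hectare warming component of the Amazon historical attribution as
# estimated with the window-local (background-rainfall) temperature
# coefficient: a small gain, +0.04 Mg C ha-1.
AMAZON_HIST_WARMING_GAIN = 0.04
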