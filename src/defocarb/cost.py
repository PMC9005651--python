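"""Biophysical and direct carbon costs of deforestation.

The biophysical AGB change at a cell is the deforestation-induced climate
change priced with the rainfall-dependent sensitivity curve evaluated at the
cell's *background* rainfall (observed climatology adjusted by the relative
rainfall change): dAGB = s_P * dP_mm + s_T * dT. The direct loss is the
tree-cover change times the observed tree-cover/AGB slope. Losses are carried
as signed changes (negative = loss); percent additionality is
100 * biophysical / direct. Regional uncertainty is propagated in quadrature
from the regional precipitation and temperature SDs through the global
observational regression coefficients, assuming independence:
sigma = sqrt((a sigma_dP)^2 + (b sigma_dT)^2).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr

from .constants import EDGE_EFFECT_PCT, OBS_A, OBS_B
from .grid import area_weighted_mean
from .sensitivity import SensitivityCurve

__all__ = [
    "background_rainfall",
    "sensitivity_lookup",
    "biophysical_agb_change",
    "treecover_agb_slope",
    "direct_agb_loss",
    "percent_additionality",
    "propagate_uncertainty",
    "combine_additionality",
    "RegionalSummary",
    "regional_summary",
    "summary_table",
    "additionality_table",
]


def background_rainfall(obs_climatology: xr.DataArray,
                        dp_rel_mean) -> xr.DataArray:
    """Post-deforestation background rainfall: climatology * (1 + dP_rel/100),
    floored at zero."""
    bg = obs_climatology * (1.0 + dp_rel_mean / 100.0)
    bg = bg.clip(min=0.0)
    bg.attrs["units"] = "mm yr-1"
    bg.name = "background_MAP"
    return bg


def sensitivity_lookup(curve: SensitivityCurve, bg: xr.DataArray):
    """Per-cell (s_P, s_T) from the curve at the background rainfall level."""
    return curve.lookup(bg)


def biophysical_agb_change(s_p, s_t, dp_mm, dt):
    """dAGB = s_P * dP_mm + s_T * dT (Mg C ha-1), with the precipitation and
    temperature contributions returned separately."""
    p_term = s_p * dp_mm
    t_term = s_t * dt
    total = p_term + t_term
    for da, name in ((total, "dAGB_biophys"), (p_term, "dAGB_P"),
                     (t_term, "dAGB_T")):
        if isinstance(da, xr.DataArray):
            da.name = name
            da.attrs["units"] = "Mg C ha-1"
    return total, p_term, t_term


def treecover_agb_slope(agb, tree_cover, mask=None) -> tuple[float, float]:
    """OLS slope of AGB on tree-cover percentage, per 10 percentage points,
    with its standard error (also per 10 points)."""
    agb = np.asarray(getattr(agb, "values", agb), float).ravel()
    tc = np.asarray(getattr(tree_cover, "values", tree_cover), float).ravel()
    sel = np.isfinite(agb) & np.isfinite(tc)
    if mask is not None:
        sel &= np.asarray(getattr(mask, "values", mask), bool).ravel()
    agb, tc = agb[sel], tc[sel]
    if agb.size < 30:
        raise ValueError("need at least 30 cells")
    cover_pct = 100.0 * tc
    if np.ptp(cover_pct) == 0:
        raise ValueError("degenerate tree-cover variance")
    res = sm.OLS(agb, sm.add_constant(cover_pct)).fit()
    return float(res.params[1] * 10.0), float(res.bse[1] * 10.0)


def direct_agb_loss(dcover_pct: float, slope_per_10pct: float) -> float:
    """Direct AGB change from a tree-cover change (percentage points) and the
    observational slope (Mg C ha-1 per 10 points); negative for cover loss."""
    if slope_per_10pct <= 0:
        raise ValueError("slope must be positive")
    return dcover_pct * slope_per_10pct / 10.0


def percent_additionality(biophysical_loss: float, direct_loss: float) -> float:
    """Biophysical loss as a percentage of the direct loss (both signed)."""
    if direct_loss == 0:
        raise ValueError("zero direct loss")
    return 100.0 * biophysical_loss / direct_loss


def propagate_uncertainty(a: float, b: float, sigma_dp_mm: float,
                          sigma_dt: float) -> float:
    """Quadrature SD of the biophysical loss:
    sqrt((a sigma_dP)^2 + (b sigma_dT)^2)."""
    if sigma_dp_mm < 0 or sigma_dt < 0:
        raise ValueError("negative sigma")
    return float(np.hypot(a * sigma_dp_mm, b * sigma_dt))


def combine_additionality(edge_pct: float, regional_pct: float) -> int:
    """Total indirect additionality: local edge effect plus regional climate
    feedback, rounded to integer percent for table output."""
    if edge_pct < 0 or regional_pct < 0:
        raise ValueError("percentages must be >= 0")
    return int(round(edge_pct + regional_pct))


@dataclass
class RegionalSummary:
    """One summary row per region: deforestation response, direct and
    biophysical AGB losses with SDs, and percent additionality."""
    region: str
    dcover: float
    dcover_sd: float
    dp_rel: float
    dp_rel_sd: float
    dp_mm: float
    dp_mm_sd: float
    dt: float
    dt_sd: float
    direct: float
    direct_sd: float
    biophys: float
    biophys_sd: float
    pct: float
    pct_sd: float

    def to_dict(self) -> dict:
        return asdict(self)


def regional_summary(region: str, climate_row: dict, dagb_total: xr.DataArray,
                     mask: xr.DataArray, slope_per_10pct: float,
                     a: float = OBS_A, b: float = OBS_B) -> RegionalSummary:
    """Assemble a summary row.

    The regional biophysical loss is the area-weighted mean of the per-cell
    product; its SD comes from quadrature propagation of the regional
    precipitation/temperature SDs through the global observation fit (a, b);
    the direct loss and its SD scale the tree-cover change by the regional
    observational slope.
    """
    biophys = area_weighted_mean(dagb_total, mask)
    biophys_sd = propagate_uncertainty(a, b, climate_row["dP_mm_sd"],
                                       climate_row["dT_sd"])
    direct = direct_agb_loss(climate_row["dcover"], slope_per_10pct)
    direct_sd = abs(climate_row["dcover_sd"]) * slope_per_10pct / 10.0
    pct = percent_additionality(biophys, direct)
    pct_sd = 100.0 * biophys_sd / abs(direct)
    return RegionalSummary(
        region=region,
        dcover=climate_row["dcover"], dcover_sd=climate_row["dcover_sd"],
        dp_rel=climate_row["dP_rel"], dp_rel_sd=climate_row["dP_rel_sd"],
        dp_mm=climate_row["dP_mm"], dp_mm_sd=climate_row["dP_mm_sd"],
        dt=climate_row["dT"], dt_sd=climate_row["dT_sd"],
        direct=direct, direct_sd=direct_sd,
        biophys=biophys, biophys_sd=biophys_sd,
        pct=pct, pct_sd=pct_sd)


def summary_table(rows: list[RegionalSummary]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


def additionality_table(rows: list[RegionalSummary],
                        edge_pct: dict[str, float] | None = None
                        ) -> pd.DataFrame:
    """Combined local-edge + regional-feedback additionality per region;
    the edge percentages are literature constants, not computed here."""
    edge_pct = EDGE_EFFECT_PCT if edge_pct is None else edge_pct
    recs = []
    for r in rows:
        edge = edge_pct.get(r.region)
        recs.append({
            "region": r.region,
            "edge_pct": edge,
            "regional_feedback_pct": r.pct,
            "combined_pct": (combine_additionality(edge, max(r.pct, 0.0))
                             if edge is not None else None),
        })
    return pd.DataFrame(recs)
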