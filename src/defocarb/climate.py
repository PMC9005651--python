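"""Deforestation climate response of a multimodel ensemble.

Per-model deltas are last-30-year means of the deforested run minus the
control run; relative precipitation change is expressed against the control
run's own climatology (each model's bias divides out), and absolute
precipitation change is the product of the multimodel mean relative change
with the *observed* climatology. The ensemble summary carries the unweighted
multimodel mean, the cross-model SD (ddof=1) and a per-cell sign-agreement
count; the robust mask requires agreement of at least ceil(0.75 * n_models)
models (6 of 8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grid import area_weighted_mean, time_window_mean

__all__ = [
    "deforestation_delta",
    "ensemble_summary",
    "EnsembleDelta",
    "absolute_precip_change",
    "regional_climate_row",
    "regional_climate_table",
]

DELTA_UNITS = {"dP": "mm yr-1", "dP_rel": "%", "dT": "degC",
               "dcover": "percentage points"}


def deforestation_delta(pair: dict[str, xr.Dataset],
                        n_years: int = 30) -> xr.Dataset:
    """Per-model deforestation-minus-control delta fields.

    ``pair`` maps {"control", "deforest"} to annual series datasets with
    variables P, T and (optionally) tree_cover. Relative precipitation change
    is undefined (NaN) where the control climatology is zero.
    """
    ctl, dfo = pair["control"], pair["deforest"]
    if not np.allclose(ctl.lat, dfo.lat) or not np.allclose(ctl.lon, dfo.lon):
        raise ValueError("control and deforest runs on different grids")
    p_ctl = time_window_mean(ctl["P"], "last", n_years)
    p_dfo = time_window_mean(dfo["P"], "last", n_years)
    t_ctl = time_window_mean(ctl["T"], "last", n_years)
    t_dfo = time_window_mean(dfo["T"], "last", n_years)
    dp = p_dfo - p_ctl
    dp_rel = 100.0 * dp / p_ctl.where(p_ctl != 0)
    out = xr.Dataset({"dP": dp, "dP_rel": dp_rel, "dT": t_dfo - t_ctl})
    if "tree_cover" in ctl and "tree_cover" in dfo:
        tc_c, tc_d = ctl["tree_cover"], dfo["tree_cover"]
        if "year" in tc_c.dims:
            tc_c = time_window_mean(tc_c, "last", n_years)
            tc_d = time_window_mean(tc_d, "last", n_years)
        out["dcover"] = 100.0 * (tc_d - tc_c)
    for k, u in DELTA_UNITS.items():
        if k in out:
            out[k].attrs["units"] = u
    return out


@dataclass
class EnsembleDelta:
    """Stacked per-model delta fields plus multimodel summaries."""
    deltas: xr.Dataset            # dims (model, lat, lon)
    mean: xr.Dataset
    sd: xr.Dataset
    agreement: xr.Dataset         # integer count per variable
    n_models: int
    agreement_frac: float = 0.75

    @property
    def robust_count(self) -> int:
        return math.ceil(self.agreement_frac * self.n_models)

    def robust_mask(self, var: str) -> xr.DataArray:
        """Cells where at least ceil(frac * n_models) models share the sign
        of the multimodel mean."""
        return self.agreement[var] >= self.robust_count


def ensemble_summary(deltas: list[xr.Dataset],
                     agreement_frac: float = 0.75) -> EnsembleDelta:
    """Combine per-model deltas into mean, cross-model SD (ddof=1) and
    sign-agreement count (zero deltas agree with neither sign)."""
    if len(deltas) < 2:
        raise ValueError("need >= 2 models (cross-model SD undefined)")
    stack = xr.concat(deltas, dim=pd.Index(range(len(deltas)), name="model"))
    mean = stack.mean("model")
    sd = stack.std("model", ddof=1)
    sign_mean = np.sign(mean)
    agree = ((np.sign(stack) == sign_mean) & (stack != 0)).sum("model")
    agree = agree.astype(int)
    return EnsembleDelta(deltas=stack, mean=mean, sd=sd, agreement=agree,
                         n_models=len(deltas), agreement_frac=agreement_frac)


def absolute_precip_change(dp_rel_mean: xr.DataArray,
                           obs_climatology: xr.DataArray) -> xr.DataArray:
    """Cellwise mm yr-1 change: (relative change % / 100) x observed
    climatology."""
    if float(obs_climatology.min()) < 0:
        raise ValueError("negative climatological precipitation")
    out = dp_rel_mean / 100.0 * obs_climatology
    out.attrs["units"] = "mm yr-1"
    out.name = "dP_mm"
    return out


def regional_climate_row(ens: EnsembleDelta, mask: xr.DataArray,
                         obs_climatology: xr.DataArray) -> dict:
    """Regional climate-response statistics: cross-model mean and SD of
    per-model regional means of dcover, dP_rel, dP_mm and dT.

    The mm yr-1 change per model is the regional mean of that model's
    relative change applied to the observed climatology, so the reported SD
    is across per-model products.
    """
    per_model: dict[str, list[float]] = {"dcover": [], "dP_rel": [],
                                         "dP_mm": [], "dT": []}
    for m in range(ens.n_models):
        d = ens.deltas.isel(model=m)
        per_model["dP_rel"].append(area_weighted_mean(d["dP_rel"], mask))
        per_model["dT"].append(area_weighted_mean(d["dT"], mask))
        if "dcover" in d:
            per_model["dcover"].append(area_weighted_mean(d["dcover"], mask))
        dp_mm = absolute_precip_change(d["dP_rel"], obs_climatology)
        per_model["dP_mm"].append(area_weighted_mean(dp_mm, mask))
    row = {}
    for key, vals in per_model.items():
        if not vals:
            row[key] = row[f"{key}_sd"] = float("nan")
            continue
        arr = np.asarray(vals)
        row[key] = float(arr.mean())
        row[f"{key}_sd"] = float(arr.std(ddof=1))
    return row


def regional_climate_table(ens: EnsembleDelta, masks: dict[str, xr.DataArray],
                           obs_climatology: xr.DataArray) -> pd.DataFrame:
    rows = []
    for name, mask in masks.items():
        row = {"region": name}
        row.update(regional_climate_row(ens, mask, obs_climatology))
        rows.append(row)
    return pd.DataFrame(rows)
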