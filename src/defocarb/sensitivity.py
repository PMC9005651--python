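"""Spatial sensitivity of aboveground biomass (AGB) to climate.

The central object is :class:`AGBClimateModel`, a regression model of AGB
(Mg C ha-1) on mean annual precipitation (MAP, mm yr-1) and mean annual
temperature (MAT, degC) across tropical grid cells:

    AGB = intercept + a * MAP + b * MAT + eps

``fit()`` returns an :class:`AGBClimateRegression` results object (estimates,
standard errors, p-values, R2, RMSE and the relative sensitivities
delta_MAP = a*100 / mean(AGB) in % per 100 mm yr-1 and delta_MAT analogous
per degC). ``fit_moving_window()`` repeats the fit inside overlapping
precipitation bands (+-500 mm around each level from 600 to 3100 mm yr-1)
and returns a :class:`SensitivityCurve`, the rainfall-dependent sensitivity
used to price deforestation-driven climate change in carbon.

Cells enter the regressions unweighted; significance of a window means both
climate coefficients have two-sided p < alpha (default 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr

__all__ = [
    "vegc_to_agb",
    "dry_biomass_to_carbon",
    "apply_domain_filters",
    "AGBClimateModel",
    "AGBClimateRegression",
    "SensitivityCurve",
    "derived_covariates",
    "collinearity_diagnostics",
]

DEFAULT_LEVELS = np.arange(600, 3101, 100)


def vegc_to_agb(veg_carbon: xr.DataArray,
                tree_cover: xr.DataArray) -> xr.DataArray:
    """Convert total vegetation carbon to aboveground biomass carbon with the
    tree-cover-weighted aboveground fraction 0.8*tc + 0.4*(1 - tc)
    (0.8 for closed forest, 0.4 for savanna)."""
    tc = tree_cover
    if float(tc.min()) < 0 or float(tc.max()) > 1:
        raise ValueError("tree cover must lie in [0, 1]")
    out = veg_carbon * (0.8 * tc + 0.4 * (1.0 - tc))
    out.attrs["units"] = "Mg C ha-1"
    out.name = "AGB"
    return out


def dry_biomass_to_carbon(agb_dry):
    """Dry aboveground biomass (Mg ha-1) to carbon (Mg C ha-1), factor 0.5."""
    arr = np.asarray(agb_dry, dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("negative dry biomass")
    out = arr * 0.5
    return out if out.ndim else float(out)


def apply_domain_filters(bundle: xr.Dataset, min_map: float = 100.0,
                         min_land: float = 0.5, max_abs_lat: float = 23.0,
                         max_map: float | None = None) -> xr.DataArray:
    """Analysis-cell mask: |lat| <= 23, MAP >= 100 mm yr-1, land fraction
    >= 0.5, and all regressors non-missing.

    ``max_map`` optionally caps the rainfall range, e.g. to restrict a fit
    to the regime where the AGB-climate relationship is linear.
    """
    lat_ok = np.abs(bundle.lat) <= max_abs_lat
    mask = (bundle["MAP"] >= min_map) & (bundle["land_fraction"] >= min_land)
    if max_map is not None:
        mask = mask & (bundle["MAP"] <= max_map)
    mask = mask & bundle["MAP"].notnull() & bundle["MAT"].notnull() \
        & bundle["AGB"].notnull()
    mask = mask & (xr.zeros_like(bundle["MAP"], dtype=bool) | lat_ok)
    if not bool(mask.any()):
        raise ValueError("domain filters leave no analysis cells")
    mask.name = "analysis_cells"
    return mask


@dataclass
class AGBClimateRegression:
    """OLS results for the AGB-climate regression on one cell set."""
    a: float                 # Mg C ha-1 per mm yr-1
    b: float                 # Mg C ha-1 per degC
    intercept: float
    se_a: float
    se_b: float
    p_a: float
    p_b: float
    r_squared: float
    rmse: float
    n_cells: int
    mean_agb: float

    @property
    def delta_map(self) -> float:
        """Relative sensitivity, % per 100 mm yr-1."""
        return 100.0 * self.a * 100.0 / self.mean_agb

    @property
    def delta_mat(self) -> float:
        """Relative sensitivity, % per degC."""
        return 100.0 * self.b / self.mean_agb

    def summary(self) -> str:
        rows = [
            ("a*100 (Mg C ha-1 / 100 mm yr-1)", self.a * 100, self.se_a * 100,
             self.p_a),
            ("b (Mg C ha-1 / degC)", self.b, self.se_b, self.p_b),
        ]
        lines = ["AGB ~ MAP + MAT spatial regression",
                 f"n_cells = {self.n_cells}   R2 = {self.r_squared:.3f}   "
                 f"RMSE = {self.rmse:.2f} Mg C ha-1",
                 f"{'term':36s}{'coef':>10s}{'se':>10s}{'p':>12s}"]
        for name, c, se, p in rows:
            lines.append(f"{name:36s}{c:10.4f}{se:10.4f}{p:12.3g}")
        lines.append(f"intercept = {self.intercept:.3f} Mg C ha-1")
        lines.append(f"delta_MAP = {self.delta_map:.2f} % / 100 mm yr-1   "
                     f"delta_MAT = {self.delta_mat:.2f} % / degC")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "intercept": self.intercept,
            "se_a": self.se_a, "se_b": self.se_b,
            "p_a": self.p_a, "p_b": self.p_b,
            "r_squared": self.r_squared, "rmse": self.rmse,
            "n_cells": self.n_cells, "mean_agb": self.mean_agb,
            "delta_map": self.delta_map, "delta_mat": self.delta_mat,
        }


class AGBClimateModel:
    """Spatial AGB-climate regression model over a set of tropical cells."""

    def __init__(self, agb, map_, mat, mask=None):
        agb = np.asarray(getattr(agb, "values", agb), float).ravel()
        map_ = np.asarray(getattr(map_, "values", map_), float).ravel()
        mat = np.asarray(getattr(mat, "values", mat), float).ravel()
        if mask is not None:
            sel = np.asarray(getattr(mask, "values", mask), bool).ravel()
        else:
            sel = np.ones_like(agb, bool)
        sel = sel & np.isfinite(agb) & np.isfinite(map_) & np.isfinite(mat)
        self.agb = agb[sel]
        self.map = map_[sel]
        self.mat = mat[sel]

    @classmethod
    def from_bundle(cls, bundle: xr.Dataset, min_map: float = 100.0,
                    min_land: float = 0.5,
                    max_map: float | None = None) -> "AGBClimateModel":
        mask = apply_domain_filters(bundle, min_map=min_map,
                                    min_land=min_land, max_map=max_map)
        return cls(bundle["AGB"], bundle["MAP"], bundle["MAT"], mask)

    @property
    def n_cells(self) -> int:
        return self.agb.size

    def _ols(self, sel, intercept=True):
        y = self.agb[sel]
        X = np.column_stack([self.map[sel], self.mat[sel]])
        if intercept:
            X = sm.add_constant(X, has_constant="add")
        res = sm.OLS(y, X).fit()
        k = 1 if intercept else 0
        rmse = float(np.sqrt(np.mean(res.resid ** 2)))
        return AGBClimateRegression(
            a=float(res.params[k]), b=float(res.params[k + 1]),
            intercept=float(res.params[0]) if intercept else 0.0,
            se_a=float(res.bse[k]), se_b=float(res.bse[k + 1]),
            p_a=float(res.pvalues[k]), p_b=float(res.pvalues[k + 1]),
            r_squared=float(res.rsquared), rmse=rmse,
            n_cells=int(y.size), mean_agb=float(np.mean(y)))

    def fit(self, intercept: bool = True) -> AGBClimateRegression:
        """Global OLS over all analysis cells (>= 30 required)."""
        if self.n_cells < 30:
            raise ValueError("need at least 30 cells for the global fit")
        if np.allclose(np.corrcoef(self.map, self.mat)[0, 1] ** 2, 1.0,
                       atol=1e-12):
            raise ValueError("MAP and MAT are collinear to machine precision")
        return self._ols(np.ones(self.n_cells, bool), intercept=intercept)

    def fit_moving_window(self, levels=None, half_width: float = 500.0,
                          alpha: float = 1e-3, min_cells: int = 30,
                          intercept: bool = True) -> "SensitivityCurve":
        """Moving-window fits on closed MAP intervals [L-hw, L+hw].

        Windows with fewer than ``min_cells`` cells (or a degenerate design)
        are reported but flagged not significant.
        """
        levels = DEFAULT_LEVELS if levels is None else np.asarray(levels)
        rows = []
        for lvl in levels:
            sel = (self.map >= lvl - half_width) & (self.map <= lvl + half_width)
            n = int(sel.sum())
            row = {"level": float(lvl), "n_cells": n}
            ok = n >= max(min_cells, 4)
            if ok:
                sub = np.column_stack([self.map[sel], self.mat[sel]])
                if (np.ptp(sub[:, 0]) == 0 or np.ptp(sub[:, 1]) == 0):
                    ok = False
            if ok:
                fit = self._ols(sel, intercept=intercept)
                row.update(a=fit.a, b=fit.b, intercept=fit.intercept,
                           p_a=fit.p_a, p_b=fit.p_b,
                           r_squared=fit.r_squared, rmse=fit.rmse)
                row["significant"] = bool(n >= min_cells
                                          and fit.p_a < alpha
                                          and fit.p_b < alpha)
            else:
                row.update(a=np.nan, b=np.nan, intercept=np.nan,
                           p_a=np.nan, p_b=np.nan, r_squared=np.nan,
                           rmse=np.nan, significant=False)
            rows.append(row)
        return SensitivityCurve(pd.DataFrame(rows), alpha=alpha,
                                half_width=float(half_width))


class SensitivityCurve:
    """Rainfall-dependent AGB-climate sensitivity: per precipitation level a
    window regression fit and a joint-significance flag."""

    def __init__(self, table: pd.DataFrame, alpha: float = 1e-3,
                 half_width: float = 500.0):
        self.table = table.reset_index(drop=True)
        self.alpha = alpha
        self.half_width = half_width

    @property
    def levels(self) -> np.ndarray:
        return self.table["level"].to_numpy()

    def effective_coeffs(self) -> tuple[np.ndarray, np.ndarray]:
        """(a, b) per level with non-significant levels set to zero —
        no sensitivity is attributed where the fit is not robust."""
        sig = self.table["significant"].to_numpy(bool)
        a = np.where(sig, self.table["a"].to_numpy(), 0.0)
        b = np.where(sig, self.table["b"].to_numpy(), 0.0)
        return np.nan_to_num(a), np.nan_to_num(b)

    def lookup(self, background_map):
        """Sensitivities (s_P, s_T) at given background rainfall levels.

        Linear interpolation between bracketing levels; outside the level
        range the nearest endpoint's (possibly zero) value is used. Where
        both bracketing levels are non-significant the result is (0, 0).
        """
        if len(self.table) == 0:
            raise ValueError("empty sensitivity curve")
        bg = np.asarray(getattr(background_map, "values", background_map),
                        float)
        a_eff, b_eff = self.effective_coeffs()
        s_p = np.interp(bg, self.levels, a_eff)
        s_t = np.interp(bg, self.levels, b_eff)
        if isinstance(background_map, xr.DataArray):
            s_p = xr.DataArray(s_p, coords=background_map.coords,
                               dims=background_map.dims, name="s_P")
            s_t = xr.DataArray(s_t, coords=background_map.coords,
                               dims=background_map.dims, name="s_T")
        return s_p, s_t

    def significant_range(self) -> tuple[float, float] | None:
        sig = self.table[self.table["significant"]]
        if sig.empty:
            return None
        return float(sig["level"].min()), float(sig["level"].max())

    def summary(self) -> str:
        rng = self.significant_range()
        head = (f"moving-window sensitivity: {len(self.table)} levels, "
                f"window +-{self.half_width:.0f} mm yr-1, "
                f"alpha = {self.alpha:g}")
        rng_s = ("no significant levels" if rng is None else
                 f"significant from {rng[0]:.0f} to {rng[1]:.0f} mm yr-1")
        with pd.option_context("display.width", 120):
            return f"{head}\n{rng_s}\n{self.table.to_string(index=False)}"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, alpha: float = 1e-3,
                 half_width: float = 500.0) -> "SensitivityCurve":
        t = pd.read_csv(path)
        t["significant"] = t["significant"].astype(bool)
        return cls(t, alpha=alpha, half_width=half_width)


def derived_covariates(monthly_p: xr.DataArray,
                       monthly_t: xr.DataArray) -> xr.Dataset:
    """Seasonality covariates from 12 monthly values per cell.

    MAXT is the maximum of the supplied monthly temperatures (monthly means
    if that is what was supplied — recorded in the attrs); Pamp / Tamp are
    max-month minus min-month; PRD is the minimum rainfall over the 12
    cyclic consecutive-3-month windows.
    """
    for da in (monthly_p, monthly_t):
        if da.sizes.get("month") != 12:
            raise ValueError("need 12 monthly values per cell")
        if bool(da.isnull().any()):
            raise ValueError("missing months")
    p = monthly_p.transpose("month", ...).values
    rolled = np.stack([np.roll(p, -k, axis=0)[:3].sum(axis=0)
                       for k in range(12)])
    prd = rolled.min(axis=0)
    tmpl = monthly_p.isel(month=0, drop=True)
    ds = xr.Dataset(
        {
            "MAXT": monthly_t.max("month"),
            "Pamp": monthly_p.max("month") - monthly_p.min("month"),
            "Tamp": monthly_t.max("month") - monthly_t.min("month"),
            "PRD": (tmpl.dims, prd),
        }
    )
    ds["MAXT"].attrs.update(units="degC",
                            definition="max of supplied monthly values")
    ds["Pamp"].attrs["units"] = "mm"
    ds["Tamp"].attrs["units"] = "degC"
    ds["PRD"].attrs["units"] = "mm"
    return ds


def collinearity_diagnostics(X: np.ndarray, index_threshold: float = 30.0,
                             proportion_threshold: float = 0.5):
    """Belsley condition indices and variance-decomposition proportions.

    Columns are scaled to unit length; from the SVD X = U S V', the condition
    indices are s_max / s_i and the variance of coefficient j decomposes over
    singular values with proportions phi_ij = (v_ji^2 / s_i^2) / sum_i.
    A set of columns is flagged collinear when a condition index above the
    threshold carries more than ``proportion_threshold`` of the variance of
    at least two columns.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D design with >= 2 columns")
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-variance (all-zero) column")
    Xs = X / norms
    _, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    tiny = np.finfo(float).eps * max(X.shape) * s[0]
    s_safe = np.where(s > tiny, s, tiny)
    cond_idx = s[0] / s_safe
    phi_terms = (Vt.T ** 2) / (s_safe ** 2)      # (col j, sv i)
    props = (phi_terms / phi_terms.sum(axis=1, keepdims=True)).T  # (sv, col)
    flags = []
    for i, ci in enumerate(cond_idx):
        if ci > index_threshold:
            cols = np.where(props[i] > proportion_threshold)[0]
            if cols.size >= 2:
                flags.append({"condition_index": float(ci),
                              "columns": cols.tolist()})
    return {"condition_indices": cond_idx,
            "variance_proportions": props,
            "collinear_sets": flags}
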