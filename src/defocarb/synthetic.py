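"""Synthetic observation bundle and pseudo multimodel ensemble.

The generator does not try to be geographically realistic. It reproduces the
statistical structure the downstream analysis relies on:

* AGB approximately linear in mean annual precipitation (MAP) and mean annual
  temperature (MAT), with Gaussian noise, clipped at zero, and blended toward
  a constant above a high-rainfall saturation threshold so that the
  moving-window regression loses significance in the wettest bands;
* MAT anticorrelated with MAP, with more spatial MAT variation in dry areas;
* tree cover a monotone saturating function of MAP;
* three continent-like land bands hosting an Amazon-analog box (climatology
  ~2240 mm yr-1), a Congo-analog box (~1520 mm yr-1) and a wet tropical-Asia
  band, each with per-model deforestation responses drawn from configurable
  Normal(mean, SD) distributions.

One RNG stream is derived per model member from the master seed, so adding
members never perturbs earlier ones; identical seeds give bit-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import xarray as xr

from .constants import REGION_RESPONSES
from .grid import box_mask, make_grid, save_dataset

__all__ = [
    "SyntheticConfig",
    "generate_observation_bundle",
    "generate_ensemble",
    "generate_co2_pair",
    "generate_region_masks",
    "write_bundle",
]

# land bands: name -> (lon_min, lon_max, MAP ramp low, MAP ramp high)
LAND_BANDS = {
    "south_america": (-80.0, -48.0, 300.0, 3300.0),
    "africa": (0.0, 40.0, 200.0, 2600.0),
    "asia": (95.0, 143.0, 1800.0, 3400.0),
}

# region boxes: (lat_min, lat_max, lon_min, lon_max); tropical_asia is the
# stated 10S-10N, 95E-155E box, the basin analogs are synthetic polygons
REGION_BOXES = {
    "amazon": (-15.0, 5.0, -66.0, -56.0),
    "congo": (-10.0, 5.0, 18.0, 28.0),
    "tropical_asia": (-10.0, 10.0, 95.0, 155.0),
}


def _resp(name):
    r = REGION_RESPONSES[name]
    return {"dp_rel": r.dp_rel, "dt": r.dt, "dcover": r.dcover}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic world (defaults documented in the methods
    note)."""
    seed: int = 0
    lat_min: float = -23.0
    lat_max: float = 23.0
    lon_min: float = -85.0
    lon_max: float = 156.0
    step: float = 1.0
    # observational AGB surface, Mg C ha-1
    a_true: float = 0.034          # per mm yr-1
    b_true: float = -0.32          # per degC
    intercept_true: float = 20.0
    sigma_obs: float = 6.0         # Mg C ha-1, linear regime
    sigma_obs_wet: float = 14.0    # Mg C ha-1 in the saturated wet regime
    saturation_map: float | None = 2400.0  # mm yr-1
    saturation_width: float = 300.0
    map_noise_sd: float = 120.0
    mat_noise_sd: tuple[float, float] = (2.0, 3.5)  # wet end, dry end
    tc_max: float = 0.95
    tc_efold: float = 1200.0       # mm yr-1
    tc_noise_sd: float = 0.01
    # ensemble
    n_models: int = 8
    n_years: int = 35
    p_interannual_frac: float = 0.04
    t_interannual_sd: float = 0.3
    responses: dict = field(default_factory=lambda: {
        name: _resp(name) for name in REGION_BOXES})
    # pseudo CO2-ramp experiment (for the CO2-driven feedback parameter)
    co2_n_years: int = 140
    co2_warming: tuple[float, float] = (3.5, 0.5)  # degC at ramp end (mean, SD)
    co2_fertilization: float = 20.0                # Mg C ha-1 at ramp end
    gamma_co2_true: dict = field(default_factory=lambda: {
        "amazon": -2.5, "congo": -1.2, "tropical_asia": -0.6})

    def __post_init__(self):
        if self.n_models < 2:
            raise ValueError("n_models must be >= 2")
        if self.sigma_obs < 0:
            raise ValueError("sigma_obs must be >= 0")
        if self.lat_min < -23.0 or self.lat_max > 23.0:
            raise ValueError("grid must lie inside 23S-23N")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("non-positive grid extent")

    def grid(self):
        return make_grid(self.lat_min, self.lat_max,
                         self.lon_min, self.lon_max, self.step)


def _lat_factor(lat: np.ndarray) -> np.ndarray:
    return 1.0 - 0.35 * (np.abs(lat) / 23.0) ** 2


def _base_map(cfg: SyntheticConfig, lat: np.ndarray, lon: np.ndarray):
    """Deterministic part of the MAP surface and the land-fraction field."""
    latf = _lat_factor(lat)[:, None]
    ramp = np.full((lat.size, lon.size), 1200.0)
    land = np.zeros((lat.size, lon.size))
    for (lo, hi, m0, m1) in LAND_BANDS.values():
        cols = (lon > lo) & (lon < hi)
        idx = np.where(cols)[0]
        if idx.size == 0:
            continue
        frac = (lon[idx] - lon[idx[0]]) / max(lon[idx[-1]] - lon[idx[0]], 1.0)
        ramp[:, idx] = m0 + (m1 - m0) * frac[None, :]
        land[:, idx] = 1.0
        land[:, idx[0]] = 0.4   # coastal edge columns
        land[:, idx[-1]] = 0.4
    return ramp * latf, land


def _surfaces(cfg: SyntheticConfig, rng: np.random.Generator):
    """MAP, MAT, noiseless AGB, tree cover and land fraction arrays."""
    lat, lon = cfg.grid()
    base, land = _base_map(cfg, lat, lon)
    map_ = base + rng.normal(0.0, cfg.map_noise_sd, base.shape)
    map_ = np.clip(map_, 1.0, None)
    mnorm = np.clip((map_ - 100.0) / 3000.0, 0.0, 1.0)
    sd_wet, sd_dry = cfg.mat_noise_sd
    mat = (22.0 + 7.0 * (1.0 - mnorm)
           + rng.normal(0.0, 1.0, map_.shape)
           * (sd_wet + (sd_dry - sd_wet) * (1.0 - mnorm)))
    agb_det = _agb_surface(cfg, map_, mat)
    tc = np.clip(cfg.tc_max * (1.0 - np.exp(-map_ / cfg.tc_efold))
                 + rng.normal(0.0, cfg.tc_noise_sd, map_.shape), 0.0, 1.0)
    return lat, lon, map_, mat, agb_det, tc, land


def _agb_surface(cfg: SyntheticConfig, map_: np.ndarray,
                 mat: np.ndarray) -> np.ndarray:
    """Noiseless AGB: linear core blended toward a constant above the
    saturation threshold (slope -> 0 for both climate regressors)."""
    lin = cfg.intercept_true + cfg.a_true * map_ + cfg.b_true * mat
    if cfg.saturation_map is None:
        return lin
    sat = cfg.intercept_true + cfg.a_true * cfg.saturation_map \
        + cfg.b_true * 22.0
    w = _saturation_weight(cfg, map_)
    return (1.0 - w) * lin + w * sat


def _saturation_weight(cfg: SyntheticConfig, map_: np.ndarray) -> np.ndarray:
    if cfg.saturation_map is None:
        return np.zeros_like(map_)
    return np.clip((map_ - cfg.saturation_map) / cfg.saturation_width,
                   0.0, 1.0)


def _streams(cfg: SyntheticConfig):
    """Named independent RNG streams derived from the master seed."""
    ss = np.random.SeedSequence(cfg.seed)
    obs, ens, co2 = ss.spawn(3)
    return obs, ens.spawn(cfg.n_models), co2.spawn(cfg.n_models)


def generate_observation_bundle(cfg: SyntheticConfig) -> xr.Dataset:
    """Observation-like grids: MAP (mm yr-1), MAT (degC), AGB (Mg C ha-1),
    tree cover (fraction) and land fraction."""
    obs_ss, _, _ = _streams(cfg)
    rng = np.random.default_rng(obs_ss)
    lat, lon, map_, mat, agb_det, tc, land = _surfaces(cfg, rng)
    # retrieval noise grows in the saturated wet regime, as for radar AGB
    w = _saturation_weight(cfg, map_)
    sigma = cfg.sigma_obs * (1.0 - w) + cfg.sigma_obs_wet * w
    agb = np.clip(agb_det + rng.normal(0.0, 1.0, map_.shape) * sigma,
                  0.0, None)
    coords = {"lat": lat, "lon": lon}
    ds = xr.Dataset(
        {
            "MAP": (("lat", "lon"), map_, {"units": "mm yr-1"}),
            "MAT": (("lat", "lon"), mat, {"units": "degC"}),
            "AGB": (("lat", "lon"), agb, {"units": "Mg C ha-1"}),
            "tree_cover": (("lat", "lon"), tc, {"units": "1"}),
            "land_fraction": (("lat", "lon"), land, {"units": "1"}),
        },
        coords=coords,
    )
    ds.attrs["seed"] = cfg.seed
    return ds


def generate_region_masks(cfg: SyntheticConfig) -> dict[str, xr.DataArray]:
    """Three disjoint named land-region masks on the analysis grid."""
    lat, lon = cfg.grid()
    _, land = _base_map(cfg, lat, lon)
    template = xr.DataArray(np.zeros((lat.size, lon.size)),
                            coords={"lat": lat, "lon": lon},
                            dims=("lat", "lon"))
    land_da = xr.DataArray(land >= 0.5, coords=template.coords,
                           dims=template.dims)
    masks = {}
    for name, (la0, la1, lo0, lo1) in REGION_BOXES.items():
        masks[name] = box_mask(template, la0, la1, lo0, lo1, name=name,
                               land=land_da)
    # sanity: disjoint by construction
    total = sum(m.astype(int) for m in masks.values())
    if int(total.max()) > 1:
        raise ValueError("region masks overlap")
    return masks


def _region_index(cfg: SyntheticConfig):
    masks = generate_region_masks(cfg)
    return {name: m.values for name, m in masks.items()}


def generate_ensemble(cfg: SyntheticConfig) -> list[dict[str, xr.Dataset]]:
    """Per-model paired control / deforested annual series.

    Each model draws one regional (dP_rel %, dT degC, dcover percentage
    points) response per region from the configured Normal distributions,
    applies it uniformly over the region box, and adds interannual noise so
    the windowed delta estimator is exercised. The control precipitation
    climatology equals the observation bundle's deterministic MAP surface.
    """
    if cfg.n_years < 30:
        raise ValueError("n_years shorter than the 30-year averaging window")
    obs_ss, model_ss, _ = _streams(cfg)
    # deterministic climatology shared with the observation bundle
    rng_obs = np.random.default_rng(obs_ss)
    lat, lon, map_, mat, agb_det, tc, land = _surfaces(cfg, rng_obs)
    regions = _region_index(cfg)
    factor = 0.8 * tc + 0.4 * (1.0 - tc)
    vegc = agb_det / factor
    coords = {"year": np.arange(cfg.n_years), "lat": lat, "lon": lon}
    nyr = cfg.n_years
    out = []
    for m, ss in enumerate(model_ss):
        rng = np.random.default_rng(ss)
        dp = np.zeros_like(map_)
        dt = np.zeros_like(map_)
        dc = np.zeros_like(map_)
        for name, sel in regions.items():
            r = cfg.responses[name]
            dp[sel] = rng.normal(*r["dp_rel"])
            dt[sel] = rng.normal(*r["dt"])
            dc[sel] = rng.normal(*r["dcover"])
        runs = {}
        for run, (p_clim, t_clim, tc_run) in {
            "control": (map_, mat, tc),
            "deforest": (map_ * (1.0 + dp / 100.0), mat + dt,
                         np.clip(tc + dc / 100.0, 0.0, 1.0)),
        }.items():
            shape = (nyr,) + map_.shape
            p_noise = (rng.normal(0.0, 1.0, shape).astype("f4")
                       * (cfg.p_interannual_frac * map_).astype("f4"))
            p = np.clip(p_clim.astype("f4") + p_noise, 0.0, None)
            t = (t_clim.astype("f4")
                 + rng.normal(0.0, cfg.t_interannual_sd, shape).astype("f4"))
            runs[run] = xr.Dataset(
                {
                    "P": (("year", "lat", "lon"), p, {"units": "mm yr-1"}),
                    "T": (("year", "lat", "lon"), t, {"units": "degC"}),
                    "tree_cover": (("lat", "lon"), tc_run, {"units": "1"}),
                    "veg_carbon": (("lat", "lon"), vegc,
                                   {"units": "Mg C ha-1"}),
                },
                coords=coords,
            )
            runs[run].attrs["model"] = m
        out.append(runs)
    return out


def generate_co2_pair(cfg: SyntheticConfig, model: int) -> dict[str, xr.Dataset]:
    """One model's fully coupled vs biogeochemistry-only CO2-ramp pair.

    Both runs share a CO2-fertilization AGB trend; only the fully coupled run
    warms, and its AGB additionally responds with the injected per-region
    feedback parameter (Mg C ha-1 per degC). Series are 140 years so
    first/last 20-year windows apply.
    """
    if not 0 <= model < cfg.n_models:
        raise ValueError("model index out of range")
    obs_ss, _, co2_ss = _streams(cfg)
    rng_obs = np.random.default_rng(obs_ss)
    lat, lon, map_, mat, agb_det, tc, land = _surfaces(cfg, rng_obs)
    regions = _region_index(cfg)
    gamma = np.zeros_like(map_)
    for name, sel in regions.items():
        gamma[sel] = cfg.gamma_co2_true.get(name, 0.0)
    rng = np.random.default_rng(co2_ss[model])
    nyr = cfg.co2_n_years
    ramp = (np.arange(nyr) / (nyr - 1)).astype("f4")[:, None, None]
    warm_end = rng.normal(*cfg.co2_warming)
    warming = warm_end * ramp
    noise = lambda sd: rng.normal(0.0, sd, (nyr,) + map_.shape).astype("f4")
    fert = cfg.co2_fertilization * ramp
    coords = {"year": np.arange(nyr), "lat": lat, "lon": lon}

    def _run(t_trend, agb_trend):
        return xr.Dataset(
            {
                "T": (("year", "lat", "lon"),
                      mat.astype("f4") + t_trend + noise(cfg.t_interannual_sd)),
                "AGB": (("year", "lat", "lon"),
                        np.clip(agb_det.astype("f4") + agb_trend
                                + noise(1.0), 0.0, None)),
            },
            coords=coords,
        )

    full = _run(warming, fert + gamma.astype("f4") * warming)
    bgc = _run(0.0 * ramp, fert + 0.0 * ramp)
    return {"1pctCO2": full, "1pctCO2-bgc": bgc}


def write_bundle(cfg: SyntheticConfig, outdir) -> dict[str, Path]:
    """Write the observation bundle, masks and a JSON config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    bundle = generate_observation_bundle(cfg)
    paths["bundle"] = outdir / "observation_bundle.nc"
    save_dataset(bundle, paths["bundle"])
    masks = generate_region_masks(cfg)
    mask_ds = xr.Dataset({name: m for name, m in masks.items()})
    paths["masks"] = outdir / "region_masks.nc"
    save_dataset(mask_ds, paths["masks"])
    paths["config"] = outdir / "synthetic_config.json"
    cfg_dict = asdict(cfg)
    with open(paths["config"], "w") as fh:
        json.dump(cfg_dict, fh, indent=2, default=str)
    return paths
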