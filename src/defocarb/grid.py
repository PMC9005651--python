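"""Gridded-field utilities.

A *field* is an :class:`xarray.DataArray` over dims ``("lat", "lon")`` with
cell-center coordinates (1-degree spacing on the analysis grid, longitudes in
[-180, 180)) and a ``units`` attribute. Annual series add a leading ``"year"``
dim. Region masks are boolean DataArrays on the same grid; masks and fields
must share a grid — there is no implicit regridding.

Missing data are explicit NaNs, never silent zeros; every spatial statistic
uses pairwise-complete cells and can report its effective cell count.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "make_grid",
    "make_field",
    "regrid_bilinear",
    "area_weighted_mean",
    "time_window_mean",
    "box_mask",
    "cell_area_km2",
    "region_area_km2",
    "save_dataset",
    "open_dataset",
]


def make_grid(lat_min: float, lat_max: float, lon_min: float, lon_max: float,
              step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center coordinates of a regular lat/lon grid.

    ``lat_min``/``lat_max`` etc. are the outer *edges*; centers sit at
    edge + step/2. Latitude is strictly increasing.
    """
    lat = np.arange(lat_min + step / 2.0, lat_max, step)
    lon = np.arange(lon_min + step / 2.0, lon_max, step)
    if lat.size == 0 or lon.size == 0:
        raise ValueError("non-positive grid extent")
    return lat, lon


def make_field(values: np.ndarray, lat: np.ndarray, lon: np.ndarray,
               name: str, units: str = "") -> xr.DataArray:
    """Wrap a 2-D array as a field on the given cell-center grid."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(lat), len(lon)):
        raise ValueError(f"shape {values.shape} does not match grid "
                         f"({len(lat)}, {len(lon)})")
    da = xr.DataArray(values, coords={"lat": np.asarray(lat, float),
                                      "lon": np.asarray(lon, float)},
                      dims=("lat", "lon"), name=name)
    da.attrs["units"] = units
    return da


def _check_regular(coord: np.ndarray, name: str) -> None:
    d = np.diff(coord)
    if coord.size > 1 and not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{name} coordinate is not regular")


def regrid_bilinear(field: xr.DataArray, target_lat: np.ndarray,
                    target_lon: np.ndarray) -> xr.DataArray:
    """Bilinear interpolation onto a target cell-center grid.

    The value at each target center is the bilinear interpolant of the four
    surrounding source centers; target cells outside the source convex hull
    fall back to the nearest inside source cell. Units are preserved.
    """
    _check_regular(np.asarray(field.lat.values), "lat")
    _check_regular(np.asarray(field.lon.values), "lon")
    target_lat = np.asarray(target_lat, float)
    target_lon = np.asarray(target_lon, float)
    out = field.interp(lat=target_lat, lon=target_lon, method="linear")
    # nearest-inside extrapolation for edge cells only
    outside = (
        (out.lat < float(field.lat.min())) | (out.lat > float(field.lat.max()))
    ) | (
        (out.lon < float(field.lon.min())) | (out.lon > float(field.lon.max()))
    )
    if bool(outside.any()):
        nearest = field.reindex(lat=target_lat, lon=target_lon,
                                method="nearest")
        out = out.where(~outside, nearest)
    if out.isnull().all():
        raise ValueError("all-missing neighborhood after regridding")
    out.attrs["units"] = field.attrs.get("units", "")
    out.name = field.name
    return out


def _align_check(field: xr.DataArray, mask: xr.DataArray | None) -> None:
    if mask is not None:
        if (len(mask.lat) != len(field.lat) or len(mask.lon) != len(field.lon)
                or not np.allclose(mask.lat, field.lat)
                or not np.allclose(mask.lon, field.lon)):
            raise ValueError("mask and field are on different grids")


def area_weighted_mean(field: xr.DataArray, mask: xr.DataArray | None = None,
                       with_count: bool = False):
    """cos(latitude)-weighted spatial mean over an optional region mask.

    Missing cells are excluded from numerator and denominator alike. Raises
    on an empty effective mask. With ``with_count=True`` also returns the
    effective number of cells.
    """
    _align_check(field, mask)
    w = xr.ones_like(field) * np.cos(np.deg2rad(field.lat))
    valid = field.notnull()
    if mask is not None:
        valid = valid & mask.astype(bool)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("empty effective mask: no valid cells")
    num = float(field.where(valid).weighted(w.where(valid, 0.0)).mean())
    if with_count:
        return num, n
    return num


def time_window_mean(series: xr.DataArray, window: str = "last",
                     n_years: int = 30) -> xr.DataArray:
    """Per-cell mean over the first or last ``n_years`` of an annual series."""
    if "year" not in series.dims:
        raise ValueError("series must have a 'year' dimension")
    if series.sizes["year"] < n_years:
        raise ValueError(f"series shorter ({series.sizes['year']}) than "
                         f"window ({n_years})")
    if window == "last":
        sel = series.isel(year=slice(-n_years, None))
    elif window == "first":
        sel = series.isel(year=slice(0, n_years))
    else:
        raise ValueError("window must be 'first' or 'last'")
    out = sel.mean("year")
    out.attrs.update(series.attrs)
    return out


def box_mask(template: xr.DataArray, lat_min: float, lat_max: float,
             lon_min: float, lon_max: float, name: str = "box",
             land: xr.DataArray | None = None) -> xr.DataArray:
    """Boolean mask of cells whose centers fall inside a lat/lon box,
    optionally intersected with a boolean land mask."""
    m = ((template.lat >= lat_min) & (template.lat < lat_max)) & \
        ((template.lon >= lon_min) & (template.lon < lon_max))
    m = xr.zeros_like(template, dtype=bool) | m
    if land is not None:
        _align_check(template, land)
        m = m & land.astype(bool)
    m.name = name
    if not bool(m.any()):
        raise ValueError(f"empty region mask {name!r}")
    return m


def cell_area_km2(template: xr.DataArray) -> xr.DataArray:
    """Spherical cell areas (km^2) for a regular cell-center grid."""
    lat = np.asarray(template.lat.values)
    lon = np.asarray(template.lon.values)
    dlat = float(np.abs(np.diff(lat)[0])) if lat.size > 1 else 1.0
    dlon = float(np.abs(np.diff(lon)[0])) if lon.size > 1 else 1.0
    a = (EARTH_RADIUS_KM ** 2 * np.deg2rad(dlat) * np.deg2rad(dlon)
         * np.cos(np.deg2rad(lat)))
    area = xr.ones_like(template) * xr.DataArray(a, coords={"lat": lat},
                                                 dims=("lat",))
    area.attrs["units"] = "km2"
    area.name = "cell_area"
    return area


def region_area_km2(mask: xr.DataArray) -> float:
    """Total spherical area (km^2) of a boolean region mask."""
    return float(cell_area_km2(mask).where(mask.astype(bool)).sum())


def _encode_bools(ds: xr.Dataset) -> xr.Dataset:
    # netCDF3 (scipy backend) has no boolean type
    out = ds.copy()
    for k, v in out.data_vars.items():
        if v.dtype == bool:
            out[k] = v.astype("i1")
            out[k].attrs["dtype"] = "bool"
    return out


def save_dataset(ds: xr.Dataset, path) -> None:
    """Write a dataset as classic NetCDF (CF-style lat/lon coordinates)."""
    _encode_bools(ds).to_netcdf(path, engine="scipy")


def open_dataset(path) -> xr.Dataset:
    """Read a dataset written by :func:`save_dataset`, restoring booleans."""
    ds = xr.open_dataset(path, engine="scipy").load()
    for k, v in ds.data_vars.items():
        if v.attrs.get("dtype") == "bool":
            ds[k] = v.astype(bool)
            ds[k].attrs.pop("dtype", None)
    return ds
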