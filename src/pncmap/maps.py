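"""Yearly prediction maps and the published NetCDF layout.

One file per year, named ``YYYY.nc``, with CF-style lat/lon coordinate
variables and three gridded fields in cm^-3:

* ``PNC`` — annual-mean particle number concentration (point prediction);
* ``CI``  — width of the 95% conformal coverage interval;
* ``UFP`` — estimated ultrafine concentration (fraction x PNC).

Sea cells and cells outside the supported latitude extent carry the fill
value (-9999) and share one mask across the three fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xarray as xr

from .conformal import ConformalModel, interval_width, jab_interval
from .fusion import FEATURE_NAMES, CovariateStack
from .grids import GridDefinition
from .ufp import FractionModel

FILL_VALUE = -9999.0
MAP_VARIABLES = ("PNC", "CI", "UFP")


@dataclass
class YearMaps:
    """Gridded annual PNC, interval width and UFP fields for one year."""

    grid: GridDefinition
    year: int
    pnc: np.ndarray
    ci: np.ndarray
    ufp: np.ndarray
    mask: np.ndarray  # True where the maps are undefined (sea / out of extent)

    def __post_init__(self) -> None:
        for name in ("pnc", "ci", "ufp", "mask"):
            if np.asarray(getattr(self, name)).shape != self.grid.shape:
                raise ValueError(f"{name} field does not conform to the grid")
        valid = ~self.mask
        for name in ("pnc", "ci", "ufp"):
            a = getattr(self, name)[valid]
            if a.size and (np.any(~np.isfinite(a)) or np.any(a < 0)):
                raise ValueError(f"{name} must be finite and non-negative where unmasked")


def predict_year_maps(
    conformal_model: ConformalModel,
    fraction_model: FractionModel,
    stack: CovariateStack,
    year: int,
    alpha: float | None = None,
) -> YearMaps:
    """Predict the three fields over every unmasked land cell of the stack."""
    if not stack.emissions_downscaled:
        raise ValueError("stack emissions must be downscaled before prediction")
    grid = stack.grid
    mask = stack.sea_mask.copy()
    pnc = np.full(grid.shape, FILL_VALUE)
    ci = np.full(grid.shape, FILL_VALUE)
    ufp = np.full(grid.shape, FILL_VALUE)

    rows, cols = np.where(~mask)
    if rows.size:
        X = np.column_stack([stack.layers[name][rows, cols] for name in FEATURE_NAMES])
        lower, upper, point = jab_interval(conformal_model, X, alpha=alpha)
        point = np.clip(point, 0.0, None)  # concentrations cannot be negative
        pnc[rows, cols] = point
        ci[rows, cols] = interval_width(lower, upper)
        ufp[rows, cols] = point * fraction_model.mean_fraction
    return YearMaps(grid=grid, year=int(year), pnc=pnc, ci=ci, ufp=ufp, mask=mask)


def write_year_netcdf(maps: YearMaps, directory: str | Path) -> Path:
    """Write one year's maps as ``<year>.nc`` in the published layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{maps.year}.nc"
    g = maps.grid

    def packed(a: np.ndarray) -> np.ndarray:
        out = np.asarray(a, dtype=float).copy()
        out[maps.mask] = FILL_VALUE
        return out

    long_names = {
        "PNC": "annual mean particle number concentration",
        "CI": "width of the 95% conformal coverage interval",
        "UFP": "estimated ultrafine particle number concentration",
    }
    fields = {"PNC": maps.pnc, "CI": maps.ci, "UFP": maps.ufp}
    ds = xr.Dataset(
        {
            name: (
                ("lat", "lon"),
                packed(arr),
                {"units": "cm-3", "long_name": long_names[name], "_FillValue": FILL_VALUE},
            )
            for name, arr in fields.items()
        },
        coords={
            "lat": ("lat", g.lat_centers, {"units": "degrees_north", "standard_name": "latitude"}),
            "lon": ("lon", g.lon_centers, {"units": "degrees_east", "standard_name": "longitude"}),
        },
        attrs={
            "title": "Annual particle number concentration surface",
            "year": maps.year,
            "Conventions": "CF-1.8",
            "source": "pncmap gradient-boosted exposure model with conformal intervals",
            "cell_size_deg": g.cell,
            "lat_min": g.lat_min,
            "lon_min": g.lon_min,
        },
    )
    # mask + fill handled manually above: disable xarray's encoding pass
    ds.to_netcdf(path, engine="scipy")
    return path


def read_year_netcdf(path: str | Path) -> YearMaps:
    """Read and validate one ``YYYY.nc`` file."""
    path = Path(path)
    with xr.open_dataset(path, engine="scipy", mask_and_scale=False) as ds:
        ds.load()
    for name in MAP_VARIABLES:
        if name not in ds.variables:
            raise ValueError(f"schema error: variable {name!r} missing from {path.name}")
        if ds[name].attrs.get("units") != "cm-3":
            raise ValueError(f"schema error: variable {name!r} lacks units 'cm-3'")
    for coord in ("lat", "lon"):
        if coord not in ds.variables:
            raise ValueError(f"schema error: coordinate {coord!r} missing from {path.name}")
    ny, nx = ds.sizes["lat"], ds.sizes["lon"]
    grid = GridDefinition(
        lat_min=float(ds.attrs["lat_min"]),
        lon_min=float(ds.attrs["lon_min"]),
        cell=float(ds.attrs["cell_size_deg"]),
        ny=ny,
        nx=nx,
    )
    pnc = np.asarray(ds["PNC"].values, dtype=float)
    ci = np.asarray(ds["CI"].values, dtype=float)
    ufp = np.asarray(ds["UFP"].values, dtype=float)
    mask = pnc == FILL_VALUE
    if not (np.array_equal(mask, ci == FILL_VALUE) and np.array_equal(mask, ufp == FILL_VALUE)):
        raise ValueError("schema error: PNC/CI/UFP fill masks differ")
    return YearMaps(
        grid=grid, year=int(ds.attrs["year"]), pnc=pnc, ci=ci, ufp=ufp, mask=mask
    )
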