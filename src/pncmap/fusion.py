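"""Assemble the 14-feature covariate table on the master grid.

The exposure model is trained on 14 gridded covariates: four human-activity
layers (population, built-up volume, degree of urbanisation, human
settlement), the rasterized road network, two ambient pollutant layers
(NO2, PM2.5), four combustion-emission species on a coarser grid (black
carbon, CO, CO2, NOx), and three meteorological layers (temperature,
boundary-layer height, precipitation).

Coarse emission totals are downscaled dasymetrically to the master grid by
weighting with the fine-cell shares of population and built-up volume:

    Em_fine = Em_coarse * (Pop_fine/Pop_coarse + BV_fine/BV_coarse) / 2

which conserves each coarse-block total exactly. Roads arrive as line
geometries and become per-cell intersection counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import LineString, box

from .grids import LAT_EXTENT, GridDefinition
from .harmonize import AnnualObservation

logger = logging.getLogger(__name__)

#: The 14 model features, in fixed column order.
FEATURE_NAMES = (
    "population",
    "built_up_volume",
    "urbanisation",
    "settlement",
    "road_network",
    "no2",
    "pm25",
    "bc_emission",
    "co_emission",
    "co2_emission",
    "nox_emission",
    "temperature",
    "blh",
    "precipitation",
)

#: Emission layers stored block-constant on the coarse grid until downscaled.
EMISSION_NAMES = ("bc_emission", "co_emission", "co2_emission", "nox_emission")

#: Layers regridded by nearest neighbour (categorical / indicator).
CATEGORICAL_NAMES = ("urbanisation",)


@dataclass
class CovariateStack:
    """Master grid plus the 14 named covariate layers and a sea mask."""

    grid: GridDefinition
    layers: dict[str, np.ndarray]
    sea_mask: np.ndarray  # True over sea (excluded from modelling)
    coarse_grid: GridDefinition = None  # emission-grid definition
    emissions_downscaled: bool = False

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.layers)
        extra = set(self.layers) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(
                f"layer names must be exactly the 14 features; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        for name, arr in self.layers.items():
            if np.asarray(arr).shape != self.grid.shape:
                raise ValueError(f"layer {name!r} does not conform to the grid")
        if np.asarray(self.sea_mask).shape != self.grid.shape:
            raise ValueError("sea mask does not conform to the grid")

    @property
    def land_mask(self) -> np.ndarray:
        return ~self.sea_mask


# ---------------------------------------------------------------------------
# Dasymetric emission downscaling
# ---------------------------------------------------------------------------

def _block_view(a: np.ndarray, f: int) -> np.ndarray:
    """(ny, nx) -> (ny/f, nx/f, f, f) block view."""
    ny, nx = a.shape
    return a.reshape(ny // f, f, nx // f, f).swapaxes(1, 2)


def downscale_emissions(
    em_coarse: np.ndarray,
    pop_fine: np.ndarray,
    bv_fine: np.ndarray,
    coarse_factor: int,
) -> np.ndarray:
    """Redistribute per-coarse-cell emission totals onto the fine grid.

    Each fine cell receives ``Em_coarse * (pop_share + bv_share) / 2`` where
    the shares are the cell's fraction of the coarse block's population and
    built-up-volume sums. A block whose population (or built-up) sum is zero
    uses the uniform share ``1/k`` for that term, preserving conservation.
    """
    em_coarse = np.asarray(em_coarse, dtype=float)
    pop = np.asarray(pop_fine, dtype=float)
    bv = np.asarray(bv_fine, dtype=float)
    if np.any(em_coarse < 0) or np.any(pop < 0) or np.any(bv < 0):
        raise ValueError("emissions, population and built-up volume must be >= 0")
    f = int(coarse_factor)
    ny, nx = pop.shape
    if ny % f or nx % f or em_coarse.shape != (ny // f, nx // f):
        raise ValueError("fine cells must partition each coarse cell exactly")

    k = f * f

    def shares(w: np.ndarray) -> np.ndarray:
        blocks = _block_view(w, f)  # (nyc, nxc, f, f)
        sums = blocks.sum(axis=(2, 3), keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(sums > 0, blocks / np.where(sums > 0, sums, 1.0), 1.0 / k)
        return s

    weight = 0.5 * (shares(pop) + shares(bv))  # (nyc, nxc, f, f), sums to 1/block
    em_fine_blocks = em_coarse[:, :, None, None] * weight
    return em_fine_blocks.swapaxes(1, 2).reshape(ny, nx)


def coarse_totals(layer_fine: np.ndarray, coarse_factor: int, mode: str = "first") -> np.ndarray:
    """Per-coarse-block value of a block-constant fine layer (or block sum)."""
    blocks = _block_view(np.asarray(layer_fine, dtype=float), int(coarse_factor))
    if mode == "first":
        return blocks[:, :, 0, 0].copy()
    if mode == "sum":
        return blocks.sum(axis=(2, 3))
    raise ValueError(f"unknown mode {mode!r}")


def downscale_stack(stack: CovariateStack, coarse_factor: int | None = None) -> CovariateStack:
    """Replace the block-constant emission layers with downscaled ones."""
    if stack.emissions_downscaled:
        return stack
    if coarse_factor is None:
        if stack.coarse_grid is None:
            raise ValueError("no coarse grid recorded on the stack")
        coarse_factor = round(stack.coarse_grid.cell / stack.grid.cell)
    layers = dict(stack.layers)
    pop, bv = layers["population"], layers["built_up_volume"]
    for name in EMISSION_NAMES:
        totals = coarse_totals(layers[name], coarse_factor, mode="first")
        layers[name] = downscale_emissions(totals, pop, bv, coarse_factor)
    return CovariateStack(
        grid=stack.grid,
        layers=layers,
        sea_mask=stack.sea_mask,
        coarse_grid=stack.coarse_grid,
        emissions_downscaled=True,
    )


# ---------------------------------------------------------------------------
# Road rasterization
# ---------------------------------------------------------------------------

def _candidate_cells(seg: LineString, grid: GridDefinition) -> set[tuple[int, int]]:
    """Cells whose closed box the segment's pieces might touch (superset)."""
    cands: set[tuple[int, int]] = set()
    coords = list(seg.coords)
    lat_e, lon_e = grid.lat_edges, grid.lon_edges
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        # x = lon, y = lat
        j0 = int(np.clip(np.searchsorted(lon_e, min(x0, x1), "right") - 1, 0, grid.nx - 1))
        j1 = int(np.clip(np.searchsorted(lon_e, max(x0, x1), "right") - 1, 0, grid.nx - 1))
        for j in range(j0, j1 + 1):
            lo, hi = lon_e[j], lon_e[j + 1]
            xs = np.clip([x0, x1], lo, hi)
            if x1 != x0:
                t = np.clip((np.array(xs) - x0) / (x1 - x0), 0.0, 1.0)
            else:
                t = np.array([0.0, 1.0])
            ys = y0 + t * (y1 - y0)
            ymin, ymax = min(ys), max(ys)
            i0 = int(np.clip(np.searchsorted(lat_e, ymin, "right") - 1, 0, grid.ny - 1))
            i1 = int(np.clip(np.searchsorted(lat_e, ymax, "right") - 1, 0, grid.ny - 1))
            for i in range(i0, i1 + 1):
                cands.add((i, j))
                # neighbours guard against float round-off at shared edges
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < grid.ny and 0 <= jj < grid.nx:
                        cands.add((ii, jj))
    return cands


def rasterize_roads(segments: Sequence[LineString], grid: GridDefinition) -> np.ndarray:
    """Count, per cell, the distinct road segments intersecting it.

    Cells are half-open ``[edge, edge + size)``: geometry lying exactly on a
    shared edge is counted only in the cell whose half-open box contains the
    edge (the cell on the increasing side, or the last cell on the outer
    maximum boundary). Segments are clipped to the grid bounding box.
    """
    counts = np.zeros(grid.shape, dtype=int)
    domain = box(grid.lon_min, grid.lat_min, grid.lon_max, grid.lat_max)
    lat_e, lon_e = grid.lat_edges, grid.lon_edges
    for seg in segments:
        if not isinstance(seg, LineString):
            seg = LineString(seg)
        clipped = seg.intersection(domain)
        if clipped.is_empty:
            continue
        parts = getattr(clipped, "geoms", [clipped])
        seen: set[tuple[int, int]] = set()
        for part in parts:
            if part.is_empty or not isinstance(part, LineString):
                continue
            for (i, j) in _candidate_cells(part, grid):
                if (i, j) in seen:
                    continue
                cellbox = box(lon_e[j], lat_e[i], lon_e[j + 1], lat_e[i + 1])
                inter = part.intersection(cellbox)
                if inter.is_empty:
                    continue
                minx, miny, maxx, maxy = inter.bounds
                # exclude geometry confined to the cell's max-edge lines —
                # it belongs to the neighbouring half-open cell
                on_right = minx == maxx == lon_e[j + 1] and j + 1 < grid.nx
                on_top = miny == maxy == lat_e[i + 1] and i + 1 < grid.ny
                if on_right or on_top:
                    continue
                seen.add((i, j))
        for (i, j) in seen:
            counts[i, j] += 1
    return counts


# ---------------------------------------------------------------------------
# Regridding
# ---------------------------------------------------------------------------

def regrid_to_master(
    layer: np.ndarray,
    native: GridDefinition,
    master: GridDefinition,
    mode: str = "block_mean",
) -> np.ndarray:
    """Bring a layer from its native grid onto the master grid.

    ``nearest`` assigns each master cell the native cell containing its
    center (categorical/indicator layers); ``block_mean`` averages the
    native cells whose centers fall inside each master cell (continuous
    layers), falling back to nearest where no native center lands. Identical
    grids return the layer unchanged.
    """
    layer = np.asarray(layer, dtype=float)
    if layer.shape != native.shape:
        raise ValueError("layer does not conform to its native grid")
    if native.same_as(master):
        return layer.copy()
    overlap = (
        native.lat_min < master.lat_max
        and master.lat_min < native.lat_max
        and native.lon_min < master.lon_max
        and master.lon_min < native.lon_max
    )
    if not overlap:
        raise ValueError("native and master grids are disjoint")

    def native_index(lat, lon):
        r = np.floor((lat - native.lat_min) / native.cell).astype(int)
        c = np.floor((lon - native.lon_min) / native.cell).astype(int)
        return np.clip(r, 0, native.ny - 1), np.clip(c, 0, native.nx - 1)

    if mode == "nearest" or native.cell > master.cell:
        nearest_vals = _nearest(layer, native, master, native_index)
        if mode == "nearest":
            return nearest_vals
        # block_mean requested but native is coarser: nearest is the block mean
        return nearest_vals
    if mode != "block_mean":
        raise ValueError(f"unknown regrid mode {mode!r}")

    # native finer (or equal cell, offset): average native centers per master cell
    lat_c = np.repeat(native.lat_centers, native.nx)
    lon_c = np.tile(native.lon_centers, native.ny)
    inside = master.contains(lat_c, lon_c)
    sums = np.zeros(master.shape)
    cnts = np.zeros(master.shape)
    r, c = master.cell_index(lat_c[inside], lon_c[inside])
    np.add.at(sums, (r, c), layer.ravel()[inside])
    np.add.at(cnts, (r, c), 1.0)
    out = np.divide(sums, cnts, out=np.zeros_like(sums), where=cnts > 0)
    if np.any(cnts == 0):
        out = np.where(cnts > 0, out, _nearest(layer, native, master, native_index))
    return out


def _nearest(layer, native, master, native_index):
    glat = master.lat_centers[:, None] * np.ones((1, master.nx))
    glon = np.ones((master.ny, 1)) * master.lon_centers[None, :]
    r, c = native_index(glat, glon)
    return layer[r, c]


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """One row per (station, year): 14 features plus the annual-mean target."""

    frame: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("station_id", "year", "lat", "lon") + FEATURE_NAMES + ("pnc_annual",)

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        self.frame = self.frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if self.frame[list(FEATURE_NAMES) + ["pnc_annual"]].isna().any().any():
            raise ValueError("feature table contains missing values")
        dup = self.frame.duplicated(subset=["station_id", "year"])
        if dup.any():
            raise ValueError("feature table has duplicate (station, year) rows")

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[list(FEATURE_NAMES)]

    @property
    def y(self) -> pd.Series:
        return self.frame["pnc_annual"]

    def __len__(self) -> int:
        return len(self.frame)


def assemble_features(
    observations: Sequence[AnnualObservation],
    stack: CovariateStack,
    years: Sequence[int] | None = None,
) -> FeatureTable:
    """Join each annual observation to the covariates of its containing cell.

    Observations outside the grid (or the supported latitude extent) and
    observations falling on sea-masked cells are dropped; the drop reasons
    are logged and kept on the returned table.
    """
    if not stack.emissions_downscaled:
        raise ValueError("downscale the stack's emission layers before assembling")
    rows, dropped = [], []
    for o in observations:
        if years is not None and o.year not in years:
            continue
        if not (LAT_EXTENT[0] <= o.lat <= LAT_EXTENT[1]) or not bool(
            stack.grid.contains(o.lat, o.lon)
        ):
            dropped.append((o.station_id, o.year, "outside_extent"))
            continue
        r, c = stack.grid.cell_index(o.lat, o.lon)
        r, c = int(r), int(c)
        if stack.sea_mask[r, c]:
            dropped.append((o.station_id, o.year, "sea_cell"))
            continue
        row = {
            "station_id": o.station_id,
            "year": o.year,
            "lat": o.lat,
            "lon": o.lon,
            "pnc_annual": o.pnc_annual,
        }
        for name in FEATURE_NAMES:
            row[name] = float(stack.layers[name][r, c])
        rows.append(row)
    dropped_df = pd.DataFrame(dropped, columns=["station_id", "year", "reason"])
    for _, d in dropped_df.iterrows():
        logger.info(
            "dropped station-year %s/%s: %s", d["station_id"], d["year"], d["reason"]
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(columns=list(FeatureTable.COLUMNS))
    return FeatureTable(frame=frame, dropped=dropped_df)


# ---------------------------------------------------------------------------
# Stack serialization
# ---------------------------------------------------------------------------

def write_stack_netcdf(stack: CovariateStack, path: str | Path) -> Path:
    """One NetCDF variable per feature plus the sea mask."""
    path = Path(path)
    g = stack.grid
    data = {
        name: (("lat", "lon"), np.asarray(stack.layers[name], dtype=float))
        for name in FEATURE_NAMES
    }
    data["sea_mask"] = (("lat", "lon"), stack.sea_mask.astype(np.int8))
    ds = xr.Dataset(
        data,
        coords={
            "lat": ("lat", g.lat_centers, {"units": "degrees_north"}),
            "lon": ("lon", g.lon_centers, {"units": "degrees_east"}),
        },
        attrs={
            "cell_size_deg": g.cell,
            "lat_min": g.lat_min,
            "lon_min": g.lon_min,
            "coarse_cell_size_deg": stack.coarse_grid.cell if stack.coarse_grid else -1.0,
            "emissions_downscaled": int(stack.emissions_downscaled),
        },
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def read_stack_netcdf(path: str | Path) -> CovariateStack:
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        ds.load()
    ny, nx = ds.sizes["lat"], ds.sizes["lon"]
    grid = GridDefinition(
        lat_min=float(ds.attrs["lat_min"]),
        lon_min=float(ds.attrs["lon_min"]),
        cell=float(ds.attrs["cell_size_deg"]),
        ny=ny,
        nx=nx,
    )
    coarse_cell = float(ds.attrs.get("coarse_cell_size_deg", -1.0))
    coarse = None
    if coarse_cell > 0:
        factor = round(coarse_cell / grid.cell)
        coarse = grid.coarsen(factor)
    layers = {name: np.asarray(ds[name].values, dtype=float) for name in FEATURE_NAMES}
    return CovariateStack(
        grid=grid,
        layers=layers,
        sea_mask=np.asarray(ds["sea_mask"].values).astype(bool),
        coarse_grid=coarse,
        emissions_downscaled=bool(int(ds.attrs.get("emissions_downscaled", 0))),
    )
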