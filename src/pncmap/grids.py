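"""Regular latitude-longitude grids.

Everything downstream (covariate layers, rasterized roads, prediction maps)
lives on a plate-carrée grid of square cells in degrees. Cells are half-open
``[edge, edge + size)`` in both axes; points landing exactly on the outer
maximum boundary are assigned to the last cell so that the grid partitions
its bounding box without double counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Latitude extent of the modelling domain (degrees). The exposure surface
#: is only defined where the covariate products overlap.
LAT_EXTENT = (-55.0, 68.0)


@dataclass(frozen=True)
class GridDefinition:
    """A regular lat/lon grid of square half-open cells.

    Parameters
    ----------
    lat_min, lon_min
        Coordinates of the outer south-west corner (degrees).
    cell
        Cell edge length in degrees (default 0.01, roughly 1 km at the
        equator).
    ny, nx
        Number of rows (latitude) and columns (longitude).
    """

    lat_min: float
    lon_min: float
    cell: float
    ny: int
    nx: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")
        if self.ny <= 0 or self.nx <= 0:
            raise ValueError(f"grid dimensions must be positive, got {self.ny}x{self.nx}")
        if self.lat_min < LAT_EXTENT[0] - 1e-9 or self.lat_max > LAT_EXTENT[1] + 1e-9:
            raise ValueError(
                f"grid latitude range [{self.lat_min}, {self.lat_max}] outside "
                f"the supported extent {LAT_EXTENT}"
            )

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.ny * self.cell

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.nx * self.cell

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat_min + self.cell * np.arange(self.ny + 1)

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon_min + self.cell * np.arange(self.nx + 1)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.cell * (np.arange(self.ny) + 0.5)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.cell * (np.arange(self.nx) + 0.5)

    def contains(self, lat, lon) -> np.ndarray:
        """Vectorized point-in-grid test (closed on the outer max boundary)."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return (
            (lat >= self.lat_min)
            & (lat <= self.lat_max)
            & (lon >= self.lon_min)
            & (lon <= self.lon_max)
        )

    def cell_index(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (row, col) under the half-open cell convention.

        Points exactly on the outer maximum boundary fall in the last
        row/column. Raises for points outside the grid.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if not np.all(self.contains(lat, lon)):
            raise ValueError("point(s) outside the grid bounding box")
        row = np.floor((lat - self.lat_min) / self.cell).astype(int)
        col = np.floor((lon - self.lon_min) / self.cell).astype(int)
        return np.clip(row, 0, self.ny - 1), np.clip(col, 0, self.nx - 1)

    def coarsen(self, factor: int) -> "GridDefinition":
        """The grid of ``factor``-times larger cells over the same extent."""
        if factor <= 0 or self.ny % factor or self.nx % factor:
            raise ValueError(
                f"coarsening factor {factor} must divide grid shape {self.shape}"
            )
        return GridDefinition(
            lat_min=self.lat_min,
            lon_min=self.lon_min,
            cell=self.cell * factor,
            ny=self.ny // factor,
            nx=self.nx // factor,
        )

    def same_as(self, other: "GridDefinition", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.lat_min - other.lat_min) <= tol
            and abs(self.lon_min - other.lon_min) <= tol
            and abs(self.cell - other.cell) <= tol
        )
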