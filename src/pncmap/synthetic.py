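"""Synthetic station network and covariate world.

Real PNC mapping fuses station measurements (flagged, gappy, multi-network)
with gridded covariates that are strongly cross-correlated: population
clusters drive built-up volume, emissions and ambient NO2, while weather
fields vary smoothly. This module generates a small world with exactly that
structure plus a *known* latent annual-mean PNC surface, so every pipeline
stage — harmonization, fusion, modelling, conformal intervals, mapping —
can be tested end-to-end without downloading anything.

Key generator facts (see docs/methods.md for rationale):

* station-day size distributions are two-mode lognormal mixtures
  (geometric means ~20 nm and ~150 nm, geometric SD ~1.7) whose mode
  weights are set so the sub-100 nm number fraction follows
  Beta(18.75, 1.89), matching the fraction model fitted downstream;
* the default diameter grid places a bin border exactly at 100 nm, so the
  discretized fraction reproduces the drawn one without apportionment bias;
* daily totals are the local latent PNC times mean-corrected lognormal
  day and station-year factors;
* quality flags are valid (0.000/0.100) except with a configured invalid
  rate, and whole days drop out at a configured rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import LineString

from .fusion import EMISSION_NAMES, CovariateStack, rasterize_roads
from .grids import GridDefinition
from .harmonize import SizeGrid, StationRecord
from .stationio import write_pnc_text, write_psd_netcdf

#: Default PSD diameters (nm): log-uniform, 0.1-decade spacing, chosen so
#: that 100 nm is an exact bin border (geometric midpoint of 89.1 and 112).
DEFAULT_DIAMETERS = tuple(float(d) for d in 10.0 ** (0.55 + 0.1 * np.arange(25)))

#: Lognormal PSD modes: (geometric mean nm, geometric SD).
PSD_MODES = ((20.0, 1.7), (150.0, 1.7))

#: Invalid quality-flag codes drawn for corrupted records (EBAS dialect).
INVALID_FLAGS = (0.459, 0.599, 0.999)


@dataclass(frozen=True)
class TruthParams:
    """Coefficients of the latent log-linear PNC surface.

    ``pnc_true = exp(b0 + b1*log1p(BV) + b2*z(NO2) + b3*z(BC)
                     - b4*z(BLH) + b5*z(T))``

    with layers standardized over land cells. Defaults put rural cells in
    the low thousands of cm^-3 and dense urban cells above 10^4 cm^-3.
    """

    b0: float = 4.6
    b1: float = 0.33
    b2: float = 0.30
    b3: float = 0.20
    b4: float = 0.15
    b5: float = 0.05

    def as_array(self) -> np.ndarray:
        a = np.array([self.b0, self.b1, self.b2, self.b3, self.b4, self.b5])
        if not np.all(np.isfinite(a)):
            raise ValueError("truth coefficients must be finite")
        return a


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world."""

    seed: int = 0
    nx: int = 80
    ny: int = 80
    cell: float = 0.01
    lat_min: float = 40.0
    lon_min: float = 10.0
    coarse_factor: int = 10
    n_clusters: int = 5
    n_stations: int = 40
    years: tuple[int, ...] = (2013, 2014, 2015)
    flag_invalid_rate: float = 0.05
    day_dropout_rate: float = 0.10
    day_sigma: float = 0.3
    year_sigma: float = 0.1
    truth_params: TruthParams = field(default_factory=TruthParams)
    fraction_alpha: float = 18.75
    fraction_beta: float = 1.89
    pnc_only_fraction: float = 0.3
    sea_border: int = 2
    diameters: tuple[float, ...] = tuple(DEFAULT_DIAMETERS)

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.coarse_factor <= 0 or self.nx % self.coarse_factor or self.ny % self.coarse_factor:
            raise ValueError("coarse_factor must divide nx and ny")
        for name in ("flag_invalid_rate", "day_dropout_rate", "pnc_only_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_alpha <= 0 or self.fraction_beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if len(self.years) == 0:
            raise ValueError("years must be non-empty")
        if len(self.diameters) < 10:
            raise ValueError("need at least 10 PSD diameters")

    @property
    def grid(self) -> GridDefinition:
        return GridDefinition(
            lat_min=self.lat_min, lon_min=self.lon_min, cell=self.cell,
            ny=self.ny, nx=self.nx,
        )

    @property
    def size_grid(self) -> SizeGrid:
        return SizeGrid.from_diameters(np.asarray(self.diameters))


@dataclass
class TruthSurface:
    """Latent annual-mean PNC per cell — the generator's ground truth."""

    grid: GridDefinition
    pnc_true: np.ndarray  # cm^-3, strictly positive

    def __post_init__(self) -> None:
        if np.asarray(self.pnc_true).shape != self.grid.shape:
            raise ValueError("truth surface does not conform to the grid")
        if not np.all(np.isfinite(self.pnc_true)) or np.any(self.pnc_true <= 0):
            raise ValueError("latent PNC must be finite and strictly positive")


# ---------------------------------------------------------------------------
# Covariate world
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-variance smooth Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    return (f - f.mean()) / (f.std() + 1e-12)


def gen_covariate_world(config: WorldConfig) -> CovariateStack:
    """Generate the 14 covariate layers, sea mask and road geometry.

    Population is a sum of Gaussian clusters (people per ~1 km^2 cell);
    built-up volume and settlement are monotone noisy functions of it;
    emissions are block-constant on the coarse grid and increase with block
    population; NO2 and PM2.5 are smoothed transforms of emissions and
    population; temperature, boundary-layer height and precipitation are
    smooth random fields. The sea mask is a fixed border band.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    ny, nx = grid.shape

    sea = np.zeros((ny, nx), dtype=bool)
    b = config.sea_border
    if b > 0:
        sea[:b, :] = sea[-b:, :] = True
        sea[:, :b] = sea[:, -b:] = True

    # --- population: clustered blobs over land + a small diffuse floor
    rows, cols = np.mgrid[0:ny, 0:nx]
    land_r, land_c = np.where(~sea)
    centers_idx = rng.choice(land_r.size, size=config.n_clusters, replace=False)
    pop = np.zeros((ny, nx))
    centers = []
    for k in centers_idx:
        cr, cc = land_r[k], land_c[k]
        centers.append((cr, cc))
        amp = rng.lognormal(mean=np.log(4000.0), sigma=0.5)
        width = rng.uniform(3.0, 7.0)
        pop += amp * np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * width**2))
    pop += rng.uniform(0.0, 30.0, size=pop.shape)
    pop[sea] = 0.0

    # --- built environment: monotone noisy transforms of population
    bv = 500.0 * pop**0.9 * rng.lognormal(0.0, 0.25, size=pop.shape)
    settlement = ndimage.gaussian_filter(pop, 1.5, mode="nearest") * rng.lognormal(
        0.0, 0.15, size=pop.shape
    )
    urb = np.ones_like(pop)
    urb[pop > 250.0] = 2.0
    urb[pop > 800.0] = 3.0

    # --- roads: segments joining cluster centres, rasterized to counts
    def cell_lonlat(rc):
        r, c = rc
        return (grid.lon_min + (c + 0.5) * grid.cell, grid.lat_min + (r + 0.5) * grid.cell)

    segments = []
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            segments.append(LineString([cell_lonlat(centers[i]), cell_lonlat(centers[j])]))
    roads = rasterize_roads(segments, grid).astype(float)

    # --- emissions: block-constant on the coarse grid, scale with block population
    f = config.coarse_factor
    block_pop = pop.reshape(ny // f, f, nx // f, f).sum(axis=(1, 3))
    scales = {"bc_emission": 0.002, "co_emission": 0.5, "co2_emission": 50.0, "nox_emission": 0.1}
    emissions = {}
    for name, s in scales.items():
        noise = rng.lognormal(0.0, 0.2, size=block_pop.shape)
        coarse_tot = s * (block_pop + 1.0) ** 0.9 * noise
        emissions[name] = np.repeat(np.repeat(coarse_tot, f, axis=0), f, axis=1)

    # --- ambient pollutants: smoothed emission/population transforms + noise
    nox_proxy = emissions["nox_emission"] / emissions["nox_emission"].max()
    no2 = (
        40.0 * ndimage.gaussian_filter(pop / (pop.max() + 1e-12), 3.0, mode="nearest")
        + 15.0 * ndimage.gaussian_filter(nox_proxy, 2.0, mode="nearest")
        + 2.0
        + 1.5 * rng.standard_normal(pop.shape)
    )
    no2 = np.clip(no2, 0.5, None)
    bc_proxy = emissions["bc_emission"] / emissions["bc_emission"].max()
    pm25 = (
        8.0
        + 25.0 * ndimage.gaussian_filter(bc_proxy, 3.0, mode="nearest")
        + 1.0 * rng.standard_normal(pop.shape)
    )
    pm25 = np.clip(pm25, 1.0, None)

    # --- meteorology: smooth random fields in plausible units
    temperature = 288.0 + 5.0 * _smooth_field(rng, pop.shape, 8.0)
    blh = np.clip(600.0 + 250.0 * _smooth_field(rng, pop.shape, 8.0), 100.0, None)
    precipitation = np.clip(800.0 + 400.0 * _smooth_field(rng, pop.shape, 10.0), 0.0, None)

    layers = {
        "population": pop,
        "built_up_volume": bv,
        "urbanisation": urb,
        "settlement": settlement,
        "road_network": roads,
        "no2": no2,
        "pm25": pm25,
        "temperature": temperature,
        "blh": blh,
        "precipitation": precipitation,
        **emissions,
    }
    return CovariateStack(
        grid=grid,
        layers=layers,
        sea_mask=sea,
        coarse_grid=grid.coarsen(f),
        emissions_downscaled=False,
    )


# ---------------------------------------------------------------------------
# Latent truth surface
# ---------------------------------------------------------------------------

def _zscore(a: np.ndarray, mask: np.ndarray) -> np.ndarray:
    m, s = a[mask].mean(), a[mask].std()
    return (a - m) / (s + 1e-12)


def gen_truth_pnc(stack: CovariateStack, params: TruthParams | None = None) -> TruthSurface:
    """Latent annual-mean PNC from built-up volume, pollution and weather."""
    p = params or TruthParams()
    b = p.as_array()
    land = stack.land_mask
    log_pnc = (
        b[0]
        + b[1] * np.log1p(stack.layers["built_up_volume"])
        + b[2] * _zscore(stack.layers["no2"], land)
        + b[3] * _zscore(stack.layers["bc_emission"], land)
        - b[4] * _zscore(stack.layers["blh"], land)
        + b[5] * _zscore(stack.layers["temperature"], land)
    )
    return TruthSurface(grid=stack.grid, pnc_true=np.exp(log_pnc))


# ---------------------------------------------------------------------------
# Station records
# ---------------------------------------------------------------------------

def _mode_bin_masses(size_grid: SizeGrid) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-bin number mass of each lognormal mode (normalized to the grid)
    and each mode's sub-100 nm share on the grid."""
    b = size_grid.borders
    masses = []
    below = []
    for gm, gsd in PSD_MODES:
        z = (np.log(b) - math.log(gm)) / math.log(gsd)
        cdf = stats.norm.cdf(z)
        m = np.diff(cdf)
        m = m / m.sum()
        masses.append(m)
        below.append(float(m[b[1:] <= 100.0 + 1e-9].sum()))
    return masses[0], masses[1], below[0], below[1]


def gen_station_records(
    truth: TruthSurface,
    stack: CovariateStack,
    config: WorldConfig,
) -> tuple[list[StationRecord], pd.DataFrame, SizeGrid]:
    """Generate sub-daily station records plus the station registry.

    Stations sit preferentially in high-population cells (probability
    proportional to population plus a uniform floor, land only). PSD
    stations report one dN/dlog10 D spectrum per day whose integrated total
    equals the local latent PNC times mean-corrected lognormal station-year
    and day factors, and whose sub-100 nm fraction is a Beta draw;
    PNC-only stations report the daily total directly.
    """
    if len(config.years) == 0:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    grid = truth.grid
    land_r, land_c = np.where(stack.land_mask)
    if config.n_stations > land_r.size:
        raise ValueError("more stations than land cells")

    pop = stack.layers["population"][land_r, land_c]
    prob = pop + 0.1 * pop.mean() + 1e-9
    prob = prob / prob.sum()
    picks = rng.choice(land_r.size, size=config.n_stations, replace=False, p=prob)

    size_grid = config.size_grid
    m1, m2, p1, p2 = _mode_bin_masses(size_grid)

    records: list[StationRecord] = []
    registry_rows = []
    n_pnc_only = int(round(config.pnc_only_fraction * config.n_stations))

    for s, k in enumerate(picks):
        r, c = int(land_r[k]), int(land_c[k])
        sid = f"ST{s:03d}"
        lat = grid.lat_min + (r + rng.uniform(0.2, 0.8)) * grid.cell
        lon = grid.lon_min + (c + rng.uniform(0.2, 0.8)) * grid.cell
        kind = "PNC" if s < n_pnc_only else "PSD"
        registry_rows.append(
            {"station_id": sid, "lat": lat, "lon": lon, "kind": kind, "row": r, "col": c}
        )
        base = truth.pnc_true[r, c]
        for year in config.years:
            days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D", tz="UTC")
            keep = rng.random(days.size) >= config.day_dropout_rate
            days = days[keep]
            yf = math.exp(
                rng.normal(-0.5 * config.year_sigma**2, config.year_sigma)
            )
            df_ = np.exp(
                rng.normal(-0.5 * config.day_sigma**2, config.day_sigma, size=days.size)
            )
            totals = base * yf * df_
            invalid = rng.random(days.size) < config.flag_invalid_rate
            if kind == "PSD":
                fracs = rng.beta(config.fraction_alpha, config.fraction_beta, size=days.size)
                w = np.clip((fracs - p2) / (p1 - p2), 0.0, 1.0)
                spectra = totals[:, None] * (
                    w[:, None] * m1[None, :] + (1.0 - w)[:, None] * m2[None, :]
                ) / size_grid.log_widths[None, :]
                flags = np.where(
                    invalid,
                    rng.choice(INVALID_FLAGS, size=days.size),
                    rng.choice([0.0, 0.1], size=days.size),
                )
                for i, day in enumerate(days):
                    records.append(
                        StationRecord(
                            station_id=sid,
                            timestamp=day + pd.Timedelta(hours=12),
                            kind="PSD",
                            values=spectra[i],
                            flag=float(flags[i]),
                        )
                    )
            else:
                flags = np.where(invalid, 999.0, 0.0)
                for i, day in enumerate(days):
                    records.append(
                        StationRecord(
                            station_id=sid,
                            timestamp=day + pd.Timedelta(hours=12),
                            kind="PNC",
                            values=np.array([totals[i]]),
                            flag=float(flags[i]),
                        )
                    )
    registry = pd.DataFrame(registry_rows)
    return records, registry, size_grid


def write_station_files(
    records: Sequence[StationRecord],
    registry: pd.DataFrame,
    size_grid: SizeGrid,
    directory: str | Path,
) -> list[Path]:
    """Serialize records per station: PSD -> NetCDF dialect, PNC -> flat text."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_station: dict[str, list[StationRecord]] = {}
    for rec in records:
        by_station.setdefault(rec.station_id, []).append(rec)
    paths = []
    for _, row in registry.iterrows():
        recs = by_station.get(row["station_id"], [])
        if not recs:
            continue
        recs.sort(key=lambda r: r.timestamp)
        times = [r.timestamp for r in recs]
        flags = [r.flag for r in recs]
        if row["kind"] == "PSD":
            path = write_psd_netcdf(
                directory / f"{row['station_id']}.nc",
                row["station_id"], row["lat"], row["lon"],
                times, size_grid, np.vstack([r.values for r in recs]), flags,
            )
        else:
            path = write_pnc_text(
                directory / f"{row['station_id']}.nas",
                row["station_id"], row["lat"], row["lon"],
                times, [float(r.values[0]) for r in recs], [int(f) for f in flags],
            )
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Synthetic regression benchmark (for conformal-coverage validation)
# ---------------------------------------------------------------------------

def make_nonlinear_regression(
    n: int, seed: int, noise_sd: float = 1.0, n_features: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Friedman-style nonlinear regression with homoscedastic Gaussian noise.

    ``y = 10 sin(pi x0 x1) + 20 (x2 - 0.5)^2 + 10 x3 + 5 x4 + N(0, sd^2)``
    with features uniform on [0, 1].
    """
    if n_features < 5:
        raise ValueError("needs at least 5 features")
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, n_features))
    y = (
        10.0 * np.sin(np.pi * X[:, 0] * X[:, 1])
        + 20.0 * (X[:, 2] - 0.5) ** 2
        + 10.0 * X[:, 3]
        + 5.0 * X[:, 4]
        + rng.normal(0.0, noise_sd, size=n)
    )
    return X, y
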