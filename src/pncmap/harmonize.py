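"""Harmonize raw station records into annual-mean PNC observations.

Station networks report either particle number size distributions (PSD,
``dN/dlog10 D`` over discrete diameters) or total particle number
concentrations (PNC). This module turns both into one common training unit:
the (station, year) annual-mean PNC in cm^-3, applying the quality-control
and aggregation rules used for long-term aerosol climatologies:

* only records with valid/verified quality flags are kept;
* PSDs are integrated to totals by summing ``dN/dlog10 D`` times the
  logarithmic bin width, with bin borders placed at geometric midpoints
  between the reported diameters (log-linearly extrapolated at the ends);
* sub-daily records are averaged to daily means and daily means to the
  annual mean, and a station-year is rejected unless it covers at least
  150 unique calendar days.

The sub-100 nm (ultrafine) number fraction of each PSD is computed alongside,
feeding the Beta fraction model in :mod:`pncmap.ufp`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Quality flags accepted in the NetCDF (EBAS-style) dialect:
#: 0.000 = valid measurement, 0.100 = checked by originator, valid.
VALID_FLAGS_EBAS = (0.0, 0.1)
#: Flags accepted in the flat-text dialect (numflag column): 0 = valid.
VALID_FLAGS_TEXT = (0,)

#: Minimum number of unique calendar days for a station-year to count.
MIN_UNIQUE_DAYS = 150

#: Ultrafine cutoff diameter (nm): particles below this are UFPs.
UFP_CUTOFF_NM = 100.0


# ---------------------------------------------------------------------------
# Size-grid construction (bin borders and logarithmic widths)
# ---------------------------------------------------------------------------

def bin_borders(diameters: Sequence[float]) -> np.ndarray:
    """Bin borders for discrete PSD diameters, in nm.

    Interior borders sit at the geometric midpoint of adjacent diameters,
    ``b_i = sqrt(D_{i-1} * D_i)``; the outer borders extrapolate the same
    log-spacing outward:

    ``b_0 = 10^(1.5 log10 D_0 - 0.5 log10 D_1)`` and
    ``b_N = 10^(1.5 log10 D_{N-1} - 0.5 log10 D_{N-2})``.
    """
    d = np.asarray(diameters, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need at least two diameters")
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("diameters must be positive and finite")
    if np.any(np.diff(d) <= 0):
        raise ValueError("diameters must be strictly increasing")
    ld = np.log10(d)
    borders = np.empty(d.size + 1)
    borders[1:-1] = 10.0 ** (0.5 * (ld[:-1] + ld[1:]))
    borders[0] = 10.0 ** (1.5 * ld[0] - 0.5 * ld[1])
    borders[-1] = 10.0 ** (1.5 * ld[-1] - 0.5 * ld[-2])
    return borders


def log_bin_widths(borders: Sequence[float]) -> np.ndarray:
    """Logarithmic bin sizes ``Delta_j = log10(b_{j+1} / b_j)``."""
    b = np.asarray(borders, dtype=float)
    if b.ndim != 1 or b.size < 2:
        raise ValueError("need at least two borders")
    if np.any(b <= 0) or not np.all(np.isfinite(b)):
        raise ValueError("borders must be positive and finite")
    if np.any(np.diff(b) <= 0):
        raise ValueError("borders must be strictly increasing")
    return np.diff(np.log10(b))


@dataclass(frozen=True)
class SizeGrid:
    """Discrete PSD size grid: diameters, bin borders and log10 widths (nm)."""

    diameters: np.ndarray
    borders: np.ndarray = field(default=None)  # type: ignore[assignment]
    log_widths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        b = bin_borders(d) if self.borders is None else np.asarray(self.borders, float)
        w = log_bin_widths(b) if self.log_widths is None else np.asarray(self.log_widths, float)
        if b.size != d.size + 1 or w.size != d.size:
            raise ValueError("inconsistent size grid")
        if np.any(d <= b[:-1]) or np.any(d >= b[1:]):
            raise ValueError("each diameter must lie inside its bin")
        object.__setattr__(self, "diameters", d)
        object.__setattr__(self, "borders", b)
        object.__setattr__(self, "log_widths", w)

    @property
    def n_bins(self) -> int:
        return self.diameters.size

    @classmethod
    def from_diameters(cls, diameters: Sequence[float]) -> "SizeGrid":
        return cls(diameters=np.asarray(diameters, dtype=float))


# ---------------------------------------------------------------------------
# Record containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StationRecord:
    """One timestamped PSD or PNC measurement with its quality flag."""

    station_id: str
    timestamp: pd.Timestamp  # UTC
    kind: str  # "PSD" | "PNC"
    values: np.ndarray  # PSD: dN/dlog10D per bin (cm^-3); PNC: one total
    flag: float

    def __post_init__(self) -> None:
        if self.kind not in ("PSD", "PNC"):
            raise ValueError(f"record kind must be PSD or PNC, got {self.kind!r}")


@dataclass(frozen=True)
class AnnualObservation:
    """One harmonized (station, year) annual-mean PNC — a training row target."""

    station_id: str
    lat: float
    lon: float
    year: int
    pnc_annual: float  # cm^-3
    n_unique_days: int
    source_kind: str  # "PSD" | "PNC"

    def __post_init__(self) -> None:
        if not self.pnc_annual > 0:
            raise ValueError("annual-mean PNC must be positive")


# ---------------------------------------------------------------------------
# PSD integration and the ultrafine fraction
# ---------------------------------------------------------------------------

def integrate_pnc(values: Sequence[float], size_grid: SizeGrid) -> float:
    """Total number concentration: sum of dN/dlog10D times log10 bin width."""
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != size_grid.n_bins:
        raise ValueError(
            f"value count {v.shape[-1]} does not match size grid ({size_grid.n_bins} bins)"
        )
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValueError("dN/dlog10D values must be finite and non-negative")
    return float(np.sum(v * size_grid.log_widths, axis=-1)) if v.ndim == 1 else (
        v * size_grid.log_widths
    ).sum(axis=-1)


def ufp_fraction(
    values: Sequence[float], size_grid: SizeGrid, cutoff: float = UFP_CUTOFF_NM
) -> float:
    """Fraction of the total number below ``cutoff`` (nm).

    Within a bin, dN/dlog10D is taken constant, so a bin straddling the
    cutoff contributes the fraction ``log10(cutoff / b_j) / Delta_j`` of its
    number — log-uniform apportionment.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (size_grid.n_bins,):
        raise ValueError("value count does not match size grid")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValueError("dN/dlog10D values must be finite and non-negative")
    b = size_grid.borders
    total = float(np.sum(v * size_grid.log_widths))
    if total <= 0:
        raise ValueError("undefined ultrafine fraction: total number is zero")
    # log10-width of the part of each bin below the cutoff
    below = np.clip(np.log10(np.minimum(b[1:], cutoff)) - np.log10(b[:-1]), 0.0, None)
    below = np.where(b[:-1] >= cutoff, 0.0, below)
    return float(np.sum(v * below) / total)


# ---------------------------------------------------------------------------
# Flag filtering and annual aggregation
# ---------------------------------------------------------------------------

def filter_valid(
    records: Iterable[StationRecord],
    allowed_flags: Sequence[float] = VALID_FLAGS_EBAS,
    tol: float = 1e-9,
) -> list[StationRecord]:
    """Keep exactly the records whose flag is in the allowed set."""
    allowed = np.asarray(list(allowed_flags), dtype=float)
    return [r for r in records if np.any(np.abs(allowed - float(r.flag)) <= tol)]


@dataclass(frozen=True)
class RejectedYear:
    """Typed outcome for a station-year below the unique-day threshold."""

    station_id: str
    year: int
    n_unique_days: int


def annual_aggregate(
    totals: pd.DataFrame,
    station_id: str,
    lat: float,
    lon: float,
    year: int,
    source_kind: str,
    min_days: int = MIN_UNIQUE_DAYS,
) -> AnnualObservation | RejectedYear:
    """Two-stage mean for one station-year: daily means, then their mean.

    ``totals`` holds columns ``timestamp`` (UTC) and ``pnc`` for already
    QC-filtered, already-integrated records of one station and year. The
    station-year is rejected (not an error) when it covers fewer than
    ``min_days`` unique calendar days; exactly ``min_days`` is accepted.
    """
    ts = pd.to_datetime(totals["timestamp"], utc=True)
    days = ts.dt.floor("D")
    daily = totals["pnc"].astype(float).groupby(days.values).mean()
    n_days = int(daily.size)
    if n_days < min_days:
        return RejectedYear(station_id=station_id, year=year, n_unique_days=n_days)
    return AnnualObservation(
        station_id=station_id,
        lat=float(lat),
        lon=float(lon),
        year=int(year),
        pnc_annual=float(daily.mean()),
        n_unique_days=n_days,
        source_kind=source_kind,
    )


# ---------------------------------------------------------------------------
# Record-collection pipeline
# ---------------------------------------------------------------------------

def harmonize_records(
    records: Iterable[StationRecord],
    registry: pd.DataFrame,
    size_grid: SizeGrid | None = None,
    allowed_flags: Sequence[float] = VALID_FLAGS_EBAS,
    min_days: int = MIN_UNIQUE_DAYS,
) -> tuple[list[AnnualObservation], list[RejectedYear], np.ndarray]:
    """Full harmonization of a record collection.

    Filters flags, integrates PSDs, aggregates to annual means per
    (station, year), and collects the daily-mean sub-100 nm fractions of
    all valid PSD records.

    Parameters
    ----------
    records
        Mixed PSD/PNC station records.
    registry
        DataFrame with columns ``station_id``, ``lat``, ``lon``.
    size_grid
        Size grid shared by all PSD records (required if any are present).

    Returns
    -------
    observations, rejections, fractions
        Accepted annual observations, rejected station-years, and the array
        of daily-mean ultrafine fractions from PSD records.
    """
    kept = filter_valid(records, allowed_flags)
    coords = registry.set_index("station_id")[["lat", "lon"]]

    rows = []
    for r in kept:
        if r.kind == "PSD":
            if size_grid is None:
                raise ValueError("PSD records present but no size grid given")
            total = integrate_pnc(r.values, size_grid)
            frac = ufp_fraction(r.values, size_grid) if total > 0 else np.nan
        else:
            total = float(np.asarray(r.values).reshape(-1)[0])
            if total < 0:
                raise ValueError(
                    f"negative PNC after QC at {r.station_id} {r.timestamp}"
                )
            frac = np.nan
        rows.append((r.station_id, r.timestamp, r.kind, total, frac))
    if not rows:
        return [], [], np.array([])

    df = pd.DataFrame(rows, columns=["station_id", "timestamp", "kind", "pnc", "frac"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df["year"] = df["timestamp"].dt.year
    df["day"] = df["timestamp"].dt.floor("D")

    observations: list[AnnualObservation] = []
    rejections: list[RejectedYear] = []
    for (sid, year), grp in df.groupby(["station_id", "year"], sort=True):
        lat, lon = coords.loc[sid, "lat"], coords.loc[sid, "lon"]
        kind = "PSD" if (grp["kind"] == "PSD").any() else "PNC"
        out = annual_aggregate(grp, sid, lat, lon, int(year), kind, min_days=min_days)
        if isinstance(out, AnnualObservation):
            observations.append(out)
        else:
            rejections.append(out)

    psd = df[df["kind"] == "PSD"].dropna(subset=["frac"])
    fractions = (
        psd.groupby(["station_id", "day"])["frac"].mean().to_numpy()
        if len(psd)
        else np.array([])
    )
    return observations, rejections, fractions


def observations_to_frame(observations: Sequence[AnnualObservation]) -> pd.DataFrame:
    """Tabular view of annual observations (one row per station-year)."""
    return pd.DataFrame(
        [
            {
                "station_id": o.station_id,
                "lat": o.lat,
                "lon": o.lon,
                "year": o.year,
                "pnc_annual": o.pnc_annual,
                "n_unique_days": o.n_unique_days,
                "source_kind": o.source_kind,
            }
            for o in observations
        ]
    )
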