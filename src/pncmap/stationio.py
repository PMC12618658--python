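"""Station-file dialects.

Two on-disk forms mirror the formats aerosol networks distribute:

* an EBAS-style NetCDF with dimensions ``(time, diameter)`` carrying a
  ``particle_number_size_distribution`` variable (cm^-3, as dN/dlog10 D)
  and a per-record numeric ``flag``;
* a flat-text table (NASA-Ames-like dialect) of total number concentration
  with ``#``-prefixed header lines and columns ``time conc numflag``.

Writers are used by the synthetic generator; readers feed the harmonizer.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .harmonize import SizeGrid, StationRecord

_NC_ENGINE = "scipy"  # NetCDF3 classic; readable by any NetCDF tool


def write_psd_netcdf(
    path: str | Path,
    station_id: str,
    lat: float,
    lon: float,
    times: Sequence,
    size_grid: SizeGrid,
    dndlogd: np.ndarray,  # (time, diameter)
    flags: Sequence[float],
) -> Path:
    """Write one station's PSD time series in the EBAS-style NetCDF dialect."""
    path = Path(path)
    times = pd.to_datetime(list(times))
    if times.tz is not None:
        times = times.tz_localize(None)  # stored as naive UTC
    ds = xr.Dataset(
        {
            "particle_number_size_distribution": (
                ("time", "diameter"),
                np.asarray(dndlogd, dtype=float),
                {"units": "cm-3", "long_name": "dN/dlog10(D)"},
            ),
            "flag": (
                ("time",),
                np.asarray(flags, dtype=float),
                {"long_name": "numeric quality flag (0.000 valid, 0.100 verified)"},
            ),
        },
        coords={
            "time": ("time", times),
            "diameter": ("diameter", size_grid.diameters, {"units": "nm"}),
        },
        attrs={"station_id": station_id, "latitude": float(lat), "longitude": float(lon)},
    )
    ds.to_netcdf(path, engine=_NC_ENGINE)
    return path


def read_psd_netcdf(path: str | Path) -> tuple[list[StationRecord], SizeGrid, dict]:
    """Read the EBAS-style NetCDF dialect back into records + metadata."""
    with xr.open_dataset(Path(path), engine=_NC_ENGINE) as ds:
        ds.load()
    meta = {
        "station_id": str(ds.attrs["station_id"]),
        "lat": float(ds.attrs["latitude"]),
        "lon": float(ds.attrs["longitude"]),
    }
    grid = SizeGrid.from_diameters(np.asarray(ds["diameter"].values, dtype=float))
    values = np.asarray(ds["particle_number_size_distribution"].values, dtype=float)
    flags = np.asarray(ds["flag"].values, dtype=float)
    times = pd.to_datetime(ds["time"].values).tz_localize("UTC")
    records = [
        StationRecord(
            station_id=meta["station_id"],
            timestamp=t,
            kind="PSD",
            values=values[i],
            flag=float(flags[i]),
        )
        for i, t in enumerate(times)
    ]
    return records, grid, meta


def write_pnc_text(
    path: str | Path,
    station_id: str,
    lat: float,
    lon: float,
    times: Sequence,
    conc: Sequence[float],
    numflags: Sequence[int],
) -> Path:
    """Write one station's total-PNC series in the flat-text dialect."""
    path = Path(path)
    times = pd.to_datetime(list(times))
    if times.tz is not None:
        times = times.tz_localize(None)
    lines = [
        f"# station_id: {station_id}",
        f"# latitude: {lat:.6f}",
        f"# longitude: {lon:.6f}",
        "# component: particle_number_concentration",
        "# units: cm-3",
        "# columns: time conc numflag",
    ]
    for t, c, f in zip(times, conc, numflags):
        lines.append(f"{t.strftime('%Y-%m-%dT%H:%M:%S')} {float(c):.4f} {int(f)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_pnc_text(path: str | Path) -> tuple[list[StationRecord], dict]:
    """Read the flat-text dialect back into records + metadata."""
    meta: dict = {}
    records: list[StationRecord] = []
    station_id = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        t_str, c_str, f_str = line.split()
        if station_id is None:
            station_id = meta.get("station_id", Path(path).stem)
        records.append(
            StationRecord(
                station_id=station_id,
                timestamp=pd.Timestamp(t_str, tz="UTC"),
                kind="PNC",
                values=np.array([float(c_str)]),
                flag=float(int(f_str)),
            )
        )
    out_meta = {
        "station_id": meta.get("station_id", Path(path).stem),
        "lat": float(meta.get("latitude", "nan")),
        "lon": float(meta.get("longitude", "nan")),
    }
    return records, out_meta
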