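"""Readers/writers for the package's file formats.

Gridded monthly climate and anomaly trajectories travel as netCDF (classic
format, via the scipy backend) or long-format CSV; soils and class maps as
CSV grids; CO2 as a two-column CSV; run manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "write_climate_netcdf", "read_climate_netcdf",
    "write_climate_csv", "read_climate_csv",
    "write_grid_csv", "write_soils_csv", "read_soils_csv",
    "write_co2_csv", "read_co2_csv",
    "write_manifest",
]


def write_climate_netcdf(ds: xr.Dataset, path) -> None:
    ds.to_netcdf(path, engine="scipy")


def read_climate_netcdf(path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")


def write_climate_csv(ds: xr.Dataset, path) -> None:
    """Long-format CSV: year, month, y, x, ppt, tmax, tmin, vpr."""
    df = ds.to_dataframe().reset_index()
    cols = ["year", "month", "y", "x", "ppt", "tmax", "tmin", "vpr"]
    df[cols].to_csv(path, index=False)


def read_climate_csv(path) -> xr.Dataset:
    df = pd.read_csv(path)
    df = df.sort_values(["year", "month", "y", "x"])
    years = np.sort(df["year"].unique())
    months = np.arange(1, 13)
    ny = df["y"].nunique()
    nx = df["x"].nunique()
    nt = len(years) * 12
    data = {}
    for v in ("ppt", "tmax", "tmin", "vpr"):
        data[v] = (("time", "y", "x"), df[v].values.reshape(nt, ny, nx))
    return xr.Dataset(
        data,
        coords={"time": np.arange(nt),
                "year": ("time", np.repeat(years, 12)),
                "month": ("time", np.tile(months, len(years))),
                "y": np.arange(ny), "x": np.arange(nx)})


def write_grid_csv(arr: np.ndarray, path) -> None:
    """A single-band map as a plain CSV grid (rows = y, north at top)."""
    pd.DataFrame(np.asarray(arr)).to_csv(path, index=False, header=False)


def write_soils_csv(soils: xr.Dataset, path) -> None:
    soils.to_dataframe().reset_index().to_csv(path, index=False)


def read_soils_csv(path) -> xr.Dataset:
    df = pd.read_csv(path).sort_values(["y", "x"])
    ny, nx = df["y"].nunique(), df["x"].nunique()
    data = {v: (("y", "x"), df[v].values.reshape(ny, nx))
            for v in df.columns if v not in ("y", "x")}
    return xr.Dataset(data, coords={"y": np.arange(ny), "x": np.arange(nx)})


def write_co2_csv(series: pd.Series, path) -> None:
    series.rename_axis("year").reset_index().to_csv(path, index=False)


def read_co2_csv(path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values,
                     name="co2_ppm")


def write_manifest(path, **fields) -> None:
    """Run manifest (config, seed, version) for reproducibility."""
    from . import __version__
    payload = {"vegfire_version": __version__}
    payload.update(fields)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
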