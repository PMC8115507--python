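"""Readers and writers for cubes, domains, surveys, maps and summaries.

NetCDF files are written in classic (NetCDF-3) format through xarray's
scipy engine with CF-style time units; cubes use dimensions (time, y, x)
with row 0 the northernmost row and 0-based indices, stated in the file
metadata.  2-D maps can additionally be exported as single-band TIFF
rasters.  All writers are deterministic: identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr
import yaml

from .cubes import FlowCube, SaturationCube, WetnessCube
from .domain import DomainGrid
from .metrics import STABILITY_CLASSES, CoverageSeries, ExceedanceMap, StabilityMap
from .survey import SURVEY_COLUMNS

__all__ = [
    "write_saturation", "read_saturation", "write_flow", "read_flow",
    "write_wetness", "read_wetness", "write_domain", "read_domain",
    "write_survey", "read_survey", "write_exceedance_map",
    "write_stability_map", "write_coverage_csv", "write_map_tiff",
    "load_yaml", "dump_yaml",
]

_GRID_META = {"grid_convention": "row 0 = northernmost row; 0-based indices"}


def _time_encoding(dates: pd.DatetimeIndex) -> dict:
    units = f"days since {dates[0].strftime('%Y-%m-%d')} 00:00:00"
    return {"time": {"dtype": "int32", "units": units,
                     "calendar": "proleptic_gregorian"}}


def _cube_dataset(values: np.ndarray, dates: pd.DatetimeIndex, name: str,
                  attrs: dict, var_attrs: dict) -> xr.Dataset:
    da = xr.DataArray(values, dims=("time", "y", "x"),
                      coords={"time": dates}, name=name, attrs=var_attrs)
    ds = da.to_dataset()
    ds.attrs.update(_GRID_META)
    ds.attrs.update(attrs)
    return ds


def write_saturation(cube: SaturationCube, path) -> None:
    ds = _cube_dataset(cube.values.astype(np.float32), cube.dates,
                       "saturation",
                       {"scenario_label": cube.scenario_label},
                       {"units": "1", "long_name": "surface layer soil saturation"})
    ds.to_netcdf(path, engine="scipy", encoding=_time_encoding(cube.dates))


def read_saturation(path) -> SaturationCube:
    with xr.open_dataset(path, engine="scipy") as ds:
        return SaturationCube(
            values=np.clip(ds["saturation"].values.astype(float), 0.0, 1.0),
            dates=pd.DatetimeIndex(ds["time"].values),
            scenario_label=str(ds.attrs.get("scenario_label", "")))


def write_flow(cube: FlowCube, path) -> None:
    ds = _cube_dataset(cube.values.astype(np.float32), cube.dates,
                       "flowrate", {},
                       {"units": "m3 s-1", "long_name": "surface water flowrate"})
    ds.to_netcdf(path, engine="scipy", encoding=_time_encoding(cube.dates))


def read_flow(path) -> FlowCube:
    with xr.open_dataset(path, engine="scipy") as ds:
        return FlowCube(values=np.clip(ds["flowrate"].values.astype(float),
                                       0.0, None),
                        dates=pd.DatetimeIndex(ds["time"].values))


def write_wetness(cube: WetnessCube, path) -> None:
    ds = _cube_dataset(cube.values.astype(np.int32), cube.dates,
                       "wetness_index", {"theta": float(cube.theta)},
                       {"units": "days",
                        "long_name": "consecutive ponded days"})
    ds.to_netcdf(path, engine="scipy", encoding=_time_encoding(cube.dates))


def read_wetness(path) -> WetnessCube:
    with xr.open_dataset(path, engine="scipy") as ds:
        return WetnessCube(values=ds["wetness_index"].values.astype(np.int32),
                           dates=pd.DatetimeIndex(ds["time"].values),
                           theta=float(ds.attrs.get("theta", np.nan)))


def write_domain(domain: DomainGrid, path) -> None:
    """Write all static layers as one grouped NetCDF file."""
    ds = xr.Dataset(
        {
            "soil_class": (("y", "x"), domain.soil_class.astype(np.int8)),
            "farm_id": (("y", "x"), domain.farm_id.astype(np.int8)),
            "elevation": (("y", "x"), domain.elevation.astype(np.float32)),
            "flow_dir": (("y", "x"), domain.flow_dir.astype(np.int8)),
            "stream_mask_static": (("y", "x"),
                                   domain.stream_mask_static.astype(np.int8)),
        },
        attrs={**_GRID_META, "cell_size_m": float(domain.cell_size),
               "soil_legend": "0=SLOW 1=FAST 2=RIPARIAN",
               "flow_dir_legend": "D8 codes 0..7 clockwise from north; -1=pit"},
    )
    ds.to_netcdf(path, engine="scipy")


def read_domain(path) -> DomainGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        soil = ds["soil_class"].values.astype(np.int8)
        return DomainGrid(
            n_rows=soil.shape[0], n_cols=soil.shape[1],
            cell_size=float(ds.attrs["cell_size_m"]),
            soil_class=soil,
            farm_id=ds["farm_id"].values.astype(np.int8),
            elevation=ds["elevation"].values.astype(float),
            flow_dir=ds["flow_dir"].values.astype(np.int8),
            stream_mask_static=ds["stream_mask_static"].values.astype(bool),
        )


def write_survey(survey: pd.DataFrame, path) -> None:
    survey[SURVEY_COLUMNS].to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survey CSV missing columns: {sorted(missing)}")
    df["larvae_present"] = df["larvae_present"].astype(bool)
    return df[SURVEY_COLUMNS]


def write_map_tiff(values: np.ndarray, path) -> None:
    """Single-band TIFF export of a 2-D map (float32 or uint8)."""
    arr = np.asarray(values)
    if arr.dtype != np.uint8:
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)


def write_exceedance_map(emap: ExceedanceMap, path) -> None:
    da = xr.DataArray(emap.values.astype(np.float32), dims=("y", "x"),
                      name="exceedance_probability",
                      attrs={"units": "1"})
    ds = da.to_dataset()
    ds.attrs.update(_GRID_META)
    ds.attrs.update({"T_days": int(emap.T), "period": emap.period,
                     "scenario_label": emap.scenario_label,
                     "mask_applied": int(emap.mask_applied)})
    ds.to_netcdf(path, engine="scipy")


def write_stability_map(smap: StabilityMap, path_nc, path_hist_csv=None) -> None:
    legend = " ".join(f"{k}={v}" for k, v in STABILITY_CLASSES.items())
    ds = xr.Dataset(
        {"stability_class": (("y", "x"), smap.classes.astype(np.int16)),
         "max_duration": (("y", "x"),
                          np.asarray(smap.max_duration, dtype=np.int32))},
        attrs={**_GRID_META, "class_legend": legend + " 255=masked"})
    ds.to_netcdf(path_nc, engine="scipy")
    if path_hist_csv is not None:
        smap.histogram.to_csv(path_hist_csv, index=False)


def write_coverage_csv(series: CoverageSeries, path) -> None:
    pd.DataFrame({"date": series.dates.strftime("%Y-%m-%d"),
                  "F": series.values}).to_csv(path, index=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def sha256_file(path) -> str:
    import hashlib
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
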