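"""Interchange formats: light TSV, twilight/track/bird-day CSV, weather
NetCDF, GeoJSON track export and fit JSON.

All timestamps are serialized ISO-8601 UTC; coordinates are decimal
degrees (lat in [-90, 90], lon in (-180, 180]).  Readers validate the
schema and name the offending column in their errors; write -> read ->
write round-trips are byte-identical for the CSV/TSV products.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "write_light",
    "read_light",
    "write_twilights",
    "read_twilights",
    "write_track",
    "read_track",
    "track_to_geojson",
    "write_weather",
    "read_weather",
    "write_bird_days",
    "read_bird_days",
    "write_fit",
]

_TIME_FMT = "%Y-%m-%dT%H:%M:%S.%fZ"


def _require(df: pd.DataFrame, cols: list, what: str, path) -> None:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{what} file {path}: missing column {c!r}")


def _fmt_time(s: pd.Series) -> pd.Series:
    return pd.DatetimeIndex(s).strftime(_TIME_FMT)


def write_light(light: pd.DataFrame, path) -> None:
    """Two-column TSV: ISO-8601 UTC timestamp, light intensity."""
    out = pd.DataFrame({"time": _fmt_time(light["time"]), "light": light["light"]})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_light(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["time", "light"], "light", path)
    df["time"] = pd.to_datetime(df["time"], format="mixed")
    bad = df["light"].isna()
    if bad.any():
        raise ValueError(f"light file {path}: non-numeric light at row {int(bad.idxmax())}")
    return df


def write_twilights(tw: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "date": pd.DatetimeIndex(tw["date"]).strftime("%Y-%m-%d"),
            "type": tw["type"],
            "time": _fmt_time(tw["time"]),
            "flag": tw["flag"],
            "original_time": [
                "" if pd.isna(t) else pd.Timestamp(t).strftime(_TIME_FMT)
                for t in tw["original_time"]
            ],
        }
    )
    out.to_csv(path, index=False)


def read_twilights(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    _require(df, ["date", "type", "time", "flag", "original_time"], "twilight", path)
    df["date"] = pd.to_datetime(df["date"])
    df["time"] = pd.to_datetime(df["time"], format="mixed")
    df["original_time"] = pd.to_datetime(
        df["original_time"].replace("", pd.NaT), format="mixed"
    )
    bad = ~df["type"].isin(["sunrise", "sunset"])
    if bad.any():
        raise ValueError(f"twilight file {path}: bad type at row {int(bad.idxmax())}")
    return df


_TRACK_COLS = ["date", "lat", "lon", "lat_sd", "lon_sd", "sunrise", "sunset"]


def write_track(track: pd.DataFrame, path) -> None:
    out = pd.DataFrame({"date": pd.DatetimeIndex(track["date"]).strftime("%Y-%m-%d")})
    for c in ["lat", "lon", "lat_sd", "lon_sd"]:
        out[c] = np.round(track[c].to_numpy(dtype=float), 6) if c in track else np.nan
    for c in ["sunrise", "sunset"]:
        out[c] = _fmt_time(track[c]) if c in track else ""
    out.to_csv(path, index=False)


def read_track(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, _TRACK_COLS, "track", path)
    df["date"] = pd.to_datetime(df["date"])
    for c in ["sunrise", "sunset"]:
        df[c] = pd.to_datetime(df[c], format="mixed")
    if (df["lat"].abs() > 90).any():
        raise ValueError(f"track file {path}: latitude out of range")
    return df


def track_to_geojson(track: pd.DataFrame, path=None) -> dict:
    """GeoJSON LineString of the (median) track; coordinates [lon, lat]."""
    coords = [
        [round(float(lo), 6), round(float(la), 6)]
        for la, lo in zip(track["lat"], track["lon"])
        if np.isfinite(la) and np.isfinite(lo)
    ]
    gj = {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": {
            "start": str(pd.Timestamp(track["date"].iloc[0]).date()),
            "end": str(pd.Timestamp(track["date"].iloc[-1]).date()),
        },
    }
    if path is not None:
        Path(path).write_text(json.dumps(gj, indent=1))
    return gj


def write_weather(ds: xr.Dataset, path) -> None:
    ds.to_netcdf(path)


def read_weather(path, dim_names: dict | None = None) -> xr.Dataset:
    """Read gridded weather, renaming dimensions per `dim_names`
    (e.g. {'latitude': 'lat'}); dimension order is irrelevant — all access
    is by name."""
    ds = xr.open_dataset(path)
    if dim_names:
        ds = ds.rename(dim_names)
    for d in ("time", "lat", "lon"):
        if d not in ds.dims:
            raise ValueError(f"weather file {path}: missing dimension {d!r}")
    return ds


_BIRD_DAY_COLS = [
    "bird", "date", "state", "lat", "lon", "temperature", "pressure",
    "wind_speed", "precipitation", "flow_assistance", "remaining_distance",
    "departed", "travel_speed",
]


def write_bird_days(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    if "sunset" in out:
        out["sunset"] = _fmt_time(out["sunset"])
    out.to_csv(path, index=False, float_format="%.8g")


def read_bird_days(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, _BIRD_DAY_COLS, "bird-day", path)
    df["date"] = pd.to_datetime(df["date"])
    if "sunset" in df:
        df["sunset"] = pd.to_datetime(df["sunset"], format="mixed")
    return df


def write_fit(fit, path) -> None:
    """FitResult as JSON (terms, estimates, CrIs, variance components)."""
    if fit.summary_ is None:
        raise ValueError("run posterior_sim before writing a fit")
    payload = {
        "response": fit.spec.response,
        "family": fit.spec.family,
        "transform": fit.spec.transform,
        "group": fit.spec.group,
        "n": fit.n,
        "n_dropped": fit.n_dropped,
        "random_sd": fit.random_sd,
        "resid_sd": fit.resid_sd,
        "scale": fit.scale,
        "marginal_r2": fit.marginal_r2,
        "conditional_r2": fit.conditional_r2,
        "scaling": fit.scaling,
        "terms": [
            {
                "term": r.term,
                "estimate": float(r.estimate),
                "cri_lo": float(r.cri_lo),
                "cri_hi": float(r.cri_hi),
                "significant": bool(r.significant),
            }
            for r in fit.summary_.itertuples()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
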