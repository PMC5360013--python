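"""Environmental annotation of bird-days.

Interpolates gridded weather to track locations at local sunset, sums
precipitation over a +-3 h sunset window, computes wind flow assistance
(airspeed formulation) over the four standard pressure levels, and builds
the model-ready bird-day table that the mixed-model layer consumes.

Flow assistance follows the airspeed equation

    fa = y*cos(theta) + sqrt(z^2 - (y*sin(theta))^2) - z

with y the wind speed [m/s], z the bird's airspeed (default 13 m/s) and
theta the angle between the direction the wind blows toward and the bird's
preferred direction (the initial great-circle bearing to the next goal).
When the crosswind component exceeds the airspeed (y*sin(theta) > z) the
quantity is undefined and reported as missing, not an error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from . import geo

DEFAULT_AIRSPEED = 13.0  # m/s
PRESSURE_LEVELS = (1000, 925, 850, 700)

__all__ = [
    "interp_field",
    "precip_window",
    "flow_assistance",
    "best_flow",
    "hourly_mean_flow",
    "sunset_covariates",
    "build_bird_day_table",
]


def _check_hull(fields: xr.Dataset | xr.DataArray, time, lat, lon) -> None:
    for axis, val in (("time", time), ("lat", lat), ("lon", lon)):
        coord = fields[axis].values
        lo, hi = coord.min(), coord.max()
        dtype = "datetime64[ns]" if axis == "time" else float
        v = np.atleast_1d(np.asarray(val, dtype=dtype))
        if (v < lo).any() or (v > hi).any():
            raise ValueError(f"query outside grid hull on axis '{axis}'")


def interp_field(field: xr.DataArray, time, lat, lon, level=None) -> float | np.ndarray:
    """Bilinear-in-space, linear-in-time interpolation of a gridded field.

    `level`, when given, must match one of the discrete pressure levels
    exactly.  Queries outside the grid hull raise, naming the offending
    axis — time extrapolation is never allowed.
    """
    _check_hull(field, time, lat, lon)
    if level is not None:
        field = field.sel(level=level)
    t = xr.DataArray(np.atleast_1d(np.asarray(time, dtype="datetime64[ns]")), dims="pt")
    la = xr.DataArray(np.atleast_1d(np.asarray(lat, dtype=float)), dims="pt")
    lo = xr.DataArray(np.atleast_1d(np.asarray(lon, dtype=float)), dims="pt")
    out = field.interp(time=t, lat=la, lon=lo, method="linear").values
    return float(out[0]) if out.size == 1 and np.ndim(time) == 0 else out


def precip_window(
    field: xr.DataArray, sunset, lat: float, lon: float, half_width_h: float = 3.0
) -> float:
    """Sum of the interpolated precipitation rate at hourly steps over
    [sunset - 3 h, sunset + 3 h] (7 samples for the default window)."""
    sunset = pd.Timestamp(sunset)
    offsets = np.arange(-half_width_h, half_width_h + 0.5)
    times = sunset + pd.to_timedelta(offsets, unit="h")
    vals = interp_field(field, times.values, np.full(len(times), lat), np.full(len(times), lon))
    return float(np.sum(vals))


def flow_assistance(u: float, v: float, preferred_dir: float, airspeed: float = DEFAULT_AIRSPEED):
    """Airspeed-formulation flow assistance [m/s], or NaN when undefined.

    u, v: wind components [m/s] (direction the wind blows toward is
    atan2(u, v), degrees clockwise from north); preferred_dir: the bird's
    intended track, degrees clockwise from north.
    """
    if airspeed <= 0:
        raise ValueError("airspeed must be positive")
    u, v = np.asarray(u, float), np.asarray(v, float)
    y = np.hypot(u, v)
    wind_to = np.rad2deg(np.arctan2(u, v))
    theta = np.deg2rad(wind_to - np.asarray(preferred_dir, float))
    cross = y * np.sin(theta)
    with np.errstate(invalid="ignore"):
        fa = np.where(
            np.abs(cross) <= airspeed,
            y * np.cos(theta) + np.sqrt(np.maximum(airspeed**2 - cross**2, 0.0)) - airspeed,
            np.nan,
        )
    return float(fa) if np.ndim(fa) == 0 else fa


def best_flow(
    fields: xr.Dataset, lat, lon, time, goal: tuple, airspeed: float = DEFAULT_AIRSPEED
):
    """Best (maximum) flow assistance over the four pressure levels.

    Missing (NaN) levels are ignored; the result is missing only when the
    crosswind exceeds the airspeed at every level.
    """
    bearing = geo.initial_bearing(lat, lon, goal[0], goal[1])
    vals = []
    for lev in fields["level"].values:
        u = interp_field(fields["uwnd"], time, lat, lon, level=lev)
        v = interp_field(fields["vwnd"], time, lat, lon, level=lev)
        vals.append(flow_assistance(u, v, bearing, airspeed))
    vals = np.asarray(vals, float)
    return float(np.nanmax(vals)) if np.isfinite(vals).any() else float("nan")


def hourly_mean_flow(
    fields: xr.Dataset,
    from_loc: tuple,
    to_loc: tuple,
    start,
    hours: int,
    airspeed: float = DEFAULT_AIRSPEED,
):
    """Mean of hourly best flow assistance along the great-circle path.

    Positions are stepped hourly from `from_loc` to `to_loc`; wind is
    interpolated in space and time at each step so no abrupt grid-cell
    transitions occur.
    """
    if hours < 1:
        raise ValueError("zero-length night")
    lats, lons = geo.gc_waypoints(*from_loc, *to_loc, hours + 1)
    vals = []
    for h in range(hours):
        t = pd.Timestamp(start) + pd.Timedelta(hours=h)
        vals.append(best_flow(fields, lats[h], lons[h], t, to_loc, airspeed))
    vals = np.asarray(vals, float)
    return float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")


def sunset_covariates(
    fields: xr.Dataset,
    lat: float,
    lon: float,
    sunset,
    bearing_to_goal: float,
    airspeed: float = DEFAULT_AIRSPEED,
) -> dict:
    """Surface conditions and best-level flow assistance at local sunset."""
    t = pd.Timestamp(sunset)
    u = interp_field(fields["uwnd_surface"], t, lat, lon)
    v = interp_field(fields["vwnd_surface"], t, lat, lon)
    vals = []
    for lev in fields["level"].values:
        ul = interp_field(fields["uwnd"], t, lat, lon, level=lev)
        vl = interp_field(fields["vwnd"], t, lat, lon, level=lev)
        vals.append(flow_assistance(ul, vl, bearing_to_goal, airspeed))
    vals = np.asarray(vals, float)
    fa = float(np.nanmax(vals)) if np.isfinite(vals).any() else float("nan")
    return {
        "temperature": interp_field(fields["air_temperature"], t, lat, lon),
        "pressure": interp_field(fields["surface_pressure"], t, lat, lon),
        "wind_speed": float(np.hypot(u, v)),
        "precipitation": precip_window(fields["precipitation_rate"], t, lat, lon),
        "flow_assistance": fa,
    }


def build_bird_day_table(
    schedule: pd.DataFrame,
    track: pd.DataFrame,
    fields: xr.Dataset,
    destination: tuple,
    airspeed: float = DEFAULT_AIRSPEED,
    bird_id: str = "bird",
) -> pd.DataFrame:
    """Assemble the model-ready bird-day table.

    One row per stopover day (response: departure 0/1, set on the last
    evening of the stopover) and per travel day (response: travel speed,
    km/day).  `schedule` is the daily table from the schedule module
    (columns date, state, plus stopover ids); `track` provides per-day
    locations, sunsets and latitude SDs.  Rows whose flow assistance is
    undefined at all four levels are flagged, not dropped.
    """
    t = track.set_index(pd.DatetimeIndex(track["date"]).normalize())
    s = schedule.set_index(pd.DatetimeIndex(schedule["date"]).normalize())
    common = t.index.intersection(s.index)
    if len(common) == 0:
        raise ValueError("schedule and track share no dates")

    rows = []
    dates = common.sort_values()
    for i, d in enumerate(dates):
        state = s.loc[d, "state"]
        lat, lon = float(t.loc[d, "lat"]), float(t.loc[d, "lon"])
        sunset = t.loc[d, "sunset"] if "sunset" in t.columns else pd.NaT
        if pd.isna(sunset):
            from . import solar

            sunset = solar.twilight_time(d, lat, lon, 90.833, "sunset")
        if pd.isna(sunset):
            continue  # polar day: no sunset-referenced covariates
        remaining = geo.gc_distance(lat, lon, destination[0], destination[1])
        bearing = geo.initial_bearing(lat, lon, destination[0], destination[1])
        try:
            cov = sunset_covariates(fields, lat, lon, sunset, bearing, airspeed)
        except ValueError:
            continue  # outside weather hull (e.g. last partial day)
        if state == "stopover":
            # departure on the stopover's last evening
            nxt = dates[i + 1] if i + 1 < len(dates) else None
            departed = int(nxt is not None and s.loc[nxt, "state"] == "travel")
            response = {"departed": departed, "travel_speed": np.nan}
        else:
            # displacement to the next day's location; the flow covariate
            # for a flight night is the mean hourly assistance along the
            # path, not the point value at the departure site
            if i + 1 < len(dates):
                nlat, nlon = float(t.loc[dates[i + 1], "lat"]), float(
                    t.loc[dates[i + 1], "lon"]
                )
                speed = geo.gc_distance(lat, lon, nlat, nlon)
                try:
                    cov["flow_assistance"] = hourly_mean_flow(
                        fields, (lat, lon), (nlat, nlon),
                        sunset + pd.Timedelta(hours=1), 8, airspeed,
                    )
                except ValueError:
                    pass  # path leaves the weather hull: keep sunset value
            else:
                speed = np.nan
            response = {"departed": np.nan, "travel_speed": speed}
        rows.append(
            {
                "bird": bird_id,
                "date": d,
                "state": state,
                "lat": lat,
                "lon": lon,
                "sunset": sunset,
                **cov,
                "remaining_distance": remaining,
                "lat_sd": float(t.loc[d, "lat_sd"]) if "lat_sd" in t.columns else np.nan,
                **response,
                "flow_missing": bool(np.isnan(cov["flow_assistance"])),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_flow_missing"] = int(out["flow_missing"].sum()) if len(out) else 0
    return out
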