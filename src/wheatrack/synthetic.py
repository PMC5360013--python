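"""Synthetic world: weather fields, an agent-based migrant, and its light record.

This module is the ground truth for every recovery test in the package.
It emulates the three data sources a geolocator study rests on:

* gridded reanalysis-style weather (2.5 deg grid, 6-hourly by default) with
  deterministic latitudinal/seasonal structure plus AR(1)-in-time,
  Gaussian-smoothed-in-space anomalies;
* a nocturnally migrating bird whose stopover-departure decisions follow a
  logistic model on z-scored sunset covariates and whose nightly flight
  distances follow a log10-linear model — the same model families the
  inference layer fits, so recovery can be checked coefficient by
  coefficient;
* the archival light series that bird's tag would have recorded, with
  one-sided log-normal twilight shading (delays apparent sunrise, advances
  apparent sunset).

Everything is driven by a single integer seed; the same configuration and
seed reproduce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from . import geo, solar

PRESSURE_LEVELS = (1000, 925, 850, 700)

__all__ = [
    "PRESSURE_LEVELS",
    "WorldConfig",
    "AgentConfig",
    "make_weather",
    "simulate_track",
    "simulate_light",
    "light_from_elevation",
]


@dataclass
class WorldConfig:
    """Grid, date span and weather-process parameters of a synthetic world."""

    lat_min: float = 0.0
    lat_max: float = 70.0
    lon_min: float = -180.0
    lon_max: float = -40.0
    grid_step: float = 2.5
    time_step_hours: float = 6.0
    start: str = "2013-08-01"
    end: str = "2013-10-15"
    seed: int = 0
    # deterministic temperature structure
    temp_at_equator: float = 25.0          # degC at lat 0, mid-season
    temp_gradient: float = -0.5            # degC per degree latitude
    seasonal_amplitude: float = 10.0       # degC, annual cycle
    seasonal_peak_doy: int = 200           # day of year of warmest day
    diel_amplitude: float = 3.0            # degC, day/night cycle
    # anomaly process
    ar1: float = 0.8                       # AR(1) coefficient in time
    spatial_smooth_cells: float = 2.0      # Gaussian sigma, grid cells
    temp_noise_sd: float = 3.0             # degC
    pressure_noise_sd: float = 8.0         # hPa
    wind_noise_sd: float = 4.0             # m/s
    # mean zonal wind per pressure level (m/s); surface uses the 1000 value
    zonal_wind_by_level: dict = field(
        default_factory=lambda: {1000: 2.0, 925: 4.0, 850: 6.0, 700: 10.0}
    )
    # precipitation occurrence/intensity
    precip_prob: float = 0.25
    precip_shape: float = 0.8
    precip_scale: float = 2e-5             # kg/m^2/s
    land_mask: Optional[np.ndarray] = None  # bool (lat, lon); default all land

    def __post_init__(self):
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("AR(1) coefficient must be in [0, 1)")

    @property
    def lats(self) -> np.ndarray:
        return np.arange(self.lat_min, self.lat_max + 1e-9, self.grid_step)

    @property
    def lons(self) -> np.ndarray:
        return np.arange(self.lon_min, self.lon_max + 1e-9, self.grid_step)

    @property
    def times(self) -> pd.DatetimeIndex:
        # pad past the nominal end: a sunset near the date boundary at far-west
        # longitudes queries up to ~36 h beyond the last tracked day
        return pd.date_range(
            pd.Timestamp(self.start),
            pd.Timestamp(self.end) + pd.Timedelta(days=2),
            freq=pd.Timedelta(hours=self.time_step_hours),
        )


#: default truth coefficients for the departure (logit, z-scale) and nightly
#: flight-distance (log10 km) models; names refer to bird-day covariates.
DEFAULT_BETA = {
    "intercept": -1.6,
    "temperature": -0.5,
    "pressure": 0.2,
    "flow_assistance": 0.4,
    "remaining_distance": 0.8,
    "temperature:remaining_distance": -0.5,
}
DEFAULT_GAMMA = {"intercept": 2.45, "temperature": -0.12, "flow_assistance": 0.1}


@dataclass
class AgentConfig:
    """Behavioural truth model of the simulated migrant."""

    breeding: tuple = (65.6, -145.4)
    wintering: tuple = (30.0, -60.0)
    season_start: str = "2013-08-05"
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    gamma: dict = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    gamma_resid_sd: float = 0.15           # log10 km per night
    airspeed: float = 13.0                 # m/s
    max_flight_hours: float = 10.0
    continue_prob: float = 0.45            # P(keep flying | flew last night)
    shading_meanlog: float = 2.2           # log-minutes
    shading_sdlog: float = 1.0
    zenith: float = 96.8                   # light-threshold sun zenith [deg]
    # fixed standardisation constants defining the z-scale of beta/gamma
    covariate_scales: dict = field(
        default_factory=lambda: {
            "temperature": (10.0, 10.0),
            "pressure": (1000.0, 10.0),
            "wind_speed": (5.0, 3.0),
            "precipitation": (5e-5, 1e-4),
            "flow_assistance": (0.0, 5.0),
            "remaining_distance": (4000.0, 2500.0),
        }
    )

    def __post_init__(self):
        if self.airspeed <= 0:
            raise ValueError("airspeed must be positive")
        if self.shading_sdlog <= 0:
            raise ValueError("shading sdlog must be positive")


def _anomaly(rng, nt, nlat, nlon, ar1, sigma_cells, sd):
    """AR(1)-in-time field of spatially smoothed Gaussian anomalies."""
    out = np.empty((nt, nlat, nlon))
    innov_sd = sd * np.sqrt(1.0 - ar1**2) if ar1 > 0 else sd
    x = gaussian_filter(rng.standard_normal((nlat, nlon)), sigma_cells) * _smooth_gain(
        sigma_cells
    )
    out[0] = x * sd
    for t in range(1, nt):
        e = gaussian_filter(rng.standard_normal((nlat, nlon)), sigma_cells)
        out[t] = ar1 * out[t - 1] + innov_sd * e * _smooth_gain(sigma_cells)
    return out


def _smooth_gain(sigma_cells: float) -> float:
    """Rescale so a smoothed unit-variance field keeps ~unit variance."""
    if sigma_cells <= 0:
        return 1.0
    # variance of gaussian_filter(white noise) ~ 1/(4 pi sigma^2) in 2-D
    return float(2.0 * np.sqrt(np.pi) * sigma_cells)


def make_weather(config: WorldConfig) -> xr.Dataset:
    """Generate the gridded weather fields of a synthetic world.

    Returns an xarray Dataset with variables air_temperature [degC],
    surface_pressure [hPa], uwnd_surface/vwnd_surface [m/s],
    precipitation_rate [kg/m^2/s] on (time, lat, lon) and uwnd/vwnd [m/s]
    on (level, time, lat, lon) for the 1000/925/850/700 mbar levels.
    """
    lats, lons, times = config.lats, config.lons, config.times
    if len(lats) < 2 or len(lons) < 2:
        raise ValueError("degenerate grid: need at least 2x2 cells")
    rng = np.random.default_rng(config.seed)
    nt, nlat, nlon = len(times), len(lats), len(lons)

    doy = times.dayofyear.to_numpy(dtype=float)
    hour = times.hour.to_numpy(dtype=float)
    seasonal = config.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - config.seasonal_peak_doy) / 365.25
    )
    # diel cycle peaks mid-afternoon local solar time
    local_hour = hour[:, None, None] + lons[None, None, :] / 15.0
    diel = config.diel_amplitude * np.cos(2.0 * np.pi * (local_hour - 15.0) / 24.0)

    base_t = (
        config.temp_at_equator
        + config.temp_gradient * lats[None, :, None]
        + seasonal[:, None, None]
        + diel
    )
    args = (nt, nlat, nlon, config.ar1, config.spatial_smooth_cells)
    temp = base_t + _anomaly(rng, *args[:3], *args[3:], config.temp_noise_sd)

    pressure = 1013.0 - 0.05 * (lats[None, :, None] - 30.0) ** 2 / 30.0 + _anomaly(
        rng, *args[:3], *args[3:], config.pressure_noise_sd
    )

    uwnd = np.empty((len(PRESSURE_LEVELS), nt, nlat, nlon))
    vwnd = np.empty_like(uwnd)
    for i, lev in enumerate(PRESSURE_LEVELS):
        mean_u = config.zonal_wind_by_level.get(lev, 0.0) * np.sin(
            np.deg2rad(np.clip(lats, 0, 90))[None, :, None] * 2.0
        )
        uwnd[i] = mean_u + _anomaly(rng, *args[:3], *args[3:], config.wind_noise_sd)
        vwnd[i] = _anomaly(rng, *args[:3], *args[3:], config.wind_noise_sd)

    occur = rng.random((nt, nlat, nlon)) < config.precip_prob
    amount = rng.gamma(config.precip_shape, config.precip_scale, (nt, nlat, nlon))
    prate = np.where(occur, amount, 0.0)
    if config.spatial_smooth_cells > 0:
        for t in range(nt):
            prate[t] = gaussian_filter(prate[t], config.spatial_smooth_cells / 2.0)

    mask = (
        config.land_mask
        if config.land_mask is not None
        else np.ones((nlat, nlon), dtype=bool)
    )

    ds = xr.Dataset(
        {
            "air_temperature": (("time", "lat", "lon"), temp),
            "surface_pressure": (("time", "lat", "lon"), pressure),
            "uwnd_surface": (("time", "lat", "lon"), uwnd[0].copy()),
            "vwnd_surface": (("time", "lat", "lon"), vwnd[0].copy()),
            "precipitation_rate": (("time", "lat", "lon"), prate),
            "uwnd": (("level", "time", "lat", "lon"), uwnd),
            "vwnd": (("level", "time", "lat", "lon"), vwnd),
            "land": (("lat", "lon"), mask),
        },
        coords={
            "time": times,
            "lat": lats,
            "lon": lons,
            "level": list(PRESSURE_LEVELS),
        },
    )
    ds.attrs["seed"] = config.seed
    return ds


def _zscore(agent: AgentConfig, name: str, value: float) -> float:
    c, s = agent.covariate_scales[name]
    return (value - c) / s


def simulate_track(
    agent: AgentConfig, weather: xr.Dataset, world: WorldConfig
) -> pd.DataFrame:
    """Simulate the daily truth table of one migrant.

    Each row is one bird-day: the day's (true) location, behavioural state,
    sunset covariates (raw and z-scored), the departure indicator for
    stopover evenings and the realised nightly flight distance for travel
    nights.  Movement follows the great circle toward the wintering site.
    """
    from . import envann  # deferred: envann imports geo/solar only

    rng = np.random.default_rng(world.seed + 1)
    lat, lon = agent.breeding
    dest_lat, dest_lon = agent.wintering
    day = pd.Timestamp(agent.season_start).normalize()
    end_day = pd.Timestamp(world.end).normalize()

    rows = []
    state = "stopover"
    truncated = True
    while day <= end_day:
        sunset = solar.twilight_time(day, lat, lon, 90.833, "sunset")
        if pd.isna(sunset):
            # polar day: use local civil 22:00 as the decision time
            sunset = day + pd.Timedelta(hours=22.0 - lon / 15.0)
        remaining = geo.gc_distance(lat, lon, dest_lat, dest_lon)
        bearing = geo.initial_bearing(lat, lon, dest_lat, dest_lon)
        cov = envann.sunset_covariates(
            weather, lat, lon, sunset, bearing, agent.airspeed
        )
        cov_z = {k: _zscore(agent, k, v) for k, v in cov.items() if not np.isnan(v)}
        cov_z["remaining_distance"] = _zscore(agent, "remaining_distance", remaining)

        if state == "stopover":
            eta = _linpred(agent.beta, cov_z)
            p_depart = 1.0 / (1.0 + np.exp(-eta))
            depart = bool(rng.random() < p_depart)
        else:
            # travel bouts persist with fixed probability
            depart = bool(rng.random() < agent.continue_prob)

        night_km = 0.0
        if depart and remaining > 1.0:
            mu = _linpred(agent.gamma, cov_z)
            night_km = 10.0 ** (mu + agent.gamma_resid_sd * rng.standard_normal())
            cap = agent.max_flight_hours * agent.airspeed * 3.6
            night_km = float(min(night_km, cap, remaining))

        rows.append(
            {
                "date": day,
                "lat": lat,
                "lon": lon,
                "state": state,
                "departed": int(depart) if state == "stopover" else np.nan,
                "night_km": night_km if depart else 0.0,
                "sunset": sunset,
                "remaining_distance": remaining,
                "remaining_distance_z": cov_z["remaining_distance"],
                **{k: v for k, v in cov.items()},
                **{f"{k}_z": cov_z.get(k, np.nan) for k in cov},
                "p_depart": p_depart if state == "stopover" else np.nan,
            }
        )

        if depart and night_km > 0.0:
            lat, lon = geo.destination(lat, lon, bearing, night_km)
            state = "travel"
        else:
            state = "stopover"
        if geo.gc_distance(lat, lon, dest_lat, dest_lon) <= 25.0:
            truncated = False
            day += pd.Timedelta(days=1)
            break
        day += pd.Timedelta(days=1)

    truth = pd.DataFrame(rows)
    truth.attrs["truncated"] = truncated
    if truncated:
        import warnings

        warnings.warn("destination not reached within the date span; track truncated")
    return truth


def _linpred(coefs: dict, cov_z: dict) -> float:
    eta = coefs.get("intercept", 0.0)
    for name, b in coefs.items():
        if name == "intercept":
            continue
        if ":" in name:
            a, c = name.split(":")
            eta += b * cov_z.get(a, 0.0) * cov_z.get(c, 0.0)
        else:
            eta += b * cov_z.get(name, 0.0)
    return float(eta)


def light_from_elevation(elev_deg, zenith, threshold=1.35, lmax=64.0, slope=1.5):
    """Logistic light response to solar elevation [deg].

    Calibrated so the curve crosses `threshold` exactly when the sun sits at
    the configured zenith angle, which makes the threshold method exactly
    invertible in the noise-free limit.
    """
    e0 = 90.0 - zenith
    b = np.log(threshold / (lmax - threshold))
    return lmax / (1.0 + np.exp(-(slope * (np.asarray(elev_deg) - e0) + b)))


def simulate_light(
    truth: pd.DataFrame,
    agent: AgentConfig,
    cadence_min: float = 5.0,
    threshold: float = 1.35,
    seed: int = 0,
    shading: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the tag's light series from a daily truth track.

    Returns (light, twilights): `light` is a two-column frame (time, light)
    at the logger cadence; `twilights` records per day the true and shaded
    (apparent) sunrise/sunset, with polar days flagged.

    Shading draws an independent log-normal delay (minutes) per twilight,
    delaying apparent sunrise and advancing apparent sunset — light can be
    blocked, never created.
    """
    rng = np.random.default_rng(seed)
    z0 = agent.zenith
    recs = []
    for _, row in truth.iterrows():
        d, la, lo = row["date"], row["lat"], row["lon"]
        sr = solar.twilight_time(d, la, lo, z0, "sunrise")
        ss = solar.twilight_time(d, la, lo, z0, "sunset")
        polar = pd.isna(sr) or pd.isna(ss)
        if shading and not polar:
            d_sr = float(np.exp(rng.normal(agent.shading_meanlog, agent.shading_sdlog)))
            d_ss = float(np.exp(rng.normal(agent.shading_meanlog, agent.shading_sdlog)))
        else:
            d_sr = d_ss = 0.0
        recs.append(
            {
                "date": d,
                "lat": la,
                "lon": lo,
                "true_sunrise": sr,
                "true_sunset": ss,
                "delay_sunrise_min": d_sr,
                "delay_sunset_min": d_ss,
                "apparent_sunrise": sr + pd.Timedelta(minutes=d_sr) if not polar else pd.NaT,
                "apparent_sunset": ss - pd.Timedelta(minutes=d_ss) if not polar else pd.NaT,
                "polar_day": polar,
            }
        )
    tw = pd.DataFrame(recs)

    # mean local solar noon per truth day, and the solar-midnight boundaries
    # that delimit each day's light window (a high-west-longitude day's
    # sunset falls on the next UTC date, so UTC dates cannot be used)
    noon = truth["date"].to_numpy() + np.timedelta64(12, "h") - (
        truth["lon"].to_numpy() / 15.0 * 3.6e12
    ).astype("timedelta64[ns]")
    boundaries = noon - np.timedelta64(12, "h")
    times = pd.date_range(
        boundaries[0],
        boundaries[-1] + np.timedelta64(24, "h"),
        freq=pd.Timedelta(minutes=cadence_min),
        inclusive="left",
    )
    day_idx = np.clip(
        np.searchsorted(boundaries, times.to_numpy(), side="right") - 1,
        0,
        len(truth) - 1,
    )
    lats = truth["lat"].to_numpy()[day_idx]
    lons = truth["lon"].to_numpy()[day_idx]

    # effective sample time: delayed on the morning side of local solar noon,
    # advanced on the evening side, per that day's drawn shading
    d_sr = tw["delay_sunrise_min"].to_numpy()[day_idx]
    d_ss = tw["delay_sunset_min"].to_numpy()[day_idx]
    is_morning = times.to_numpy() <= noon[day_idx]
    shift_min = np.where(is_morning, -d_sr, d_ss)
    t_eff = times.to_numpy() + (shift_min * 6e10).astype("timedelta64[ns]")

    zen = solar.solar_zenith(t_eff, lats, lons)
    light = light_from_elevation(90.0 - np.asarray(zen), z0, threshold)
    light = np.maximum(light, 0.0)
    light_df = pd.DataFrame({"time": times, "light": light})
    return light_df, tw
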