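"""Low-precision solar ephemeris for threshold geolocation.

Implements the compact solar-position algorithm of Meeus (Astronomical
Algorithms, ch. 25, low-accuracy variant): geometric mean longitude and
anomaly of the Sun, equation of centre, apparent longitude, obliquity,
declination and the equation of time.  Accuracy is a few hundredths of a
degree in declination and a few seconds in the equation of time over the
years relevant to archival tags — far below the minutes-scale twilight
noise the downstream models absorb.

All angles are degrees, all times UTC.  Functions are vectorised over
numpy arrays of timestamps/coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "julian_day",
    "solar_declination_eot",
    "solar_zenith",
    "hour_angle",
    "twilight_time",
    "twilight_times",
]

_J2000 = 2451545.0


def julian_day(times) -> np.ndarray:
    """Julian day (UT) for datetime64/Timestamp input."""
    t = pd.DatetimeIndex(np.atleast_1d(np.asarray(times, dtype="datetime64[ns]")))
    # days since the J2000.0 epoch (2000-01-01 12:00 UT)
    delta = (t - pd.Timestamp("2000-01-01 12:00:00")) / pd.Timedelta(days=1)
    return _J2000 + delta.to_numpy(dtype=float)


def solar_declination_eot(times):
    """Solar declination [deg] and equation of time [minutes].

    Equation of time is apparent solar time minus mean solar time:
    positive when the sundial runs ahead of the clock.
    """
    jd = julian_day(times)
    T = (jd - _J2000) / 36525.0  # Julian centuries

    # geometric mean longitude and mean anomaly of the Sun [deg]
    L0 = (280.46646 + 36000.76983 * T + 0.0003032 * T**2) % 360.0
    M = 357.52911 + 35999.05029 * T - 0.0001537 * T**2
    Mr = np.deg2rad(M)

    # equation of centre and true/apparent longitude
    C = (
        (1.914602 - 0.004817 * T - 0.000014 * T**2) * np.sin(Mr)
        + (0.019993 - 0.000101 * T) * np.sin(2 * Mr)
        + 0.000289 * np.sin(3 * Mr)
    )
    true_lon = L0 + C
    omega = 125.04 - 1934.136 * T
    app_lon = true_lon - 0.00569 - 0.00478 * np.sin(np.deg2rad(omega))

    # obliquity (corrected for nutation)
    eps0 = 23.0 + (26.0 + (21.448 - 46.815 * T - 0.00059 * T**2) / 60.0) / 60.0
    eps = eps0 + 0.00256 * np.cos(np.deg2rad(omega))
    epsr = np.deg2rad(eps)

    decl = np.rad2deg(np.arcsin(np.sin(epsr) * np.sin(np.deg2rad(app_lon))))

    # equation of time, Meeus 28.3 (Smart's expansion), in minutes
    y = np.tan(epsr / 2.0) ** 2
    L0r = np.deg2rad(L0)
    e = 0.016708634 - 0.000042037 * T - 0.0000001267 * T**2
    eot = (
        y * np.sin(2 * L0r)
        - 2 * e * np.sin(Mr)
        + 4 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y**2 * np.sin(4 * L0r)
        - 1.25 * e**2 * np.sin(2 * Mr)
    )
    eot = 4.0 * np.rad2deg(eot)  # radians -> minutes of time
    return decl, eot


def hour_angle(times, lon):
    """Local solar hour angle [deg], 0 at local apparent noon, +ve after."""
    t = pd.DatetimeIndex(np.atleast_1d(np.asarray(times, dtype="datetime64[ns]")))
    _, eot = solar_declination_eot(times)
    frac_hours = (
        t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9
    ).to_numpy(dtype=float)
    # true solar time in minutes
    tst = frac_hours * 60.0 + eot + 4.0 * np.asarray(lon, dtype=float)
    ha = tst / 4.0 - 180.0
    return (ha + 180.0) % 360.0 - 180.0


def solar_zenith(times, lat, lon):
    """Solar zenith angle [deg] at (time, lat, lon); no refraction."""
    decl, _ = solar_declination_eot(times)
    ha = hour_angle(times, lon)
    latr = np.deg2rad(np.asarray(lat, dtype=float))
    dr = np.deg2rad(decl)
    cosz = np.sin(latr) * np.sin(dr) + np.cos(latr) * np.cos(dr) * np.cos(
        np.deg2rad(ha)
    )
    z = np.rad2deg(np.arccos(np.clip(cosz, -1.0, 1.0)))
    return z if z.shape != (1,) else float(z[0])


def _sunrise_ha(decl, lat, zenith):
    """|hour angle| [deg] at which the sun reaches `zenith`; NaN if never."""
    latr = np.deg2rad(np.asarray(lat, dtype=float))
    dr = np.deg2rad(np.asarray(decl, dtype=float))
    cosH = (np.cos(np.deg2rad(zenith)) - np.sin(latr) * np.sin(dr)) / (
        np.cos(latr) * np.cos(dr)
    )
    with np.errstate(invalid="ignore"):
        H = np.rad2deg(np.arccos(np.where(np.abs(cosH) <= 1.0, cosH, np.nan)))
    return H


def twilight_time(date, lat, lon, zenith, kind):
    """UTC time on `date` at which the sun crosses `zenith` at (lat, lon).

    kind: 'sunrise' (downward zenith crossing, morning) or 'sunset'.
    Returns pandas Timestamp, or NaT during polar day/night (no crossing).
    Iterates the sunrise equation twice so declination/EoT are evaluated
    near the event itself rather than at noon.
    """
    d0 = pd.Timestamp(date).normalize()
    sign = -1.0 if kind == "sunrise" else 1.0
    # initial guess: local noon
    t = d0 + pd.Timedelta(hours=12.0 - float(lon) / 15.0)
    for _ in range(3):
        decl, eot = solar_declination_eot(t)
        H = _sunrise_ha(decl, lat, zenith)
        if np.isnan(H[0]):
            return pd.NaT
        # minutes UTC of solar noon at this longitude
        noon_min = 720.0 - 4.0 * float(lon) - eot[0]
        ev_min = noon_min + sign * 4.0 * H[0]
        t = d0 + pd.Timedelta(minutes=float(ev_min))
    return t


def twilight_times(dates, lat, lon, zenith):
    """Sunrise/sunset pairs for a sequence of dates at a fixed site.

    Returns a DataFrame with columns date, sunrise, sunset (UTC; NaT when
    the sun never reaches `zenith` on that date — polar day or night).
    """
    rows = []
    lat = np.broadcast_to(np.asarray(lat, dtype=float), (len(dates),))
    lon = np.broadcast_to(np.asarray(lon, dtype=float), (len(dates),))
    for d, la, lo in zip(dates, lat, lon):
        rows.append(
            {
                "date": pd.Timestamp(d).normalize(),
                "sunrise": twilight_time(d, la, lo, zenith, "sunrise"),
                "sunset": twilight_time(d, la, lo, zenith, "sunset"),
            }
        )
    return pd.DataFrame(rows)
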