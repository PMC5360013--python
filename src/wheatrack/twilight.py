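"""Twilight detection and editing on archival light series.

Sunrise/sunset events are threshold crossings of the light record (default
threshold 1.35, the conventional arbitrary level for BAS/Biotrack tags and
1.35 lux for Intigeo tags), linearly interpolated between the bracketing
samples.  The editor implements the standard screening rule: an event
deviating by more than a limit (default 30 min) from the locally stable
run of same-type neighbours is snapped to the neighbourhood trend; when
the neighbourhood itself is unstable the event is discarded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 1.35

__all__ = ["DEFAULT_THRESHOLD", "detect_twilights", "edit_twilights", "twilight_pairs"]


def _validate_light(light: pd.DataFrame) -> pd.DataFrame:
    if not {"time", "light"} <= set(light.columns):
        raise ValueError("light series needs 'time' and 'light' columns")
    t = pd.to_datetime(light["time"])
    if t.duplicated().any():
        raise ValueError("duplicate timestamps in light series")
    if not t.is_monotonic_increasing:
        raise ValueError("timestamps must be strictly increasing")
    if t.iloc[-1] - t.iloc[0] < pd.Timedelta(days=1):
        raise ValueError("need at least one full day of light data")
    out = light.copy()
    out["time"] = t
    return out


def detect_twilights(
    light: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Detect sunrise (upward) and sunset (downward) threshold crossings.

    Returns a twilight table with columns date, type ('sunrise'|'sunset'),
    time (UTC, linearly interpolated between the bracketing samples), flag
    ('kept') and original_time (NaT).  A constant-light series (polar day
    or night) yields an empty table; the count of crossing-free days is
    stored in ``result.attrs['days_without_events']``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    light = _validate_light(light)
    lv = light["light"].to_numpy(dtype=float)
    tv = light["time"].to_numpy()

    above = lv > threshold
    flip = np.nonzero(above[1:] != above[:-1])[0]  # crossing between i, i+1
    rows = []
    for i in flip:
        l0, l1 = lv[i], lv[i + 1]
        frac = (threshold - l0) / (l1 - l0)
        t = tv[i] + frac * (tv[i + 1] - tv[i])
        kind = "sunrise" if l1 > l0 else "sunset"
        rows.append(
            {
                "date": pd.Timestamp(t).normalize(),
                "type": kind,
                "time": pd.Timestamp(t),
                "flag": "kept",
                "original_time": pd.NaT,
            }
        )
    tw = pd.DataFrame(rows, columns=["date", "type", "time", "flag", "original_time"])

    n_days = len(np.unique(light["time"].dt.normalize()))
    tw.attrs["days_without_events"] = int(
        n_days - len(np.unique(tw["date"])) if len(tw) else n_days
    )
    tw.attrs["threshold"] = threshold
    return tw


def _tod_minutes(times: pd.Series) -> np.ndarray:
    t = pd.DatetimeIndex(times)
    return (
        t.hour * 60.0 + t.minute + t.second / 60.0 + t.microsecond / 6e7
    ).to_numpy(dtype=float)


def _unwrap_tod(tod: np.ndarray) -> np.ndarray:
    """Lift times-of-day onto a continuous scale (no midnight wrap jumps)."""
    out = tod.copy()
    for i in range(1, len(out)):
        d = out[i] - out[i - 1]
        if d > 720.0:
            out[i:] -= 1440.0
            out = out.copy()
        elif d < -720.0:
            out[i:] += 1440.0
    return out


def edit_twilights(
    tw: pd.DataFrame, window: int = 5, limit: float = 30.0
) -> pd.DataFrame:
    """Screen twilight events against their same-type neighbourhood.

    For each event the `window` nearest same-type neighbours (excluding the
    event itself) define a local linear trend of time-of-day against day
    number; the deviation is the event's residual from that trend.  If
    |deviation| > `limit` minutes and the neighbours are themselves stable
    (their residual spread <= limit), the event time is replaced by the
    trend prediction and flagged 'adjusted'; with unstable neighbours it is
    flagged 'discarded'.  Events too close to the series ends to have a
    full neighbourhood are kept unflagged.  Summary counts go to
    ``result.attrs['edit_summary']``.
    """
    if limit <= 0:
        raise ValueError("limit must be positive")
    if window < 3:
        raise ValueError("window must cover at least 3 neighbours")
    out = tw.copy().reset_index(drop=True)
    for kind in ("sunrise", "sunset"):
        idx = out.index[out["type"] == kind].to_numpy()
        if len(idx) < window + 1:
            continue
        times = out.loc[idx, "time"]
        day = (
            pd.DatetimeIndex(times).normalize()
            - pd.DatetimeIndex(times).normalize()[0]
        ) / pd.Timedelta(days=1)
        day = np.asarray(day, dtype=float)
        tod = _unwrap_tod(_tod_minutes(times))
        new_time = {}
        flags = {}
        for j in range(len(idx)):
            # nearest same-type neighbours; one-sided at the series ends,
            # where unscreened events would otherwise anchor the track
            nb = sorted(
                (k for k in range(len(idx)) if k != j), key=lambda k: abs(k - j)
            )[:window]
            if len(nb) < window:
                continue  # fewer than `window` neighbours: keep unflagged
            x, y = day[nb], tod[nb]
            # robust local trend (Theil-Sen) removes the seasonal/travel
            # drift without being dragged by displaced neighbours
            slopes = [
                (y[l] - y[k]) / (x[l] - x[k])
                for k in range(len(x))
                for l in range(k + 1, len(x))
                if x[l] != x[k]
            ]
            b = float(np.median(slopes)) if slopes else 0.0
            a = float(np.median(y - b * x))
            resid = y - (a + b * x)
            dev = tod[j] - (a + b * day[j])
            # "stable surroundings": at most one gross outlier among the
            # neighbours — a second large residual means the deviation is
            # shared with the neighbourhood and no trustworthy reference
            # exists, so the event is discarded rather than snapped
            second_largest = np.sort(np.abs(resid))[-2]
            stable = second_largest <= limit
            if abs(dev) > limit:
                if stable:
                    flags[idx[j]] = "adjusted"
                    new_time[idx[j]] = out.loc[idx[j], "time"] - pd.Timedelta(
                        minutes=float(dev)
                    )
                else:
                    flags[idx[j]] = "discarded"
        for i, f in flags.items():
            out.loc[i, "flag"] = f
            if f == "adjusted":
                out.loc[i, "original_time"] = out.loc[i, "time"]
                out.loc[i, "time"] = new_time[i]
    summary = out["flag"].value_counts().to_dict()
    out.attrs = dict(tw.attrs)
    out.attrs["edit_summary"] = {
        "kept": summary.get("kept", 0),
        "adjusted": summary.get("adjusted", 0),
        "discarded": summary.get("discarded", 0),
    }
    return out


def twilight_pairs(tw: pd.DataFrame) -> pd.DataFrame:
    """Pair each sunrise with the following sunset (one daytime pair per day).

    Discarded events are excluded.  Returns a frame with columns date,
    sunrise, sunset, sunrise_flag, sunset_flag.
    """
    ok = tw[tw["flag"] != "discarded"].sort_values("time").reset_index(drop=True)
    rows = []
    for i in range(len(ok) - 1):
        if ok.loc[i, "type"] == "sunrise" and ok.loc[i + 1, "type"] == "sunset":
            rows.append(
                {
                    "date": ok.loc[i, "date"],
                    "sunrise": ok.loc[i, "time"],
                    "sunset": ok.loc[i + 1, "time"],
                    "sunrise_flag": ok.loc[i, "flag"],
                    "sunset_flag": ok.loc[i + 1, "flag"],
                }
            )
    return pd.DataFrame(rows, columns=["date", "sunrise", "sunset", "sunrise_flag", "sunset_flag"])
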