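"""Migration schedule: stopover segmentation and phenology metrics.

Stationary periods are found by a changepoint analysis on the twilight
series: each sunrise/sunset event gets the probability that it marks a
mean shift within a sliding window of same-type events (two-segment vs
one-segment F test mapped through its null distribution).  Events above
the 0.75 quantile of all probabilities mark movement; runs of quiet
events lasting at least two days are stationary periods, and consecutive
periods whose mean locations sit within 200 km are merged (iterated to a
fixed point).  Phenology metrics follow: onset/termination by the
longitude and distance rules, total migration distance, total speed
(distance / duration, stopovers included) and per-travel-day speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import geo

__all__ = [
    "changepoint_probabilities",
    "segment",
    "merge_neighbours",
    "daily_states",
    "define_season",
    "phenology_metrics",
    "StationaryPeriod",
]


@dataclass
class StationaryPeriod:
    start: pd.Timestamp
    end: pd.Timestamp
    lat: float
    lon: float
    merged_from: list = field(default_factory=list)

    @property
    def duration_days(self) -> int:
        return int((self.end - self.start) / pd.Timedelta(days=1)) + 1


def _tod_unwrapped_minutes(times) -> np.ndarray:
    t = pd.DatetimeIndex(times)
    tod = (
        t.hour * 60.0 + t.minute + t.second / 60.0 + t.microsecond / 6e7
    ).to_numpy(dtype=float)
    out = tod.copy()
    for i in range(1, len(out)):
        d = out[i] - out[i - 1]
        if d > 720.0:
            out[i:] -= 1440.0
        elif d < -720.0:
            out[i:] += 1440.0
    return out


def changepoint_probabilities(tw: pd.DataFrame, window: int = 6) -> pd.DataFrame:
    """Changepoint probability per twilight event.

    For each event, the `window` same-type events centred on it are split
    at the event; the F statistic of the two-segment versus one-segment
    mean model, pushed through its null CDF, is the probability that the
    event differs from its surroundings.  Sunrise and sunset series are
    scored separately and interleaved.
    """
    ev = tw[tw["flag"] != "discarded"].sort_values("time").reset_index(drop=True)
    probs = np.zeros(len(ev))
    for kind in ("sunrise", "sunset"):
        idx = ev.index[ev["type"] == kind].to_numpy()
        if len(idx) < window + 1:
            raise ValueError(
                f"need at least {window + 1} {kind} events for the changepoint window"
            )
        y = _tod_unwrapped_minutes(ev.loc[idx, "time"])
        # null (stationary) noise scale: robust global estimate from the
        # first differences — stationary stretches dominate the median, so
        # travel steps do not inflate it
        d1 = np.abs(np.diff(y))
        sigma = max(1.4826 * float(np.median(d1)) / np.sqrt(2.0), 0.5)
        # two-segment vs one-segment mean comparison at the minimal window
        # (the event against its same-type predecessor): uniquely localises
        # a travel night even inside a run of consecutive flights, where a
        # wider window would absorb earlier steps into the null segment.
        # F = (y_j - y_{j-1})^2 / (2 sigma^2) against its null distribution;
        # sigma is held at the robust global value, so the reference is
        # effectively chi-square (df -> large via `window`-scaled df)
        df2 = max(2 * (window - 1), 2)
        for j in range(1, len(idx)):
            F = (y[j] - y[j - 1]) ** 2 / (2.0 * sigma**2)
            probs[idx[j]] = float(stats.f.cdf(F, 1, df2))
    out = ev.copy()
    out["prob"] = probs
    return out


def segment(
    tw_probs: pd.DataFrame,
    track: pd.DataFrame,
    q: float = 0.75,
    min_days: int = 2,
) -> list[StationaryPeriod]:
    """Stationary periods from thresholded changepoint probabilities.

    Events above the `q` quantile of all probabilities mark movement; runs
    of quiet events spanning >= `min_days` days form stationary periods
    whose mean location comes from the track's daily estimates.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError("q must be in (0, 1]")
    ev = tw_probs.sort_values("time").reset_index(drop=True)

    # day-level movement evidence: a night flight shifts both twilights of
    # the following bird-day (sunrise + next sunset — NOT the UTC date,
    # which splits a western-hemisphere day's pair across two dates), but
    # latitude and longitude displacements can partly cancel on one side,
    # so the two events' tail probabilities are combined by Fisher's
    # method; the movement is attributed to the departure evening (the
    # previous day)
    kinds = ev["type"].to_numpy()
    probs_arr = ev["prob"].to_numpy()
    times = pd.DatetimeIndex(ev["time"])
    day_keys, day_evidence = [], []
    cur_day, cur_ps = None, []

    def _fisher(ps):
        x = -2.0 * sum(np.log(np.maximum(1.0 - p, 1e-12)) for p in ps)
        return float(stats.chi2.cdf(x, 2 * len(ps)))

    for k, p, t in zip(kinds, probs_arr, times):
        if k == "sunrise":
            if cur_day is not None and cur_ps:
                day_keys.append(cur_day)
                day_evidence.append(_fisher(cur_ps))
            cur_day, cur_ps = t.normalize(), [p]
        elif cur_day is not None:
            cur_ps.append(p)
    if cur_day is not None and cur_ps:
        day_keys.append(cur_day)
        day_evidence.append(_fisher(cur_ps))
    day_evidence = np.asarray(day_evidence)
    thresh = np.quantile(day_evidence, q)
    by_day = pd.Series(day_evidence > thresh, index=pd.DatetimeIndex(day_keys))
    by_day.index = by_day.index - pd.Timedelta(days=1)
    by_day = by_day.iloc[1:] if len(by_day) > 1 else by_day

    tloc = track.set_index(pd.DatetimeIndex(track["date"]).normalize())
    periods: list[StationaryPeriod] = []
    run: list[pd.Timestamp] = []
    for day, mv in by_day.items():
        if not mv:
            run.append(day)
        else:
            _close_run(run, tloc, periods, min_days)
            run = []
    _close_run(run, tloc, periods, min_days)
    return periods


def _close_run(run, tloc, periods, min_days):
    if not run:
        return
    start, end = run[0], run[-1]
    if (end - start) / pd.Timedelta(days=1) + 1 < min_days:
        return
    sub = tloc.loc[tloc.index.isin(run)]
    if len(sub) == 0:
        return
    periods.append(
        StationaryPeriod(
            start=start,
            end=end,
            lat=float(sub["lat"].mean()),
            lon=float(geo.wrap_lon(_circ_mean_lon(sub["lon"].to_numpy()))),
        )
    )


def _circ_mean_lon(lons: np.ndarray) -> float:
    r = np.deg2rad(lons)
    return float(np.rad2deg(np.arctan2(np.mean(np.sin(r)), np.mean(np.cos(r)))))


def merge_neighbours(
    periods: list[StationaryPeriod], track: pd.DataFrame, radius_km: float = 200.0
) -> list[StationaryPeriod]:
    """Merge consecutive periods whose mean locations sit within `radius_km`.

    Applied iteratively until a fixed point: a merged period's mean
    location (day-weighted) is re-tested against its next neighbour.
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    ps = [
        StationaryPeriod(p.start, p.end, p.lat, p.lon, list(p.merged_from) or [i])
        for i, p in enumerate(periods)
    ]
    changed = True
    while changed:
        changed = False
        out: list[StationaryPeriod] = []
        for p in ps:
            if out and geo.gc_distance(out[-1].lat, out[-1].lon, p.lat, p.lon) <= radius_km:
                a = out[-1]
                wa, wb = a.duration_days, p.duration_days
                lat = (a.lat * wa + p.lat * wb) / (wa + wb)
                lon = _circ_mean_lon(
                    np.concatenate([np.full(wa, a.lon), np.full(wb, p.lon)])
                )
                out[-1] = StationaryPeriod(
                    a.start, p.end, lat, geo.wrap_lon(lon), a.merged_from + p.merged_from
                )
                changed = True
            else:
                out.append(p)
        ps = out
    return ps


def daily_states(
    track: pd.DataFrame, periods: list[StationaryPeriod]
) -> pd.DataFrame:
    """Per-day state table: every tracked day is stopover or travel."""
    days = pd.DatetimeIndex(track["date"]).normalize()
    state = np.full(len(days), "travel", dtype=object)
    sid = np.full(len(days), -1)
    for i, p in enumerate(periods):
        m = (days >= p.start) & (days <= p.end)
        state[m] = "stopover"
        sid[m] = i
    return pd.DataFrame({"date": days, "state": state, "period_id": sid})


def define_season(
    periods: list[StationaryPeriod],
    daily: pd.DataFrame,
    breeding: tuple,
    wintering: Optional[tuple] = None,
    season: str = "autumn",
    lon_margin_deg: float = 2.0,
    winter_radius_km: float = 200.0,
) -> dict:
    """Onset and termination dates for one migration season.

    Autumn onset: start of the flight run preceding the last stationary
    site more than `lon_margin_deg` of longitude from the breeding area
    (when all stopovers sit closer, the last day of the subsequent flight
    run).  Autumn termination: first day of the wintering period — taken
    as the longest non-breeding stationary period when `wintering` is not
    given.  Spring onset: first day of the flight run preceding the first
    stationary period `winter_radius_km` from the wintering ground; spring
    termination: last day of the last flight run, or the last estimable
    location when the track truncates (24-h polar daylight).
    """
    res = {"season": season, "onset": None, "termination": None, "reason": None,
           "truncated": False}
    if not periods:
        res["reason"] = "no stationary periods"
        return res
    days = pd.DatetimeIndex(daily["date"])
    states = daily["state"].to_numpy()

    def flight_run_before(day):
        m = days < day
        run_end = None
        for d, st in zip(days[m][::-1], states[m][::-1]):
            if st == "travel":
                if run_end is None:
                    run_end = d
                run_start = d
            elif run_end is not None:
                return run_start, run_end
        if run_end is not None:
            return run_start, run_end
        return None

    def flight_run_after(day):
        m = days > day
        run_start = None
        for d, st in zip(days[m], states[m]):
            if st == "travel":
                if run_start is None:
                    run_start = d
                run_end = d
            elif run_start is not None:
                return run_start, run_end
        if run_start is not None:
            return run_start, run_end
        return None

    if season == "autumn":
        far = [
            p
            for p in periods
            if abs(geo.wrap_lon(p.lon - breeding[1])) > lon_margin_deg
        ]
        if far:
            # the stationary site past the longitude margin closest to the
            # breeding area in time: its preceding flight run starts the season
            anchor = far[0]
            run = flight_run_before(anchor.start)
            if run:
                res["onset"] = run[0]
            else:
                res["onset"] = anchor.start
        else:
            near = periods[0]
            run = flight_run_after(near.end)
            if run:
                res["onset"] = run[1]
            else:
                res["reason"] = "no flight run after the near-breeding stopover"
        if wintering is None:
            # longest stationary period away from the breeding region
            cands = [
                p
                for p in periods
                if geo.gc_distance(p.lat, p.lon, *breeding) > 500.0
            ]
            if cands:
                w = max(cands, key=lambda p: p.duration_days)
                res["termination"] = w.start
                res["wintering"] = (w.lat, w.lon)
            else:
                res["reason"] = "no non-breeding stationary period"
        else:
            near_w = [
                p
                for p in periods
                if geo.gc_distance(p.lat, p.lon, *wintering) <= winter_radius_km
            ]
            if near_w:
                res["termination"] = near_w[0].start
                res["wintering"] = wintering
            else:
                res["reason"] = "no stationary period near the wintering ground"
    elif season == "spring":
        if wintering is None:
            res["reason"] = "spring rules need the wintering location"
            return res
        away = [
            p
            for p in periods
            if geo.gc_distance(p.lat, p.lon, *wintering) > winter_radius_km
        ]
        if away:
            run = flight_run_before(away[0].start)
            res["onset"] = run[0] if run else away[0].start
        else:
            res["reason"] = "no stationary period away from the wintering ground"
        # termination: last day of the last flight run; truncated tracks end
        # at the last estimable location
        travel_days = days[states == "travel"]
        if len(travel_days):
            res["termination"] = travel_days[-1]
            if states[-1] == "travel" or travel_days[-1] >= days[-1] - pd.Timedelta(days=1):
                res["truncated"] = True
        else:
            res["reason"] = "no travel days"
    else:
        raise ValueError("season must be 'autumn' or 'spring'")
    return res


def phenology_metrics(
    track: pd.DataFrame,
    daily: pd.DataFrame,
    onset,
    termination,
    periods: Optional[list] = None,
    truncated: bool = False,
) -> dict:
    """Phenology metrics over the migration window [onset, termination].

    total distance = sum of great-circle legs between consecutive daily
    locations; total speed = distance / duration (stopovers included);
    travel speed per travel day; stopover days per 1000 km.

    When `periods` is given, days inside a stationary period take the
    period's mean location: day-to-day jitter of the position estimates
    at a fixed site is measurement noise, not distance travelled.
    """
    if onset is None or termination is None:
        raise ValueError("undefined migration window")
    onset, termination = pd.Timestamp(onset), pd.Timestamp(termination)
    duration = (termination - onset) / pd.Timedelta(days=1)
    if duration <= 0:
        raise ValueError("zero-duration migration window")
    t = track.set_index(pd.DatetimeIndex(track["date"]).normalize()).sort_index()
    win = t.loc[(t.index >= onset) & (t.index <= termination)]
    lats = win["lat"].to_numpy(dtype=float).copy()
    lons = win["lon"].to_numpy(dtype=float).copy()
    if periods:
        for p in periods:
            m = (win.index >= p.start) & (win.index <= p.end)
            lats[m] = p.lat
            lons[m] = p.lon
    legs = geo.gc_distance(lats[:-1], lons[:-1], lats[1:], lons[1:])
    total_km = float(np.sum(legs))

    d = daily.set_index(pd.DatetimeIndex(daily["date"]).normalize())
    d = d.loc[(d.index >= onset) & (d.index <= termination)]
    n_stop = int((d["state"] == "stopover").sum())
    n_travel = int((d["state"] == "travel").sum())

    travel_mask = d.reindex(win.index[:-1])["state"].to_numpy() == "travel"
    travel_speeds = legs[travel_mask]

    return {
        "onset": onset,
        "termination": termination,
        "duration_days": float(duration),
        "total_distance_km": total_km,
        "total_speed_kmday": total_km / duration,
        "total_stopover_days": n_stop,
        "n_travel_days": n_travel,
        "mean_travel_speed_kmday": float(np.mean(travel_speeds)) if len(travel_speeds) else float("nan"),
        "stopover_days_per_1000km": 1000.0 * n_stop / total_km if total_km > 0 else float("nan"),
        "truncated": truncated,
    }
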