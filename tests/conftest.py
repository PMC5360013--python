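"""Shared fixtures: a small synthetic world, tracks and light series.

Everything is generated at test time from fixed seeds; nothing binary is
stored in the repository.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from wheatrack import solar, synthetic

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def world():
    return synthetic.WorldConfig(seed=42)


@pytest.fixture(scope="session")
def weather(world):
    return synthetic.make_weather(world)


@pytest.fixture(scope="session")
def agent():
    return synthetic.AgentConfig()


@pytest.fixture(scope="session")
def truth_track(agent, weather, world):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.simulate_track(agent, weather, world)


@pytest.fixture(scope="session")
def stationary_truth():
    """40 days parked at the Eagle Summit breeding site, mid-August on."""
    days = pd.date_range("2013-08-10", periods=40, freq="D")
    return pd.DataFrame({"date": days, "lat": 65.6, "lon": -145.4})


@pytest.fixture(scope="session")
def clean_light(stationary_truth, agent):
    light, tw = synthetic.simulate_light(
        stationary_truth, agent, seed=3, shading=False
    )
    return light, tw


def synthetic_twilights(rng, pattern, jitter_min=3.0, start="2013-08-05",
                        lat0=60.0, lon0=-145.0):
    """Twilight series for a stopover('s')/travel('t') day pattern.

    Travel nights shift the position westward and slightly south; every
    event gets Gaussian timing jitter.  Returns (twilight table, daily
    true track).
    """
    rows, locs = [], []
    lat, lon = lat0, lon0
    day = pd.Timestamp(start)
    for state in pattern:
        locs.append((lat, lon))
        sr = solar.twilight_time(day, lat, lon, 96.8, "sunrise")
        ss = solar.twilight_time(day, lat, lon, 96.8, "sunset")
        for kind, t in (("sunrise", sr), ("sunset", ss)):
            rows.append(
                {
                    "date": t.normalize(),
                    "type": kind,
                    "time": t + pd.Timedelta(minutes=float(rng.normal(0, jitter_min))),
                    "flag": "kept",
                    "original_time": pd.NaT,
                }
            )
        if state == "t":
            lon += float(rng.uniform(-6, -3))
            lat -= float(rng.uniform(0.3, 1.0))
        day += pd.Timedelta(days=1)
    tw = pd.DataFrame(rows).sort_values("time").reset_index(drop=True)
    track = pd.DataFrame(
        {
            "date": pd.date_range(start, periods=len(pattern)),
            "lat": [l[0] for l in locs],
            "lon": [l[1] for l in locs],
        }
    )
    return tw, track


def true_stopovers(pattern, min_days=2):
    """(start_index, end_index) of stopover runs >= min_days in a pattern."""
    out, i = [], 0
    while i < len(pattern):
        if pattern[i] == "s":
            j = i
            while j < len(pattern) and pattern[j] == "s":
                j += 1
            if j - i >= min_days:
                out.append((i, j - 1))
            i = j
        else:
            i += 1
    return out


def random_pattern(rng, n_stop=6):
    parts = []
    for k in range(n_stop):
        parts.append("s" * int(rng.integers(2, 8)))
        if k < n_stop - 1:
            parts.append("t" * int(rng.integers(1, 4)))
    return "".join(parts)
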