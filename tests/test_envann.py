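"""Field interpolation, precipitation windows, flow assistance, bird-days."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from wheatrack import envann, geo, schedule


def grid_field(fn, times, lats, lons):
    T, La, Lo = np.meshgrid(
        np.arange(len(times), dtype=float), lats, lons, indexing="ij"
    )
    return xr.DataArray(
        fn(T, La, Lo),
        dims=("time", "lat", "lon"),
        coords={"time": times, "lat": lats, "lon": lons},
    )


@pytest.fixture(scope="module")
def linear_field():
    times = pd.date_range("2013-08-01", periods=10, freq="6h")
    lats = np.arange(40.0, 50.1, 2.5)
    lons = np.arange(-110.0, -99.9, 2.5)
    return grid_field(lambda t, la, lo: 2.0 * t + 0.5 * la - 0.25 * lo, times, lats, lons)


def test_interp_identity_on_grid_node(linear_field):
    v = envann.interp_field(
        linear_field, pd.Timestamp("2013-08-01 06:00"), 42.5, -105.0
    )
    assert v == pytest.approx(float(linear_field.isel(time=1).sel(lat=42.5, lon=-105.0)))


def test_interp_exact_for_linear_field(linear_field):
    # bilinear+linear interpolation reproduces a trilinear function exactly
    v = envann.interp_field(
        linear_field, pd.Timestamp("2013-08-01 03:00"), 43.75, -106.25
    )
    expected = 2.0 * 0.5 + 0.5 * 43.75 - 0.25 * (-106.25)
    assert v == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "query,axis",
    [
        ((pd.Timestamp("2013-09-01"), 45.0, -105.0), "time"),
        ((pd.Timestamp("2013-08-01 06:00"), 80.0, -105.0), "lat"),
        ((pd.Timestamp("2013-08-01 06:00"), 45.0, -200.0), "lon"),
    ],
)
def test_out_of_hull_names_axis(linear_field, query, axis):
    with pytest.raises(ValueError, match=axis):
        envann.interp_field(linear_field, *query)


def test_interp_error_shrinks_under_refinement():
    """Richardson-style check: for a smooth field the interpolation error
    is bounded by curvature x cell size^2, so refining the grid 2x shrinks
    the worst error ~4x."""
    times = pd.date_range("2013-08-01", periods=3, freq="6h")
    fn = lambda t, la, lo: np.sin(np.deg2rad(4 * la)) * np.cos(np.deg2rad(3 * lo))
    errs = []
    for step in (2.5, 1.25):
        lats = np.arange(40.0, 50.0001, step)
        lons = np.arange(-110.0, -99.9999, step)
        f = grid_field(fn, times, lats, lons)
        qla = np.linspace(41.0, 49.0, 23)
        qlo = np.linspace(-109.0, -101.0, 23)
        worst = 0.0
        for la in qla:
            v = envann.interp_field(
                f, np.repeat(times[1].to_numpy(), len(qlo)),
                np.full(len(qlo), la), qlo,
            )
            truth = fn(1.0, la, qlo)
            worst = max(worst, float(np.max(np.abs(v - truth))))
        errs.append(worst)
    assert errs[1] < errs[0] / 3.0


@pytest.fixture(scope="module")
def const_precip():
    times = pd.date_range("2013-08-01", periods=30, freq="6h")
    lats = np.arange(40.0, 50.1, 2.5)
    lons = np.arange(-110.0, -99.9, 2.5)
    return grid_field(lambda t, la, lo: np.full_like(t, 3e-5), times, lats, lons)


def test_precip_constant_rate_gives_seven_samples(const_precip):
    s = envann.precip_window(const_precip, pd.Timestamp("2013-08-03 01:00"), 45.0, -105.0)
    assert s == pytest.approx(7 * 3e-5, rel=1e-9)


def test_precip_zero(const_precip):
    z = const_precip * 0.0
    s = envann.precip_window(z, pd.Timestamp("2013-08-03 01:00"), 45.0, -105.0)
    assert s == 0.0


def test_precip_triangular_pulse_hand_sum():
    """Rate rises linearly to a peak at sunset then falls: the 7-point
    hourly sum is computable by hand from the hat function."""
    times = pd.date_range("2013-08-01", periods=49, freq="1h")
    lats = np.arange(40.0, 50.1, 5.0)
    lons = np.arange(-110.0, -99.9, 5.0)
    peak_idx = 24.0
    fn = lambda t, la, lo: np.maximum(0.0, 1.0 - np.abs(t - peak_idx) / 4.0) * 1e-4
    f = grid_field(fn, times, lats, lons)
    sunset = times[24]
    s = envann.precip_window(f, sunset, 45.0, -105.0)
    # offsets -3..3 h: values (1/4, 2/4, 3/4, 1, 3/4, 2/4, 1/4) x 1e-4
    assert s == pytest.approx(4.0 * 1e-4, rel=1e-9)


def test_precip_window_clipped_by_span(const_precip):
    with pytest.raises(ValueError, match="time"):
        envann.precip_window(const_precip, pd.Timestamp("2013-08-01 01:00"), 45.0, -105.0)


class TestFlowAssistance:
    def test_pure_tailwind_adds_fully(self):
        # wind blowing north at 5 m/s, bird heading north
        assert envann.flow_assistance(0.0, 5.0, 0.0, 13.0) == pytest.approx(5.0, abs=1e-12)

    def test_pure_headwind_subtracts_fully(self):
        assert envann.flow_assistance(0.0, 5.0, 180.0, 13.0) == pytest.approx(-5.0, abs=1e-12)

    def test_crosswind_exact_value(self):
        # theta=90, y=5, z=13: sqrt(169-25) - 13 = -1
        fa = envann.flow_assistance(5.0, 0.0, 0.0, 13.0)
        assert fa == pytest.approx(np.sqrt(144.0) - 13.0, abs=1e-12)

    def test_crosswind_stronger_than_airspeed_is_missing(self):
        assert np.isnan(envann.flow_assistance(14.0, 0.0, 0.0, 13.0))

    def test_tailwind_identity_for_all_speeds(self):
        for y in np.linspace(0.0, 13.0, 14):
            assert envann.flow_assistance(0.0, y, 0.0, 13.0) == pytest.approx(y, abs=1e-9)

    def test_airspeed_must_be_positive(self):
        with pytest.raises(ValueError):
            envann.flow_assistance(1.0, 1.0, 0.0, 0.0)


def _wind_dataset(u_by_level, v_by_level):
    times = pd.date_range("2013-08-01", periods=4, freq="6h")
    lats = np.arange(40.0, 50.1, 2.5)
    lons = np.arange(-110.0, -99.9, 2.5)
    shape = (4, len(times), len(lats), len(lons))
    u = np.empty(shape)
    v = np.empty(shape)
    for i in range(4):
        u[i] = u_by_level[i]
        v[i] = v_by_level[i]
    return xr.Dataset(
        {"uwnd": (("level", "time", "lat", "lon"), u),
         "vwnd": (("level", "time", "lat", "lon"), v)},
        coords={"level": [1000, 925, 850, 700], "time": times, "lat": lats, "lon": lons},
    )


def test_best_flow_identical_levels_equals_single_level():
    ds = _wind_dataset([0, 0, 0, 0], [5, 5, 5, 5])
    fa = envann.best_flow(ds, 45.0, -105.0, pd.Timestamp("2013-08-01 06:00"), (50.0, -105.0))
    assert fa == pytest.approx(5.0, abs=1e-9)


def test_best_flow_picks_the_tailwind_level():
    # three headwind levels, one tailwind level
    ds = _wind_dataset([0, 0, 0, 0], [-6, -4, 7, -2])
    fa = envann.best_flow(ds, 45.0, -105.0, pd.Timestamp("2013-08-01 06:00"), (50.0, -105.0))
    assert fa == pytest.approx(7.0, abs=1e-9)


def test_best_flow_equals_brute_force_max():
    rng = np.random.default_rng(8)
    u = rng.normal(0, 6, 4)
    v = rng.normal(0, 6, 4)
    ds = _wind_dataset(list(u), list(v))
    t = pd.Timestamp("2013-08-01 06:00")
    goal = (49.0, -103.0)
    fa = envann.best_flow(ds, 45.0, -105.0, t, goal)
    brg = geo.initial_bearing(45.0, -105.0, *goal)
    vals = [envann.flow_assistance(u[i], v[i], brg) for i in range(4)]
    assert fa == pytest.approx(np.nanmax(vals), abs=1e-9)


def test_best_flow_missing_only_if_all_levels_missing():
    ds = _wind_dataset([20, 25, -22, 30], [0, 0, 0, 0])  # all crosswind > z
    fa = envann.best_flow(ds, 45.0, -105.0, pd.Timestamp("2013-08-01 06:00"), (50.0, -105.0))
    assert np.isnan(fa)


def test_hourly_mean_flow_uniform_field_equals_point_value():
    ds = _wind_dataset([0, 0, 0, 0], [4, 4, 4, 4])
    fa = envann.hourly_mean_flow(
        ds, (44.0, -106.0), (46.0, -104.0), pd.Timestamp("2013-08-01 03:00"), 6
    )
    point = envann.best_flow(ds, 44.0, -106.0, pd.Timestamp("2013-08-01 03:00"), (46.0, -104.0))
    assert fa == pytest.approx(point, abs=0.15)


def test_hourly_mean_flow_matches_independent_loop():
    rng = np.random.default_rng(3)
    u = list(rng.normal(0, 5, 4))
    v = list(rng.normal(0, 5, 4))
    ds = _wind_dataset(u, v)
    start = pd.Timestamp("2013-08-01 03:00")
    a, b = (44.0, -108.0), (47.0, -102.0)
    fa = envann.hourly_mean_flow(ds, a, b, start, 5)
    lats, lons = geo.gc_waypoints(*a, *b, 6)
    vals = []
    for h in range(5):
        vals.append(envann.best_flow(ds, lats[h], lons[h], start + pd.Timedelta(hours=h), b))
    assert fa == pytest.approx(np.nanmean(vals), abs=1e-9)


def test_hourly_mean_flow_zero_length_rejected():
    ds = _wind_dataset([0] * 4, [4] * 4)
    with pytest.raises(ValueError, match="night"):
        envann.hourly_mean_flow(ds, (44, -106), (46, -104), "2013-08-01 03:00", 0)


def test_bird_day_table_counts_and_departure_pattern(weather):
    """Five stationary days then departure: rows (0,0,0,0,1); travel rows
    carry a travel-speed response; row count equals truth-day count."""
    days = pd.date_range("2013-08-10", periods=8)
    lats = [55.0] * 5 + [53.0, 51.0, 49.0]
    lons = [-140.0] * 5 + [-141.0, -142.0, -143.0]
    track = pd.DataFrame({"date": days, "lat": lats, "lon": lons})
    daily = pd.DataFrame(
        {"date": days, "state": ["stopover"] * 5 + ["travel"] * 3}
    )
    table = envann.build_bird_day_table(daily, track, weather, (30.0, -60.0))
    stop = table[table.state == "stopover"]
    assert list(stop.departed.astype(int)) == [0, 0, 0, 0, 1]
    trav = table[table.state == "travel"]
    assert trav.travel_speed.iloc[0] == pytest.approx(
        geo.gc_distance(53.0, -141.0, 51.0, -142.0), rel=1e-6
    )
    assert len(table) == len(days)


def test_remaining_distance_zero_at_destination(weather):
    days = pd.date_range("2013-08-10", periods=3)
    track = pd.DataFrame({"date": days, "lat": [30.0] * 3, "lon": [-60.0] * 3})
    daily = pd.DataFrame({"date": days, "state": ["stopover"] * 3})
    table = envann.build_bird_day_table(daily, track, weather, (30.0, -60.0))
    assert (table.remaining_distance < 1e-6).all()


def test_remaining_distance_nonincreasing_along_route(truth_track):
    rd = truth_track.remaining_distance.to_numpy()
    assert (np.diff(rd) <= 1e-6).all()


def test_bird_day_table_deterministic(weather):
    days = pd.date_range("2013-08-10", periods=5)
    track = pd.DataFrame({"date": days, "lat": [55.0] * 5, "lon": [-140.0] * 5})
    daily = pd.DataFrame({"date": days, "state": ["stopover"] * 5})
    a = envann.build_bird_day_table(daily, track, weather, (30.0, -60.0))
    b = envann.build_bird_day_table(daily, track, weather, (30.0, -60.0))
    pd.testing.assert_frame_equal(a, b)


def test_date_mismatch_rejected(weather):
    track = pd.DataFrame({"date": pd.date_range("2013-08-10", periods=3),
                          "lat": [50.0] * 3, "lon": [-100.0] * 3})
    daily = pd.DataFrame({"date": pd.date_range("2014-01-01", periods=3),
                          "state": ["stopover"] * 3})
    with pytest.raises(ValueError, match="share no dates"):
        envann.build_bird_day_table(daily, track, weather, (30.0, -60.0))
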