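"""ODBA-fix linking, resting classification, sites, cover and darkness."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import felimove as fm
from felimove import activity as act


def _fixes(times, x=None, y=None, animal="w"):
    n = len(times)
    return pd.DataFrame(
        {
            "animal": animal,
            "time": pd.DatetimeIndex(times),
            "x": np.zeros(n) if x is None else x,
            "y": np.zeros(n) if y is None else y,
        }
    )


def _odba_frame(times, values):
    return pd.DataFrame({"time": pd.DatetimeIndex(times), "odba": values})


# -- linking ----------------------------------------------------------------


def test_complete_bursts_give_fifteen_values_per_fix():
    fixes = _fixes(pd.date_range("2020-11-01 01:00", periods=20, freq="30min"))
    ot = pd.date_range("2020-11-01 00:00", "2020-11-01 11:00", freq="2min")
    linked = act.link_odba(fixes, _odba_frame(ot, np.ones(len(ot))))
    inner = linked.iloc[1:-1]
    assert (inner["n"] == 15).all()
    assert ((linked["n"] >= 13) & (linked["n"] <= 15)).all()


def test_fix_with_a_burst_gap_is_dropped():
    fixes = _fixes(pd.date_range("2020-11-01 01:00", periods=5, freq="30min"))
    ot = pd.date_range("2020-11-01 00:00", "2020-11-01 04:00", freq="2min")
    keep = ~((ot >= "2020-11-01 01:50") & (ot <= "2020-11-01 02:14"))
    linked = act.link_odba(fixes, _odba_frame(ot[keep], np.ones(keep.sum())))
    # The 02:00 fix lost 12 of its window values -> n < 13 -> dropped.
    assert pd.Timestamp("2020-11-01 02:00") not in set(linked["time"])
    assert ((linked["n"] >= 13) & (linked["n"] <= 15)).all()


def test_assignment_matches_brute_force_nearest_fix_scan():
    rng = np.random.default_rng(17)
    fixes = _fixes(pd.date_range("2020-11-01", periods=30, freq="30min"))
    ot = pd.date_range("2020-11-01", "2020-11-01 14:30", freq="2min")
    vals = rng.gamma(2.0, 800.0, len(ot))
    shuffle = rng.permutation(len(ot))
    linked = act.link_odba(
        fixes, _odba_frame(ot[shuffle], vals[shuffle]), min_values=1
    )

    # Brute force on the ordered stream, ties to the earlier fix.
    ft = pd.DatetimeIndex(fixes["time"])
    buckets: dict[int, list[float]] = {}
    for t, v in zip(ot, vals):
        d = np.abs((ft - t).total_seconds())
        best = int(np.flatnonzero(d == d.min())[0])
        if d[best] <= 900:
            buckets.setdefault(best, []).append(v)
    for i, row in linked.iterrows():
        idx = int(np.flatnonzero(ft == row["time"])[0])
        vals_i = buckets[idx]
        assert row["n"] == len(vals_i)
        assert row["mean_odba"] == pytest.approx(np.mean(vals_i))
        assert row["max_odba"] == pytest.approx(np.max(vals_i))


def test_disjoint_streams_raise():
    fixes = _fixes(pd.date_range("2020-11-01", periods=5, freq="30min"))
    ot = pd.date_range("2021-05-01", periods=5, freq="2min")
    with pytest.raises(act.EmptyOverlapError):
        act.link_odba(fixes, _odba_frame(ot, np.ones(5)))


# -- resting classification -------------------------------------------------


def _linked_row(values):
    v = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {
            "mean_odba": [v.mean()],
            "sd_odba": [v.std(ddof=1)],
            "max_odba": [v.max()],
        }
    )


def test_resting_rule_on_stated_examples():
    # All values 500: mean + 2 SD = 500 < 2000 and max 500 < 2000 -> resting.
    assert act.classify_resting(_linked_row([500.0] * 15)).iloc[0]
    # mean 1500, SD 300 -> 2100 >= 2000 -> not resting.
    direct = pd.DataFrame(
        {"mean_odba": [1500.0], "sd_odba": [300.0], "max_odba": [1900.0]}
    )
    assert not act.classify_resting(direct).iloc[0]
    # Low mean but one 2500 spike -> fails the max criterion.
    spike = pd.DataFrame(
        {"mean_odba": [800.0], "sd_odba": [100.0], "max_odba": [2500.0]}
    )
    assert not act.classify_resting(spike).iloc[0]
    # Strict inequality: exactly 2000 on either criterion is not resting.
    edge = pd.DataFrame(
        {"mean_odba": [1000.0], "sd_odba": [500.0], "max_odba": [1999.0]}
    )
    assert not act.classify_resting(edge).iloc[0]


def test_classifier_recovers_pure_state_windows(week_config):
    """Pure resting and pure active tracks through the full generator:
    link, classify, and require >= 99% state recovery."""
    accuracy_n = 0
    accuracy_hit = 0
    for weights, resting_truth in (((0.0,) * 24, True), ((1.0,) * 24, False)):
        cfg = fm.SimConfig(
            seed=29, n_animals=1,
            start_date=dt.date(2020, 11, 1), end_date=dt.date(2020, 11, 4),
            diel_weights=weights,
        )
        path = fm.simulate_track(cfg, 0)
        series = fm.series_from_bursts(fm.simulate_acc(path, cfg))
        fixes = fm.sample_gps(path, cfg)
        linked = act.link_odba(fixes, series)
        got = act.classify_resting(linked)
        assert ((linked["n"] >= 13) & (linked["n"] <= 15)).all()
        accuracy_n += len(got)
        accuracy_hit += (got == resting_truth).sum()
    assert accuracy_n > 200
    assert accuracy_hit / accuracy_n >= 0.99


# -- resting sites ----------------------------------------------------------


def _resting_points(xy, t0="2020-11-05"):
    n = len(xy)
    times = pd.date_range(t0, periods=n, freq="30min")
    df = _fixes(times, x=np.asarray(xy)[:, 0], y=np.asarray(xy)[:, 1])
    df["resting"] = True
    return df


def test_site_rule_is_strictly_more_than_twenty():
    point = np.zeros((25, 2))
    assert len(act.resting_sites(_resting_points(point))) == 1
    assert len(act.resting_sites(_resting_points(np.zeros((21, 2))))) == 1
    assert len(act.resting_sites(_resting_points(np.zeros((20, 2))))) == 0


@pytest.mark.parametrize("method", ["lattice", "exhaustive"])
def test_two_distant_clusters_give_two_sites(method):
    rng = np.random.default_rng(4)
    a = rng.normal(0, 5, (30, 2))
    b = rng.normal(1000, 5, (30, 2))
    sites = act.resting_sites(_resting_points(np.vstack((a, b))), method=method)
    assert len(sites) == 2
    assert sorted(sites["n"]) == [30, 30]
    centers = sorted(sites["cx"])
    assert abs(centers[0]) < 30 and abs(centers[1] - 1000) < 30


def test_lattice_scan_matches_exhaustive_on_small_instances():
    rng = np.random.default_rng(12)
    for seed in range(5):
        pts = np.random.default_rng(seed).normal(0, 40, (60, 2))
        df = _resting_points(pts)
        lat = act.resting_sites(df, method="lattice", resolution=1.0)
        exact = act.resting_sites(df, method="exhaustive")
        assert len(lat) == len(exact)
        if len(exact):
            assert sorted(lat["n"]) == pytest.approx(sorted(exact["n"]), abs=1)


def test_cross_month_site_identity():
    a = _resting_points(np.zeros((25, 2)), t0="2020-11-05")
    b = _resting_points(np.full((25, 2), 10.0), t0="2020-12-05")
    c = _resting_points(np.full((25, 2), 500.0), t0="2020-12-06")
    sites = act.match_sites(
        act.resting_sites(pd.concat([a, b, c], ignore_index=True))
    )
    assert len(sites) == 3
    assert sites["site_id"].nunique() == 2  # Nov and Dec squares coincide


# -- forest cover -----------------------------------------------------------


def _raster(pattern, tcd_value=100.0):
    cfg = fm.SimConfig(n_animals=1, home_centers=((250.0, 250.0),))
    return fm.make_landcover(cfg, pattern, extent=(0, 0, 500, 500),
                             tcd_value=tcd_value)


def test_forest_cover_extremes_and_half_plane():
    assert act.forest_cover(250, 250, _raster("uniform")) == 100.0
    assert act.forest_cover(250, 250, _raster("uniform", tcd_value=10.0)) == 0.0
    half = _raster("half")
    assert act.forest_cover(250, 250, half) == pytest.approx(50.0, abs=3.0)
    with pytest.raises(ValueError, match="outside"):
        act.forest_cover(9000, 250, half)


# -- darkness ---------------------------------------------------------------


def test_darkness_indicator():
    lat, lon, tz = 40.7, 23.3, 2.0
    noon = pd.DatetimeIndex([dt.datetime(2020, 12, 15, 12)])
    assert act.darkness(noon, lat, lon, tz)[0] == 0
    one_am = pd.DatetimeIndex([dt.datetime(2020, 12, 15, 1)])
    assert act.darkness(one_am, lat, lon, tz)[0] == 1
    from felimove import solar

    _, sunset, _ = solar.sun_times(dt.date(2020, 12, 15), lat, lon, tz)
    near = pd.DatetimeIndex([sunset + dt.timedelta(minutes=29)])
    past = pd.DatetimeIndex([sunset + dt.timedelta(minutes=31)])
    assert act.darkness(near, lat, lon, tz)[0] == 0
    assert act.darkness(past, lat, lon, tz)[0] == 1
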