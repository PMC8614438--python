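"""Brownian bridge UD, motion variance, contours and MCP."""

import datetime as dt
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull
from scipy.stats import norm

import felimove as fm
from felimove import homerange as hr


def _fix_frame(times, x, y, animal="w"):
    return pd.DataFrame({"animal": animal, "time": times, "x": x, "y": y})


def _regular_fixes(n, spacing_s=1800.0, start="2020-11-01"):
    times = pd.date_range(start, periods=n, freq=f"{int(spacing_s)}s")
    rng = np.random.default_rng(5)
    steps = rng.normal(0, 50, (n, 2))
    xy = np.cumsum(steps, axis=0)
    return _fix_frame(times, xy[:, 0], xy[:, 1])


def _brownian_fixes(sigma2, delta, days, spacing_s=1800.0, seed=0):
    """Pure Brownian track observed with Gaussian location error."""
    rng = np.random.default_rng(seed)
    n = int(days * 86400 / spacing_s)
    truth = np.cumsum(
        rng.normal(0, np.sqrt(sigma2 * spacing_s), (n, 2)), axis=0
    )
    obs = truth + rng.normal(0, delta, (n, 2))
    times = pd.date_range("2020-11-01", periods=n, freq=f"{int(spacing_s)}s")
    return _fix_frame(times, obs[:, 0], obs[:, 1])


# -- prepare_track ----------------------------------------------------------


def test_release_window_and_segment_counts():
    fixes = _regular_fixes(3 * 48)  # 3 days at 30-min spacing
    seg = hr.prepare_track(fixes)
    # 48 fixes dropped in the first 24 h -> 96 retained -> 95 segments.
    assert len(seg) == 95
    # A single 3 h gap breaks the track: two segments lost, none else.
    gappy = fixes.drop(index=[100, 101, 102, 103, 104]).reset_index(drop=True)
    seg2 = hr.prepare_track(gappy)
    assert len(seg2) == 95 - 5 - 1


def test_segments_match_brute_force_pairwise_filter():
    fixes = _regular_fixes(200).drop(index=[60, 61, 62, 120, 121, 150])
    fixes = fixes.reset_index(drop=True)
    seg = hr.prepare_track(fixes, exclude_hours=0.0)
    # Brute force: walk successive pairs, keep lags <= 7200 s.
    t = pd.DatetimeIndex(fixes["time"])
    expect = [
        (fixes["x"][i], fixes["x"][i + 1])
        for i in range(len(fixes) - 1)
        if (t[i + 1] - t[i]).total_seconds() <= 7200
    ]
    assert len(seg) == len(expect)
    assert np.allclose(seg.x0, [e[0] for e in expect])
    assert np.allclose(seg.x1, [e[1] for e in expect])


def test_too_few_fixes_raise():
    fixes = _regular_fixes(50)  # all within the release-day exclusion
    with pytest.raises(hr.InsufficientDataError):
        hr.prepare_track(fixes)


# -- motion variance --------------------------------------------------------


def test_motion_variance_recovered_within_15_percent():
    fixes = _brownian_fixes(sigma2=1.0, delta=20.0, days=30, seed=2)
    seg = hr.prepare_track(fixes)
    est = hr.estimate_motion_variance(seg)
    assert est == pytest.approx(1.0, rel=0.15)


def test_likelihood_optimum_beats_grid_scan():
    fixes = _brownian_fixes(sigma2=2.5, delta=20.0, days=10, seed=3)
    seg = hr.prepare_track(fixes)
    est = hr.estimate_motion_variance(seg)
    ll_est = hr.motion_variance_loglik(seg, est)
    grid = np.geomspace(1e-4, 1e3, 200)
    ll_grid = max(hr.motion_variance_loglik(seg, s2) for s2 in grid)
    assert ll_est >= ll_grid - 1e-6


def test_identical_fixes_drive_variance_to_zero():
    times = pd.date_range("2020-11-01", periods=100, freq="1800s")
    fixes = _fix_frame(times, np.zeros(100), np.zeros(100))
    seg = hr.prepare_track(fixes, exclude_hours=0.0, loc_error=1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = hr.estimate_motion_variance(seg)
    assert est < 1e-4


# -- utilization distribution ----------------------------------------------


def _two_fix_segments(delta=20.0):
    return hr.BridgeSegments(
        x0=np.array([0.0]), y0=np.array([0.0]), t0=np.array([0.0]),
        x1=np.array([400.0]), y1=np.array([100.0]), t1=np.array([1800.0]),
        delta=delta,
    )


def test_two_fix_bridge_matches_dense_quadrature():
    """Implementation (60 s midpoint steps, CDF cells) vs an independent
    dense quadrature at 5 s steps written directly with scipy.stats.norm."""
    seg = _two_fix_segments()
    sigma2 = 5.0
    ud = fm.build_ud(seg, sigma2, cell=50.0, time_step=900.0, sub_steps=15)

    ny, nx = ud.mass.shape
    xe = ud.x0 + np.arange(nx + 1) * ud.cell
    ye = ud.y0 + np.arange(ny + 1) * ud.cell
    T = 1800.0
    n_t = 360
    alpha = (np.arange(n_t) + 0.5) / n_t
    oracle = np.zeros_like(ud.mass)
    for a in alpha:
        mx, my = a * 400.0, a * 100.0
        var = T * a * (1 - a) * sigma2 + ((1 - a) ** 2 + a**2) * 20.0**2
        sd = np.sqrt(var)
        px = np.diff(norm.cdf(xe, loc=mx, scale=sd))
        py = np.diff(norm.cdf(ye, loc=my, scale=sd))
        oracle += np.outer(py, px)
    oracle /= oracle.sum()
    assert np.abs(ud.mass - oracle).max() <= 0.01 * oracle.max()


def test_ud_mass_is_one_on_generated_tracks(week_fixes):
    seg = hr.prepare_track(week_fixes)
    s2 = hr.estimate_motion_variance(seg)
    ud = fm.build_ud(seg, s2)
    assert ud.total_mass == pytest.approx(1.0, abs=1e-6)


def test_degenerate_bridge_concentrates_on_the_chord():
    seg = _two_fix_segments(delta=1.0)
    ud = fm.build_ud(seg, sigma2=1e-9, cell=50.0, sub_steps=15)
    ny, nx = ud.mass.shape
    xc = ud.x0 + (np.arange(nx) + 0.5) * ud.cell
    yc = ud.y0 + (np.arange(ny) + 0.5) * ud.cell
    xx, yy = np.meshgrid(xc, yc)
    # Distance from each cell centre to the chord (0,0)-(400,100).
    ax, ay = 400.0, 100.0
    tpar = np.clip((xx * ax + yy * ay) / (ax**2 + ay**2), 0, 1)
    d = np.hypot(xx - tpar * ax, yy - tpar * ay)
    assert ud.mass[d <= ud.cell].sum() >= 0.99


def test_wider_location_error_widens_the_contour():
    areas = []
    for delta in (10.0, 20.0, 40.0):
        ud = fm.build_ud(_two_fix_segments(delta), sigma2=1e-9, cell=10.0,
                         sub_steps=15)
        areas.append(hr.ud_contour_area(ud, 0.95))
    assert areas[0] < areas[1] < areas[2]


def test_grid_cap_advises_coarser_cells():
    with pytest.raises(ValueError, match="coarser"):
        fm.build_ud(_two_fix_segments(), sigma2=5.0, cell=1.0, max_cells=1000)


# -- contour area -----------------------------------------------------------


def _uniform_ud(n_cells=100, cell=50.0):
    mass = np.full((10, n_cells // 10), 1.0 / n_cells)
    return hr.UtilizationDistribution(x0=0, y0=0, cell=cell, mass=mass, sigma2=1.0)


def test_uniform_contour_area():
    ud = _uniform_ud()
    assert hr.ud_contour_area(ud, 0.95) == pytest.approx(0.2375)
    assert hr.ud_contour_area(ud, 1.0) == pytest.approx(0.25)


def test_contour_area_monotone_in_level(week_fixes):
    seg = hr.prepare_track(week_fixes)
    ud = fm.build_ud(seg, hr.estimate_motion_variance(seg))
    areas = [hr.ud_contour_area(ud, lv) for lv in (0.5, 0.8, 0.95, 1.0)]
    assert areas == sorted(areas)
    with pytest.raises(ValueError):
        hr.ud_contour_area(ud, 0.0)


# -- MCP --------------------------------------------------------------------


def test_square_corners_level_one():
    x = np.array([0.0, 1000.0, 1000.0, 0.0])
    y = np.array([0.0, 0.0, 1000.0, 1000.0])
    assert hr.mcp_area(x, y, 1.0) == pytest.approx(1.0)


def test_far_outlier_is_peeled():
    rng = np.random.default_rng(1)
    x = np.append(rng.uniform(0, 1000, 99), 100_000.0)
    y = np.append(rng.uniform(0, 1000, 99), 0.0)
    assert hr.mcp_area(x, y, 0.95) <= hr.mcp_area(x[:99], y[:99], 1.0)


def test_collinear_fixes_give_zero_area_with_warning():
    x = np.arange(10.0)
    with pytest.warns(UserWarning, match="collinear"):
        assert hr.mcp_area(x, 2 * x, 1.0) == 0.0


def test_mcp_matches_independent_hull_library():
    """Same centroid peel, independent hull: scipy.spatial.ConvexHull."""
    rng = np.random.default_rng(99)
    for _ in range(100):
        n = rng.integers(20, 200)
        x = rng.normal(0, 500, n)
        y = rng.normal(0, 500, n)
        got = hr.mcp_area(x, y, 0.95)
        n_remove = int(np.floor(0.05 * n))
        d2 = (x - x.mean()) ** 2 + (y - y.mean()) ** 2
        keep = np.argsort(d2, kind="stable")[: n - n_remove]
        hull = ConvexHull(np.column_stack((x[keep], y[keep])))
        assert got == pytest.approx(hull.volume / 1e6, rel=1e-9)


# -- seasonal split ---------------------------------------------------------


def test_trimester_boundaries():
    times = pd.to_datetime(
        ["2020-12-31 23:59", "2021-01-01 00:00", "2021-04-01 00:00",
         "2021-08-15 12:00"]
    )
    labels = fm.seasonal_split(times)
    assert list(labels) == ["oct_dec", "jan_mar", "apr_jun", "other"]


def test_partition_is_exhaustive_and_disjoint():
    times = pd.date_range("2020-01-01", "2021-12-31", freq="13h")
    labels = fm.seasonal_split(times)
    assert labels.isin(["oct_dec", "jan_mar", "apr_jun", "other"]).all()
    assert len(labels) == len(times)


# -- integrated sanity ------------------------------------------------------


def test_bb_area_bounded_by_buffered_hull_on_dense_track():
    cfg = fm.SimConfig(seed=21, n_animals=1,
                       start_date=dt.date(2020, 11, 1),
                       end_date=dt.date(2020, 11, 21))
    fixes = fm.sample_gps(fm.simulate_track(cfg, 0), cfg)
    seg = hr.prepare_track(fixes)
    ud = fm.build_ud(seg, hr.estimate_motion_variance(seg))
    bb = hr.ud_contour_area(ud, 0.95)
    from shapely.geometry import MultiPoint

    keep = fixes["time"] >= fixes["time"].iloc[0] + pd.Timedelta(hours=24)
    hull = MultiPoint(
        list(zip(fixes.loc[keep, "x"], fixes.loc[keep, "y"]))
    ).convex_hull
    assert bb <= hull.buffer(ud.cell).area / 1e6


def test_bb_area_stable_across_replicate_simulations():
    areas = []
    for seed in (31, 32, 33):
        cfg = fm.SimConfig(seed=seed, n_animals=1,
                           start_date=dt.date(2020, 11, 1),
                           end_date=dt.date(2020, 12, 1))
        fixes = fm.sample_gps(fm.simulate_track(cfg, 0), cfg)
        seg = hr.prepare_track(fixes)
        ud = fm.build_ud(seg, hr.estimate_motion_variance(seg))
        areas.append(hr.ud_contour_area(ud, 0.95))
    mid = np.mean(areas)
    assert all(abs(a - mid) / mid < 0.15 for a in areas)
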