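"""Linking ODBA to GPS fixes, resting classification, resting sites,
forest cover and darkness covariates.

Each 2-min ODBA value is assigned to its temporally nearest GPS fix
(ties to the earlier fix); per fix only values within +/-15 min are kept
and fixes with fewer than 13 of the at-most-15 possible values are
excluded.  A linked location is *resting* when both (a) mean ODBA +
2 * SD ODBA < 2000 and (b) the maximum 2-min ODBA in the 30-min window
< 2000 (strict inequalities, raw collar units).  Frequently used resting
sites are 30 x 30 m squares holding more than 20 resting locations of
one animal in one month, found by a greedy window scan; sites whose
centres fall within 30 m across months are treated as the same physical
site when assessing seasonal fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import solar
from .odba import OdbaSeries
from .simulate import LandcoverRaster

__all__ = [
    "link_odba",
    "classify_resting",
    "resting_sites",
    "match_sites",
    "forest_cover",
    "darkness",
    "RestingSite",
    "RESTING_THRESHOLD",
]

RESTING_THRESHOLD = 2000.0   # raw collar units
LINK_WINDOW_S = 900.0        # +/-15 min
MIN_LINK_VALUES = 13
MAX_LINK_VALUES = 15
SITE_SIDE_M = 30.0
SITE_MIN_COUNT = 20          # strictly more than this many resting fixes
SITE_MATCH_RADIUS_M = 30.0


class EmptyOverlapError(ValueError):
    """Fix and ODBA streams do not overlap in time."""


def link_odba(
    fixes: pd.DataFrame,
    series: OdbaSeries | pd.DataFrame,
    window_s: float = LINK_WINDOW_S,
    min_values: int = MIN_LINK_VALUES,
    max_values: int = MAX_LINK_VALUES,
) -> pd.DataFrame:
    """Attach windowed ODBA summaries to GPS fixes of one animal.

    Returns one row per retained fix with columns of ``fixes`` plus
    ``n``, ``mean_odba``, ``sd_odba`` (ddof=1), ``max_odba``.  Fixes with
    fewer than ``min_values`` or more than ``max_values`` assigned ODBA
    values are dropped.
    """
    odf = series.to_frame() if isinstance(series, OdbaSeries) else series
    fixes = fixes.sort_values("time").reset_index(drop=True)
    ft = pd.DatetimeIndex(fixes["time"]).asi8
    ot = pd.DatetimeIndex(odf["time"]).asi8
    vals = odf["odba"].to_numpy(dtype=float)
    if len(ft) == 0 or len(ot) == 0 or ot[-1] < ft[0] or ot[0] > ft[-1]:
        raise EmptyOverlapError("no temporal overlap between fixes and ODBA")

    right = np.searchsorted(ft, ot)
    left = np.clip(right - 1, 0, len(ft) - 1)
    right = np.clip(right, 0, len(ft) - 1)
    dl = np.abs(ot - ft[left])
    dr = np.abs(ft[right] - ot)
    nearest = np.where(dl <= dr, left, right)  # tie -> earlier fix
    dist_ns = np.abs(ot - ft[nearest])
    in_window = dist_ns <= window_s * 1e9

    assigned = pd.DataFrame(
        {"fix": nearest[in_window], "odba": vals[in_window]}
    )
    agg = assigned.groupby("fix")["odba"].agg(
        n="size", mean_odba="mean", sd_odba=lambda v: v.std(ddof=1), max_odba="max"
    )
    out = fixes.join(agg, how="inner")
    out = out[(out["n"] >= min_values) & (out["n"] <= max_values)]
    return out.reset_index(drop=True)


def classify_resting(
    linked: pd.DataFrame, threshold: float = RESTING_THRESHOLD
) -> pd.Series:
    """Resting flag per linked location (strict inequalities)."""
    mean_crit = linked["mean_odba"] + 2.0 * linked["sd_odba"] < threshold
    max_crit = linked["max_odba"] < threshold
    return (mean_crit & max_crit).rename("resting")


@dataclass
class RestingSite:
    """A 30 x 30 m footprint holding >20 resting fixes of one animal-month."""

    animal: str
    period: str     # "YYYY-MM"
    cx: float       # footprint centre
    cy: float
    n: int


def _best_square_lattice(
    x: np.ndarray, y: np.ndarray, side: float, resolution: float
) -> tuple[float, float, int]:
    """Best square with origin on a ``resolution``-m lattice (fast path)."""
    k = max(1, int(round(side / resolution)))
    gx0 = np.floor(x.min() / resolution) * resolution - side
    gy0 = np.floor(y.min() / resolution) * resolution - side
    nx = int(np.ceil((x.max() - gx0) / resolution)) + k + 1
    ny = int(np.ceil((y.max() - gy0) / resolution)) + k + 1
    hist = np.zeros((ny, nx), dtype=np.int64)
    ix = ((x - gx0) / resolution).astype(int)
    iy = ((y - gy0) / resolution).astype(int)
    np.add.at(hist, (iy, ix), 1)
    # Sliding k x k window sum via 2-D cumulative sums.
    c = np.zeros((ny + 1, nx + 1), dtype=np.int64)
    c[1:, 1:] = hist.cumsum(0).cumsum(1)
    win = c[k:, k:] - c[:-k, k:] - c[k:, :-k] + c[:-k, :-k]
    j = int(np.argmax(win))
    oy, ox = divmod(j, win.shape[1])
    return gx0 + ox * resolution, gy0 + oy * resolution, int(win[oy, ox])


def _best_square_exhaustive(
    x: np.ndarray, y: np.ndarray, side: float
) -> tuple[float, float, int]:
    """Exact best square: some optimal square touches a point on its left
    and bottom edges, so only point coordinates need be tried as origins."""
    best = (x[0], y[0], 0)
    for xi in np.unique(x):
        in_slab = (x >= xi) & (x <= xi + side)
        ys = y[in_slab]
        for yj in np.unique(ys):
            cnt = int(np.count_nonzero((ys >= yj) & (ys <= yj + side)))
            if cnt > best[2]:
                best = (float(xi), float(yj), cnt)
    return best


def resting_sites(
    linked: pd.DataFrame,
    side: float = SITE_SIDE_M,
    min_count: int = SITE_MIN_COUNT,
    method: str = "lattice",
    resolution: float = 5.0,
) -> pd.DataFrame:
    """Greedy monthly resting-site detection.

    ``linked`` must carry ``animal``, ``time``, ``x``, ``y`` and a boolean
    ``resting`` column.  Within each animal-month, the ``side``-m square
    covering the most unassigned resting fixes is taken repeatedly until
    the best square holds ``min_count`` or fewer (the rule is strictly
    more than ``min_count``).  ``method="lattice"`` anchors candidate
    squares on a ``resolution``-m lattice; ``method="exhaustive"`` scans
    all point-anchored squares (exact, for small inputs and tests).

    Returns a frame with columns animal, period, cx, cy, n.
    """
    rest = linked[linked["resting"]].copy()
    if rest.empty:
        return pd.DataFrame(columns=["animal", "period", "cx", "cy", "n"])
    rest["period"] = pd.DatetimeIndex(rest["time"]).strftime("%Y-%m")
    finder = {
        "lattice": lambda x, y: _best_square_lattice(x, y, side, resolution),
        "exhaustive": lambda x, y: _best_square_exhaustive(x, y, side),
    }.get(method)
    if finder is None:
        raise ValueError(f"unknown resting-site method: {method!r}")

    sites: list[RestingSite] = []
    for (animal, period), grp in rest.groupby(["animal", "period"]):
        x = grp["x"].to_numpy(dtype=float)
        y = grp["y"].to_numpy(dtype=float)
        remaining = np.ones(len(x), dtype=bool)
        while remaining.sum() > min_count:
            ox, oy, cnt = finder(x[remaining], y[remaining])
            if cnt <= min_count:
                break
            inside = (
                remaining
                & (x >= ox) & (x <= ox + side)
                & (y >= oy) & (y <= oy + side)
            )
            sites.append(
                RestingSite(
                    animal=animal,
                    period=period,
                    cx=ox + side / 2,
                    cy=oy + side / 2,
                    n=int(inside.sum()),
                )
            )
            remaining &= ~inside
    return pd.DataFrame([vars(s) for s in sites])


def match_sites(
    sites: pd.DataFrame, radius: float = SITE_MATCH_RADIUS_M
) -> pd.DataFrame:
    """Assign cross-month site identities per animal.

    Sites of the same animal whose centres lie within ``radius`` m (in
    any pair of months, transitively) share a ``site_id``; the number of
    distinct ids per animal is its count of unique physical resting
    sites.  Returns ``sites`` with a ``site_id`` column added.
    """
    sites = sites.reset_index(drop=True).copy()
    sites["site_id"] = -1
    next_id = 0
    for animal, grp in sites.groupby("animal"):
        idx = grp.index.to_numpy()
        cx = grp["cx"].to_numpy()
        cy = grp["cy"].to_numpy()
        parent = np.arange(len(idx))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                if (cx[i] - cx[j]) ** 2 + (cy[i] - cy[j]) ** 2 < radius**2:
                    parent[find(i)] = find(j)
        roots = {}
        for i in range(len(idx)):
            r = find(i)
            if r not in roots:
                roots[r] = next_id
                next_id += 1
            sites.loc[idx[i], "site_id"] = roots[r]
    return sites


def forest_cover(
    x: float,
    y: float,
    raster: LandcoverRaster,
    radius: float = 100.0,
    tcd_cut: float = 20.0,
) -> float:
    """Percent forested cells within ``radius`` m of a location.

    A cell counts as forested when its tree-cover density exceeds
    ``tcd_cut`` percent or it carries the small-woody-feature flag; cells
    are included when their centres lie within the radius.
    """
    if not raster.contains(x, y):
        raise ValueError(f"location ({x:.0f}, {y:.0f}) is outside the raster")
    ny, nx = raster.shape
    c = raster.cell
    i0 = max(0, int((x - raster.x0 - radius) / c) - 1)
    i1 = min(nx, int((x - raster.x0 + radius) / c) + 2)
    j0 = max(0, int((y - raster.y0 - radius) / c) - 1)
    j1 = min(ny, int((y - raster.y0 + radius) / c) + 2)
    xc = raster.x0 + (np.arange(i0, i1) + 0.5) * c
    yc = raster.y0 + (np.arange(j0, j1) + 0.5) * c
    xx, yy = np.meshgrid(xc, yc)
    near = (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
    if not near.any():
        return 0.0
    forested = (raster.tcd[j0:j1, i0:i1] > tcd_cut) | raster.swf[j0:j1, i0:i1]
    return 100.0 * float(forested[near].mean())


def darkness(
    times: pd.Series | pd.DatetimeIndex,
    latitude: float,
    longitude: float = 0.0,
    tz_offset_hours: float = 0.0,
    margin_min: float = 30.0,
) -> np.ndarray:
    """Darkness indicator: 1 from 30 min after sunset up to 30 min before
    sunrise, else 0 (local civil time)."""
    t = pd.DatetimeIndex(times)
    out = np.zeros(len(t), dtype=int)
    margin = pd.Timedelta(minutes=margin_min)
    for date in np.unique(t.normalize()):
        day = pd.Timestamp(date).date()
        sunrise, sunset, _ = solar.sun_times(
            day, latitude, longitude, tz_offset_hours
        )
        sel = t.normalize() == date
        dark = (t[sel] >= pd.Timestamp(sunset) + margin) | (
            t[sel] < pd.Timestamp(sunrise) - margin
        )
        out[np.asarray(sel)] = dark.astype(int)
    return out
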