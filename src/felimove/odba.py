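"""Overall dynamic body acceleration (ODBA) and its time aggregates.

ODBA summarises a tri-axial accelerometer burst as the sum over axes of
the mean absolute dynamic (static-subtracted) acceleration; it is a
standard proxy for energy expenditure.  The static component is, by
default, the whole-burst per-axis mean (a 4-s window); a shorter running
mean can be requested.  Aggregation follows the collar protocol: one
ODBA value per 2-min burst, hourly means over each clock hour, daily
means over 24 h, and nightly means over the fixed 18:30-06:30 window
(the night is attributed to the date it starts on).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "AccBurst",
    "OdbaSeries",
    "DielProfile",
    "MalformedBurstError",
    "odba_from_burst",
    "odba_values",
    "series_from_bursts",
    "hourly_means",
    "hourly_profile",
    "daily_activity",
    "NIGHT_START",
    "NIGHT_END",
]

#: Fixed nighttime window, local clock (18:30 to 06:30 the next morning).
NIGHT_START = dt.time(18, 30)
NIGHT_END = dt.time(6, 30)


class MalformedBurstError(ValueError):
    """Burst does not have the expected sample count."""


class EmptyProfileError(ValueError):
    """No data in the requested profile range."""


@dataclass
class AccBurst:
    """One 4-s burst: 3 axes x ``n`` raw samples starting at ``start``."""

    animal: str
    start: dt.datetime
    samples: np.ndarray  # shape (3, n)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 3:
            raise MalformedBurstError("samples must have shape (3, n)")
        if not np.all(np.isfinite(self.samples)):
            raise MalformedBurstError("samples must be finite")


def _dynamic(samples: np.ndarray, static_window: float | None, hz: float) -> np.ndarray:
    """Static-subtracted acceleration along the last axis."""
    if static_window is None:
        static = samples.mean(axis=-1, keepdims=True)
    else:
        width = int(round(static_window * hz))
        if width < 1:
            raise ValueError("static_window too short for the sampling rate")
        if width >= samples.shape[-1]:
            static = samples.mean(axis=-1, keepdims=True)
        else:
            static = uniform_filter1d(samples, size=width, axis=-1, mode="nearest")
    return samples - static


def odba_from_burst(
    burst: AccBurst,
    static_window: float | None = None,
    expected_samples: int | None = None,
    hz: float = 10.0,
) -> float:
    """ODBA of one burst, raw units (non-negative scalar).

    Per axis the static acceleration is the running mean over
    ``static_window`` seconds (default: the whole-burst mean); ODBA is the
    sum over the three axes of the mean absolute dynamic acceleration.
    """
    if expected_samples is not None and burst.samples.shape[1] != expected_samples:
        raise MalformedBurstError(
            f"expected {expected_samples} samples/axis, got {burst.samples.shape[1]}"
        )
    dyn = _dynamic(burst.samples, static_window, hz)
    return float(np.abs(dyn).mean(axis=-1).sum())


def odba_values(
    samples: np.ndarray, static_window: float | None = None, hz: float = 10.0
) -> np.ndarray:
    """Vectorised ODBA for a (n_bursts, 3, k) sample array."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 3 or samples.shape[1] != 3:
        raise MalformedBurstError("samples must have shape (n, 3, k)")
    dyn = _dynamic(samples, static_window, hz)
    return np.abs(dyn).mean(axis=-1).sum(axis=-1)


@dataclass
class OdbaSeries:
    """Per-burst ODBA values of one animal at 2-min slots, time-sorted."""

    animal: str
    times: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.times)
        self.times = pd.DatetimeIndex(self.times[order])
        self.values = np.asarray(self.values, dtype=float)[order]
        if np.any(self.values < 0):
            raise ValueError("ODBA values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animal, "time": self.times, "odba": self.values}
        )


def series_from_bursts(
    burst_set, static_window: float | None = None
) -> OdbaSeries:
    """Compute the ODBA series of a :class:`~felimove.simulate.BurstSet`."""
    vals = odba_values(burst_set.samples, static_window=static_window)
    return OdbaSeries(animal=burst_set.animal, times=burst_set.times, values=vals)


@dataclass
class DielProfile:
    """Hour-of-day activity profile: 24 mean-ODBA values with SDs and ns.

    Hours with no data carry NaN means and n = 0 -- absent, never
    zero-filled.
    """

    animal: str
    period: str
    means: np.ndarray  # (24,)
    sds: np.ndarray
    ns: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.means, self.sds, self.ns):
            if np.shape(arr) != (24,):
                raise ValueError("diel profile requires exactly 24 entries")

    def peak_hour(self) -> int:
        return int(np.nanargmax(self.means))

    def trough_hour(self) -> int:
        return int(np.nanargmin(self.means))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal,
                "period": self.period,
                "hour": np.arange(24),
                "mean_odba": self.means,
                "sd_odba": self.sds,
                "n": self.ns,
            }
        )


def plot_diel_profiles(profiles: list[DielProfile], path) -> None:
    """Plain line plot of hour-of-day mean ODBA, one line per profile."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    hours = np.arange(24)
    for p in profiles:
        ax.plot(hours, p.means, marker="o", ms=3, label=f"{p.animal} ({p.period})")
    ax.set_xlabel("hour of day")
    ax.set_ylabel("mean ODBA (raw units)")
    ax.set_xticks(range(0, 24, 3))
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def hourly_means(series: OdbaSeries) -> pd.DataFrame:
    """Mean ODBA per (date, clock hour): the arithmetic mean of that
    hour's 2-min values.  Returns columns date, hour, mean_odba, n."""
    df = series.to_frame()
    grouped = df.groupby(
        [df["time"].dt.normalize().rename("date"), df["time"].dt.hour.rename("hour")]
    )["odba"]
    out = grouped.agg(mean_odba="mean", n="size").reset_index()
    out.insert(0, "animal", series.animal)
    return out


def hourly_profile(
    series: OdbaSeries,
    date_range: tuple[dt.date, dt.date] | None = None,
    period: str = "all",
) -> DielProfile:
    """Mean ODBA per clock hour across all days in ``date_range``
    (inclusive start, exclusive end; default: the whole series)."""
    df = series.to_frame()
    if date_range is not None:
        start, end = date_range
        mask = (df["time"] >= pd.Timestamp(start)) & (df["time"] < pd.Timestamp(end))
        df = df[mask]
    if df.empty:
        raise EmptyProfileError("no ODBA values in the requested range")
    g = df.groupby(df["time"].dt.hour)["odba"]
    means = np.full(24, np.nan)
    sds = np.full(24, np.nan)
    ns = np.zeros(24, dtype=int)
    agg = g.agg(["mean", "std", "size"])
    means[agg.index] = agg["mean"]
    sds[agg.index] = agg["std"]
    ns[agg.index] = agg["size"]
    return DielProfile(animal=series.animal, period=period, means=means, sds=sds, ns=ns)


def _night_bins(times: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign 2-min values to night bins.

    The 18:30-06:30 window is binned into the ten full clock hours 19-23
    and 0-5 plus the two half-hour bins 18:30-19:00 (label 18.5) and
    06:00-06:30 (label 6.0) -- 13 bins in total, all weighted equally in
    the nightly mean.  Each value is attributed to the date its night
    started on.  Returns (in_night, night_date, bin_label).
    """
    minutes = times.hour * 60 + times.minute
    evening = minutes >= 18 * 60 + 30
    morning = minutes < 6 * 60 + 30
    in_night = evening | morning
    night_date = times.normalize().to_numpy()
    night_date = np.where(
        morning, night_date - np.timedelta64(1, "D"), night_date
    )
    label = times.hour.to_numpy().astype(float)
    label = np.where((times.hour == 18) & evening, 18.5, label)
    return in_night.to_numpy() if hasattr(in_night, "to_numpy") else in_night, night_date, label


def daily_activity(
    series: OdbaSeries,
    window: str = "h24",
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Daily activity table: one mean-ODBA value per animal-date.

    ``window="h24"`` averages the date's 24 hourly means (equal hour
    weights, so it equals the mean of hourly means on complete days);
    ``window="night"`` averages the 13 equal-weight night bins of the
    18:30-06:30 window, attributed to the date the night starts.  Days
    with fewer than ``min_fraction`` of the expected bins are dropped
    (partial collar days would bias diel-weighted means).
    """
    if window == "h24":
        hm = hourly_means(series)
        g = hm.groupby("date")
        out = g.agg(mean_odba=("mean_odba", "mean"), bins=("hour", "size")).reset_index()
        expected = 24
    elif window == "night":
        df = series.to_frame()
        in_night, night_date, label = _night_bins(pd.DatetimeIndex(df["time"]))
        df = df.loc[in_night].assign(
            date=night_date[in_night], bin=label[in_night]
        )
        if df.empty:
            return pd.DataFrame(columns=["animal", "date", "mean_odba"])
        binmeans = df.groupby(["date", "bin"])["odba"].mean().reset_index()
        g = binmeans.groupby("date")
        out = g.agg(mean_odba=("odba", "mean"), bins=("bin", "size")).reset_index()
        expected = 13
    else:
        raise ValueError("window must be 'h24' or 'night'")
    out = out[out["bins"] >= min_fraction * expected].drop(columns="bins")
    out.insert(0, "animal", series.animal)
    return out.reset_index(drop=True)
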