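"""Readers and writers for the collar-data file dialects.

GPS fixes travel as Movebank-style CSV (``individual-local-identifier``,
``timestamp`` in ISO-8601 UTC, ``utm-easting``, ``utm-northing``);
accelerometer bursts as one row per burst with the raw samples
axis-interleaved (x y z x y z ...) in an ``eobs:accelerations-raw``
column, the dialect e-obs loggers upload to Movebank.  Rasters use the
plain-text ESRI ASCII grid format.  All timestamps are naive local civil
time throughout the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .homerange import UtilizationDistribution
from .odba import OdbaSeries
from .simulate import BurstSet, LandcoverRaster

__all__ = [
    "write_fixes_csv", "read_fixes_csv",
    "write_bursts_csv", "read_bursts_csv",
    "write_odba_csv", "read_odba_csv",
    "write_covariates_csv", "read_covariates_csv",
    "write_ascii_grid", "read_ascii_grid",
    "write_landcover", "read_landcover",
    "write_ud_grid", "polygon_geojson",
]

TIME_FMT = "%Y-%m-%d %H:%M:%S"


def write_fixes_csv(fixes: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "individual-local-identifier": fixes["animal"],
            "timestamp": pd.DatetimeIndex(fixes["time"]).strftime(TIME_FMT),
            "utm-easting": fixes["x"].map(lambda v: f"{v:.3f}"),
            "utm-northing": fixes["y"].map(lambda v: f"{v:.3f}"),
        }
    )
    out.to_csv(path, index=False)


def read_fixes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame(
        {
            "animal": df["individual-local-identifier"],
            "time": pd.to_datetime(df["timestamp"]),
            "x": df["utm-easting"].astype(float),
            "y": df["utm-northing"].astype(float),
        }
    )


def write_bursts_csv(bursts: BurstSet, path: str | Path) -> None:
    """One row per burst; samples rounded to integer counts and
    axis-interleaved, space separated."""
    inter = np.swapaxes(bursts.samples, 1, 2).reshape(len(bursts), -1)
    inter = np.rint(inter).astype(int)
    rows = [" ".join(map(str, r)) for r in inter]
    out = pd.DataFrame(
        {
            "individual-local-identifier": bursts.animal,
            "timestamp": bursts.times.strftime(TIME_FMT),
            "eobs:accelerations-raw": rows,
        }
    )
    out.to_csv(path, index=False)


def read_bursts_csv(path: str | Path) -> list[BurstSet]:
    """Read a burst CSV back into one BurstSet per animal."""
    df = pd.read_csv(path)
    out = []
    for animal, grp in df.groupby("individual-local-identifier", sort=False):
        raw = np.array(
            [np.fromstring(r, sep=" ") for r in grp["eobs:accelerations-raw"]]
        )
        k = raw.shape[1] // 3
        samples = np.swapaxes(raw.reshape(len(grp), k, 3), 1, 2)
        out.append(
            BurstSet(
                animal=str(animal),
                times=pd.DatetimeIndex(pd.to_datetime(grp["timestamp"])),
                samples=samples,
                active=np.zeros(len(grp), dtype=bool),  # unknown from file
            )
        )
    return out


def write_odba_csv(series_list: list[OdbaSeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series_list]).to_csv(
        path, index=False, float_format="%.3f"
    )


def read_odba_csv(path: str | Path) -> list[OdbaSeries]:
    df = pd.read_csv(path, parse_dates=["time"])
    return [
        OdbaSeries(
            animal=str(a),
            times=pd.DatetimeIndex(g["time"]),
            values=g["odba"].to_numpy(dtype=float),
        )
        for a, g in df.groupby("animal", sort=False)
    ]


def write_covariates_csv(env: pd.DataFrame, path: str | Path) -> None:
    out = env.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.4f")


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_ascii_grid(
    grid: np.ndarray, x0: float, y0: float, cell: float, path: str | Path
) -> None:
    """ESRI ASCII grid (row 0 of the file is the northernmost row)."""
    ny, nx = grid.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {x0:.3f}\nyllcorner {y0:.3f}\n"
        f"cellsize {cell:.3f}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid[::-1], fmt="%.4g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)[::-1]
    return grid, head["xllcorner"], head["yllcorner"], head["cellsize"]


def write_landcover(raster: LandcoverRaster, prefix: str | Path) -> None:
    """Write TCD and SWF as two sibling ASCII grids (<prefix>_tcd.asc /
    <prefix>_swf.asc)."""
    prefix = Path(prefix)
    write_ascii_grid(raster.tcd, raster.x0, raster.y0, raster.cell,
                     prefix.with_name(prefix.name + "_tcd.asc"))
    write_ascii_grid(raster.swf.astype(int), raster.x0, raster.y0, raster.cell,
                     prefix.with_name(prefix.name + "_swf.asc"))


def read_landcover(prefix: str | Path) -> LandcoverRaster:
    prefix = Path(prefix)
    tcd, x0, y0, cell = read_ascii_grid(prefix.with_name(prefix.name + "_tcd.asc"))
    swf, *_ = read_ascii_grid(prefix.with_name(prefix.name + "_swf.asc"))
    return LandcoverRaster(x0=x0, y0=y0, cell=cell, tcd=tcd, swf=swf > 0.5)


def write_ud_grid(ud: UtilizationDistribution, path: str | Path) -> None:
    write_ascii_grid(ud.mass, ud.x0, ud.y0, ud.cell, path)


def polygon_geojson(coords: list[tuple[float, float]], path: str | Path,
                    properties: dict | None = None) -> None:
    """Write one polygon (planar coordinates) as a GeoJSON feature."""
    ring = [list(c) for c in coords]
    if ring and ring[0] != ring[-1]:
        ring.append(ring[0])
    feature = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": properties or {},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        ],
    }
    Path(path).write_text(json.dumps(feature))
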