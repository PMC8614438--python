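"""End-to-end pipeline: simulate -> ODBA -> home range -> activity models.

``run_pipeline`` executes every stage on one synthetic collaring
campaign, writes tidy CSV artefacts (fix/burst-dialect inputs, hourly
and daily activity, per-period home ranges, resting sites, model
coefficient tables) and returns a :class:`StudySummary`.  Identical seed
and configuration give byte-identical outputs.  ``descriptive_stats``
recomputes campaign-level summary numbers (trapping rates, logging
effort, home-range means) from a tracking-effort table.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity, homerange, io, mixedmodels, odba, simulate

__all__ = ["PipelineConfig", "StudySummary", "run_pipeline", "descriptive_stats"]

log = logging.getLogger("felimove")

ENV_CANDIDATES = ["tmin", "tmax", "tmean", "precip", "wind", "day_length", "moon_phase"]


@dataclass
class PipelineConfig:
    """All stage parameters with the field protocol's defaults.

    Home range: 50 m UD cells, 15 min bridge time step, 120 min maximum
    lag, 20 m location error, 95% contour, first 24 h after release
    excluded.  Activity: 2000-count resting threshold, +/-15 min linking
    window with 13-15 values per retained fix, 30 m / >20-fix resting
    sites, 100 m forest radius with a 20% TCD cut, 18:30-06:30 night.
    """

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    cell: float = 50.0
    time_step: float = 900.0
    max_lag: float = 7200.0
    loc_error: float = 20.0
    contour_level: float = 0.95
    exclude_hours: float = 24.0
    resting_threshold: float = 2000.0
    link_window_s: float = 900.0
    min_link_values: int = 13
    site_side: float = 30.0
    site_min_count: int = 20
    forest_radius: float = 100.0
    tcd_cut: float = 20.0
    landcover_pattern: str = "patches"

    def __post_init__(self) -> None:
        for name in (
            "cell", "time_step", "max_lag", "loc_error", "contour_level",
            "resting_threshold", "link_window_s", "site_side", "forest_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["start_date"] = self.sim.start_date.isoformat()
        d["sim"]["end_date"] = self.sim.end_date.isoformat()
        d["sim"]["home_centers"] = [list(c) for c in self.sim.home_centers]
        d["sim"]["diel_weights"] = list(self.sim.diel_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        for key in ("start_date", "end_date"):
            if key in sim and isinstance(sim[key], str):
                sim[key] = dt.date.fromisoformat(sim[key])
        if "home_centers" in sim and sim["home_centers"] is not None:
            sim["home_centers"] = tuple(tuple(c) for c in sim["home_centers"])
        if "diel_weights" in sim:
            sim["diel_weights"] = tuple(sim["diel_weights"])
        return cls(sim=simulate.SimConfig(**sim), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StudySummary:
    """Every table the pipeline produces, recomputed from raw outputs."""

    per_animal: pd.DataFrame        # fixes/bursts/days per animal
    home_ranges: pd.DataFrame       # animal x period x estimator areas
    diel_profiles: pd.DataFrame
    daily_activity: pd.DataFrame
    resting_sites: pd.DataFrame
    site_counts: pd.DataFrame       # per animal: unique sites + monthly counts
    model_tables: dict[str, pd.DataFrame]
    r2: dict[str, float]
    sigma2: dict[str, float]        # fitted motion variance per animal


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> StudySummary:
    """Run all stages and write artefacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> StudySummary:
    sim = config.sim
    log.info("resolved config: %s", config.to_dict())

    _stage("simulate")
    env = simulate.simulate_environment(sim)
    mult = simulate.activity_multipliers(env)
    raster = simulate.make_landcover(sim, config.landcover_pattern)
    paths, fix_tables, odba_series = [], [], []
    for a in range(sim.n_animals):
        path = simulate.simulate_track(sim, a)
        bursts = simulate.simulate_acc(path, sim, daily_multiplier=mult)
        series = odba.series_from_bursts(bursts)
        fixes = simulate.sample_gps(
            path, sim,
            burst_odba=pd.Series(series.values, index=series.times)
            if sim.adaptive_fix_rule else None,
        )
        paths.append(path)
        fix_tables.append(fixes)
        odba_series.append(series)
    all_fixes = pd.concat(fix_tables, ignore_index=True)
    io.write_fixes_csv(all_fixes, outdir / "fixes.csv")
    io.write_odba_csv(odba_series, outdir / "odba.csv")
    io.write_covariates_csv(env, outdir / "covariates.csv")
    io.write_landcover(raster, outdir / "landcover")

    _stage("odba aggregates")
    profiles = pd.concat(
        [odba.hourly_profile(s).to_frame() for s in odba_series],
        ignore_index=True,
    )
    daily = pd.concat(
        [
            odba.daily_activity(s, "h24").assign(window="h24")
            for s in odba_series
        ]
        + [
            odba.daily_activity(s, "night").assign(window="night")
            for s in odba_series
        ],
        ignore_index=True,
    )
    profiles.to_csv(outdir / "diel_profiles.csv", index=False, float_format="%.3f")
    odba.plot_diel_profiles(
        [odba.hourly_profile(s) for s in odba_series],
        outdir / "diel_profiles.png",
    )
    daily.to_csv(outdir / "daily_activity.csv", index=False, float_format="%.3f")

    _stage("home range")
    hr_rows, sigma2 = [], {}
    for fixes in fix_tables:
        animal = fixes["animal"].iloc[0]
        segments = homerange.prepare_track(
            fixes, exclude_hours=config.exclude_hours,
            max_lag=config.max_lag, loc_error=config.loc_error,
        )
        s2 = homerange.estimate_motion_variance(segments)
        sigma2[animal] = s2
        season = homerange.seasonal_split(fixes["time"])
        subsets = {"total": fixes}
        for label in season.unique():
            subsets[label] = fixes[np.asarray(season == label)]
        for label, sub in subsets.items():
            if len(sub) < 5:
                continue
            try:
                seg = homerange.prepare_track(
                    sub, release_time=fixes["time"].iloc[0],
                    exclude_hours=config.exclude_hours,
                    max_lag=config.max_lag, loc_error=config.loc_error,
                )
                ud = homerange.build_ud(
                    seg, s2, cell=config.cell, time_step=config.time_step
                )
                bb = homerange.ud_contour_area(ud, config.contour_level)
            except homerange.InsufficientDataError:
                continue
            mcp = homerange.mcp_area(
                sub["x"].to_numpy(), sub["y"].to_numpy(), config.contour_level
            )
            hr_rows.append({"animal": animal, "period": label, "estimator": "BB",
                            "area_km2": bb})
            hr_rows.append({"animal": animal, "period": label, "estimator": "MCP",
                            "area_km2": mcp})
    home_ranges = pd.DataFrame(hr_rows)
    home_ranges.to_csv(outdir / "home_ranges.csv", index=False, float_format="%.4f")

    _stage("resting sites")
    linked_tables = []
    for fixes, series in zip(fix_tables, odba_series):
        linked = activity.link_odba(
            fixes, series, window_s=config.link_window_s,
            min_values=config.min_link_values,
        )
        linked["resting"] = activity.classify_resting(
            linked, config.resting_threshold
        )
        linked["forest_cover"] = [
            activity.forest_cover(x, y, raster, config.forest_radius, config.tcd_cut)
            if raster.contains(x, y) else np.nan
            for x, y in zip(linked["x"], linked["y"])
        ]
        linked["darkness"] = activity.darkness(
            linked["time"], sim.latitude, sim.longitude, sim.tz_offset_hours
        )
        linked_tables.append(linked)
    all_linked = pd.concat(linked_tables, ignore_index=True)
    sites = activity.resting_sites(
        all_linked, side=config.site_side, min_count=config.site_min_count
    )
    if len(sites):
        sites = activity.match_sites(sites)
        monthly = (
            sites.groupby(["animal", "period"]).size().unstack(fill_value=0)
        )
        unique = sites.groupby("animal")["site_id"].nunique().rename("unique_sites")
        site_counts = pd.concat([unique, monthly], axis=1).reset_index()
    else:
        site_counts = pd.DataFrame(columns=["animal", "unique_sites"])
    sites.to_csv(outdir / "resting_sites.csv", index=False, float_format="%.2f")
    site_counts.to_csv(outdir / "site_counts.csv", index=False)

    _stage("environmental models")
    model_tables: dict[str, pd.DataFrame] = {}
    r2: dict[str, float] = {}
    env_keyed = env.set_index(pd.DatetimeIndex(env["date"]))
    for window in ("h24", "night"):
        resp = daily[daily["window"] == window].copy()
        table = resp.merge(env, left_on="date", right_on="date", how="inner")
        if table["animal"].nunique() >= 2 and len(table) >= 30:
            sel = mixedmodels.select_and_average(
                table, "mean_odba",
                [c for c in ENV_CANDIDATES if c in table.columns],
            )
            model_tables[window] = sel.coefficients.reset_index()
            r2[window] = sel.r2_global
            sel.coefficients.to_csv(
                outdir / f"model_{window}.csv", float_format="%.4f"
            )

    usable = all_linked.dropna(subset=["forest_cover"])
    if usable["animal"].nunique() >= 2 and (~usable["resting"]).sum() >= 30:
        loc_model, inestimable = mixedmodels.location_activity_model(usable)
        coef = pd.DataFrame(
            {"estimate": loc_model.params, "se": loc_model.bse}
        ).reset_index(names="term")
        model_tables["location"] = coef
        r2["location"] = loc_model.r2
        coef.to_csv(outdir / "model_location.csv", index=False, float_format="%.4f")

    _stage("summary")
    per_animal = pd.DataFrame(
        {
            "animal": [p.animal for p in paths],
            "days_tracked": [sim.n_days] * len(paths),
            "gps_fixes": [len(f) for f in fix_tables],
            "acc_logs": [len(s.values) for s in odba_series],
        }
    )
    per_animal["daily_logs"] = per_animal["acc_logs"] / per_animal["days_tracked"]
    per_animal.to_csv(outdir / "per_animal.csv", index=False, float_format="%.2f")

    return StudySummary(
        per_animal=per_animal,
        home_ranges=home_ranges,
        diel_profiles=profiles,
        daily_activity=daily,
        resting_sites=sites,
        site_counts=site_counts,
        model_tables=model_tables,
        r2=r2,
        sigma2=sigma2,
    )


def descriptive_stats(
    collar_table: pd.DataFrame,
    trap_nights: int | None = None,
    captures: int | None = None,
    collar_mass_g: float | None = None,
    possible_daily_logs: int = 720,
) -> dict[str, float]:
    """Campaign descriptive statistics from a tracking-effort table.

    ``collar_table`` needs columns ``days_tracked`` and ``gps_fixes``,
    optionally ``acc_logs`` and ``weight_kg``.  Dispersion uses the
    population SD (ddof=0).  Trapping rates require ``trap_nights`` and
    ``captures``; zero trap-nights is an error.
    """
    if collar_table.empty:
        raise ValueError("empty collar table")
    out: dict[str, float] = {}
    days = collar_table["days_tracked"].astype(float)
    fixes = collar_table["gps_fixes"].astype(float)
    out["n_collared"] = float(len(collar_table))
    out["mean_days_tracked"] = float(days.mean())
    out["sd_days_tracked"] = float(days.std(ddof=0))
    out["mean_gps_fixes"] = float(fixes.mean())
    out["sd_gps_fixes"] = float(fixes.std(ddof=0))

    if "acc_logs" in collar_table:
        acc = collar_table.dropna(subset=["acc_logs"])
        logs = acc["acc_logs"].astype(float)
        daily = logs / acc["days_tracked"].astype(float)
        out["total_acc_logs"] = float(logs.sum())
        out["mean_daily_acc_logs"] = float(daily.mean())
        out["sd_daily_acc_logs"] = float(daily.std(ddof=0))
        pct = 100.0 * daily / possible_daily_logs
        out["min_pct_of_possible_logs"] = float(pct.min())
        out["max_pct_of_possible_logs"] = float(pct.max())

    if trap_nights is not None and captures is not None:
        if trap_nights <= 0:
            raise ValueError("trap_nights must be positive")
        out["trapping_rate_per_100_trap_nights"] = 100.0 * captures / trap_nights
        out["trap_nights_per_capture"] = (
            trap_nights / captures if captures else 0.0
        )

    if collar_mass_g is not None and "weight_kg" in collar_table:
        pct = 100.0 * collar_mass_g / 1000.0 / collar_table["weight_kg"]
        out["max_collar_mass_pct"] = float(pct.max())
    return out
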