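"""End-to-end orchestration of the green-wave / annual-cycle analysis.

``run_all`` drives the full chain on coupled synthetic data: simulate a
latitude-graded climate and compute spring onset (GDD jerk) per station;
simulate multi-study seasonal biomass whose green-up is calibrated to the
climate's onset gradient and fit the green-wave stage model; script and
render geolocator tracks whose nests sit at a common true biomass stage;
detect annual-cycle events from the raw series; estimate site marginal
means; and assemble the indicator tables (nest date vs onset date vs
target-stage date per site, and the indicator-vs-indicator comparison
with a cutpoint scan across the latitude grid).

All randomness flows from a single config seed through spawned
``numpy.random.SeedSequence`` streams, so a config run is deterministic:
the same config and seed produce byte-identical result tables.  Every
output directory carries a manifest (config hash, seeds, package version,
timestamp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import degree_days as dd
from . import geolocator as geo
from . import greenwave as gw
from . import synthetic as syn
from . import timing as tm

logger = logging.getLogger(__name__)

CANONICAL_EVENTS = ("fall_departure", "winter_arrival", "spring_departure",
                    "breeding_arrival", "nest_initiation")

DURATION_FIELDS = ("spring_migration_days", "pre_nesting_days", "nesting_period_days",
                   "fall_migration_days", "wintering_days")


@dataclass
class SiteConfig:
    name: str
    latitude: float
    longitude: float
    n_individuals: int
    n_repeat: int = 0  # individuals tracked a second year


@dataclass
class RunConfig:
    """Configuration for a full synthetic-study run."""

    seed: int = 1
    sites: tuple = (
        SiteConfig("NJ", 39.2, -75.24, 21, 4),
        SiteConfig("MA_south", 41.38, -70.01, 6, 5),
        SiteConfig("MA_north_ME", 43.03, -70.56, 7, 2),
    )
    latitude_grid: tuple = tuple(np.round(np.linspace(32.0, 44.0, 30), 3))
    # climatological normals (noise-free seasonal cycle): the finite-difference
    # jerk statistic requires smooth multi-year mean curves, and a wide moving
    # average merges the two curvature bumps of the single-sine GDD response
    climate: syn.ClimateParams = field(default_factory=lambda: syn.ClimateParams(noise_sd=0.0, years=1))
    biomass: syn.BiomassParams = field(default_factory=syn.BiomassParams)
    gdd: dd.GDDConfig = field(default_factory=lambda: dd.GDDConfig(smoothing_halfwidth=25))
    target_stage: float = 0.295
    nest_sd_days: float = 1.5
    individual_sd_days: float = 2.0
    sampling_interval_min: int = 10
    min_dry_hours: float = 20.0
    light_threshold: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "sites" in raw:
            kwargs["sites"] = tuple(SiteConfig(**s) for s in raw.pop("sites"))
        if "climate" in raw:
            kwargs["climate"] = syn.ClimateParams(**raw.pop("climate"))
        if "biomass" in raw:
            kwargs["biomass"] = syn.BiomassParams(**raw.pop("biomass"))
        if "gdd" in raw:
            kwargs["gdd"] = dd.GDDConfig(**{k: tuple(v) if isinstance(v, list) else v
                                            for k, v in raw.pop("gdd").items()})
        if "latitude_grid" in raw:
            kwargs["latitude_grid"] = tuple(raw.pop("latitude_grid"))
        kwargs.update(raw)
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return conv(self)


def _onset_for_latitude(latitude: float, climate: syn.ClimateParams, gdd: dd.GDDConfig,
                        seed: int) -> int:
    params = dataclasses.replace(climate, seed=seed)
    records = syn.gen_climate(params, latitude)
    return dd.onset_for_station(records, gdd, latitude=latitude).doy


def compute_onset_table(latitudes, climate: syn.ClimateParams, gdd: dd.GDDConfig,
                        seed_seq: np.random.SeedSequence) -> pd.DataFrame:
    """Spring-onset day per station latitude from simulated climate records."""
    seeds = seed_seq.generate_state(len(latitudes))
    rows = [{"latitude": float(lat), "onset_doy": _onset_for_latitude(float(lat), climate, gdd, int(s) % (2 ** 31))}
            for lat, s in zip(latitudes, seeds)]
    return pd.DataFrame(rows)


def couple_biomass_to_onset(biomass: syn.BiomassParams, site_onsets: pd.DataFrame,
                            target_stage: float) -> tuple:
    """Calibrate biomass midpoints so the true stage hits ``target_stage`` on the onset line.

    A line onset ~ latitude is fitted through the per-site onset days; the
    logistic midpoints are then positioned so the true stage curve reaches
    the target stage exactly on that line.  Returns ``(params, slope,
    intercept)``; the common-stage nest date at latitude L is
    ``intercept + slope * L``.
    """
    lat = site_onsets["latitude"].to_numpy(float)
    onset = site_onsets["onset_doy"].to_numpy(float)
    slope, intercept = np.polyfit(lat, onset, 1)
    mid_ref = (intercept + slope * biomass.ref_latitude) - biomass.stage_date_offset(target_stage)
    params = dataclasses.replace(biomass, logistic_midpoint_at_ref=float(mid_ref),
                                 midpoint_lat_shift=float(slope))
    return params, float(slope), float(intercept)


def _script_events(nest: int, rng: np.random.Generator) -> dict:
    """Draw an individual's annual-cycle event dates around its nest date."""
    pre_nest = int(round(rng.normal(20.0, 2.0)))
    migration = int(round(rng.normal(13.0, 1.5)))
    nesting = int(round(rng.normal(65.0, 3.0)))
    fall_migr = int(round(rng.normal(23.0, 2.0)))
    arrival = nest - max(pre_nest, 8)
    return {
        "spring_departure": arrival - max(migration, 6),
        "breeding_arrival": arrival,
        "nest_initiation": nest,
        "fall_departure": nest + max(nesting, 30),
        "winter_arrival": nest + max(nesting, 30) + max(fall_migr, 6),
    }


def simulate_site_tracks(site: SiteConfig, nest_mean: float, config: RunConfig,
                         seed_seq: np.random.SeedSequence):
    """Scripts (with truth) for a site's individuals, including repeat-tracked years."""
    rng = np.random.default_rng(seed_seq)
    scripts = []
    for i in range(site.n_individuals):
        indiv = f"{site.name}_{i:02d}"
        effect = rng.normal(0.0, config.individual_sd_days)
        years = 2 if i < site.n_repeat else 1
        for yr in range(years):
            nest = int(round(nest_mean + effect + rng.normal(0.0, config.nest_sd_days)))
            ev = _script_events(nest, rng)
            scripts.append((indiv, yr + 1, syn.make_annual_script(
                indiv, site.latitude, site.longitude, seed=int(rng.integers(2 ** 31)),
                sampling_interval_min=config.sampling_interval_min, **ev)))
    return scripts


def detect_events_for_scripts(scripts, config: RunConfig) -> pd.DataFrame:
    """Render each script and run the full detection chain; one row per track-year."""
    rows = []
    for indiv, year_no, script in scripts:
        light, cond, truth = syn.gen_geolocator_track(script)
        ev = geo.analyze_track(light, cond, script.site_latitude, script.site_longitude,
                               individual_id=indiv, site="", light_threshold=config.light_threshold,
                               min_dry_hours=config.min_dry_hours)
        row = ev.to_dict()
        row["year"] = year_no
        row["latitude"] = script.site_latitude
        row.update({f"true_{k}": v for k, v in truth.items() if k != "individual_id"
                    and k != "flight_hours"})
        rows.append(row)
    return pd.DataFrame(rows)


def marginal_mean_tables(events: pd.DataFrame) -> tuple:
    """Timing and duration marginal-mean tables (per event x site) from detected events."""
    timing_rows, duration_rows = [], []
    for name, fields in (("timing", CANONICAL_EVENTS), ("duration", DURATION_FIELDS)):
        for ev_name in fields:
            sub = events[["individual_id", "site", ev_name]].dropna().rename(columns={ev_name: "doy"})
            if sub.empty or sub["site"].nunique() < 2:
                continue
            est, _vc = tm.fit_random_intercept(sub)
            est.insert(0, "event", ev_name)
            (timing_rows if name == "timing" else duration_rows).append(est)
    timing_table = pd.concat(timing_rows, ignore_index=True) if timing_rows else pd.DataFrame()
    duration_table = pd.concat(duration_rows, ignore_index=True) if duration_rows else pd.DataFrame()
    return timing_table, duration_table


def rising_limb(standardized: pd.DataFrame) -> pd.DataFrame:
    """Green-up subset: each study's observations up to its seasonal stage peak."""
    keep = []
    for _sid, g in standardized.groupby("study_id"):
        peak_doy = g.loc[g["stage"].idxmax(), "doy"]
        keep.append(g[g["doy"] <= peak_doy])
    return pd.concat(keep, ignore_index=True)


def timing_difference_summary(table) -> dict:
    """Average cross-site timing offset from a timing marginal-mean table.

    Accepts a path or DataFrame, either long (``site, event, mean_doy``
    with optional ``latitude``) or wide (``event`` column plus one column
    per site, southernmost first).  For each of the five canonical annual
    cycle events, the difference between each northern site's mean and the
    southernmost site's mean is computed; the mean of those offsets is the
    headline "shifted later by N days" figure.
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table)
    df = table.copy()
    if {"site", "event"}.issubset(df.columns):
        value_col = "mean_doy" if "mean_doy" in df.columns else "marginal_mean"
        if "latitude" in df.columns:
            site_order = (df.groupby("site")["latitude"].mean().sort_values().index.tolist())
        else:
            site_order = list(pd.unique(df["site"]))
        wide = df.pivot_table(index="event", columns="site", values=value_col)[site_order]
    else:
        wide = df.set_index("event")
    missing = [e for e in CANONICAL_EVENTS if e not in wide.index]
    if missing:
        raise ValueError(f"missing stage rows: {missing}")
    wide = wide.loc[list(CANONICAL_EVENTS)]
    south = wide.columns[0]
    offsets = wide.drop(columns=[south]).sub(wide[south], axis=0)
    return {
        "mean_offset_days": float(offsets.to_numpy().mean()),
        "southern_site": str(south),
        "per_event": {e: {str(c): float(offsets.loc[e, c]) for c in offsets.columns}
                      for e in offsets.index},
    }


def load_reference_timing() -> pd.DataFrame:
    """Published marginal-mean timing of eastern willet annual-cycle events.

    Geolocator-derived marginal means (day-of-year +- SE) at three Atlantic
    coast breeding site groups (New Jersey; southern Massachusetts;
    northern Massachusetts and Maine), with all-individuals winter-arrival
    values.  Shipped as package reference data.
    """
    path = Path(__file__).parent / "data" / "willet_annual_cycle_means.csv"
    return pd.read_csv(path)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage, original):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage


def run_all(config: RunConfig, output_dir=None) -> dict:
    """Run the full coupled synthetic study; returns the results bundle.

    Produces (i) the per-site event-timing and duration tables, (ii) the
    per-station spring-onset table, (iii) the fitted green-wave model,
    (iv) the per-site indicator table (nest date vs onset date vs
    target-stage date), (v) the grid-wide indicator-vs-indicator
    comparison with a cutpoint scan, and (vi) a manifest.  If
    ``output_dir`` is given, all tables are written there as CSV/JSON.
    """
    root = np.random.SeedSequence(config.seed)
    seq_climate, seq_biomass, seq_tracks, seq_cut = root.spawn(4)
    results: dict = {}
    stage = "climate/onset"
    try:
        site_lats = [s.latitude for s in config.sites]
        grid = list(config.latitude_grid)
        onset_grid = compute_onset_table(grid, config.climate, config.gdd, seq_climate)
        site_onsets = compute_onset_table(site_lats, config.climate, config.gdd,
                                          np.random.SeedSequence(config.seed + 1))
        site_onsets["site"] = [s.name for s in config.sites]
        results["onsets_grid"] = onset_grid
        results["onsets_sites"] = site_onsets

        stage = "coupling"
        biomass_params, onset_slope, onset_icept = couple_biomass_to_onset(
            dataclasses.replace(config.biomass, seed=int(seq_biomass.generate_state(1)[0] % (2 ** 31))),
            site_onsets, config.target_stage)
        nest_means = {s.name: onset_icept + onset_slope * s.latitude for s in config.sites}

        stage = "biomass/greenwave"
        biomass_obs = syn.gen_biomass_studies(biomass_params)
        standardized = gw.standardize_biomass(biomass_obs)
        # fit the green-up (rising-limb) window under working independence:
        # the linear surface approximates a sigmoid, and a moment-estimated
        # AR(1) would absorb that systematic misfit (rho ~ 0.8) and
        # destabilize the calibration; independence + sandwich SEs is the
        # defensive GEE choice under mean-model approximation
        model = gw.fit_greenwave(rising_limb(standardized), working="independence")
        results["biomass_observations"] = biomass_obs
        results["standardized"] = standardized
        results["greenwave_model"] = model

        stage = "tracks/events"
        scripts = []
        for site, sub_seq in zip(config.sites, seq_tracks.spawn(len(config.sites))):
            scripts.extend(simulate_site_tracks(site, nest_means[site.name], config, sub_seq))
        events = detect_events_for_scripts(scripts, config)
        events["site"] = [indiv.rsplit("_", 1)[0] for indiv in events["individual_id"]]
        results["events"] = events

        stage = "timing"
        timing_table, duration_table = marginal_mean_tables(events)
        lat_of = {s.name: s.latitude for s in config.sites}
        timing_table["latitude"] = timing_table["site"].map(lat_of)
        results["timing_table"] = timing_table
        results["duration_table"] = duration_table
        offsets = timing_difference_summary(
            timing_table.rename(columns={"marginal_mean": "mean_doy"}))
        results["timing_offsets"] = offsets

        stage = "stage_at_events"
        nest_events = events[["individual_id", "site", "latitude", "nest_initiation"]].rename(
            columns={"nest_initiation": "nest_doy"})
        per_indiv, per_site_stage, stage_test = gw.stage_at_events(model, nest_events)
        target_recomputed = float(per_indiv["predicted_stage"].mean())
        results["stage_per_individual"] = per_indiv
        results["stage_per_site"] = per_site_stage
        results["stage_test"] = stage_test
        results["target_stage_recomputed"] = target_recomputed

        stage = "fig3"
        nest_mm = timing_table[timing_table["event"] == "nest_initiation"].set_index("site")
        fig3 = pd.DataFrame({
            "site": [s.name for s in config.sites],
            "latitude": site_lats,
            "nest_marginal_mean": [float(nest_mm.loc[s.name, "marginal_mean"]) for s in config.sites],
            "onset_doy": site_onsets["onset_doy"].to_numpy(float),
            "stage_date_doy": [gw.stage_date(model, target_recomputed, s.latitude)
                               for s in config.sites],
        })
        results["fig3"] = fig3

        stage = "fig4"
        fig4 = onset_grid.copy()
        fig4["stage_date_doy"] = [gw.stage_date(model, target_recomputed, la)
                                  for la in fig4["latitude"]]
        fig4["deviation_days"] = fig4["onset_doy"] - fig4["stage_date_doy"]
        from scipy import stats as _st
        reg = _st.linregress(fig4["stage_date_doy"], fig4["onset_doy"])
        cut = tm.maxstat_cutpoint(fig4["latitude"].to_numpy(), fig4["deviation_days"].to_numpy(),
                                  n_perm=2000, seed=int(seq_cut.generate_state(1)[0] % (2 ** 31)))
        results["fig4"] = fig4
        results["indicator_regression"] = {"slope": float(reg.slope), "intercept": float(reg.intercept),
                                           "r2": float(reg.rvalue ** 2), "p": float(reg.pvalue),
                                           "n": len(fig4)}
        results["cutpoint"] = cut
    except Exception as exc:  # noqa: BLE001 - abort with the stage name
        if output_dir is not None:
            _write_outputs(results, config, output_dir)
        raise StageError(stage, exc) from exc

    if output_dir is not None:
        _write_outputs(results, config, output_dir)
    return results


def _write_outputs(results: dict, config: RunConfig, output_dir):
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "onsets_grid": "onsets_grid.csv", "onsets_sites": "onsets_sites.csv",
        "biomass_observations": "biomass_observations.csv",
        "standardized": "biomass_standardized.csv", "events": "events.csv",
        "timing_table": "timing_marginal_means.csv",
        "duration_table": "duration_marginal_means.csv",
        "stage_per_individual": "stage_at_nest.csv", "stage_per_site": "stage_by_site.csv",
        "fig3": "site_indicators.csv", "fig4": "grid_indicators.csv",
    }
    for key, fname in tables.items():
        if key in results and isinstance(results[key], pd.DataFrame):
            results[key].to_csv(out / fname, index=False)
    if "greenwave_model" in results:
        (out / "greenwave_model.json").write_text(json.dumps(results["greenwave_model"].to_dict(), indent=2))
        results["greenwave_model"].table().to_csv(out / "greenwave_table.csv", index=False)
    summary = {}
    for key in ("timing_offsets", "stage_test", "target_stage_recomputed", "indicator_regression"):
        if key in results:
            summary[key] = results[key]
    if "cutpoint" in results:
        summary["cutpoint"] = dataclasses.asdict(results["cutpoint"])
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    cfg = config.to_jsonable()
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "package_version": _version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _version() -> str:
    from . import __version__

    return __version__
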