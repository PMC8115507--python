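"""End-to-end pipeline: simulate scenarios, calibrate, map habitats, compare.

One :class:`PipelineConfig` (a YAML-serializable parameter tree) drives the
whole chain: synthetic domain and forcing -> baseline and irrigation
saturation/flow cubes -> optional threshold calibration against a synthetic
survey -> wetness-index cubes -> stream masks -> exceedance maps per
(T, period, scenario) -> coverage series, monthly means and t-tests ->
stability maps -> summary table -> manifest with file checksums.

All randomness derives from one root seed, expanded deterministically per
stage, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .bucket import BucketParams, run_bucket_model
from .calibration import calibrate_theta, filter_survey
from .domain import make_domain
from .forcing import IrrigationSchedule, make_forcing
from .metrics import (SeasonDefinition, classify_stability, coverage_series,
                      exceedance_probability, monthly_mean_coverage,
                      stream_mask)
from .stats import monthly_coverage_test, summarize_exceedance
from .survey import make_survey
from .wetness import compute_wi, max_ponding_duration

__all__ = ["PipelineConfig", "simulate_scenarios", "run_all", "PipelineError"]

SCENARIOS = ("baseline", "irrigation")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Parameters of one full pipeline run (YAML round-trippable)."""

    # domain
    n_rows: int = 80
    n_cols: int = 60
    cell_size: float = 50.0
    farm_fraction: float = 0.25
    # forcing
    year: int = 2018
    annual_rainfall: float = 1477.0
    # analysis
    theta: float | str = 0.48          # numeric, or "calibrate"
    T_list: tuple = (10, 15)
    comparator: str = "strict"
    # survey (used when theta == "calibrate")
    survey_n_points: int = 134
    survey_theta_true: float = 0.48
    survey_frac_excluded: float = 32.0 / 134.0
    calib_grid_step: float = 0.01
    calib_n_bootstrap: int = 1000
    # stream mask
    q_threshold: float = 0.01
    persistence: float = 0.9
    apply_mask_to_stats: bool = True
    # misc
    seed: int = 0
    irrigation: IrrigationSchedule = field(default_factory=IrrigationSchedule)
    bucket: BucketParams = field(default_factory=BucketParams)
    seasons: SeasonDefinition = field(default_factory=SeasonDefinition)

    def __post_init__(self) -> None:
        if not self.T_list or any(t < 1 for t in self.T_list):
            raise ValueError("T_list must be non-empty with all T >= 1")
        if isinstance(self.theta, str):
            if self.theta != "calibrate":
                raise ValueError("theta must be numeric or 'calibrate'")
        elif not (0.0 <= float(self.theta) <= 1.0):
            raise ValueError("numeric theta must be in [0, 1]")

    # --- seeds -----------------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31 derived from the root."""
        tag = zlib.crc32(stage.encode("utf-8"))
        ss = np.random.SeedSequence([int(self.seed), int(tag)])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    # --- YAML ------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["irrigation"] = {
            "group_a": sorted(self.irrigation.group_a),
            "group_b": sorted(self.irrigation.group_b),
            "turn_length": self.irrigation.turn_length,
            "daily_depth": self.irrigation.daily_depth,
            "hours_per_day": self.irrigation.hours_per_day,
            "active_months": sorted(self.irrigation.active_months),
            "enabled": self.irrigation.enabled,
        }
        d["seasons"] = {"dry_months": sorted(self.seasons.dry_months),
                        "rainy_months": sorted(self.seasons.rainy_months)}
        d["bucket"] = dataclasses.asdict(self.bucket)
        d["T_list"] = list(self.T_list)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "irrigation" in d:
            irr = dict(d["irrigation"])
            for k in ("group_a", "group_b", "active_months"):
                if k in irr:
                    irr[k] = frozenset(irr[k])
            d["irrigation"] = IrrigationSchedule(**irr)
        if "seasons" in d:
            s = d["seasons"]
            d["seasons"] = SeasonDefinition(
                dry_months=frozenset(s["dry_months"]),
                rainy_months=frozenset(s["rainy_months"]))
        if "bucket" in d:
            b = dict(d["bucket"])
            for k in ("store_capacity", "drainage_coeff"):
                if k in b:
                    b[k] = {int(c): float(v) for c, v in b[k].items()}
            d["bucket"] = BucketParams(**b)
        if "T_list" in d:
            d["T_list"] = tuple(d["T_list"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(pio.load_yaml(path))

    def to_yaml(self, path) -> None:
        pio.dump_yaml(self.to_dict(), path)


def _dates(config: PipelineConfig) -> pd.DatetimeIndex:
    return pd.date_range(f"{config.year}-01-01", f"{config.year}-12-31",
                         freq="D")


def simulate_scenarios(config: PipelineConfig) -> dict:
    """Run baseline and irrigation scenarios on a shared domain and forcing.

    Returns a dict with the domain, forcing and, per scenario, the
    saturation cube, flow cube and water budget.
    """
    domain = make_domain(config.n_rows, config.n_cols,
                         seed=config.stage_seed("domain"),
                         farm_fraction=config.farm_fraction,
                         cell_size=config.cell_size)
    forcing = make_forcing(_dates(config), seed=config.stage_seed("forcing"),
                           annual_total=config.annual_rainfall)
    bucket = dataclasses.replace(config.bucket,
                                 seed=config.stage_seed("bucket"))
    out = {"domain": domain, "forcing": forcing}
    for name in SCENARIOS:
        schedule = dataclasses.replace(config.irrigation,
                                       enabled=(name == "irrigation"
                                                and config.irrigation.enabled))
        sat, flow, budget = run_bucket_model(domain, forcing, schedule,
                                             bucket, scenario_label=name,
                                             return_budget=True)
        out[name] = {"sat": sat, "flow": flow, "budget": budget}
    return out


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    return wrap


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute the full pipeline and write every artifact plus a manifest.

    Returns the manifest dict; the manifest JSON lists every written file
    with its SHA-256 checksum together with the config used.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise PipelineError(f"output directory not writable: {exc}") from exc

    files: list[Path] = []

    def record(path: Path) -> Path:
        files.append(path)
        return path

    sim = _stage("simulate")(simulate_scenarios, config)
    domain, forcing = sim["domain"], sim["forcing"]
    pio.write_domain(domain, record(out / "domain.nc"))
    for name in SCENARIOS:
        pio.write_saturation(sim[name]["sat"],
                             record(out / f"saturation_{name}.nc"))
        pio.write_flow(sim[name]["flow"], record(out / f"flowrate_{name}.nc"))

    # Threshold: fixed or calibrated against a synthetic survey.
    calibration = None
    if config.theta == "calibrate":
        survey = _stage("survey")(
            make_survey, sim["baseline"]["sat"], domain,
            theta_true=config.survey_theta_true,
            n_points=config.survey_n_points,
            seed=config.stage_seed("survey"),
            frac_excluded_types=config.survey_frac_excluded,
            theta_grid_step=config.calib_grid_step)
        pio.write_survey(survey, record(out / "survey.csv"))
        usable = _stage("calibration")(filter_survey, survey)
        calibration = _stage("calibration")(
            calibrate_theta, sim["baseline"]["sat"], usable,
            theta_grid_step=config.calib_grid_step,
            n_bootstrap=config.calib_n_bootstrap,
            seed=config.stage_seed("calibration"))
        calibration.to_json(record(out / "calibration.json"))
        theta = calibration.theta_star
    else:
        theta = float(config.theta)

    # Wetness index and stream mask per scenario (shared baseline mask so
    # scenario statistics compare identical cell sets).
    wi = {name: _stage("wetness")(compute_wi, sim[name]["sat"], theta)
          for name in SCENARIOS}
    for name in SCENARIOS:
        pio.write_wetness(wi[name], record(out / f"wetness_{name}.nc"))
    mask = _stage("mask")(stream_mask, sim["baseline"]["flow"],
                          config.q_threshold, config.persistence)
    stats_mask = mask if config.apply_mask_to_stats else None

    inside = domain.farm_id > 0
    outside = ~inside
    regions = {"INSIDE_FARMS": inside, "OUTSIDE_FARMS": outside}

    # Exceedance maps and the Table-1-style summary.
    summaries = []
    for T in config.T_list:
        for period in ("YEAR", "DRY", "RAINY"):
            maps = {}
            for name in SCENARIOS:
                emap = _stage("exceedance")(
                    exceedance_probability, wi[name], T, period,
                    config.seasons, stats_mask)
                emap.scenario_label = name
                pio.write_exceedance_map(
                    emap, record(out / f"p_wi{T}_{period.lower()}_{name}.nc"))
                maps[name] = emap
            for region_name, region in regions.items():
                summaries.append(_stage("summary")(
                    summarize_exceedance, maps["baseline"],
                    maps["irrigation"], region, region=region_name))
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(record(out / "scenario_summary.csv"), index=False)

    # Coverage series inside farms, monthly means and per-month t-tests.
    cov = {}
    tests = {}
    for T in config.T_list:
        for name in SCENARIOS:
            series = _stage("coverage")(
                coverage_series, wi[name], T, inside,
                comparator=config.comparator, region="INSIDE_FARMS")
            cov[(T, name)] = series
            pio.write_coverage_csv(
                series, record(out / f"coverage_wi{T}_{name}.csv"))
            monthly = monthly_mean_coverage(series)
            monthly.to_csv(
                record(out / f"monthly_coverage_wi{T}_{name}.csv"),
                index=False)
        month_rows = {}
        for month in range(1, 13):
            res = _stage("ttest")(monthly_coverage_test,
                                  cov[(T, "baseline")],
                                  cov[(T, "irrigation")], month)
            month_rows[str(month)] = {
                "t_stat": res.t_stat, "p_value": res.p_value,
                "significant_at_0.01": res.significant_at_0_01,
                "degenerate": res.degenerate}
        tests[f"monthly_t_wi{T}"] = month_rows
    pio.write_json(tests, record(out / "monthly_tests.json"))

    # Stability of cells inside farms.
    stability = {}
    for name in SCENARIOS:
        dur = _stage("stability")(max_ponding_duration, wi[name])
        smap = _stage("stability")(
            classify_stability, np.where(inside, dur, 0),
            mask=(stats_mask | ~inside) if stats_mask is not None
            else ~inside)
        pio.write_stability_map(smap, record(out / f"stability_{name}.nc"),
                                record(out / f"stability_hist_{name}.csv"))
        stability[name] = smap.fractions
    pio.write_json(stability, record(out / "stability_fractions.json"))

    manifest = {
        "config": config.to_dict(),
        "theta_used": theta,
        "mass_balance_residual": {
            name: sim[name]["budget"].residual for name in SCENARIOS},
        "files": {p.name: pio.sha256_file(p) for p in sorted(files)},
    }
    pio.write_json(manifest, out / "manifest.json")
    return manifest
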