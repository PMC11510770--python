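"""Config-driven end-to-end runner: generate/ingest → calibrate → validate →
decompose → summarize → manifest.

The pipeline mirrors a sensor-network campaign workflow. On a synthetic run
it generates the network, fits one calibration model per pollutant at the
colocated sites (against the truth there, playing the role of the reference
analyzers), applies it network-wide, scores colocation agreement at hourly
resolution, decomposes every calibrated channel into baseline + local, and
writes summary tables. All stage outputs are files; a machine-readable run
manifest records the config hash, package versions, and per-stage row
counts. Results never go to stdout so the CLI composes in shells.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .analysis import diurnal_profile, site_nox_table, site_stats_table, zone_nox_means
from .baseline import BaselineConfig, decompose
from .calib import apply_calibration, fit_calibration, validate_colocation
from .core_io import (
    ConfigError,
    InsufficientDataError,
    TimeSeries,
    hourly_aggregate,
    read_met_csv,
    read_site_meta_csv,
    read_timeseries_csv,
    write_met_csv,
    write_results_csv,
    write_site_meta_csv,
    write_timeseries_csv,
)
from .synth import ScenarioConfig, config_from_dict, config_to_dict, generate_network

log = logging.getLogger("portair")


@dataclass
class PipelineConfig:
    """End-to-end run description: exactly one of ``input_csv`` (with
    ``met_csv``/``sites_csv``) or ``scenario`` must be provided."""

    output_dir: str = "portair_out"
    input_csv: str | None = None
    met_csv: str | None = None
    sites_csv: str | None = None
    scenario: ScenarioConfig | None = None
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    completeness: float = 0.75
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_csv is None) == (self.scenario is None):
            raise ConfigError("provide exactly one of input_csv or scenario")
        if self.input_csv is not None and self.sites_csv is None:
            raise ConfigError("input_csv runs need a sites_csv metadata table")


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    cfg = PipelineConfig(
        output_dir=d.get("output_dir", "portair_out"),
        input_csv=d.get("input_csv"),
        met_csv=d.get("met_csv"),
        sites_csv=d.get("sites_csv"),
        completeness=d.get("completeness", 0.75),
        seed=d.get("seed"),
        log_level=d.get("log_level", "INFO"),
    )
    if "scenario" in d and d["scenario"] is not None:
        cfg.scenario = config_from_dict(d["scenario"])
    if "baseline" in d and d["baseline"] is not None:
        cfg.baseline = BaselineConfig(**d["baseline"])
    cfg.validate()
    return cfg


def _config_hash(config: PipelineConfig) -> str:
    payload = {
        "output_dir": config.output_dir,
        "input_csv": config.input_csv,
        "met_csv": config.met_csv,
        "sites_csv": config.sites_csv,
        "scenario": config_to_dict(config.scenario) if config.scenario else None,
        "baseline": vars(config.baseline).copy(),
        "completeness": config.completeness,
        "seed": config.seed,
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``<output_dir>/manifest.json``)."""
    config.validate()
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "portair_version": __version__,
        "versions": {
            "pandas": pd.__version__,
            "numpy": __import__("numpy").__version__,
        },
        "config_hash": _config_hash(config),
        "stages": {},
    }

    # --- stage: ingest or generate -------------------------------------
    if config.scenario is not None:
        scenario = config.scenario
        if config.seed is not None:
            scenario.seed = config.seed
        log.info("synth: generating %d sites x %d days", len(scenario.sites), scenario.n_days)
        bundle = generate_network(scenario)
        sites = scenario.sites
        raw = bundle.raw_series()
        met = bundle.met
        truth = bundle.channels
        write_timeseries_csv(raw, out / "raw_sensor.csv", met=met)
        write_timeseries_csv(bundle.total_series(), out / "truth_total.csv")
        write_site_meta_csv(sites, out / "sites.csv")
        write_met_csv(met, out / "met.csv")
        manifest["stages"]["synth"] = {
            "n_sites": len(sites), "n_channels": len(raw), "n_rows": sum(len(s) for s in raw),
        }
    else:
        log.info("ingest: reading %s", config.input_csv)
        raw = read_timeseries_csv(config.input_csv)
        sites = read_site_meta_csv(config.sites_csv)
        met = read_met_csv(config.met_csv) if config.met_csv else {}
        truth = None
        manifest["stages"]["ingest"] = {
            "n_sites": len(sites), "n_channels": len(raw), "n_rows": sum(len(s) for s in raw),
        }

    by_channel = {(s.site_id, s.pollutant): s for s in raw}

    # --- stage: calibrate at colocated sites ---------------------------
    colocated = [s for s in sites if s.colocated]
    models: dict[str, object] = {}
    validation_rows = []
    if truth is not None and colocated:
        for pollutant in ("NO", "NO2"):
            site = colocated[0]
            raw_h = hourly_aggregate(by_channel[(site.site_id, pollutant)], config.completeness)
            ref_h = hourly_aggregate(truth[(site.site_id, pollutant)].total_true, config.completeness)
            met_h = _hourly_met(met[site.site_id])
            model = fit_calibration(raw_h, met_h, ref_h)
            models[pollutant] = model
            log.info("calibrate: %s gain=%.3f intercept=%.2f", pollutant,
                     model.coef_signal, model.intercept)
        with open(out / "calibration.json", "w") as fh:
            json.dump({p: m.to_dict() for p, m in models.items()}, fh, indent=2)
        manifest["stages"]["calibrate"] = {
            p: {"n_obs": m.n_obs, "coef_signal": m.coef_signal} for p, m in models.items()
        }

    # --- stage: apply calibration + validate ---------------------------
    calibrated: dict[tuple[str, str], TimeSeries] = {}
    for (site_id, pollutant), ts in by_channel.items():
        if pollutant in models:
            calibrated[(site_id, pollutant)] = apply_calibration(
                models[pollutant], ts, met[site_id]
            )
        else:  # no reference available: clip raw as-is
            calibrated[(site_id, pollutant)] = ts.with_values(ts.values.clip(lower=0))
    if truth is not None:
        for site in colocated:
            for pollutant in ("NO", "NO2"):
                sensor_h = hourly_aggregate(calibrated[(site.site_id, pollutant)], config.completeness)
                ref_h = hourly_aggregate(truth[(site.site_id, pollutant)].total_true, config.completeness)
                vm = validate_colocation(sensor_h, ref_h)
                validation_rows.append(
                    {"site_id": site.site_id, "pollutant": pollutant,
                     "r2": vm.r2, "rmse": vm.rmse, "n": vm.n}
                )
        vdf = pd.DataFrame(validation_rows)
        write_results_csv(vdf, out / "validation.csv")
        manifest["stages"]["validate"] = {"n_rows": len(vdf)}

    # --- stage: decompose ----------------------------------------------
    frames = []
    frac_rows = []
    for (site_id, pollutant), ts in sorted(calibrated.items()):
        try:
            dec = decompose(ts, config.baseline)
        except InsufficientDataError as exc:
            log.warning("decompose: skipping %s/%s (%s)", site_id, pollutant, exc)
            continue
        frame = dec.to_frame().reset_index(names="timestamp")
        frame.insert(1, "site_id", site_id)
        frame.insert(2, "pollutant", pollutant)
        frames.append(frame)
        frac_rows.append(
            {"site_id": site_id, "pollutant": pollutant,
             "local_pct": dec.local_fraction, "regional_pct": dec.regional_fraction}
        )
    dec_df = pd.concat(frames, ignore_index=True)
    dec_df["timestamp"] = pd.DatetimeIndex(dec_df["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S%z")
    dec_df.to_csv(out / "decomposition.csv", index=False)
    frac_df = pd.DataFrame(frac_rows)
    write_results_csv(frac_df, out / "fractions.csv")
    manifest["stages"]["decompose"] = {
        "n_channels": len(frac_rows), "n_rows": len(dec_df),
    }

    # --- stage: summarize ----------------------------------------------
    hourly = {key: hourly_aggregate(ts, config.completeness) for key, ts in calibrated.items()}
    stats_df = site_stats_table(list(calibrated.values()))
    write_results_csv(stats_df, out / "site_stats.csv")
    write_results_csv(site_nox_table(stats_df), out / "site_nox.csv")
    zone_df = (
        zone_nox_means(list(calibrated.values()), sites)
        .rename("nox_mean").rename_axis("zone").reset_index()
    )
    write_results_csv(zone_df, out / "zone_nox.csv")
    prof = diurnal_profile([h for (sid, p), h in hourly.items() if p == "NO"])
    prof_df = pd.DataFrame({"hour": prof.mean.index, "no_mean": prof.mean.to_numpy(),
                            "n": prof.count.to_numpy()})
    write_results_csv(prof_df, out / "diurnal_no.csv")
    manifest["stages"]["summarize"] = {
        "n_sites": len(stats_df), "zone_order": list(zone_df["zone"]),
        "diurnal_no_argmax_hour": prof.argmax_hour(),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("done: outputs in %s", out)
    return manifest


def _hourly_met(met):
    """Hourly means of a minute-cadence met series (no completeness rule)."""
    from .core_io import MetSeries

    t = met.temperature.groupby(met.index.floor("h")).mean()
    rh = met.relative_humidity.groupby(met.index.floor("h")).mean()
    return MetSeries(t, rh, "hour")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return pipeline_config_from_dict(data)
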