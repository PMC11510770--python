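"""Synthetic sensor-network scenarios with known ground truth.

Each generated channel is the sum of two truth components the downstream
decomposition tries to recover:

* a **regional background**: slowly drifting AR(1) level plus a small
  diurnal cosine modulation, clipped at zero — smooth at the minute scale;
* a **local emission signal**: sparse plume events from an inhomogeneous
  Poisson process, each decaying exponentially (amplitude ~ lognormal, so
  single truck/ship passages can spike minute NO readings to ~1000 μg/m³
  over a background of tens).

Night-time event intensity ramps up linearly from 22:00 to a peak just
before 06:00 (local policy restricts heavy trucks to night hours, so traffic
builds through the night shift), which places the diurnal concentration
maximum near 06:00. NO₂ receives a share of the NO plume mass through a
first-order lag — a modeling stand-in for gradual NO oxidation during
dispersion, not a chemistry model.

The raw sensor channel is a linear response confounded by temperature and
relative humidity plus Gaussian noise; it may read negative, the truth
channels never do. Everything is reproducible bit-for-bit from the scenario
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core_io import (
    DEFAULT_TZ,
    ZONES,
    ConfigError,
    MetSeries,
    SiteMeta,
    TimeSeries,
)

MINUTES_PER_DAY = 1440


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class BackgroundParams:
    """Regional background: level + diurnal cosine + AR(1) drift, all μg/m³.

    ``ar1_coef`` is the per-minute autocorrelation; the default corresponds
    to a drift correlation time of ~3 days, so the background is effectively
    constant within one 8-h window — the regime the lowest-percentile
    decomposition is designed for.
    """

    level: float = 20.0
    diurnal_amplitude: float = 0.6
    diurnal_phase_h: float = 5.5  # hour of the diurnal maximum
    ar1_coef: float = 0.99977
    ar1_sd: float = 0.043  # innovation SD; stationary SD ≈ 2 μg/m³

    def validate(self) -> None:
        if not 0 <= self.ar1_coef < 1:
            raise ConfigError("ar1_coef must be in [0, 1)")
        if min(self.level, self.diurnal_amplitude, self.ar1_sd) < 0:
            raise ConfigError("background level/amplitude/SD must be >= 0")


@dataclass
class PlumeParams:
    """Local plume events: Poisson arrivals, lognormal amplitudes (μg/m³),
    exponential decay. ``night_multiplier`` scales the rate over the night
    window; with ``night_shape="ramp"`` the intensity climbs linearly from
    1× at ``night_start_h`` to ``night_multiplier``× just before
    ``night_end_h`` (``"flat"`` applies the multiplier uniformly)."""

    rate_per_hour: float = 2.0
    amp_mu_log: float = 4.492  # median e^mu ≈ 89 μg/m³, mean ≈ 123 μg/m³
    amp_sigma_log: float = 0.8
    decay_tau_min: float = 12.0
    night_multiplier: float = 5.0
    night_start_h: float = 22.0
    night_end_h: float = 6.0
    night_shape: str = "ramp"

    def validate(self) -> None:
        if self.rate_per_hour < 0 or self.decay_tau_min <= 0:
            raise ConfigError("plume rate must be >= 0 and decay tau > 0")
        if self.night_multiplier < 0:
            raise ConfigError("night_multiplier must be >= 0")
        if self.night_shape not in ("ramp", "flat"):
            raise ConfigError("night_shape must be 'ramp' or 'flat'")


@dataclass
class SensorParams:
    """Linear raw-sensor response: gain·C + offset + T/RH terms + noise."""

    gain: float = 0.85
    offset: float = -10.0
    temp_coef: float = 0.8  # μg/m³ per °C
    rh_coef: float = 0.12  # μg/m³ per %
    noise_sd: float = 2.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class MetParams:
    """Diurnal temperature sinusoid and anti-phase RH, with clipping."""

    temp_mean: float = 18.0
    temp_amplitude: float = 5.0
    temp_phase_h: float = 14.0
    temp_noise_sd: float = 0.8
    temp_bounds: tuple[float, float] = (5.0, 35.0)
    rh_mean: float = 65.0
    rh_amplitude: float = 18.0
    rh_noise_sd: float = 3.0
    rh_bounds: tuple[float, float] = (20.0, 95.0)


def _default_sites() -> list[SiteMeta]:
    """17 sites across four functional zones and two terminals, with the two
    colocated (reference-paired) sites numbered 7 and 16."""
    zone_of = {
        "1": "OR", "7": "OR", "9": "OR",
        "2": "SR", "4": "SR", "12": "SR", "14": "SR", "17": "SR",
        "8": "OA", "13": "OA", "15": "OA", "16": "OA",
        "3": "BA", "5": "BA", "6": "BA", "10": "BA", "11": "BA",
    }
    return [
        SiteMeta(
            site_id=str(i),
            zone=zone_of[str(i)],
            terminal="PCT2" if i <= 8 else "PCT4",
            colocated=i in (7, 16),
        )
        for i in range(1, 18)
    ]


def _default_zone_plumes() -> dict[str, PlumeParams]:
    # base (daytime) event rates per zone; operational areas busiest,
    # outer ring quietest — fixes the zone concentration ordering
    rates = {"OA": 5.5, "SR": 4.0, "BA": 2.2, "OR": 0.7}
    return {z: PlumeParams(rate_per_hour=rates[z]) for z in ZONES}


@dataclass
class ScenarioConfig:
    """Complete description of one synthetic campaign."""

    n_days: int = 21
    sites: list[SiteMeta] = field(default_factory=_default_sites)
    seed: int = 0
    start: str = "2023-10-21"
    tz: str = DEFAULT_TZ
    background: dict[str, BackgroundParams] = field(
        default_factory=lambda: {
            "NO": BackgroundParams(),
            "NO2": BackgroundParams(level=32.0, diurnal_amplitude=1.0,
                                    diurnal_phase_h=17.0, ar1_sd=0.065),
        }
    )
    plumes: dict[str, PlumeParams] = field(default_factory=_default_zone_plumes)
    sensor: SensorParams = field(default_factory=SensorParams)
    met: MetParams = field(default_factory=MetParams)
    oxidation_fraction: float = 0.2
    no2_lag_min: float = 30.0

    def validate(self) -> None:
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if not 0 <= self.oxidation_fraction <= 1:
            raise ConfigError("oxidation_fraction must be in [0, 1]")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ConfigError("site ids must be unique")
        for bp in self.background.values():
            bp.validate()
        for pp in self.plumes.values():
            pp.validate()
        self.sensor.validate()

    def minute_index(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.start, tz=self.tz)
        return pd.date_range(start, periods=self.n_days * MINUTES_PER_DAY, freq="min")


@dataclass
class SiteTruth:
    """Truth channels for one site/pollutant: total = background + local."""

    background: TimeSeries
    local: TimeSeries
    total_true: TimeSeries
    raw_sensor: TimeSeries


@dataclass
class TruthBundle:
    """Everything a scenario generated: per-site met and per-channel truth."""

    config: ScenarioConfig
    met: dict[str, MetSeries]
    channels: dict[tuple[str, str], SiteTruth]  # (site_id, pollutant)

    def total_series(self) -> list[TimeSeries]:
        return [st.total_true for st in self.channels.values()]

    def raw_series(self) -> list[TimeSeries]:
        return [st.raw_sensor for st in self.channels.values()]


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------


def _hour_of_day(index: pd.DatetimeIndex) -> np.ndarray:
    return index.hour.to_numpy() + index.minute.to_numpy() / 60.0


def _ar1(n: int, coef: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path: x_t = coef·x_{t-1} + N(0, sd)."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd, n)
    if coef > 0:
        eps[0] = rng.normal(0.0, sd / np.sqrt(1.0 - coef**2))  # stationary start
        return lfilter([1.0], [1.0, -coef], eps)
    return eps


def generate_background(
    params: BackgroundParams, index: pd.DatetimeIndex, rng: np.random.Generator
) -> np.ndarray:
    """Regional background: max(0, level + diurnal cosine + AR(1) drift)."""
    params.validate()
    hod = _hour_of_day(index)
    diurnal = params.diurnal_amplitude * np.cos(
        2 * np.pi * (hod - params.diurnal_phase_h) / 24.0
    )
    drift = _ar1(len(index), params.ar1_coef, params.ar1_sd, rng)
    return np.clip(params.level + diurnal + drift, 0.0, None)


def event_rate_per_minute(params: PlumeParams, index: pd.DatetimeIndex) -> np.ndarray:
    """Inhomogeneous Poisson intensity (events/min) incl. the night window."""
    hod = _hour_of_day(index)
    # night window may wrap midnight, e.g. 22:00–06:00
    if params.night_start_h <= params.night_end_h:
        in_night = (hod >= params.night_start_h) & (hod < params.night_end_h)
        since_start = hod - params.night_start_h
        span = params.night_end_h - params.night_start_h
    else:
        in_night = (hod >= params.night_start_h) | (hod < params.night_end_h)
        since_start = np.where(
            hod >= params.night_start_h, hod - params.night_start_h,
            hod + 24.0 - params.night_start_h,
        )
        span = params.night_end_h + 24.0 - params.night_start_h
    mult = np.ones(len(index))
    if params.night_shape == "flat":
        mult[in_night] = params.night_multiplier
    else:  # intensity climbs through the night shift, peaking before dawn
        frac = np.clip(since_start / max(span, 1e-9), 0.0, 1.0)
        mult[in_night] = 1.0 + (params.night_multiplier - 1.0) * frac[in_night]
    return params.rate_per_hour / 60.0 * mult


def plume_signal_from_events(
    event_minutes: Sequence[int],
    amplitudes: Sequence[float],
    n: int,
    decay_tau_min: float,
) -> np.ndarray:
    """Superpose events: each contributes amp·exp(−Δt/τ) from its onset on."""
    impulses = np.zeros(n)
    np.add.at(impulses, np.asarray(event_minutes, dtype=int), np.asarray(amplitudes, float))
    a = np.exp(-1.0 / decay_tau_min)
    return lfilter([1.0], [1.0, -a], impulses)


def generate_plumes(
    params: PlumeParams, index: pd.DatetimeIndex, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Draw plume events and return (signal, number of events)."""
    params.validate()
    lam = event_rate_per_minute(params, index)
    counts = rng.poisson(lam)
    n_events = int(counts.sum())
    if n_events == 0:
        return np.zeros(len(index)), 0
    minutes = np.repeat(np.arange(len(index)), counts)
    amps = rng.lognormal(params.amp_mu_log, params.amp_sigma_log, n_events)
    return plume_signal_from_events(minutes, amps, len(index), params.decay_tau_min), n_events


def first_order_lag(x: np.ndarray, tau_min: float) -> np.ndarray:
    """Unit-gain first-order lag y_t = (1−α)·y_{t−1} + α·x_t, α = 1−e^(−1/τ)."""
    alpha = 1.0 - np.exp(-1.0 / tau_min)
    return lfilter([alpha], [1.0, -(1.0 - alpha)], x)


def generate_met(
    params: MetParams, index: pd.DatetimeIndex, rng: np.random.Generator,
    cadence: str = "minute",
) -> MetSeries:
    """Diurnal temperature and anti-phase RH with noise and clipping."""
    hod = _hour_of_day(index)
    shape = np.cos(2 * np.pi * (hod - params.temp_phase_h) / 24.0)
    temp = params.temp_mean + params.temp_amplitude * shape
    rh = params.rh_mean - params.rh_amplitude * shape
    if params.temp_noise_sd > 0:
        temp = temp + rng.normal(0, params.temp_noise_sd, len(index))
    if params.rh_noise_sd > 0:
        rh = rh + rng.normal(0, params.rh_noise_sd, len(index))
    temp = np.clip(temp, *params.temp_bounds)
    rh = np.clip(rh, *params.rh_bounds)
    return MetSeries(
        pd.Series(temp, index=index), pd.Series(rh, index=index), cadence
    )


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------


def generate_network(config: ScenarioConfig) -> TruthBundle:
    """Generate the full network: truth channels, met, and raw sensor signals.

    Each site draws from its own seed stream spawned from the scenario seed,
    so the bundle is reproducible and per-site output does not depend on the
    order sites are listed in.
    """
    config.validate()
    index = config.minute_index()
    root = np.random.SeedSequence(config.seed)
    met: dict[str, MetSeries] = {}
    channels: dict[tuple[str, str], SiteTruth] = {}
    for site, child in zip(config.sites, root.spawn(len(config.sites))):
        streams = [np.random.default_rng(s) for s in child.spawn(6)]
        rng_met, rng_plume, rng_bg_no, rng_bg_no2, rng_noise_no, rng_noise_no2 = streams
        m = generate_met(config.met, index, rng_met)
        met[site.site_id] = m

        plume, _ = generate_plumes(config.plumes[site.zone], index, rng_plume)
        bg_no = generate_background(config.background["NO"], index, rng_bg_no)
        bg_no2 = generate_background(config.background["NO2"], index, rng_bg_no2)
        local_no = plume
        local_no2 = config.oxidation_fraction * first_order_lag(plume, config.no2_lag_min)

        for pollutant, bg, local, rng_noise in (
            ("NO", bg_no, local_no, rng_noise_no),
            ("NO2", bg_no2, local_no2, rng_noise_no2),
        ):
            total = bg + local
            raw = (
                config.sensor.gain * total
                + config.sensor.offset
                + config.sensor.temp_coef * m.temperature.to_numpy()
                + config.sensor.rh_coef * m.relative_humidity.to_numpy()
            )
            if config.sensor.noise_sd > 0:
                raw = raw + rng_noise.normal(0, config.sensor.noise_sd, len(index))
            mk = lambda v: TimeSeries(site.site_id, pollutant, pd.Series(v, index=index))
            channels[(site.site_id, pollutant)] = SiteTruth(
                background=mk(bg), local=mk(local), total_true=mk(total), raw_sensor=mk(raw)
            )
    return TruthBundle(config=config, met=met, channels=channels)


def default_scenario(seed: int = 0, n_days: int = 21) -> ScenarioConfig:
    """The default 17-site, four-zone, three-week campaign scenario."""
    return ScenarioConfig(n_days=n_days, seed=seed)


def single_site_scenario(
    seed: int,
    rate_per_hour: float,
    n_days: int = 6,
    zone: str = "OA",
    **plume_overrides,
) -> ScenarioConfig:
    """A one-site scenario whose plume rate (and optionally other plume
    parameters) is overridden — used for recovery sweeps."""
    cfg = ScenarioConfig(
        n_days=n_days,
        sites=[SiteMeta("s1", zone, "PCT2", colocated=True)],
        seed=seed,
    )
    cfg.plumes = {zone: PlumeParams(rate_per_hour=rate_per_hour, **plume_overrides)}
    return cfg


def config_to_dict(config: ScenarioConfig) -> dict:
    """Plain-dict form of a scenario (YAML/JSON friendly)."""
    d = asdict(config)
    d["sites"] = [asdict(s) for s in config.sites]
    return d


def config_from_dict(d: Mapping) -> ScenarioConfig:
    """Inverse of :func:`config_to_dict`; missing blocks keep defaults."""
    d = dict(d)
    kwargs: dict = {}
    for key in ("n_days", "seed", "start", "tz", "oxidation_fraction", "no2_lag_min"):
        if key in d:
            kwargs[key] = d[key]
    if "sites" in d:
        kwargs["sites"] = [SiteMeta(**s) for s in d["sites"]]
    if "background" in d:
        kwargs["background"] = {k: BackgroundParams(**v) for k, v in d["background"].items()}
    if "plumes" in d:
        kwargs["plumes"] = {k: PlumeParams(**v) for k, v in d["plumes"].items()}
    if "sensor" in d:
        kwargs["sensor"] = SensorParams(**d["sensor"])
    if "met" in d:
        met = dict(d["met"])
        for b in ("temp_bounds", "rh_bounds"):
            if b in met:
                met[b] = tuple(met[b])
        kwargs["met"] = MetParams(**met)
    cfg = ScenarioConfig(**kwargs)
    cfg.validate()
    return cfg
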