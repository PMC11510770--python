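"""Typed in-memory model of a low-cost sensor network and CSV round-trip I/O.

The package works on per-site, per-pollutant concentration time series on a
regular local-time grid (1-min raw cadence, 1-h aggregated cadence), a small
site-metadata table (functional zone, terminal, colocation flag), and paired
temperature / relative-humidity series used for calibration.

Conventions fixed here and used everywhere downstream:

* timestamps are time-zone-aware local time (IANA zone, default
  ``Asia/Shanghai``) because diurnal profiles and 8-h window anchoring are
  defined in local time;
* hour labels are interval starts, half-open ``[t, t + 1h)``;
* missing values are explicit (``NaN`` in memory, empty field in CSV) —
  zero is a valid concentration, never a missing marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_TZ = "Asia/Shanghai"

POLLUTANTS = ("NO", "NO2")
ZONES = ("OR", "SR", "OA", "BA")
TERMINALS = ("PCT2", "PCT4")

#: grid step per cadence
CADENCE_STEP = {"minute": pd.Timedelta(minutes=1), "hour": pd.Timedelta(hours=1)}


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class PortAirError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(PortAirError):
    """Invalid or inconsistent configuration."""


class SchemaError(PortAirError):
    """Malformed input file: bad timestamps, duplicates, missing columns."""


class InsufficientDataError(PortAirError):
    """Fewer valid observations than the operation requires."""


class DegenerateDesignError(PortAirError):
    """Rank-deficient regression design (e.g. a constant covariate)."""


class AlignmentError(PortAirError):
    """Two series that must share a timestamp grid do not."""


class UndefinedMetricError(PortAirError):
    """A metric's denominator is zero (e.g. constant reference series)."""


class EmptyZoneError(PortAirError):
    """No site of the requested functional zone is present."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteMeta:
    """One monitoring site: identifier, functional zone, terminal, colocation.

    ``colocated`` marks sites operated beside a reference-grade analyzer
    (used for calibration and network validation).
    """

    site_id: str
    zone: str
    terminal: str
    colocated: bool = False

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ConfigError(f"unknown zone {self.zone!r}; expected one of {ZONES}")
        if self.terminal not in TERMINALS:
            raise ConfigError(
                f"unknown terminal {self.terminal!r}; expected one of {TERMINALS}"
            )


def _validate_grid(index: pd.DatetimeIndex, cadence: str, what: str) -> None:
    if cadence not in CADENCE_STEP:
        raise ConfigError(f"unknown cadence {cadence!r}")
    if not isinstance(index, pd.DatetimeIndex):
        raise ConfigError(f"{what}: index must be a DatetimeIndex")
    if index.tz is None:
        raise ConfigError(f"{what}: timestamps must be time-zone-aware")
    if len(index) >= 2:
        deltas = np.diff(index.asi8)
        step = CADENCE_STEP[cadence].value
        if not (deltas == step).all():
            bad = int(np.flatnonzero(deltas != step)[0])
            raise ConfigError(
                f"{what}: timestamps must be strictly increasing with constant "
                f"{cadence} spacing (violation after {index[bad]})"
            )


@dataclass
class TimeSeries:
    """One pollutant channel at one site on a regular timestamp grid.

    ``values`` is a float Series indexed by tz-aware timestamps; NaN marks
    missing samples. ``cadence`` is ``"minute"`` or ``"hour"``.
    """

    site_id: str
    pollutant: str
    values: pd.Series
    cadence: str = "minute"

    def __post_init__(self) -> None:
        if self.pollutant not in POLLUTANTS:
            raise ConfigError(
                f"unknown pollutant {self.pollutant!r}; expected one of {POLLUTANTS}"
            )
        self.values = self.values.astype(float)
        _validate_grid(self.values.index, self.cadence, f"TimeSeries({self.site_id})")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.values.index

    def dropna(self) -> pd.Series:
        return self.values.dropna()

    def with_values(self, values: pd.Series, cadence: str | None = None) -> "TimeSeries":
        return TimeSeries(self.site_id, self.pollutant, values, cadence or self.cadence)


@dataclass
class MetSeries:
    """Temperature (°C) and relative humidity (%) on a shared timestamp grid."""

    temperature: pd.Series
    relative_humidity: pd.Series
    cadence: str = "minute"

    def __post_init__(self) -> None:
        self.temperature = self.temperature.astype(float)
        self.relative_humidity = self.relative_humidity.astype(float)
        if not self.temperature.index.equals(self.relative_humidity.index):
            raise AlignmentError("temperature and RH must share one timestamp grid")
        _validate_grid(self.temperature.index, self.cadence, "MetSeries")
        rh = self.relative_humidity.dropna()
        if len(rh) and ((rh < 0) | (rh > 100)).any():
            raise ConfigError("relative humidity outside [0, 100] %")
        t = self.temperature.dropna()
        if len(t) and ((t < -40) | (t > 60)).any():
            raise ConfigError("temperature outside [-40, 60] °C")

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.temperature.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"temperature_c": self.temperature, "rh_pct": self.relative_humidity}
        )


@dataclass
class BaselineDecomposition:
    """Total = regional baseline + local signal for one site/pollutant.

    ``local_fraction`` and ``regional_fraction`` are percentages summing to
    100; ``anchors`` holds the (window-center, low-quantile value) pairs the
    baseline was smoothed through; ``local_raw`` keeps the unclipped local
    signal so conservation can be audited when clipping is on.
    """

    total: TimeSeries
    baseline: TimeSeries
    local: TimeSeries
    anchors: list[tuple[pd.Timestamp, float]]
    local_fraction: float
    regional_fraction: float
    local_raw: pd.Series | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "total": self.total.values,
                "baseline": self.baseline.values,
                "local": self.local.values,
            }
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_TS_COLUMNS = ("timestamp", "site_id", "pollutant", "value_ugm3")


def _parse_timestamps(raw: pd.Series, tz: str) -> pd.DatetimeIndex:
    try:
        parsed = pd.to_datetime(raw, format="ISO8601")
    except (ValueError, TypeError):
        # re-parse element-wise to name the offending row
        parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
        bad = int(np.flatnonzero(parsed.isna() & raw.notna())[0])
        raise SchemaError(
            f"malformed timestamp {raw.iloc[bad]!r} at data row {bad}"
        ) from None
    if parsed.isna().any():
        bad = int(np.flatnonzero(parsed.isna())[0])
        raise SchemaError(f"missing timestamp at data row {bad}")
    idx = pd.DatetimeIndex(parsed)
    return idx.tz_localize(tz) if idx.tz is None else idx.tz_convert(tz)


def _complete_grid(series: pd.Series, cadence: str) -> pd.Series:
    """Reindex onto the full regular grid spanning the series, NaN-filling gaps."""
    if len(series) == 0:
        return series
    step = CADENCE_STEP[cadence]
    full = pd.date_range(series.index[0], series.index[-1], freq=step)
    return series.reindex(full)


def read_timeseries_csv(
    path: str | Path,
    tz: str = DEFAULT_TZ,
    cadence: str = "minute",
    schema: Mapping[str, str] | None = None,
) -> list[TimeSeries]:
    """Read a long-format concentration CSV into one TimeSeries per
    (site, pollutant), completing grid gaps with missing markers.

    Expected columns: ``timestamp`` (ISO-8601), ``site_id``, ``pollutant``,
    ``value_ugm3``; ``schema`` may remap file column names onto these.
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in _TS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    idx = _parse_timestamps(df["timestamp"], tz)
    df = df.assign(_ts=idx)
    out: list[TimeSeries] = []
    for (site, pollutant), grp in df.groupby(["site_id", "pollutant"], sort=True):
        dup = grp["_ts"].duplicated()
        if dup.any():
            when = grp["_ts"][dup].iloc[0]
            raise SchemaError(
                f"duplicate sample for site {site!r} pollutant {pollutant!r} at {when}"
            )
        series = pd.Series(
            grp["value_ugm3"].to_numpy(float), index=pd.DatetimeIndex(grp["_ts"])
        ).sort_index()
        out.append(TimeSeries(str(site), str(pollutant), _complete_grid(series, cadence), cadence))
    return out


def read_met_csv(
    path: str | Path, tz: str = DEFAULT_TZ, cadence: str = "minute"
) -> dict[str, MetSeries]:
    """Read per-site temperature/RH series (columns ``timestamp``, ``site_id``,
    ``temperature_c``, ``rh_pct``) keyed by site id."""
    df = pd.read_csv(path, dtype={"site_id": str})
    required = ("timestamp", "site_id", "temperature_c", "rh_pct")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    idx = _parse_timestamps(df["timestamp"], tz)
    df = df.assign(_ts=idx)
    out: dict[str, MetSeries] = {}
    for site, grp in df.groupby("site_id", sort=True):
        if grp["_ts"].duplicated().any():
            raise SchemaError(f"duplicate met sample for site {site!r}")
        gidx = pd.DatetimeIndex(grp["_ts"])
        t = _complete_grid(pd.Series(grp["temperature_c"].to_numpy(float), gidx).sort_index(), cadence)
        rh = _complete_grid(pd.Series(grp["rh_pct"].to_numpy(float), gidx).sort_index(), cadence)
        out[str(site)] = MetSeries(t, rh, cadence)
    return out


def read_site_meta_csv(path: str | Path) -> list[SiteMeta]:
    """Read the site-metadata table (site_id, zone, terminal, colocated)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    required = ("site_id", "zone", "terminal", "colocated")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df["site_id"].duplicated().any():
        dup = df["site_id"][df["site_id"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate site_id {dup!r} in metadata")
    truthy = {"true": True, "1": True, "false": False, "0": False}
    return [
        SiteMeta(
            str(r.site_id),
            str(r.zone),
            str(r.terminal),
            truthy.get(str(r.colocated).strip().lower(), bool(r.colocated)),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

# full repr precision so read(write(x)) round-trips exactly
_FLOAT_FMT = None


def write_timeseries_csv(
    series: Iterable[TimeSeries],
    path: str | Path,
    met: Mapping[str, MetSeries] | None = None,
) -> None:
    """Write TimeSeries (plus optional per-site met) to long-format CSV."""
    frames = []
    for ts in series:
        frame = pd.DataFrame(
            {
                "timestamp": ts.index.strftime("%Y-%m-%dT%H:%M:%S%z"),
                "site_id": ts.site_id,
                "pollutant": ts.pollutant,
                "value_ugm3": ts.values.to_numpy(),
            }
        )
        if met is not None and ts.site_id in met:
            m = met[ts.site_id].to_frame().reindex(ts.index)
            frame["temperature_c"] = m["temperature_c"].to_numpy()
            frame["rh_pct"] = m["rh_pct"].to_numpy()
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_met_csv(met: Mapping[str, MetSeries], path: str | Path) -> None:
    frames = []
    for site, m in met.items():
        frame = m.to_frame().reset_index(names="timestamp")
        frame["timestamp"] = pd.DatetimeIndex(frame["timestamp"]).strftime(
            "%Y-%m-%dT%H:%M:%S%z"
        )
        frame.insert(1, "site_id", site)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_site_meta_csv(sites: Sequence[SiteMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "zone": [s.zone for s in sites],
            "terminal": [s.terminal for s in sites],
            "colocated": [s.colocated for s in sites],
        }
    ).to_csv(path, index=False)


def write_results_csv(obj, path: str | Path) -> None:
    """Write a BaselineDecomposition or a statistics DataFrame to CSV.

    Round-trip stable to 6 significant digits (``read_decomposition_csv``
    recovers a decomposition's three channels).
    """
    if isinstance(obj, BaselineDecomposition):
        frame = obj.to_frame().reset_index(names="timestamp")
        frame["timestamp"] = pd.DatetimeIndex(frame["timestamp"]).strftime(
            "%Y-%m-%dT%H:%M:%S%z"
        )
        frame.insert(1, "site_id", obj.total.site_id)
        frame.insert(2, "pollutant", obj.total.pollutant)
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False, float_format=_FLOAT_FMT)
    else:  # pragma: no cover - defensive
        raise ConfigError(f"cannot serialize object of type {type(obj).__name__}")


def read_decomposition_csv(
    path: str | Path, tz: str = DEFAULT_TZ, cadence: str = "minute"
) -> pd.DataFrame:
    """Read back a decomposition CSV (timestamp-indexed total/baseline/local)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    idx = _parse_timestamps(df["timestamp"], tz)
    out = df.drop(columns=["timestamp"]).set_index(idx)
    out.index.name = "timestamp"
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def hourly_aggregate(ts: TimeSeries, completeness: float = 0.75) -> TimeSeries:
    """Aggregate a minute-cadence series to hourly means.

    Each hour ``[t, t+1h)`` becomes the arithmetic mean of its non-missing
    minutes and is marked missing when fewer than ``completeness * 60``
    minutes are valid. Hour-cadence input is passed through with the
    completeness rule applied per single sample (so a completeness of 0
    returns it unchanged).
    """
    if not 0 < completeness <= 1:
        raise ConfigError("completeness must be in (0, 1]")
    if ts.cadence not in ("minute", "hour"):
        raise ConfigError(f"unsupported cadence {ts.cadence!r}")
    if len(ts) == 0:
        return TimeSeries(ts.site_id, ts.pollutant, ts.values.copy(), "hour")
    per_hour = 60 if ts.cadence == "minute" else 1
    hours = ts.index.floor("h")
    grouped = ts.values.groupby(hours)
    mean = grouped.mean()
    count = grouped.count()
    full = pd.date_range(hours[0], hours[-1], freq="h")
    mean = mean.reindex(full)
    count = count.reindex(full, fill_value=0)
    mean[count < completeness * per_hour] = np.nan
    return TimeSeries(ts.site_id, ts.pollutant, mean, "hour")


def align_series(*series: pd.Series) -> list[pd.Series]:
    """Restrict series to their common index; raise if grids are disjoint."""
    common = series[0].index
    for s in series[1:]:
        common = common.intersection(s.index)
    if len(common) == 0:
        raise AlignmentError("series share no timestamps")
    return [s.reindex(common) for s in series]
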