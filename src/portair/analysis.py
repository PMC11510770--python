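"""Spatiotemporal summarization: per-site descriptive statistics, functional
zone averages, diurnal profiles, NO/NOx oxidation ratios, and gas-unit
conversion.

NOx is treated throughout as the mass-concentration sum NO + NO₂ in μg/m³.
The NO/NOx ratio — the fraction of NOx still present as unoxidized NO —
indexes how fresh the emissions are: values near 1 mean strong nearby
sources with little time for oxidation, values near 0.5 mean well-aged air.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    EmptyZoneError,
    InsufficientDataError,
    PortAirError,
    SiteMeta,
    TimeSeries,
)

# ---------------------------------------------------------------------------
# reference campaign statistics
# ---------------------------------------------------------------------------

#: Published per-site descriptive statistics (μg/m³) from a 17-site,
#: two-terminal container-port campaign (autumn, three weeks; columns are
#: 25th percentile, median, mean, 75th percentile, SD for NO then NO₂).
#: Used as printed input for site-level NOx and NO/NOx ratio summaries.
CAMPAIGN_SITE_STATS = pd.read_csv(StringIO("""\
site_id,no_p25,no_median,no_mean,no_p75,no_sd,no2_p25,no2_median,no2_mean,no2_p75,no2_sd
1,9.11,14.47,47.36,29.35,104.41,30.75,40.39,41.86,51.87,16.31
2,50.52,102.24,169.68,193.50,212.35,31.57,48.38,47.13,60.27,20.15
3,30.42,67.13,136.97,148.47,207.79,28.29,45.51,45.21,59.66,23.06
4,32.43,97.95,188.85,233.43,252.61,29.11,47.36,49.77,67.45,28.03
5,36.45,65.26,119.58,127.57,161.76,55.35,75.65,76.84,94.51,28.60
6,31.89,76.51,120.64,165.09,130.24,54.74,78.52,76.56,96.97,31.07
7,23.45,34.17,79.07,74.37,130.56,33.62,42.44,42.88,50.43,12.75
8,98.89,194.97,289.78,367.16,293.95,60.27,79.54,80.30,99.02,28.50
9,18.09,45.29,98.75,116.98,160.07,31.16,42.64,43.05,53.51,17.94
10,28.14,61.51,107.89,124.89,156.11,38.13,58.84,58.54,75.44,27.14
11,69.81,75.98,105.56,96.48,80.39,33.83,53.10,55.05,71.96,27.51
12,90.72,96.08,136.40,119.66,104.10,26.45,34.65,36.31,44.08,13.89
13,38.86,81.07,175.83,216.04,221.01,83.03,122.80,121.08,155.80,51.04
14,39.93,71.42,162.58,168.04,242.09,56.99,81.18,80.29,100.66,31.28
15,99.43,153.83,222.55,266.49,194.26,86.51,119.11,118.79,147.60,41.04
16,76.78,99.83,170.71,196.04,172.43,29.73,56.58,54.93,77.49,30.85
17,71.02,93.00,95.46,106.93,66.49,33.42,52.07,52.74,69.70,26.93
"""), dtype={"site_id": str})


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    """25th percentile, median, mean, 75th percentile, SD, sample count."""

    p25: float
    median: float
    mean: float
    p75: float
    sd: float
    n: int

    def as_row(self) -> dict:
        return {
            "p25": self.p25, "median": self.median, "mean": self.mean,
            "p75": self.p75, "sd": self.sd, "n": self.n,
        }


@dataclass
class DiurnalProfile:
    """Mean concentration and sample count per hour of local day (24 bins)."""

    mean: pd.Series  # index 0..23, NaN where a bin has no samples
    count: pd.Series

    def argmax_hour(self) -> int:
        return int(self.mean.idxmax())


def _values(ts) -> np.ndarray:
    if isinstance(ts, TimeSeries):
        arr = ts.values.to_numpy()
    elif isinstance(ts, pd.Series):
        arr = ts.to_numpy(float)
    else:
        arr = np.asarray(ts, float)
    return arr[np.isfinite(arr)]


def descriptive_stats(ts) -> SummaryStats:
    """Quantiles (linear interpolation between order statistics), mean, and
    sample SD (N−1 denominator) of the non-missing values."""
    vals = _values(ts)
    if len(vals) < 2:
        raise InsufficientDataError("descriptive statistics need >= 2 values")
    p25, med, p75 = np.quantile(vals, [0.25, 0.5, 0.75])
    return SummaryStats(
        p25=float(p25),
        median=float(med),
        mean=float(vals.mean()),
        p75=float(p75),
        sd=float(vals.std(ddof=1)),
        n=int(len(vals)),
    )


# ---------------------------------------------------------------------------
# NOx arithmetic
# ---------------------------------------------------------------------------


def nox_total(no_mean: float, no2_mean: float) -> float:
    """Mass-concentration NOx = NO + NO₂ (both μg/m³)."""
    if no_mean < 0 or no2_mean < 0:
        raise PortAirError("concentrations must be non-negative")
    return float(no_mean + no2_mean)


def no_nox_ratio(no_mean: float, no2_mean: float) -> float:
    """Fraction of NOx present as NO: NO / (NO + NO₂)."""
    if no_mean < 0 or no2_mean < 0:
        raise PortAirError("concentrations must be non-negative")
    total = no_mean + no2_mean
    if total == 0:
        raise PortAirError("NO/NOx ratio undefined when NO + NO2 = 0")
    return float(no_mean / total)


def site_nox_table(stats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-site NOx mean and NO/NOx ratio from a site-statistics table.

    ``nox_mean_rounded`` rounds to the nearest integer and ``no_nox_1dp``
    to one decimal, the granularities these quantities are reported at.
    """
    df = (stats if stats is not None else CAMPAIGN_SITE_STATS).copy()
    df["nox_mean"] = [
        nox_total(a, b) for a, b in zip(df["no_mean"], df["no2_mean"])
    ]
    df["no_nox"] = [
        no_nox_ratio(a, b) for a, b in zip(df["no_mean"], df["no2_mean"])
    ]
    df["nox_mean_rounded"] = df["nox_mean"].round().astype(int)
    df["no_nox_1dp"] = df["no_nox"].round(1)
    return df[["site_id", "no_mean", "no2_mean", "nox_mean",
               "nox_mean_rounded", "no_nox", "no_nox_1dp"]]


# ---------------------------------------------------------------------------
# diurnal profiles and zone averages
# ---------------------------------------------------------------------------


def diurnal_profile(ts: TimeSeries | Sequence[TimeSeries]) -> DiurnalProfile:
    """Per-hour-of-day mean over all days (pooling sites when a sequence is
    given). Expects hourly, local-time series; bins with no samples are NaN."""
    series = [ts] if isinstance(ts, TimeSeries) else list(ts)
    pooled = pd.concat([s.values for s in series])
    hours = pooled.index.hour
    grouped = pooled.groupby(hours)
    mean = grouped.mean().reindex(range(24))
    count = grouped.count().reindex(range(24), fill_value=0)
    return DiurnalProfile(mean=mean, count=count)


def zone_average(
    series: Sequence[TimeSeries],
    meta: Sequence[SiteMeta],
    zone: str,
    pollutants: Sequence[str] = ("NO", "NO2"),
    mode: str = "pooled",
) -> SummaryStats:
    """Summary statistics of a functional zone across its member sites.

    ``mode="pooled"`` (default) concatenates all samples of the zone's
    sites; ``mode="site_means"`` computes statistics over the per-site mean
    concentrations instead. ``pollutants`` selects which channels enter
    (both by default, i.e. zone NOx when each site carries NO and NO₂).
    """
    zone_sites = {m.site_id for m in meta if m.zone == zone}
    if not zone_sites:
        raise EmptyZoneError(f"no site in zone {zone!r}")
    member = [
        s for s in series if s.site_id in zone_sites and s.pollutant in pollutants
    ]
    if not member:
        raise EmptyZoneError(f"no series for zone {zone!r}")
    if mode == "pooled":
        return descriptive_stats(pd.concat([s.values for s in member]))
    if mode == "site_means":
        means = [float(s.dropna().mean()) for s in member]
        return descriptive_stats(np.asarray(means))
    raise PortAirError(f"unknown zone_average mode {mode!r}")


def zone_nox_means(
    series: Sequence[TimeSeries], meta: Sequence[SiteMeta], mode: str = "pooled"
) -> pd.Series:
    """Mean NOx (NO + NO₂ pooled samples) per functional zone, sorted
    descending — the zone concentration ranking."""
    zones = sorted({m.zone for m in meta})
    means = {z: zone_average(series, meta, z, mode=mode).mean for z in zones}
    return pd.Series(means).sort_values(ascending=False)


def site_stats_table(series: Sequence[TimeSeries]) -> pd.DataFrame:
    """Per-site, per-pollutant descriptive statistics in the campaign-table
    layout (one row per site; NO and NO₂ column blocks)."""
    rows: dict[str, dict] = {}
    for ts in series:
        st = descriptive_stats(ts)
        prefix = "no" if ts.pollutant == "NO" else "no2"
        row = rows.setdefault(ts.site_id, {"site_id": ts.site_id})
        for key, val in st.as_row().items():
            if key != "n":
                row[f"{prefix}_{key}"] = val
    return pd.DataFrame(list(rows.values()))


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

MOLAR_MASS = {"NO": 30.006, "NO2": 46.0055}  # g/mol
R_L_ATM = 0.082057  # L·atm/(mol·K)


def ppb_to_ugm3(
    value: float, gas: str, temperature_c: float = 20.0, pressure_atm: float = 1.0
) -> float:
    """Convert a mixing ratio in ppb to μg/m³ via the ideal-gas molar volume.

    μg/m³ = ppb × MW / (R·T/P); at 20 °C and 1 atm the factors round to
    1.25 for NO and 1.91 for NO₂.
    """
    if gas not in MOLAR_MASS:
        raise PortAirError(f"unknown gas {gas!r}")
    if value < 0:
        raise PortAirError("mixing ratio must be >= 0")
    if temperature_c <= -273.15:
        raise PortAirError("temperature below absolute zero")
    molar_volume_l = R_L_ATM * (temperature_c + 273.15) / pressure_atm
    return float(value * MOLAR_MASS[gas] / molar_volume_l)


def ugm3_per_ppb(gas: str, temperature_c: float = 20.0, pressure_atm: float = 1.0) -> float:
    """Conversion factor μg/m³ per ppb for one gas."""
    return ppb_to_ugm3(1.0, gas, temperature_c, pressure_atm)


# ---------------------------------------------------------------------------
# plots (optional; used by the CLI `summarize --plot`)
# ---------------------------------------------------------------------------


def plot_site_ratios(table: pd.DataFrame, path) -> None:
    """Bar chart of per-site NO and NOx means with the NO/NOx ratio line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    x = np.arange(len(table))
    ax.bar(x - 0.2, table["no_mean"], width=0.4, label="NO", color="#4878d0")
    ax.bar(x + 0.2, table["nox_mean"], width=0.4, label="NOx", color="#ee854a")
    ax.set_xticks(x, table["site_id"])
    ax.set_xlabel("site")
    ax.set_ylabel("mean concentration (μg/m³)")
    ax2 = ax.twinx()
    ax2.plot(x, table["no_nox"], "k.-", label="NO/NOx")
    ax2.set_ylabel("NO/NOx ratio")
    ax2.set_ylim(0, 1)
    ax.legend(loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_diurnal(profiles: Mapping[str, DiurnalProfile], path) -> None:
    """Line plot of diurnal mean profiles, one line per label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, prof in profiles.items():
        ax.plot(prof.mean.index, prof.mean.to_numpy(), marker="o", ms=3, label=label)
    ax.set_xlabel("hour of day (local)")
    ax.set_ylabel("mean concentration (μg/m³)")
    ax.set_xticks(range(0, 24, 3))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
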