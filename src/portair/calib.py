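"""Field calibration of raw sensor signals and colocation validation metrics.

Low-cost electrochemical NO/NO₂ sensors respond linearly to concentration
but are confounded by temperature and relative humidity. Field calibration
runs a sensor beside a reference-grade analyzer and fits ordinary least
squares::

    ref ~ 1 + raw + temperature + relative_humidity

The fitted model maps raw readings (plus met covariates) to the reference
scale; calibrated concentrations are clipped at zero.

Deployment quality is scored with two metrics, implemented exactly in the
form used for sensor-network QA in this setting:

* ``rmse`` uses an N−1 denominator: sqrt(Σ(Sensorₜ−Refₜ)² / (N−1));
* ``r_squared`` is 1 − Σ(Sensorₜ−Refₜ)² / Σ(Sensorₜ−R̄ef)², where the
  denominator sums squared deviations of the *sensor* readings around the
  mean *reference* reading. This differs from the textbook R²; the
  conventional squared Pearson correlation is available behind
  ``convention="pearson"`` as a sanity check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import (
    AlignmentError,
    DegenerateDesignError,
    InsufficientDataError,
    MetSeries,
    TimeSeries,
    UndefinedMetricError,
    align_series,
)

#: minimum paired colocation coverage for a calibration fit
MIN_CALIBRATION_HOURS = 48.0

_COLUMNS = ("raw", "temperature", "rh")


@dataclass
class CalibrationModel:
    """Fitted linear calibration for one sensor channel."""

    intercept: float
    coef_signal: float
    coef_temperature: float
    coef_rh: float
    fit_window: tuple[pd.Timestamp, pd.Timestamp]
    n_obs: int
    stderr: dict[str, float]
    conf_int: dict[str, tuple[float, float]]  # 95 % intervals

    def predict(self, raw: pd.Series, temperature: pd.Series, rh: pd.Series) -> pd.Series:
        return (
            self.intercept
            + self.coef_signal * raw
            + self.coef_temperature * temperature
            + self.coef_rh * rh
        )

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef_signal": self.coef_signal,
            "coef_temperature": self.coef_temperature,
            "coef_rh": self.coef_rh,
            "fit_window": [str(self.fit_window[0]), str(self.fit_window[1])],
            "n_obs": self.n_obs,
            "stderr": self.stderr,
            "conf_int": {k: list(v) for k, v in self.conf_int.items()},
        }


@dataclass
class ValidationMetrics:
    """Colocation agreement between a sensor channel and its reference."""

    r2: float
    rmse: float
    n: int


def _paired_frame(
    raw: TimeSeries, met: MetSeries, ref: TimeSeries,
    window: tuple | None = None,
) -> pd.DataFrame:
    raw_v, temp, rh, ref_v = align_series(
        raw.values, met.temperature, met.relative_humidity, ref.values
    )
    df = pd.DataFrame(
        {"raw": raw_v, "temperature": temp, "rh": rh, "ref": ref_v}
    ).dropna()
    if window is not None:
        start, end = (pd.Timestamp(t) for t in window)
        if start.tz is None:
            start = start.tz_localize(df.index.tz)
        if end.tz is None:
            end = end.tz_localize(df.index.tz)
        df = df[(df.index >= start) & (df.index < end)]
    return df


def fit_calibration(
    raw: TimeSeries,
    met: MetSeries,
    ref: TimeSeries,
    window: tuple | None = None,
    min_hours: float = MIN_CALIBRATION_HOURS,
) -> CalibrationModel:
    """OLS fit of ``ref ~ 1 + raw + T + RH`` over the paired colocation window.

    Requires at least ``min_hours`` of paired non-missing data (48 h by
    default, the minimum duration of a colocation comparison period).
    Raises :class:`DegenerateDesignError` naming the offending column when
    the design is rank-deficient (e.g. constant RH).
    """
    df = _paired_frame(raw, met, ref, window)
    if len(df) < 2:
        raise InsufficientDataError("no paired samples in calibration window")
    step_h = (df.index[1] - df.index[0]).total_seconds() / 3600.0 if len(df) > 1 else 1.0
    step_h = {"minute": 1 / 60, "hour": 1.0}.get(raw.cadence, step_h)
    if len(df) * step_h < min_hours:
        raise InsufficientDataError(
            f"calibration needs >= {min_hours:g} h of paired data, "
            f"got {len(df) * step_h:.1f} h"
        )
    X = df[list(_COLUMNS)]
    for col in _COLUMNS:
        if np.ptp(X[col].to_numpy()) == 0:
            raise DegenerateDesignError(f"calibration covariate {col!r} is constant")
    design = sm.add_constant(X.to_numpy())
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateDesignError("calibration design is rank-deficient")
    fit = sm.OLS(df["ref"].to_numpy(), design).fit()
    names = ("const",) + _COLUMNS
    ci = fit.conf_int(alpha=0.05)
    return CalibrationModel(
        intercept=float(fit.params[0]),
        coef_signal=float(fit.params[1]),
        coef_temperature=float(fit.params[2]),
        coef_rh=float(fit.params[3]),
        fit_window=(df.index[0], df.index[-1]),
        n_obs=int(fit.nobs),
        stderr={n: float(se) for n, se in zip(names, fit.bse)},
        conf_int={n: (float(lo), float(hi)) for n, (lo, hi) in zip(names, ci)},
    )


def apply_calibration(
    model: CalibrationModel, raw: TimeSeries, met: MetSeries
) -> TimeSeries:
    """Map raw readings to the reference scale; negative results clip to 0,
    missing values propagate."""
    if not raw.values.index.equals(met.index):
        raise AlignmentError("met series must cover the raw series grid")
    predicted = model.predict(raw.values, met.temperature, met.relative_humidity)
    return raw.with_values(predicted.clip(lower=0.0))


# ---------------------------------------------------------------------------
# validation metrics
# ---------------------------------------------------------------------------


def _paired_arrays(sensor, ref) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sensor, TimeSeries):
        sensor = sensor.values
    if isinstance(ref, TimeSeries):
        ref = ref.values
    if isinstance(sensor, pd.Series) and isinstance(ref, pd.Series):
        sensor, ref = align_series(sensor, ref)
        mask = sensor.notna() & ref.notna()
        return sensor[mask].to_numpy(), ref[mask].to_numpy()
    s = np.asarray(sensor, float)
    r = np.asarray(ref, float)
    if s.shape != r.shape:
        raise AlignmentError("sensor and reference arrays differ in length")
    mask = np.isfinite(s) & np.isfinite(r)
    return s[mask], r[mask]


def rmse(sensor, ref) -> float:
    """Root mean squared error with the N−1 denominator:
    sqrt(Σ(Sensorₜ − Refₜ)² / (N−1))."""
    s, r = _paired_arrays(sensor, ref)
    n = len(s)
    if n < 2:
        raise InsufficientDataError("rmse needs at least 2 paired samples")
    return float(np.sqrt(np.sum((s - r) ** 2) / (n - 1)))


def r_squared(sensor, ref, convention: str = "as_deployed") -> float:
    """Coefficient of determination for sensor-vs-reference agreement.

    ``"as_deployed"`` (default): 1 − Σ(Sensorₜ−Refₜ)² / Σ(Sensorₜ−R̄ef)²
    with R̄ef the mean reference reading — deviations of the *sensor* values
    around the *reference* mean in the denominator. Can be negative for poor
    fits. ``"pearson"`` returns the squared Pearson correlation instead.
    """
    s, r = _paired_arrays(sensor, ref)
    if len(s) < 2:
        raise InsufficientDataError("r_squared needs at least 2 paired samples")
    if convention == "pearson":
        if np.std(s) == 0 or np.std(r) == 0:
            raise UndefinedMetricError("constant series: correlation undefined")
        return float(np.corrcoef(s, r)[0, 1] ** 2)
    if convention != "as_deployed":
        raise UndefinedMetricError(f"unknown r_squared convention {convention!r}")
    denom = float(np.sum((s - np.mean(r)) ** 2))
    if denom == 0:
        raise UndefinedMetricError("zero denominator in r_squared")
    return float(1.0 - np.sum((s - r) ** 2) / denom)


def validate_colocation(sensor: TimeSeries, ref: TimeSeries) -> ValidationMetrics:
    """Score a colocated sensor channel against its reference series."""
    s, r = _paired_arrays(sensor, ref)
    return ValidationMetrics(r2=r_squared(s, r), rmse=rmse(s, r), n=len(s))


# ---------------------------------------------------------------------------
# calibration-window screening
# ---------------------------------------------------------------------------

#: screening thresholds used as advisory practice, not hard preconditions
SCREEN_MIN_MAX_PPB = 50.0
SCREEN_MAX_RH = 80.0
SCREEN_TEMP_RANGE = (5.0, 35.0)


def screen_calibration_window(
    ref: TimeSeries, met: MetSeries, ugm3_per_ppb: float
) -> list[str]:
    """Check a candidate calibration window against deployment practice and
    return advisory warnings (never hard failures).

    Practice asks for a concentration span reaching above ~50 ppb, no
    sustained RH above 80 %, and temperatures within 5–35 °C.
    """
    notes: list[str] = []
    vals = ref.dropna()
    if len(vals) and vals.max() <= SCREEN_MIN_MAX_PPB * ugm3_per_ppb:
        notes.append(
            f"max concentration {vals.max():.1f} μg/m³ does not exceed "
            f"{SCREEN_MIN_MAX_PPB:g} ppb ({SCREEN_MIN_MAX_PPB * ugm3_per_ppb:.1f} μg/m³)"
        )
    rh = met.relative_humidity.dropna()
    if len(rh):
        frac_humid = float((rh > SCREEN_MAX_RH).mean())
        if frac_humid > 0.5:
            notes.append(
                f"RH above {SCREEN_MAX_RH:g}% for {100 * frac_humid:.0f}% of the window"
            )
    temp = met.temperature.dropna()
    if len(temp) and (
        temp.min() < SCREEN_TEMP_RANGE[0] or temp.max() > SCREEN_TEMP_RANGE[1]
    ):
        notes.append(
            f"temperature range [{temp.min():.1f}, {temp.max():.1f}] °C leaves "
            f"the {SCREEN_TEMP_RANGE} °C screening band"
        )
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return notes
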