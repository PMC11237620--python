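"""Consumption, growth and coupling kinetics for sealed-bottle incubations.

Quantities computed here are the standard descriptors of an N2O-respiring
culture: net amounts consumed over a window, per-cell reduction rates,
exponential growth rates from OD600, the ordinary-least-squares coupling
between cumulative donor oxidation and cumulative N2O reduction, and
fold-change rate enhancements between treatments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    ArgumentError,
    ConfigurationError,
    DegenerateFitError,
    ValidationError,
)
from .gas_partition import VesselConditions


@dataclass(frozen=True)
class IncubationSeries:
    """Time-indexed measurements for one culture vessel.

    Arrays are aligned on ``times`` (hours, strictly increasing). Missing
    measurements are NaN and are skipped, never treated as zero. Amounts
    are µmol; OD600 is dimensionless.
    """

    times: np.ndarray
    total_n2o: np.ndarray
    od600: np.ndarray
    donor: np.ndarray
    label: str = ""
    vessel: VesselConditions | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        for name in ("total_n2o", "od600", "donor"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != times.shape:
                raise ValidationError(f"{name} length {arr.size} != times length {times.size}")
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ValidationError(f"{name} contains negative values")
            object.__setattr__(self, name, arr)
        if times.size < 2:
            raise ValidationError("a series needs at least 2 timepoints")
        if np.any(~np.isfinite(times)):
            raise ValidationError("times must be finite")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class KineticsReport:
    """Summary kinetics for one incubation.

    Fields that cannot be computed from the available data (per-cell rate
    without a cell-count conversion; coupling fit with fewer than three
    paired points) are None rather than guessed.
    """

    n2o_consumed: float
    donor_consumed: float | None
    od_increase: float | None
    growth_rate: float | None
    mean_rate_per_cell: float | None
    coupling_slope: float | None
    coupling_intercept: float | None
    coupling_r2: float | None

    def to_dict(self) -> dict:
        return {
            "n2o_consumed_umol": self.n2o_consumed,
            "donor_consumed_umol": self.donor_consumed,
            "od_increase": self.od_increase,
            "growth_rate_per_h": self.growth_rate,
            "mean_rate_umol_per_h_per_cell": self.mean_rate_per_cell,
            "coupling_slope": self.coupling_slope,
            "coupling_intercept": self.coupling_intercept,
            "coupling_r2": self.coupling_r2,
        }


def consumption(initial_amount: float, final_amount: float) -> float:
    """Net amount consumed: initial minus final (µmol).

    Antisymmetric; a negative value means net production and is returned
    with a warning rather than raised.
    """
    if initial_amount < 0 or final_amount < 0:
        raise ArgumentError("amounts must be >= 0")
    consumed = initial_amount - final_amount
    if consumed < 0:
        warnings.warn(
            f"negative consumption ({consumed:g} µmol): net production over the window",
            stacklevel=2,
        )
    return consumed


def exponential_growth_rate(od_initial: float, od_final: float, interval: float) -> float:
    """Two-point exponential growth rate µ = ln(OD_f/OD_i)/Δt, h⁻¹."""
    if od_initial <= 0 or od_final <= 0:
        raise ArgumentError("OD600 values must be > 0 for a log growth rate")
    if interval <= 0:
        raise ArgumentError(f"interval must be > 0 h, got {interval}")
    return math.log(od_final / od_initial) / interval


def fit_growth_rate(
    times: Sequence[float], od600: Sequence[float]
) -> tuple[float, float, float]:
    """Least-squares fit of ln(OD600) against time over a chosen window.

    Returns ``(growth_rate, intercept, r_squared)``. Pass only the window
    of points you consider exponential; the fit makes no attempt to detect
    lag or plateau phases.
    """
    t = np.asarray(times, dtype=float)
    od = np.asarray(od600, dtype=float)
    keep = np.isfinite(t) & np.isfinite(od)
    t, od = t[keep], od[keep]
    if t.size < 2:
        raise DegenerateFitError("growth fit needs at least 2 finite points")
    if np.any(od <= 0):
        raise ArgumentError("OD600 values must be > 0 for a log-linear fit")
    if np.ptp(t) == 0:
        raise DegenerateFitError("growth fit needs time variance")
    if t.size == 2:
        mu = exponential_growth_rate(od[0], od[1], t[1] - t[0])
        return mu, math.log(od[0]) - mu * t[0], 1.0
    fit = stats.linregress(t, np.log(od))
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def od_to_cells(
    od600: float, cells_per_ml_per_od: float | None, liquid_volume_ml: float
) -> float:
    """Convert an OD600 reading to a cell count for one vessel.

    The conversion factor is an empirical property of the strain and
    spectrophotometer and has no safe default; omitting it is a
    configuration error, not a fallback.
    """
    if cells_per_ml_per_od is None:
        raise ConfigurationError(
            "cells_per_ml_per_od is required to convert OD600 to cell counts"
        )
    if cells_per_ml_per_od <= 0 or liquid_volume_ml <= 0:
        raise ArgumentError("conversion factor and volume must be > 0")
    if od600 < 0:
        raise ArgumentError(f"od600 must be >= 0, got {od600}")
    return od600 * cells_per_ml_per_od * liquid_volume_ml


def mean_rate_per_cell(
    n2o_consumed: float, interval: float, mean_cell_count: float
) -> float:
    """Average per-cell N2O reduction rate, µmol h⁻¹ cell⁻¹.

    ``mean_cell_count`` is the time-averaged population over the window:
    the arithmetic mean of the endpoint counts, or a trapezoidal average
    when a full series is available (see :func:`trapezoidal_mean`).
    """
    if interval <= 0:
        raise ArgumentError(f"interval must be > 0 h, got {interval}")
    if mean_cell_count <= 0:
        raise ArgumentError(f"mean_cell_count must be > 0, got {mean_cell_count}")
    return n2o_consumed / (interval * mean_cell_count)


def trapezoidal_mean(times: Sequence[float], values: Sequence[float]) -> float:
    """Time-weighted (trapezoidal) mean of a sampled quantity."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(t) & np.isfinite(v)
    t, v = t[keep], v[keep]
    if t.size < 2:
        raise DegenerateFitError("trapezoidal mean needs at least 2 finite points")
    span = t[-1] - t[0]
    if span <= 0:
        raise ArgumentError("times must span a positive interval")
    return float(np.trapezoid(v, t) / span)


def coupling_regression(
    donor_consumed_series: Sequence[float], n2o_consumed_series: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of cumulative N2O consumed on cumulative donor consumed.

    Returns ``(slope, intercept, r_squared)``; the slope is the observed
    mol N2O per mol donor coupling ratio. Order-invariant, as any OLS fit.
    """
    x = np.asarray(donor_consumed_series, dtype=float)
    y = np.asarray(n2o_consumed_series, dtype=float)
    if x.shape != y.shape:
        raise ArgumentError("series must have equal lengths")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise DegenerateFitError("coupling regression needs at least 3 paired points")
    if np.ptp(x) == 0:
        raise DegenerateFitError("donor series has zero variance")
    fit = stats.linregress(x, y)
    r2 = 1.0 if np.allclose(y, fit.intercept + fit.slope * x) else float(fit.rvalue**2)
    return float(fit.slope), float(fit.intercept), min(max(r2, 0.0), 1.0)


def rate_enhancement(rate_treatment: float, rate_control: float) -> float:
    """Fold-change of a treatment rate over its control (full precision).

    The reporting convention rounds to 1 decimal place.
    """
    if rate_control <= 0:
        raise ArgumentError(f"rate_control must be > 0, got {rate_control}")
    if rate_treatment < 0:
        raise ArgumentError(f"rate_treatment must be >= 0, got {rate_treatment}")
    return rate_treatment / rate_control


def _window_mask(times: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones_like(times, dtype=bool)
    lo, hi = window
    if hi <= lo:
        raise ArgumentError(f"window must satisfy start < end, got {window}")
    return (times >= lo) & (times <= hi)


def analyze_series(
    series: IncubationSeries,
    *,
    cells_per_ml_per_od: float | None = None,
    growth_window: tuple[float, float] | None = None,
    rate_window: tuple[float, float] | None = None,
) -> KineticsReport:
    """Full kinetics summary for one incubation series.

    Consumption totals use the first/last finite measurement inside
    ``rate_window`` (whole series by default). Growth is a log-linear fit
    over ``growth_window``. The per-cell rate is computed only when the
    OD-to-cell conversion factor and a vessel are available; the mean cell
    count is trapezoidal over the window when >2 OD points exist, else the
    endpoint mean. Timepoints missing N2O are excluded from consumption
    windows but retained for growth fitting.
    """
    rmask = _window_mask(series.times, rate_window)

    def _endpoints(values: np.ndarray) -> tuple[float, float, float, float] | None:
        ok = np.isfinite(values) & rmask
        if ok.sum() < 2:
            return None
        idx = np.flatnonzero(ok)
        return (
            float(values[idx[0]]),
            float(values[idx[-1]]),
            float(series.times[idx[0]]),
            float(series.times[idx[-1]]),
        )

    n2o_ep = _endpoints(series.total_n2o)
    if n2o_ep is None:
        raise ValidationError("need at least 2 finite N2O measurements in the window")
    n2o_consumed = consumption(n2o_ep[0], n2o_ep[1])

    donor_ep = _endpoints(series.donor)
    donor_consumed = None if donor_ep is None else consumption(donor_ep[0], donor_ep[1])

    gmask = _window_mask(series.times, growth_window) & np.isfinite(series.od600)
    od_increase = growth_rate = None
    if gmask.sum() >= 2:
        idx = np.flatnonzero(gmask)
        od_increase = float(series.od600[idx[-1]] - series.od600[idx[0]])
        if np.all(series.od600[gmask] > 0):
            growth_rate, _, _ = fit_growth_rate(
                series.times[gmask], series.od600[gmask]
            )

    per_cell = None
    if cells_per_ml_per_od is not None and series.vessel is not None:
        omask = rmask & np.isfinite(series.od600)
        if omask.sum() >= 2:
            volume_ml = series.vessel.liquid_volume * 1000.0
            counts = np.array(
                [
                    od_to_cells(od, cells_per_ml_per_od, volume_ml)
                    for od in series.od600[omask]
                ]
            )
            t_od = series.times[omask]
            mean_cells = (
                trapezoidal_mean(t_od, counts)
                if counts.size > 2
                else float((counts[0] + counts[-1]) / 2.0)
            )
            per_cell = mean_rate_per_cell(n2o_consumed, n2o_ep[3] - n2o_ep[2], mean_cells)

    slope = intercept = r2 = None
    paired = np.isfinite(series.total_n2o) & np.isfinite(series.donor) & rmask
    if paired.sum() >= 3:
        d0 = series.donor[paired][0]
        q0 = series.total_n2o[paired][0]
        donor_cum = d0 - series.donor[paired]
        n2o_cum = q0 - series.total_n2o[paired]
        if np.ptp(donor_cum) > 0:
            slope, intercept, r2 = coupling_regression(donor_cum, n2o_cum)

    return KineticsReport(
        n2o_consumed=n2o_consumed,
        donor_consumed=donor_consumed,
        od_increase=od_increase,
        growth_rate=growth_rate,
        mean_rate_per_cell=per_cell,
        coupling_slope=slope,
        coupling_intercept=intercept,
        coupling_r2=r2,
    )
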