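"""One-step infection kinetics: latent period, burst sizes, production rates.

All estimators follow the operational definitions used for one-step infection
experiments in algal host-virus systems:

* latent period — the interval ending at the first timepoint where free virus
  counts rise by at least 10% over the previous timepoint;
* particle/genome burst size — maximum increase in virus particles (or genome
  copies) divided by the maximum decline in host cells (lysed cells);
* maximum production rate — steepest ordinary-least-squares slope over any
  window of consecutive timepoints;
* host growth rate — steepest slope of ln(host) vs time, in d^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SeriesTable

__all__ = [
    "LatentInterval",
    "RegressionWindow",
    "KineticsResult",
    "detect_latent_period",
    "particle_burst_size",
    "genome_burst_size",
    "max_production_rate",
    "host_growth_rate",
    "analyze_table",
]


@dataclass(frozen=True)
class LatentInterval:
    """Half-open latent-period interval (t_start, t_end]: first progeny release
    happened somewhere after t_start and was visible by t_end."""

    t_start: float
    t_end: float

    def __contains__(self, t: float) -> bool:
        return self.t_start < t <= self.t_end


@dataclass(frozen=True)
class RegressionWindow:
    """An OLS fit over the consecutive-timepoint window [t_start, t_end]."""

    slope: float
    t_start: float
    t_end: float
    r_squared: float
    n_points: int


@dataclass
class KineticsResult:
    """Per-series kinetic estimates (fields absent when not applicable)."""

    treatment: str
    replicate: str
    analyte: str
    latent_interval: LatentInterval | None = None
    particle_burst: float | None = None
    genome_burst: float | None = None
    max_rate: RegressionWindow | None = None
    host_growth_rate: float | None = None
    lysis_window: tuple[float, float] | None = None


def _check_series(times: Sequence[float], values: Sequence[float], min_n: int = 3):
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if t.size != v.size:
        raise ValueError("times and values must have equal length")
    if t.size < min_n:
        raise ValueError(f"need >= {min_n} timepoints, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t, v


def detect_latent_period(
    times: Sequence[float],
    values: Sequence[float],
    threshold: float = 0.10,
    sustained_check: bool = False,
) -> LatentInterval | None:
    """First interval over which virus counts rise by >= ``threshold``.

    Returns ``(t_{k-1}, t_k]`` for the smallest k with
    ``V_k >= (1 + threshold) * V_{k-1}`` (the "at least 10%" rule is
    inclusive), or ``None`` when no such rise occurs.  With
    ``sustained_check`` the following timepoint must also be non-decreasing,
    which guards against one-point noise spikes.
    """
    t, v = _check_series(times, values, min_n=2)
    if np.any(v <= 0):
        raise ValueError("virus counts must be > 0 for ratio-based detection")
    for k in range(1, len(v)):
        # tiny relative slack keeps the "at least 10%" boundary inclusive
        # under floating-point rounding (e.g. 110 vs 1.1 * 100)
        if v[k] >= (1.0 + threshold) * v[k - 1] * (1.0 - 1e-12):
            if sustained_check and k + 1 < len(v) and v[k + 1] < v[k]:
                continue
            return LatentInterval(float(t[k - 1]), float(t[k]))
    return None


def _lysed_cells(host_values: np.ndarray) -> tuple[float, int, int]:
    """Maximum decline: peak host count minus the minimum after the peak."""
    i_peak = int(np.argmax(host_values))
    after = host_values[i_peak:]
    i_min = i_peak + int(np.argmin(after))
    return float(host_values[i_peak] - host_values[i_min]), i_peak, i_min


def _baseline(
    times: np.ndarray, values: np.ndarray, latent: LatentInterval | None
) -> float:
    """Pre-rise baseline: min over [0, latent end]; V(t0) when no rise found."""
    if latent is None:
        return float(values[0])
    mask = times <= latent.t_end
    return float(values[mask].min())


def _burst_size(
    series_times: Sequence[float],
    series_values: Sequence[float],
    host_times: Sequence[float],
    host_values: Sequence[float],
    latent: LatentInterval | None,
) -> float:
    st, sv = _check_series(series_times, series_values, min_n=2)
    ht, hv = _check_series(host_times, host_values, min_n=2)
    lysed, i_peak, i_min = _lysed_cells(hv)
    if lysed <= 0:
        raise ValueError("no lysis detected: host count never declines")
    produced = float(sv.max()) - _baseline(st, sv, latent)
    return max(produced, 0.0) / lysed


def particle_burst_size(
    virus_times: Sequence[float],
    virus_values: Sequence[float],
    host_times: Sequence[float],
    host_values: Sequence[float],
    latent_threshold: float = 0.10,
) -> float:
    """Viruses produced per lysed host cell (B_p)."""
    st, sv = np.asarray(virus_times, float), np.asarray(virus_values, float)
    latent = (
        detect_latent_period(st, sv, latent_threshold) if np.all(sv > 0) else None
    )
    return _burst_size(virus_times, virus_values, host_times, host_values, latent)


def genome_burst_size(
    copy_times: Sequence[float],
    copy_values: Sequence[float],
    host_times: Sequence[float],
    host_values: Sequence[float],
    latent_threshold: float = 0.10,
) -> float:
    """Genome copies produced per lysed host cell (B_g)."""
    st, sv = np.asarray(copy_times, float), np.asarray(copy_values, float)
    latent = (
        detect_latent_period(st, sv, latent_threshold) if np.all(sv > 0) else None
    )
    return _burst_size(copy_times, copy_values, host_times, host_values, latent)


def _ols_window(t: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Slope and r^2 of OLS v ~ t (closed form; windows are tiny)."""
    tm, vm = t.mean(), v.mean()
    dt, dv = t - tm, v - vm
    sxx = float(dt @ dt)
    sxy = float(dt @ dv)
    syy = float(dv @ dv)
    slope = sxy / sxx
    r2 = 1.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return slope, r2


def max_production_rate(
    times: Sequence[float],
    values: Sequence[float],
    min_window_points: int = 3,
) -> RegressionWindow:
    """Steepest-slope linear fit over all windows of consecutive timepoints.

    Every window of at least ``min_window_points`` consecutive timepoints is
    fitted by OLS; the window with the maximum slope wins, ties broken toward
    the earliest (then shortest) window.
    """
    t, v = _check_series(times, values, min_n=min_window_points)
    best: RegressionWindow | None = None
    n = len(t)
    for i in range(n - min_window_points + 1):
        for j in range(i + min_window_points, n + 1):
            slope, r2 = _ols_window(t[i:j], v[i:j])
            if best is None:
                best = RegressionWindow(slope, float(t[i]), float(t[j - 1]), r2, j - i)
                continue
            tol = 1e-9 * max(1.0, abs(best.slope))
            if slope > best.slope + tol:
                best = RegressionWindow(slope, float(t[i]), float(t[j - 1]), r2, j - i)
            elif abs(slope - best.slope) <= tol and t[i] == best.t_start:
                # tie at the same start: report the longest such window
                best = RegressionWindow(slope, float(t[i]), float(t[j - 1]), r2, j - i)
    assert best is not None
    return best


def host_growth_rate(
    times_h: Sequence[float],
    host_values: Sequence[float],
    min_window_points: int = 3,
) -> RegressionWindow:
    """Exponential growth rate mu (d^-1) from the steepest ln(H)-vs-time window.

    The returned window's ``slope`` is in d^-1; its time bounds stay in hours.
    """
    t, v = _check_series(times_h, host_values, min_n=min_window_points)
    if np.any(v <= 0):
        raise ValueError("host counts must be > 0 for log-linear growth fitting")
    w = max_production_rate(t, np.log(v), min_window_points=min_window_points)
    return RegressionWindow(w.slope * 24.0, w.t_start, w.t_end, w.r_squared, w.n_points)


def analyze_table(
    table: SeriesTable,
    min_window_points: int = 3,
    latent_threshold: float = 0.10,
    sustained_check: bool = False,
    control_treatment: str = "control",
) -> pd.DataFrame:
    """Run the full kinetics panel per (treatment, replicate, analyte).

    Burst sizes pair each virus/genome series with the host series of the
    same treatment and replicate; the host growth rate is reported for the
    control treatment's host series.
    """
    rows = []
    for treatment, replicate, analyte in table.groups():
        t, v = table.series(treatment, replicate, analyte)
        row: dict = {
            "treatment": treatment,
            "replicate": replicate,
            "analyte": analyte,
        }
        if len(t) >= min_window_points:
            w = max_production_rate(t, v, min_window_points)
            row.update(
                max_rate=w.slope,
                rate_window_start=w.t_start,
                rate_window_end=w.t_end,
                rate_r2=w.r_squared,
            )
        if analyte == "host_cells":
            if treatment == control_treatment and np.all(v > 0):
                row["host_growth_rate_per_day"] = host_growth_rate(
                    t, v, min_window_points
                ).slope
        else:
            if np.all(v > 0):
                latent = detect_latent_period(
                    t, v, latent_threshold, sustained_check
                )
                if latent is not None:
                    row["latent_start_h"] = latent.t_start
                    row["latent_end_h"] = latent.t_end
            ht, hv = table.series(treatment, replicate, "host_cells")
            if len(ht) >= 2:
                try:
                    burst = _burst_size(
                        t, v, ht, hv,
                        detect_latent_period(t, v, latent_threshold)
                        if np.all(v > 0) else None,
                    )
                except ValueError:
                    burst = np.nan
                key = (
                    "particle_burst" if analyte == "virus_particles" else "genome_burst"
                )
                row[key] = burst
        rows.append(row)
    return pd.DataFrame(rows)
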