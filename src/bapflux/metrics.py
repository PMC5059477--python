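"""Quantification of voltage and current traces.

Everything downstream reduces to a handful of measurements: action
potential shape metrics, statistics of the transient voltage difference
between a state pair, baseline-subtracted charge in a short window after
the spike peak (the standard 1-ms window starting 0.35 ms after the peak,
or a 5-ms variant for kinetics scans), percent changes between charges,
and mono-/biexponential decay fits.

Sign conventions: calcium currents are negative inward, so a more
negative charge means more influx; percent comparisons use magnitudes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .engine import CurrentRecord
from .trace import BAPStatePair, VoltageTrace

__all__ = [
    "APMetrics",
    "DifferenceStats",
    "ChargeMetric",
    "ExpFit",
    "ap_metrics",
    "difference_stats",
    "charge_window",
    "percent_change",
    "fit_exponentials",
    "metrics_frame",
]

#: dV/dt threshold defining the apparent spike onset (mV/ms); the value is
#: purely descriptive and configurable per call
DVDT_THRESHOLD = 20.0

#: length of the pre-rise stretch used for baseline estimates (ms)
BASELINE_MS = 2.0


@dataclass(frozen=True)
class APMetrics:
    """Shape metrics of a single action potential."""

    peak_mV: float
    peak_time_ms: float
    max_rate_of_rise: float      # mV/ms
    max_rise_time_ms: float
    apparent_threshold_mV: float
    half_duration_ms: float
    baseline_mV: float


@dataclass(frozen=True)
class DifferenceStats:
    """Statistics of the post-peak state-difference transient."""

    extremum_mV: float
    latency_after_peak_ms: float
    half_duration_ms: float


@dataclass(frozen=True)
class ChargeMetric:
    """Baseline-subtracted charge in a window referenced to the AP peak."""

    charge: float                # current x ms, sign preserved
    window_start_after_peak_ms: float
    window_length_ms: float
    reference_peak_time_ms: float
    baseline_current: float

    @property
    def magnitude(self) -> float:
        return abs(self.charge)


@dataclass(frozen=True)
class ExpFit:
    """Result of a mono- or biexponential decay fit."""

    taus: tuple[float, ...]              # ms, ordered fast -> slow
    amplitudes: tuple[float, ...]
    relative_weights: tuple[float, ...]  # %, sum to 100
    offset: float
    r_squared: float
    degenerate: bool = False


# -- crossings helper ------------------------------------------------------


def _cross_time(t0: float, t1: float, y0: float, y1: float,
                level: float) -> float:
    """Linear interpolation of the time where y crosses ``level``."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


# -- AP shape --------------------------------------------------------------


def ap_metrics(trace: VoltageTrace,
               dvdt_threshold: float = DVDT_THRESHOLD) -> APMetrics:
    """Measure one action potential in a voltage trace.

    The apparent threshold is the first sample where dV/dt exceeds
    ``dvdt_threshold``; the baseline is the mean voltage over the 2 ms
    before that point; the half-duration is the width at half of
    (peak - baseline), with interpolated crossings. Ties break to the
    earliest sample.
    """
    v = trace.samples
    dt = trace.dt
    dvdt = np.diff(v) / dt
    i_rise = int(np.argmax(dvdt))
    above = np.nonzero(dvdt > dvdt_threshold)[0]
    if above.size == 0:
        raise ValueError("no suprathreshold event found in trace")
    i_thr = int(above[0])
    i_peak = int(np.argmax(v))
    n_base = max(int(round(BASELINE_MS / dt)), 1)
    baseline = float(np.mean(v[max(i_thr - n_base, 0): max(i_thr, 1)]))
    peak = float(v[i_peak])
    level = baseline + 0.5 * (peak - baseline)
    t = trace.times
    # upward crossing before the peak
    pre = np.nonzero(v[: i_peak + 1] < level)[0]
    i_up = int(pre[-1]) if pre.size else 0
    t_up = _cross_time(t[i_up], t[i_up + 1], v[i_up], v[i_up + 1], level)
    # downward crossing after the peak
    post = np.nonzero(v[i_peak:] < level)[0]
    if post.size:
        j = i_peak + int(post[0])
        t_down = _cross_time(t[j - 1], t[j], v[j - 1], v[j], level)
    else:
        t_down = t[-1]
    return APMetrics(
        peak_mV=peak,
        peak_time_ms=float(t[i_peak]),
        max_rate_of_rise=float(dvdt[i_rise]),
        max_rise_time_ms=float(t[i_rise]),
        apparent_threshold_mV=float(v[i_thr]),
        half_duration_ms=float(t_down - t_up),
        baseline_mV=baseline,
    )


# -- state-difference transient -------------------------------------------


def difference_stats(pair: BAPStatePair,
                     search_ms: float = 5.0) -> DifferenceStats:
    """Statistics of the hyperpolarized-minus-depolarized transient.

    Restricted to the region after the depolarized-trace peak: the
    extremum of the difference within ``search_ms`` of the peak, its
    latency from the peak, and the width of the contiguous stretch around
    the extremum where the difference stays beyond half the extremum
    (interpolated edges). ``search_ms`` bounds the search to the fast
    transient; the slow late drift toward the baseline offset is a
    separate, uninteresting component.
    """
    i_d = pair.depolarized.max_rate_of_rise_index()
    i_h = pair.hyperpolarized.max_rate_of_rise_index()
    if i_d != i_h:
        raise ValueError("pair is not aligned at the maximum rate of rise")
    dt = pair.dt
    diff = pair.difference()
    i_peak = int(np.argmax(pair.depolarized.samples))
    i_end = min(i_peak + int(round(search_ms / dt)), diff.size)
    window = diff[i_peak:i_end]
    k = int(np.argmax(np.abs(window)))
    ext = float(window[k])
    if ext == 0.0:
        return DifferenceStats(0.0, 0.0, 0.0)
    half = 0.5 * ext
    sign = np.sign(ext)
    beyond = sign * window >= sign * half
    # walk outward from the extremum while still beyond the half level
    left = k
    while left > 0 and beyond[left - 1]:
        left -= 1
    right = k
    while right < window.size - 1 and beyond[right + 1]:
        right += 1
    t = dt * np.arange(window.size)
    t_left = (
        _cross_time(t[left - 1], t[left], window[left - 1], window[left], half)
        if left > 0 else t[0]
    )
    t_right = (
        _cross_time(t[right], t[right + 1], window[right], window[right + 1], half)
        if right < window.size - 1 else t[-1]
    )
    return DifferenceStats(
        extremum_mV=ext,
        latency_after_peak_ms=float(t[k]),
        half_duration_ms=float(t_right - t_left),
    )


# -- charge ----------------------------------------------------------------


def charge_window(
    record: CurrentRecord,
    window_start_after_peak_ms: float = 0.35,
    window_len_ms: float = 1.0,
    channel: str | None = None,
    dvdt_threshold: float = DVDT_THRESHOLD,
) -> ChargeMetric:
    """Baseline-subtracted charge in a window after the command AP peak.

    The baseline is the mean current over the 2 ms preceding the spike
    onset (apparent-threshold crossing of the command); the charge is the
    trapezoid integral of (I - baseline) over
    ``[t_peak + start, t_peak + start + length]``. More negative charge
    means more calcium influx.
    """
    if window_len_ms <= 0:
        raise ValueError("window length must be positive")
    cmd = record.command
    current = record.total if channel is None else record.per_channel[channel]
    dt = record.dt
    v = cmd.samples
    # reference the *last* sample at the command maximum: for
    # plateau-extended commands the repolarization starts at the end of
    # the constant peak-voltage stretch, and the window must track it
    i_peak = int(v.size - 1 - np.argmax(v[::-1]))
    dvdt = np.diff(v) / dt
    above = np.nonzero(dvdt[:i_peak + 1] > dvdt_threshold)[0]
    i_rise = int(above[0]) if above.size else i_peak
    n_base = max(int(round(BASELINE_MS / dt)), 1)
    baseline = float(np.mean(current[max(i_rise - n_base, 0): max(i_rise, 1)]))
    i0 = i_peak + int(round(window_start_after_peak_ms / dt))
    i1 = i0 + int(round(window_len_ms / dt))
    if i1 > current.size or i0 < 0:
        raise ValueError("charge window exceeds the trace")
    charge = float(np.trapezoid(current[i0:i1 + 1] - baseline, dx=dt))
    return ChargeMetric(
        charge=charge,
        window_start_after_peak_ms=window_start_after_peak_ms,
        window_length_ms=window_len_ms,
        reference_peak_time_ms=float(cmd.times[i_peak]),
        baseline_current=baseline,
    )


def percent_change(q_hyper: ChargeMetric | float,
                   q_depol: ChargeMetric | float) -> float:
    """Percent change of influx magnitude, hyperpolarized vs depolarized.

    ``100 * (|q_hyper| - |q_depol|) / |q_depol|``; positive when the
    hyperpolarized-state command drives more influx.
    """
    qh = q_hyper.magnitude if isinstance(q_hyper, ChargeMetric) else abs(q_hyper)
    qd = q_depol.magnitude if isinstance(q_depol, ChargeMetric) else abs(q_depol)
    if qd == 0.0:
        raise ZeroDivisionError("reference charge is zero")
    return 100.0 * (qh - qd) / qd


# -- exponential fitting ---------------------------------------------------


def _solve_amplitudes(t: np.ndarray, y: np.ndarray,
                      taus: np.ndarray) -> tuple[np.ndarray, float]:
    """Linear least squares for amplitudes and offset at fixed taus."""
    design = np.column_stack([np.exp(-t / tau) for tau in taus]
                             + [np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef[:-1], float(coef[-1])


def fit_exponentials(
    y: np.ndarray,
    dt: float,
    n_components: int = 2,
    window_ms: tuple[float, float] | None = None,
) -> ExpFit:
    """Fit ``y(t) = c + sum_i a_i exp(-t/tau_i)`` to a decay.

    Bounded least squares on log-spaced time constants with the
    amplitudes profiled out linearly (variable projection); three
    deterministic log-spaced starts guard against local minima of the
    biexponential. Components are ordered fast to slow and weights are
    the relative amplitude magnitudes in percent. Non-convergence raises;
    an essentially flat input is returned with ``degenerate=True``.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    y = np.asarray(y, dtype=float)
    if window_ms is not None:
        i0, i1 = (int(round(w / dt)) for w in window_ms)
        if not 0 <= i0 < i1 <= y.size:
            raise ValueError("fit window outside trace")
        y = y[i0:i1]
    if y.size < 10 * n_components:
        raise ValueError("need at least 10 samples per fitted component")
    t = dt * np.arange(y.size)
    span = t[-1]
    scale = float(np.max(np.abs(y - np.mean(y))))
    if scale < 1e-12 * max(1.0, float(np.max(np.abs(y)))) or scale == 0.0:
        return ExpFit(taus=(span,) * n_components,
                      amplitudes=(0.0,) * n_components,
                      relative_weights=(100.0 / n_components,) * n_components,
                      offset=float(np.mean(y)), r_squared=0.0, degenerate=True)

    def residual(log_taus: np.ndarray) -> np.ndarray:
        taus = np.exp(log_taus)
        amps, c = _solve_amplitudes(t, y, taus)
        model = c + sum(a * np.exp(-t / tau) for a, tau in zip(amps, taus))
        return model - y

    if n_components == 1:
        starts = [[span / 20.0], [span / 5.0], [span / 2.0]]
    else:
        starts = [[span / 50.0, span / 5.0],
                  [span / 20.0, span / 2.0],
                  [span / 100.0, span / 10.0]]
    lo, hi = np.log(dt / 10.0), np.log(span * 100.0)
    best = None
    for s in starts:
        res = least_squares(residual, np.log(s), bounds=(lo, hi), xtol=1e-12,
                            ftol=1e-12, gtol=1e-12)
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise RuntimeError("exponential fit did not converge")
    taus = np.exp(best.x)
    amps, c = _solve_amplitudes(t, y, taus)
    order = np.argsort(taus)
    taus, amps = taus[order], amps[order]
    model = c + sum(a * np.exp(-t / tau) for a, tau in zip(amps, taus))
    ss_res = float(np.sum((y - model) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    total_amp = float(np.sum(np.abs(amps)))
    weights = (
        tuple(100.0 * abs(a) / total_amp for a in amps)
        if total_amp > 0 else (100.0 / n_components,) * n_components
    )
    return ExpFit(
        taus=tuple(float(x) for x in taus),
        amplitudes=tuple(float(a) for a in amps),
        relative_weights=weights,
        offset=c,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0,
        degenerate=total_amp < 1e-9 * scale,
    )


# -- tabular export --------------------------------------------------------


def metrics_frame(items: Iterable, labels: Sequence[str] | None = None
                  ) -> pd.DataFrame:
    """One row per metrics dataclass, with named columns in field order."""
    rows = [dataclasses.asdict(item) for item in items]
    frame = pd.DataFrame(rows)
    if labels is not None:
        frame.insert(0, "label", list(labels))
    return frame
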