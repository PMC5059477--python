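"""Synthetic generator and editor for bAP-shaped voltage commands.

Granule-cell dendrites report the somatic membrane state through the shape
of their back-propagating action potentials (bAPs): near a depolarized
somatic state (about -64.6 mV) and a hyperpolarized one (about -77.2 mV)
the proximal bAP pair shares threshold, rise and absolute peak but the
hyperpolarized-state spike repolarizes faster, while beyond ~120 um the
hyperpolarized-state spike instead loses peak amplitude because the active
backpropagation no longer compensates the baseline offset.

This module builds parametric stand-ins for those recorded waveform pairs
plus every command-level manipulation used downstream: uniform voltage
offsets, splicing of the pre-spike potential, pre-peak plateau extension,
theta-modulated baselines, step protocols and the conductance-clamp style
repolarization speed-up.

The waveform model
------------------
One spike is baseline -> logistic rise -> compressed-exponential fall onto
an afterdepolarization (ADP) shoulder that relaxes slowly back to baseline:

    V(t) = B + r(t) * (S(t) - B)
    r(t) = 1 / (1 + exp(-(t - t_mid) / k))          (rise)
    S(t) = P                                  for t < t_peak
    S(t) = adp(u) + (P - V_adp) * exp(-(u / tau_f)^q),  u = t - t_peak

with ``adp(u)`` the shared ADP trajectory (absolute voltage, relaxing to
the state baseline with the slow tau, plus a small alpha-function bump).
The hyperpolarized state differs from the depolarized one only through its
baseline, a fall-time speed-up (``tau_f`` scaled down by ``repol_speedup``)
and, distally, a peak deficit ``(1 - c(d)) * (baseline difference)`` where
the compensation fraction ``c(d)`` falls from ~1 below 75 um to ~0 beyond
120 um. The compressed exponential (sharpness ``q`` > 1) gives the fall a
sigmoidal profile, which is what makes the state-difference transient as
narrow relative to its latency as the recorded one.

The generator is noise-free: identical inputs give bit-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .trace import BAPStatePair, VoltageTrace

__all__ = [
    "BAPShapeParams",
    "ProtocolSpec",
    "default_params",
    "somatic_ap_params",
    "generate_bap",
    "generate_bap_at_baseline",
    "generate_state_pair",
    "align_state_pair",
    "offset_trace",
    "splice_preceding",
    "splice_pair_preceding",
    "extend_prepeak_plateau",
    "theta_protocol",
    "step_protocol",
    "generate_gia_pair",
]

State = Literal["depolarized", "hyperpolarized"]

#: coarsest sampling interval the generator accepts (ms)
MAX_DT = 0.0125

#: rise sigmoid span, in units of the rise width, from midpoint to peak
_RISE_SPAN = 6.0

#: voltage tolerance used to detect where a trace leaves its baseline (mV)
_ONSET_TOL = 0.25


@dataclass(frozen=True)
class BAPShapeParams:
    """Shape parameters of one synthetic bAP family.

    The printed calibration constraints are the two state baselines
    (-64.6 / -77.2 mV) and the proximal state-difference statistics
    (-5 mV extremum, 0.67 ms after the peak, 1.04 ms half-duration);
    ``decay_fast_tau_ms``, ``fall_sharpness`` and ``repol_speedup``
    defaults are calibrated against those. All remaining defaults
    (somatic peak, distal attenuation length, ADP shape) are plausible
    granule-cell values and freely configurable.
    """

    baseline_mV: float = -64.6          # depolarized-state baseline
    hyper_shift_mV: float = 12.6        # baseline drop to the hyperpolarized state
    peak_mV: float = 45.0               # somatic spike peak (absolute)
    length_constant_um: float = 200.0   # exponential bAP peak attenuation
    rise_mid_ms: float = 0.0            # logistic rise midpoint = max rate of rise
    rise_width_ms: float = 0.07         # logistic rise width k
    adp_level_mV: float = 10.0          # ADP shoulder above the depolarized baseline
    decay_fast_tau_ms: float = 0.6915   # fall time scale (calibrated)
    fall_sharpness: float = 1.5618      # q > 1: sigmoidal, not exponential, fall
    decay_slow_tau_ms: float = 40.0     # ADP -> baseline relaxation
    adp_bump_mV: float = 2.0            # small ADP hump (alpha function)
    adp_bump_tau_ms: float = 8.0
    peak_compensation_c: float | None = None   # override c(d) with a constant
    comp_midpoint_um: float = 97.5      # c(d) logistic midpoint
    comp_width_um: float = 5.0          # c(d) logistic width
    repol_speedup: float = 0.0913       # fractional fall-tau reduction (calibrated)
    pre_ms: float = 10.0                # trace span before the max rate of rise
    post_ms: float = 30.0               # trace span after it

    def __post_init__(self) -> None:
        for name in ("rise_width_ms", "decay_fast_tau_ms", "decay_slow_tau_ms",
                     "adp_bump_tau_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.peak_mV > self.baseline_mV:
            raise ValueError("peak_mV must exceed baseline_mV")
        if self.peak_compensation_c is not None and not (
            0.0 <= self.peak_compensation_c <= 1.0
        ):
            raise ValueError("peak_compensation_c must lie in [0, 1]")
        if not 0.0 <= self.repol_speedup < 1.0:
            raise ValueError("repol_speedup must lie in [0, 1)")

    def compensation(self, distance_um: float) -> float:
        """Fraction of the baseline offset recovered at the spike peak."""
        if self.peak_compensation_c is not None:
            return self.peak_compensation_c
        x = (distance_um - self.comp_midpoint_um) / self.comp_width_um
        return 1.0 / (1.0 + math.exp(x))

    def depolarized_peak(self, distance_um: float) -> float:
        """Absolute depolarized-state peak voltage at a dendritic distance."""
        amp = self.peak_mV - self.baseline_mV
        return self.baseline_mV + amp * math.exp(
            -distance_um / self.length_constant_um
        )


def default_params() -> BAPShapeParams:
    """The shipped dendritic-bAP calibration."""
    return BAPShapeParams()


def somatic_ap_params() -> BAPShapeParams:
    """Somatic action potential family used for the conductance-clamp pair.

    Baseline and peak follow the printed somatic values (-68.7 mV holding,
    +40.6 mV peak); the slightly blunter fall (q = 1.3) matches the wider
    printed difference transient of the conductance-clamp comparison.
    """
    return BAPShapeParams(
        baseline_mV=-68.7,
        peak_mV=40.6,
        adp_level_mV=12.0,
        decay_fast_tau_ms=0.7778,
        fall_sharpness=1.3041,
    )


# -- generation ------------------------------------------------------------


def _validate_dt(dt: float) -> None:
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if dt > MAX_DT:
        raise ValueError(f"dt must be <= {MAX_DT} ms, got {dt}")


def generate_bap_at_baseline(
    distance_um: float,
    baseline_mV: float,
    params: BAPShapeParams,
    dt: float = 0.0005,
) -> VoltageTrace:
    """Generate one bAP with the state features interpolated by baseline.

    The state fraction ``f = (B_dep - baseline) / hyper_shift`` scales the
    repolarization speed-up, and the distal peak deficit is
    ``(1 - c(d)) * (B_dep - baseline)``; ``f = 0`` reproduces the
    depolarized-state spike, ``f = 1`` the hyperpolarized-state one, and
    intermediate baselines (as on a theta cycle) interpolate linearly.
    """
    _validate_dt(dt)
    if distance_um < 0:
        raise ValueError("distance_um must be non-negative")
    p = params
    if p.hyper_shift_mV != 0.0:
        frac = (p.baseline_mV - baseline_mV) / p.hyper_shift_mV
    else:
        frac = 0.0
    c = p.compensation(distance_um)
    peak_dep = p.depolarized_peak(distance_um)
    peak = peak_dep - (1.0 - c) * (p.baseline_mV - baseline_mV)
    v_adp = p.baseline_mV + p.adp_level_mV
    tau_f = p.decay_fast_tau_ms * (1.0 - p.repol_speedup * c * frac)
    q = p.fall_sharpness

    t = -p.pre_ms + dt * np.arange(round((p.pre_ms + p.post_ms) / dt) + 1)
    t_peak = p.rise_mid_ms + _RISE_SPAN * p.rise_width_ms
    rise = 1.0 / (1.0 + np.exp(-(t - p.rise_mid_ms) / p.rise_width_ms))

    spine = np.full_like(t, peak)
    post = t >= t_peak
    u = t[post] - t_peak
    adp = (
        baseline_mV
        + (v_adp - baseline_mV) * np.exp(-u / p.decay_slow_tau_ms)
        + p.adp_bump_mV * (u / p.adp_bump_tau_ms)
        * np.exp(1.0 - u / p.adp_bump_tau_ms)
    )
    spine[post] = adp + (peak - v_adp) * np.exp(-((u / tau_f) ** q))

    v = baseline_mV + rise * (spine - baseline_mV)
    return VoltageTrace(
        dt=dt,
        samples=v,
        t0=-p.pre_ms,
        meta={
            "distance_um": distance_um,
            "baseline_mV": baseline_mV,
            "kind": "bap",
        },
    )


def generate_bap(
    distance_um: float,
    state: State,
    params: BAPShapeParams | None = None,
    dt: float = 0.0005,
) -> VoltageTrace:
    """Generate a single synthetic bAP for one somatic state.

    ``state`` selects the depolarized (default -64.6 mV) or hyperpolarized
    (default -77.2 mV) baseline; see :func:`generate_bap_at_baseline` for
    how the state shapes the waveform.
    """
    params = params or default_params()
    if state == "depolarized":
        baseline = params.baseline_mV
    elif state == "hyperpolarized":
        baseline = params.baseline_mV - params.hyper_shift_mV
    else:
        raise ValueError(f"unknown state {state!r}")
    trace = generate_bap_at_baseline(distance_um, baseline, params, dt)
    trace.meta["state"] = state
    return trace


def generate_state_pair(
    distance_um: float,
    params: BAPShapeParams | None = None,
    dt: float = 0.0005,
) -> BAPStatePair:
    """Generate the aligned depolarized/hyperpolarized pair at one location."""
    params = params or default_params()
    dep = generate_bap(distance_um, "depolarized", params, dt)
    hyp = generate_bap(distance_um, "hyperpolarized", params, dt)
    return align_state_pair(dep, hyp, distance_um)


def align_state_pair(
    depolarized: VoltageTrace,
    hyperpolarized: VoltageTrace,
    distance_um: float,
) -> BAPStatePair:
    """Align two bAP traces at their maximum rate of rise.

    The later-rising trace is shifted back by an integer number of samples
    and both traces are cropped to the overlapping span, so aligning an
    already-aligned pair is the identity.
    """
    i_d = depolarized.max_rate_of_rise_index()
    i_h = hyperpolarized.max_rate_of_rise_index()
    shift = i_h - i_d
    d, h = depolarized.samples, hyperpolarized.samples
    if shift > 0:
        h = h[shift:]
        d = d[: len(h)]
    elif shift < 0:
        d = d[-shift:]
        h = h[: len(d)]
    n = min(len(d), len(h))
    d, h = d[:n], h[:n]
    align_index = min(i_d, i_h)
    dep = replace(depolarized, samples=d,
                  t0=depolarized.t0 + (i_d - align_index) * depolarized.dt)
    hyp = replace(hyperpolarized, samples=h, t0=dep.t0)
    return BAPStatePair(
        depolarized=dep,
        hyperpolarized=hyp,
        distance_um=distance_um,
        align_index=align_index,
    )


# -- editing operations ----------------------------------------------------


def offset_trace(trace: VoltageTrace, delta_mV: float) -> VoltageTrace:
    """Shift every sample by ``delta_mV`` (length and dt unchanged)."""
    if not math.isfinite(delta_mV):
        raise ValueError("offset must be finite")
    return trace.with_samples(trace.samples + delta_mV,
                              offset_mV=trace.meta.get("offset_mV", 0.0) + delta_mV)


def _divergence_index(trace: VoltageTrace) -> int:
    """Last pre-peak sample still within tolerance of the pre-spike baseline."""
    peak = int(np.argmax(trace.samples))
    baseline = float(trace.samples[0])
    below = np.nonzero(trace.samples[:peak] <= baseline + _ONSET_TOL)[0]
    if below.size == 0:
        raise ValueError("no pre-peak baseline segment found")
    return int(below[-1])


def splice_preceding(
    trace: VoltageTrace,
    v_pre_mV: float,
    divergence_index: int | None = None,
    ramp_ms: float = 0.1,
) -> VoltageTrace:
    """Replace the pre-spike potential with a steady ``v_pre_mV``.

    Everything before the divergence point (by default the last pre-peak
    sample at the pre-spike baseline) is set to ``v_pre_mV``, with a short
    linear ramp (<= ``ramp_ms``) into the unchanged remainder, so channel
    availability is set by ``v_pre_mV`` while the spike itself is untouched.
    """
    div = _divergence_index(trace) if divergence_index is None else divergence_index
    if not 0 <= div < trace.n:
        raise ValueError("divergence index outside trace")
    v = trace.samples.copy()
    ramp_n = min(int(round(ramp_ms / trace.dt)), div)
    v[: div - ramp_n] = v_pre_mV
    if ramp_n > 0:
        v[div - ramp_n: div] = np.linspace(
            v_pre_mV, v[div], ramp_n, endpoint=False
        )
    return trace.with_samples(v, v_pre_mV=v_pre_mV)


def splice_pair_preceding(pair: BAPStatePair, v_pre_mV: float) -> BAPStatePair:
    """Equalize the pre-peak course of a state pair at ``v_pre_mV``.

    The divergence point is detected on the depolarized trace and the
    depolarized pre-peak segment (spliced to ``v_pre_mV``) is imposed on
    both members, so the two commands differ only after the spike peak —
    isolating the repolarization-shape difference from channel
    availability.
    """
    spliced_dep = splice_preceding(pair.depolarized, v_pre_mV)
    peak = int(np.argmax(spliced_dep.samples))
    hyp_v = pair.hyperpolarized.samples.copy()
    hyp_v[: peak + 1] = spliced_dep.samples[: peak + 1]
    hyp = pair.hyperpolarized.with_samples(hyp_v, v_pre_mV=v_pre_mV)
    return BAPStatePair(
        depolarized=spliced_dep,
        hyperpolarized=hyp,
        distance_um=pair.distance_um,
        align_index=pair.align_index,
    )


def extend_prepeak_plateau(trace: VoltageTrace, extra_ms: float) -> VoltageTrace:
    """Insert a steady-voltage plateau just before the spike peak.

    The plateau holds the pre-peak shoulder voltage for ``extra_ms`` so the
    activation gates can equilibrate at spike voltage while the
    repolarization phase stays exactly as in the native waveform.
    """
    if extra_ms < 0:
        raise ValueError("extension must be non-negative")
    n_ext = int(round(extra_ms / trace.dt))
    if n_ext == 0:
        return trace
    peak = int(np.argmax(trace.samples))
    v = np.concatenate([
        trace.samples[:peak],
        np.full(n_ext, trace.samples[peak]),
        trace.samples[peak:],
    ])
    return trace.with_samples(v, plateau_extension_ms=extra_ms)


# -- protocols -------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolSpec:
    """Declarative description of a step / paired-pulse / theta protocol.

    The default holding period of 4 s mirrors the standard practice of
    letting calcium-channel availability reach steady state before the
    test pulse; it can be truncated because the simulation engine also
    initializes gates at steady state.
    """

    kind: Literal["step", "paired_pulse", "theta", "plateau_extended"] = "step"
    holding_mV: float = -80.0
    test_mV: float = 0.0
    baseline_ms: float = 4000.0
    test_ms: float = 3.0
    interpulse_ms: float = 0.0
    tail_ms: float = 50.0
    dt_ms: float = 0.0025
    theta_freq_hz: float = 5.2
    theta_peak_mV: float = -62.2
    theta_trough_mV: float = -83.9
    theta_rest_mV: float = -73.3
    ap_phase_deg: float = 0.0
    n_cycles: int = 5
    plateau_extension_ms: float = 0.0

    def __post_init__(self) -> None:
        for name in ("baseline_ms", "test_ms", "dt_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.theta_freq_hz <= 0:
            raise ValueError("theta frequency must be positive")
        if self.kind == "theta" and self.n_cycles != 0 and self.n_cycles < 5:
            raise ValueError("theta runs need >= 5 preceding cycles (or 0 for rest)")
        if not 0.0 <= self.ap_phase_deg < 360.0:
            raise ValueError("ap_phase_deg must lie in [0, 360)")


def step_protocol(spec: ProtocolSpec) -> VoltageTrace:
    """Build a piecewise-constant step or paired-pulse command."""
    dt = spec.dt_ms
    n_base = round(spec.baseline_ms / dt)
    n_test = round(spec.test_ms / dt)
    n_tail = round(spec.tail_ms / dt)
    segments = [np.full(n_base, spec.holding_mV),
                np.full(n_test, spec.test_mV)]
    if spec.kind == "paired_pulse":
        n_gap = round(spec.interpulse_ms / dt)
        segments += [np.full(n_gap, spec.holding_mV),
                     np.full(n_test, spec.test_mV)]
    segments.append(np.full(max(n_tail, 1), spec.holding_mV))
    v = np.concatenate(segments)
    return VoltageTrace(dt=dt, samples=v, t0=-spec.baseline_ms,
                        meta={"kind": spec.kind,
                              "holding_mV": spec.holding_mV,
                              "test_mV": spec.test_mV})


def theta_protocol(spec: ProtocolSpec, ap_template: VoltageTrace) -> VoltageTrace:
    """Sinusoidal theta baseline with a spike spliced at a chosen phase.

    The command oscillates between the trough and peak voltages at the
    theta frequency for ``n_cycles`` full cycles, continues into the final
    cycle up to ``ap_phase_deg`` (sine convention: 90 deg is the cycle
    peak, 270 deg the trough), and then plays the spike template from its
    onset, offset so the onset voltage equals the sinusoid value at that
    phase. ``n_cycles = 0`` produces the flat rest-baseline variant.
    """
    dt = ap_template.dt
    onset = _divergence_index(ap_template)
    ap_seg = ap_template.samples[onset:]
    if spec.n_cycles == 0:
        n_base = round(1000.0 / spec.theta_freq_hz / dt)  # one cycle worth
        base = np.full(n_base, spec.theta_rest_mV)
        v_splice = spec.theta_rest_mV
    else:
        mid = 0.5 * (spec.theta_peak_mV + spec.theta_trough_mV)
        amp = 0.5 * (spec.theta_peak_mV - spec.theta_trough_mV)
        period_ms = 1000.0 / spec.theta_freq_hz
        t_splice = (spec.n_cycles + spec.ap_phase_deg / 360.0) * period_ms
        n_base = round(t_splice / dt)
        t = dt * np.arange(n_base)
        base = mid + amp * np.sin(2.0 * np.pi * spec.theta_freq_hz * t / 1000.0)
        v_splice = mid + amp * math.sin(math.radians(spec.ap_phase_deg))
    spike = ap_seg + (v_splice - ap_seg[0])
    v = np.concatenate([base, spike])
    return VoltageTrace(dt=dt, samples=v, t0=-n_base * dt,
                        meta={"kind": "theta", "phase_deg": spec.ap_phase_deg,
                              "n_cycles": spec.n_cycles})


# -- conductance-clamp style repolarization speed-up -----------------------

#: post-peak time-compression matching the printed conductance-clamp
#: difference statistics (-3.2 mV extremum 0.75 ms after the peak,
#: 1.35 ms half-duration); calibrated once against the somatic AP family
DEFAULT_GIA_SPEEDUP = 0.0713


def generate_gia_pair(
    base_ap: VoltageTrace,
    speedup: float = DEFAULT_GIA_SPEEDUP,
) -> tuple[VoltageTrace, VoltageTrace]:
    """Mimic a transient-potassium conductance that speeds repolarization.

    Returns ``(control, modified)`` where the modified spike is the
    control with its post-peak course compressed in time by
    ``1 + speedup`` — the open-loop equivalent of injecting an A-type
    potassium conductance during the falling phase. Baseline, rise and
    peak are untouched.
    """
    peak = int(np.argmax(base_ap.samples))
    if base_ap.samples[peak] - base_ap.samples[0] < 20.0:
        raise ValueError("no action potential detected in base trace")
    if speedup == 0.0:
        return base_ap, base_ap
    u = base_ap.dt * np.arange(base_ap.n - peak)
    post = np.interp(u * (1.0 + speedup), u, base_ap.samples[peak:])
    v = base_ap.samples.copy()
    v[peak:] = post
    return base_ap, base_ap.with_samples(v, gia_speedup=speedup)
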