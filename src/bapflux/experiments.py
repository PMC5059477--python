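"""The in silico experiments, end to end.

Each experiment is a pure function of its configuration and the shipped
channel parameters: it builds (or accepts) the voltage commands, plays
them through a channel scenario, quantifies charge in the standard
windows and returns a :class:`ScanResult` table. Re-running any
experiment with the same inputs is bit-identical.

The experiments mirror the standard protocol battery for state-dependent
bAP calcium signalling:

- ``offset_scan``: shift a bAP command in 2-mV steps (+6 to -30 mV) and
  track the relative charge — large proximal spikes are insensitive,
  small distal spikes collapse quickly.
- ``kinetics_scan``: with the pre-spike potential equalized at -80 mV,
  vary activation/inactivation time constants on a grid and map where
  faster repolarization yields more influx (it requires spike-relevant
  fast inactivation).
- ``state_comparison``: hyperpolarized- vs depolarized-state charge for
  a scenario and a preceding-potential mode (native, equalized at
  -80 mV, or occluded at -60 mV).
- ``completeness_scan``: pre-peak plateau extensions probe how complete
  the activation during the native spike was.
- ``theta_scan``: charge of a spike riding on a 5.2-Hz oscillation,
  phase by phase, against the no-oscillation rest protocol.
- ``recovery_scan``: paired-pulse recovery from inactivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .channels import ScenarioConfig, build_scenario
from .engine import simulate_currents
from .metrics import charge_window, percent_change
from .trace import BAPStatePair, VoltageTrace
from .waveform import (
    BAPShapeParams,
    ProtocolSpec,
    default_params,
    extend_prepeak_plateau,
    generate_bap,
    generate_bap_at_baseline,
    generate_state_pair,
    offset_trace,
    splice_pair_preceding,
    step_protocol,
    theta_protocol,
)

__all__ = [
    "ScanResult",
    "offset_scan",
    "kinetics_scan",
    "state_comparison",
    "completeness_scan",
    "theta_scan",
    "recovery_scan",
]

#: standard charge quantification: 1-ms window starting 0.35 ms after the
#: command AP peak; the kinetics scan uses the wider 5-ms variant
CHARGE_START_MS = 0.35
CHARGE_LEN_MS = 1.0
KINETICS_LEN_MS = 5.0

PrecedingMode = Literal["native", "equalized_-80", "occluded_-60"]


@dataclass(frozen=True)
class ScanResult:
    """A parameter scan: named axes, a value table and provenance."""

    axes: dict[str, np.ndarray]
    values: np.ndarray
    exclusion_mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = tuple(len(v) for v in self.axes.values())
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != axes {shape}")
        if self.exclusion_mask is not None:
            if self.exclusion_mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")
            if not np.all(np.isnan(self.values[self.exclusion_mask])):
                raise ValueError("masked cells must carry no value (NaN)")

    def to_frame(self) -> pd.DataFrame:
        names = list(self.axes)
        grids = np.meshgrid(*self.axes.values(), indexing="ij")
        cols = {n: g.ravel() for n, g in zip(names, grids)}
        cols["value"] = self.values.ravel()
        if self.exclusion_mask is not None:
            cols["excluded"] = self.exclusion_mask.ravel()
        return pd.DataFrame(cols)


def _charge(command: VoltageTrace, scenario: ScenarioConfig,
            window_len: float = CHARGE_LEN_MS,
            window_start: float = CHARGE_START_MS) -> float:
    record = simulate_currents(command, scenario)
    return charge_window(record, window_start_after_peak_ms=window_start,
                         window_len_ms=window_len).magnitude


# -- voltage-offset scan ---------------------------------------------------


def offset_scan(
    commands: VoltageTrace | Sequence[VoltageTrace],
    offsets_mV: Sequence[float] | None = None,
    scenario: ScenarioConfig | str = "HN_HI",
) -> ScanResult:
    """Charge versus uniform voltage offset, normalized per command.

    Each command is shifted by every offset (default +6 to -30 mV in 2-mV
    steps) and the 1-ms charge is expressed in percent of the zero-offset
    charge of the same command. Rows are commands (tagged by their
    ``distance_um`` meta where present), columns are offsets.
    """
    if offsets_mV is None:
        offsets_mV = np.arange(6.0, -30.0 - 1e-9, -2.0)
    offsets = np.asarray(list(offsets_mV), dtype=float)
    if offsets.size == 0:
        raise ValueError("empty offset list")
    if isinstance(commands, VoltageTrace):
        commands = [commands]
    if isinstance(scenario, str):
        scenario = build_scenario(scenario)
    distances = np.array([
        float(c.meta.get("distance_um", i)) for i, c in enumerate(commands)
    ])
    values = np.empty((len(commands), offsets.size))
    for i, cmd in enumerate(commands):
        ref = _charge(cmd, scenario)
        for j, off in enumerate(offsets):
            values[i, j] = 100.0 * _charge(offset_trace(cmd, off), scenario) / ref
    return ScanResult(
        axes={"distance_um": distances, "offset_mV": offsets},
        values=values,
        provenance={"scenario": scenario.name, "experiment": "offset_scan"},
    )


# -- kinetics scan ---------------------------------------------------------


def _scale_tau(gate, factor):
    """Gate copy with its whole time-constant curve scaled by ``factor``."""
    tau = gate.tau
    if tau.kind == "bell":
        new = replace(tau, base=tau.base * factor, anchor_tau=tau.anchor_tau * factor)
    elif tau.kind in ("sigmoid", "two_sigmoid"):
        new = replace(tau, base=tau.base * factor, amp=tau.amp * factor,
                      amp2=tau.amp2 * factor)
    else:
        new = replace(tau, value=tau.value * factor)
    return replace(gate, tau=new)


def kinetics_scan(
    pair: BAPStatePair,
    base_channel: str = "HI",
    act_scale_factors: Sequence[float] | None = None,
    inact_taus_ms: Sequence[float] | None = None,
    exclusion_threshold: float = 0.01,
) -> ScanResult:
    """Map the gating-kinetics requirements of the repolarization effect.

    The pair's preceding potential must already be equalized (use
    :func:`bapflux.waveform.splice_pair_preceding` at -80 mV) so only the
    post-peak shape differs. For every grid cell the base channel's
    activation-tau curve is scaled by a factor and its inactivation-tau
    curve is scaled to put ``tau_h`` at the spike-repolarization
    reference (-30 mV) at the requested value; the cell value is the
    percent change of the 5-ms charge, faster- vs slower-repolarizing
    command.

    Cells whose peak open probability during the slower command falls
    below ``exclusion_threshold`` of a non-inactivating reference with
    the same activation kinetics are masked (unrealistic kinetics:
    extremely fast inactivation with slow activation).
    """
    from .channels import ChannelModel, GatingParams, _CHANNEL_DEFS

    if base_channel not in ("HI", "HN_with_h"):
        raise ValueError("kinetics scan needs an inactivating base channel")
    gating = _CHANNEL_DEFS[base_channel]
    if act_scale_factors is None:
        act_scale_factors = np.geomspace(0.25, 4.0, 9)
    if inact_taus_ms is None:
        inact_taus_ms = np.geomspace(0.5, 500.0, 12)
    acts = np.asarray(list(act_scale_factors), dtype=float)
    inacts = np.asarray(list(inact_taus_ms), dtype=float)
    if acts.size == 0 or inacts.size == 0:
        raise ValueError("degenerate kinetics grid")
    ref_tau_h = float(gating.h.time_constant(-30.0))

    values = np.full((acts.size, inacts.size), np.nan)
    mask = np.zeros_like(values, dtype=bool)
    for i, fa in enumerate(acts):
        m_gate = _scale_tau(gating.m, fa)
        # non-inactivating reference with the same activation kinetics
        ref_model = ChannelModel("ref", GatingParams(m=m_gate), 1.0)
        ref_rec = simulate_currents(pair.depolarized,
                                    _single_scenario(ref_model))
        ref_open = float(np.max(ref_rec.gates[("ref", "m")] ** m_gate.power))
        for j, ti in enumerate(inacts):
            h_gate = _scale_tau(gating.h, ti / ref_tau_h)
            model = ChannelModel(base_channel, GatingParams(m=m_gate, h=h_gate), 1.0)
            scen = _single_scenario(model)
            rec_d = simulate_currents(pair.depolarized, scen)
            open_d = (rec_d.gates[(base_channel, "m")] ** m_gate.power
                      * rec_d.gates[(base_channel, "h")] ** h_gate.power)
            if float(np.max(open_d)) < exclusion_threshold * ref_open:
                mask[i, j] = True
                continue
            q_d = charge_window(rec_d, CHARGE_START_MS, KINETICS_LEN_MS)
            rec_h = simulate_currents(pair.hyperpolarized, scen)
            q_h = charge_window(rec_h, CHARGE_START_MS, KINETICS_LEN_MS)
            values[i, j] = percent_change(q_h, q_d)
    return ScanResult(
        axes={"act_scale": acts, "inact_tau_ms": inacts},
        values=values,
        exclusion_mask=mask,
        provenance={"experiment": "kinetics_scan", "base_channel": base_channel,
                    "window_ms": KINETICS_LEN_MS,
                    "inact_tau_reference_mV": -30.0},
    )


def _single_scenario(model) -> ScenarioConfig:
    return ScenarioConfig(name=f"{model.name}_only", channels=(model,))


# -- state comparison ------------------------------------------------------


def state_comparison(
    pair: BAPStatePair,
    scenario: ScenarioConfig | str = "HN_HI",
    preceding: PrecedingMode = "native",
) -> float:
    """Percent charge change, hyperpolarized vs depolarized state.

    ``native`` plays the commands as generated (availability and shape
    effects compound, as in the pharmacology comparisons);
    ``equalized_-80`` splices both pre-spike segments to -80 mV (shape
    only, full availability); ``occluded_-60`` splices to -60 mV, where
    the inactivating channels are mostly unavailable, abolishing the
    shape effect.
    """
    if isinstance(scenario, str):
        scenario = build_scenario(scenario)
    if preceding == "native":
        prepared = pair
    elif preceding == "equalized_-80":
        prepared = splice_pair_preceding(pair, -80.0)
    elif preceding == "occluded_-60":
        prepared = splice_pair_preceding(pair, -60.0)
    else:
        raise ValueError(f"unknown preceding mode {preceding!r}")
    q_d = charge_window(simulate_currents(prepared.depolarized, scenario))
    q_h = charge_window(simulate_currents(prepared.hyperpolarized, scenario))
    return percent_change(q_h, q_d)


# -- activation-completeness scan ------------------------------------------


def completeness_scan(
    command: VoltageTrace,
    extensions_ms: Sequence[float] | None = None,
    scenario: ScenarioConfig | str = "HN_HI",
) -> ScanResult:
    """Charge versus pre-peak plateau extension, percent of unextended.

    A spike that already activates the available channels completely
    gains little from holding the peak voltage longer; a small distal
    spike with submaximal activation gains a lot.
    """
    if extensions_ms is None:
        extensions_ms = [0.0, 0.75, 1.5, 2.5, 3.75, 5.0]
    exts = np.asarray(list(extensions_ms), dtype=float)
    if isinstance(scenario, str):
        scenario = build_scenario(scenario)
    ref = _charge(command, scenario)
    values = np.array([
        100.0 * _charge(extend_prepeak_plateau(command, e), scenario) / ref
        for e in exts
    ])
    return ScanResult(
        axes={"extension_ms": exts},
        values=values,
        provenance={"scenario": scenario.name, "experiment": "completeness_scan"},
    )


# -- theta scan ------------------------------------------------------------


def theta_scan(
    phases_deg: Sequence[float] | None = None,
    distances_um: Sequence[float] = (40.0, 150.0),
    scenario: ScenarioConfig | str = "HN_HI",
    params: BAPShapeParams | None = None,
    protocol: ProtocolSpec | None = None,
    dt: float = 0.0125,
) -> ScanResult:
    """Phase-dependent charge on a theta cycle, relative to rest.

    For each phase of the final theta cycle a spike template is generated
    at the instantaneous oscillation baseline (so the waveform carries
    the state dependence a real spike would) and spliced onto the
    oscillation; the value is the percent change of its charge against
    the flat rest-baseline protocol. Rows are dendritic distances,
    columns phases. The ~5 preceding cycles equilibrate channel
    availability to the oscillatory steady state; the default coarse
    sampling keeps the second-long baseline cheap, which only the
    command representation, not the integration rule, depends on.
    """
    if phases_deg is None:
        phases_deg = np.arange(0.0, 360.0, 30.0)
    phases = np.asarray(list(phases_deg), dtype=float)
    dists = np.asarray(list(distances_um), dtype=float)
    if isinstance(scenario, str):
        scenario = build_scenario(scenario)
    params = params or default_params()
    proto = protocol or ProtocolSpec(kind="theta")
    mid = 0.5 * (proto.theta_peak_mV + proto.theta_trough_mV)
    amp = 0.5 * (proto.theta_peak_mV - proto.theta_trough_mV)

    values = np.empty((dists.size, phases.size))
    for i, d in enumerate(dists):
        rest_ap = generate_bap_at_baseline(float(d), proto.theta_rest_mV, params, dt)
        rest_cmd = theta_protocol(replace(proto, n_cycles=0), rest_ap)
        q_rest = _charge(rest_cmd, scenario)
        for j, ph in enumerate(phases):
            baseline = mid + amp * np.sin(np.radians(ph))
            ap = generate_bap_at_baseline(float(d), baseline, params, dt)
            cmd = theta_protocol(replace(proto, ap_phase_deg=float(ph)), ap)
            values[i, j] = percent_change(_charge(cmd, scenario), q_rest)
    return ScanResult(
        axes={"distance_um": dists, "phase_deg": phases},
        values=values,
        provenance={"scenario": scenario.name, "experiment": "theta_scan",
                    "freq_hz": proto.theta_freq_hz, "dt_ms": dt},
    )


# -- recovery from inactivation --------------------------------------------


def recovery_scan(
    scenario: ScenarioConfig | str = "HI_only",
    interpulse_ms: Sequence[float] | None = None,
    holding_mV: float = -80.0,
    test_ms: float = 3.0,
    dt: float = 0.0025,
) -> ScanResult:
    """Paired-pulse recovery of the peak current after inactivation.

    Two identical test pulses to 0 mV from the holding potential; the
    value is the second/first peak-current ratio versus the interpulse
    interval. A monoexponential recovery tau is fitted and reported in
    the provenance. The default scenario isolates the inactivating
    channel — the non-inactivating model recovers trivially (ratio 1).
    """
    if interpulse_ms is None:
        interpulse_ms = [25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0]
    gaps = np.asarray(list(interpulse_ms), dtype=float)
    if np.any(gaps <= 0):
        raise ValueError("interpulse intervals must be positive")
    if isinstance(scenario, str):
        scenario = build_scenario(scenario)
    baseline_ms = 200.0
    ratios = np.empty(gaps.size)
    for k, gap in enumerate(gaps):
        spec = ProtocolSpec(kind="paired_pulse", holding_mV=holding_mV,
                            test_mV=0.0, baseline_ms=baseline_ms,
                            test_ms=test_ms, interpulse_ms=float(gap), dt_ms=dt)
        record = simulate_currents(step_protocol(spec), scenario)
        current = record.total
        nb = round(baseline_ms / dt)
        nt = round(test_ms / dt)
        ng = round(gap / dt)
        p1 = float(np.min(current[nb: nb + nt]))
        p2 = float(np.min(current[nb + nt + ng: nb + 2 * nt + ng]))
        ratios[k] = p2 / p1 if p1 != 0.0 else np.nan
    provenance = {"scenario": scenario.name, "experiment": "recovery_scan",
                  "holding_mV": holding_mV}
    spread = float(np.nanmax(ratios) - np.nanmin(ratios))
    if gaps.size >= 3 and spread > 1e-3:
        popt, _ = curve_fit(
            lambda t, tau, r0: 1.0 - (1.0 - r0) * np.exp(-t / tau),
            gaps, ratios, p0=[300.0, float(ratios[0])], maxfev=10000,
        )
        provenance["recovery_tau_ms"] = float(popt[0])
        provenance["zero_interval_ratio"] = float(popt[1])
    return ScanResult(axes={"interpulse_ms": gaps}, values=ratios,
                      provenance=provenance)


# -- convenience: the default proximal pair --------------------------------


def default_proximal_pair(dt: float = 0.0005) -> BAPStatePair:
    """The shipped 24-um state pair every comparison defaults to."""
    return generate_state_pair(24.0, default_params(), dt)


def default_distal_command(dt: float = 0.0005) -> VoltageTrace:
    """A representative distal (150-um) depolarized-state command."""
    return generate_bap(150.0, "depolarized", default_params(), dt)
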