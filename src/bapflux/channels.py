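"""Hodgkin-Huxley gating models, GHK calcium flux and channel scenarios.

Two high-voltage-activated (HVA) calcium current models carry the physics:

``HI``
    an inactivating model derived from granule-cell R-type current
    properties — a Boltzmann activation gate *m* plus an inactivation gate
    *h* whose steady state is mostly removed at a depolarized subthreshold
    potential (about -60 mV) and mostly available below -75 mV, with
    spike-relevant fast inactivation (about a millisecond at spike
    voltages) but slow recovery (hundreds of ms at rest).
``HN``
    a fast, non-inactivating model derived from N-type current properties
    (activation gate only).

The printed kinetic anchors pin the activation speed of both models:
``tau_m(0 mV)`` is 1.137 ms for HI and 0.825 ms for HN. The time-constant
curves are parametrized so that the anchor value is reproduced exactly by
construction, and the remaining shape coefficients are plausible HVA
values (documented in the methods note).

Calcium current through an open channel uses the constant-field (GHK)
flux expression, shared by every channel, scaled by a per-channel
permeability share; the total theoretical maximum permeability of a
scenario is normalized to 1. A conductance-clamp family (ohmic A-type
potassium and a passive control) completes the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "TauSpec",
    "GateSpec",
    "GatingParams",
    "ChannelModel",
    "GHKConfig",
    "ScenarioConfig",
    "ClampConductance",
    "gate_steady_state",
    "gate_time_constant",
    "ghk_factor",
    "calcium_current",
    "build_channel",
    "build_scenario",
    "a_type_clamp",
    "passive_clamp",
    "clamp_current",
    "channels_to_yaml",
    "channels_from_yaml",
]

FARADAY = 96485.33212  # C / mol
GAS_CONSTANT = 8.31446  # J / (mol K)

#: exponent magnitude below which the GHK term switches to its series form
GHK_GUARD = 1e-4


# -- gating ---------------------------------------------------------------


@dataclass(frozen=True)
class TauSpec:
    """Voltage-dependent time constant, one of three functional forms.

    ``bell``
        ``base + amp / (exp((V-c)/s_left) + exp(-(V-c)/s_right))``; the
        amplitude is derived so that ``tau(anchor_v) == anchor_tau``
        exactly, which is how the printed 0-mV activation anchors are
        enforced.
    ``sigmoid``
        ``base + amp / (1 + exp((V-c)/width))`` — monotone, large at
        hyperpolarized voltages (used for inactivation/recovery).
    ``two_sigmoid``
        the sigmoid plus a second, depolarized limb
        ``amp2 / (1 + exp(-(V-c2)/w2))`` — a U-shaped curve with a fast
        pocket between the limbs (inactivation that is fastest in the
        spike-repolarization voltage range, slower at the peak and very
        slow at rest).
    ``constant``
        a fixed value (used for the quasi-static passive clamp gate).
    """

    kind: Literal["bell", "sigmoid", "two_sigmoid", "constant"] = "bell"
    base: float = 0.2
    center: float = -25.0
    sigma_left: float = 14.0
    sigma_right: float = 22.0
    anchor_v: float = 0.0
    anchor_tau: float = 1.0
    amp: float = 400.0
    width: float = 6.0
    amp2: float = 0.0
    center2: float = -20.0
    width2: float = 3.0
    value: float = 1.0

    def _bell_denom(self, v):
        return np.exp((v - self.center) / self.sigma_left) + np.exp(
            -(v - self.center) / self.sigma_right
        )

    def __call__(self, v_mV):
        v = np.asarray(v_mV, dtype=float)
        if self.kind == "bell":
            amp = (self.anchor_tau - self.base) * self._bell_denom(self.anchor_v)
            out = self.base + amp / self._bell_denom(v)
        elif self.kind == "sigmoid":
            out = self.base + self.amp / (1.0 + np.exp((v - self.center) / self.width))
        elif self.kind == "two_sigmoid":
            out = (
                self.base
                + self.amp / (1.0 + np.exp((v - self.center) / self.width))
                + self.amp2 / (1.0 + np.exp(-(v - self.center2) / self.width2))
            )
        elif self.kind == "constant":
            out = np.full_like(v, self.value)
        else:  # pragma: no cover
            raise ValueError(f"unknown tau kind {self.kind!r}")
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class GateSpec:
    """One Boltzmann gate: steady state, time constant and exponent.

    ``slope_mV`` is signed: positive for activation gates (steady state
    non-decreasing in V), negative for inactivation gates.
    """

    half_mV: float
    slope_mV: float
    tau: TauSpec
    power: int = 1

    def steady_state(self, v_mV):
        v = np.asarray(v_mV, dtype=float)
        out = 1.0 / (1.0 + np.exp(-(v - self.half_mV) / self.slope_mV))
        return out if out.ndim else float(out)

    def time_constant(self, v_mV):
        return self.tau(v_mV)


@dataclass(frozen=True)
class GatingParams:
    """The gate set of one channel: activation *m*, optional inactivation *h*."""

    m: GateSpec
    h: GateSpec | None = None

    def gate(self, name: str) -> GateSpec:
        if name == "m":
            return self.m
        if name == "h":
            if self.h is None:
                raise ValueError("this channel has no inactivation gate")
            return self.h
        raise ValueError(f"unknown gate {name!r}")


def gate_steady_state(v_mV, params, gate: str = "m"):
    """Steady-state open fraction of one gate at a membrane potential."""
    gating = params.gating if isinstance(params, ChannelModel) else params
    return gating.gate(gate).steady_state(v_mV)


def gate_time_constant(v_mV, params, gate: str = "m"):
    """Voltage-dependent time constant (ms) of one gate."""
    gating = params.gating if isinstance(params, ChannelModel) else params
    return gating.gate(gate).time_constant(v_mV)


# -- channels and scenarios ------------------------------------------------


@dataclass(frozen=True)
class ChannelModel:
    """One named gating scheme plus its share of the total permeability."""

    name: str
    gating: GatingParams
    permeability_share: float = 1.0
    is_calcium: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.permeability_share <= 1.0:
            raise ValueError("permeability_share must lie in [0, 1]")

    @property
    def has_h(self) -> bool:
        return self.gating.h is not None

    def gate_names(self) -> tuple[str, ...]:
        return ("m", "h") if self.has_h else ("m",)

    def open_fraction(self, gate_values: dict) -> np.ndarray | float:
        m = np.asarray(gate_values["m"], dtype=float)
        out = m ** self.gating.m.power
        if self.has_h:
            if "h" not in gate_values:
                raise ValueError(f"channel {self.name} needs an h gate value")
            out = out * np.asarray(gate_values["h"], dtype=float) ** self.gating.h.power
        return out


# Default gating coefficients. The two bell anchors (1.137 / 0.825 ms at
# 0 mV) are the printed constraints; half-activation, slopes and the
# inactivation curve are chosen so that availability is mostly lost at
# -60 mV and mostly intact below -75 mV, recovery at rest takes ~400 ms,
# and inactivation at spike voltages is fast enough (~1 ms above -20 mV)
# to register the repolarization-speed difference of a single bAP — the
# regime in which only inactivating HVA models reward faster
# repolarization with more influx.

_HI_M = GateSpec(half_mV=-10.0, slope_mV=5.0,
                 tau=TauSpec(kind="bell", base=0.2, center=-10.0,
                             sigma_left=12.0, sigma_right=22.0,
                             anchor_v=0.0, anchor_tau=1.137))
_HI_H = GateSpec(half_mV=-68.0, slope_mV=-4.0,
                 tau=TauSpec(kind="two_sigmoid", base=0.5, amp=400.0,
                             center=-55.0, width=5.0,
                             amp2=10.0, center2=15.0, width2=3.0))
_HN_M = GateSpec(half_mV=-9.0, slope_mV=5.0,
                 tau=TauSpec(kind="bell", base=0.15, center=-2.0,
                             sigma_left=11.0, sigma_right=20.0,
                             anchor_v=0.0, anchor_tau=0.825))

_CHANNEL_DEFS: dict[str, GatingParams] = {
    "HI": GatingParams(m=_HI_M, h=_HI_H),
    "HN": GatingParams(m=_HN_M),
    # HN activation supplemented with HI-style voltage-dependent
    # inactivation — the construction showing that a non-inactivating
    # current becomes repolarization-sensitive once it can inactivate.
    "HN_with_h": GatingParams(m=_HN_M, h=_HI_H),
}


def build_channel(name: str, permeability_share: float = 1.0,
                  gating: GatingParams | None = None) -> ChannelModel:
    """Instantiate a shipped calcium-channel model by name."""
    if gating is None:
        try:
            gating = _CHANNEL_DEFS[name]
        except KeyError:
            raise ValueError(f"unknown channel {name!r}; "
                             f"known: {sorted(_CHANNEL_DEFS)}") from None
    return ChannelModel(name=name, gating=gating,
                        permeability_share=permeability_share)


@dataclass(frozen=True)
class GHKConfig:
    """Constant-field flux parameters.

    Concentrations in mM (5 mM external mirrors the elevated-calcium
    recording solution; 100 nM free internal calcium is a conventional
    resting value — only relative outputs are reported, so it is
    non-critical). The amplitude factor subsumes absolute permeability
    units; every downstream quantity is a ratio or percent change and is
    invariant to it.
    """

    ca_out_mM: float = 5.0
    ca_in_mM: float = 1e-4
    temperature_C: float = 24.0
    valence: int = 2
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.ca_out_mM <= 0 or self.ca_in_mM <= 0:
            raise ValueError("concentrations must be positive")
        if self.ca_out_mM <= self.ca_in_mM:
            raise ValueError("ca_out must exceed ca_in")

    @property
    def kelvin(self) -> float:
        return self.temperature_C + 273.15

    @property
    def reversal_mV(self) -> float:
        """Nernst potential for calcium at these concentrations (mV)."""
        return (
            1000.0
            * GAS_CONSTANT * self.kelvin / (self.valence * FARADAY)
            * math.log(self.ca_out_mM / self.ca_in_mM)
        )


def ghk_factor(v_mV, ghk: GHKConfig):
    """Constant-field flux driving term (negative = inward).

    Evaluates ``zF * u * (c_in - c_out exp(-u)) / (1 - exp(-u))`` with
    ``u = zFV/RT``; for ``|u| < 1e-4`` the removable singularity at V = 0
    is replaced by its second-order series
    ``zF * [(c_in-c_out) + u (c_in+c_out)/2 + u^2 (c_in-c_out)/12]``.
    """
    v = np.asarray(v_mV, dtype=float)
    z = ghk.valence
    zf = z * FARADAY
    u = zf * (v / 1000.0) / (GAS_CONSTANT * ghk.kelvin)
    ci, co = ghk.ca_in_mM, ghk.ca_out_mM
    small = np.abs(u) < GHK_GUARD
    u_safe = np.where(small, 1.0, u)
    exact = u_safe * (ci - co * np.exp(-u_safe)) / (1.0 - np.exp(-u_safe))
    series = (ci - co) + u * (ci + co) / 2.0 + u * u * (ci - co) / 12.0
    out = zf * np.where(small, series, exact)
    return out if out.ndim else float(out)


def calcium_current(v_mV, gate_values: dict, channel: ChannelModel,
                    ghk: GHKConfig):
    """Calcium current density of one channel (arbitrary units).

    Product of the permeability share, the gate open fraction, the
    amplitude factor and the GHK driving term; zero whenever a required
    gate is closed.
    """
    return (
        channel.permeability_share
        * ghk.amplitude
        * channel.open_fraction(gate_values)
        * ghk_factor(v_mV, ghk)
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """A named channel composition with total permeability normalized to 1.

    The compartment constants record the single-compartment provenance
    (area 100 um^2, c_m 1 uF/cm^2, R_a 35.4 Ohm cm); under a forced
    voltage they do not enter the computation.
    """

    name: str
    channels: tuple[ChannelModel, ...]
    ghk: GHKConfig = field(default_factory=GHKConfig)
    area_um2: float = 100.0
    cm_uF_cm2: float = 1.0
    ra_ohm_cm: float = 35.4

    def __post_init__(self) -> None:
        total = sum(c.permeability_share for c in self.channels if c.is_calcium)
        if self.channels and abs(total - 1.0) > 1e-12 and total != 0.0:
            raise ValueError(
                f"calcium permeability shares must sum to 1, got {total}"
            )


_SCENARIOS = ("HI_only", "HN_only", "HN_HI")


def build_scenario(name: str, ghk: GHKConfig | None = None) -> ScenarioConfig:
    """Build one of the three shipped channel scenarios.

    ``HI_only`` and ``HN_only`` give the single model the full
    permeability; ``HN_HI`` combines both HVA models one-to-one
    (0.5 / 0.5), the composition that best matched the recorded
    ensemble HVA currents.
    """
    ghk = ghk or GHKConfig()
    if name == "HI_only":
        channels = (build_channel("HI", 1.0),)
    elif name == "HN_only":
        channels = (build_channel("HN", 1.0),)
    elif name == "HN_HI":
        channels = (build_channel("HN", 0.5), build_channel("HI", 0.5))
    else:
        raise ValueError(f"unknown scenario {name!r}; known: {_SCENARIOS}")
    return ScenarioConfig(name=name, channels=channels, ghk=ghk)


# -- conductance clamp -----------------------------------------------------


@dataclass(frozen=True)
class ClampConductance:
    """Ohmic conductance-clamp model: ``I = g_max * m * h * (V - V_rev)``."""

    name: str
    g_max_nS: float
    v_rev_mV: float
    gating: GatingParams
    instantaneous_m: bool = False

    def __post_init__(self) -> None:
        if self.g_max_nS < 0:
            raise ValueError("g_max must be non-negative")


_A_TYPE_M = GateSpec(half_mV=-30.0, slope_mV=12.0,
                     tau=TauSpec(kind="bell", base=0.25, center=-45.0,
                                 sigma_left=20.0, sigma_right=30.0,
                                 anchor_v=0.0, anchor_tau=0.6))
_A_TYPE_H = GateSpec(half_mV=-60.0, slope_mV=-6.0,
                     tau=TauSpec(kind="sigmoid", base=8.0, amp=22.0,
                                 center=-65.0, width=8.0))
# Passive control: activation instantaneous and saturated, inactivation so
# slow (1e9 ms) that the conductance stays fully on; V_rev at -70 mV keeps
# the injected current near zero at rest.
_PASSIVE_H = GateSpec(half_mV=1000.0, slope_mV=-4.0,
                      tau=TauSpec(kind="constant", value=1e9))


def a_type_clamp(g_max_nS: float = 7.0, v_rev_mV: float = -90.0) -> ClampConductance:
    """Transient (A-type) potassium conductance-clamp model."""
    return ClampConductance(name="A_type_K", g_max_nS=g_max_nS,
                            v_rev_mV=v_rev_mV,
                            gating=GatingParams(m=_A_TYPE_M, h=_A_TYPE_H))


def passive_clamp(g_max_nS: float = 7.0, v_rev_mV: float = -70.0) -> ClampConductance:
    """Always-on passive control conductance for the clamp circuit."""
    return ClampConductance(name="passive_K", g_max_nS=g_max_nS,
                            v_rev_mV=v_rev_mV,
                            gating=GatingParams(m=GateSpec(
                                half_mV=-1000.0, slope_mV=4.0,
                                tau=TauSpec(kind="constant", value=1e9)),
                                h=_PASSIVE_H),
                            instantaneous_m=True)


def clamp_current(v_mV, gate_values: dict, clamp: ClampConductance):
    """Injected clamp current in nS * mV (= pA) for given gate values."""
    v = np.asarray(v_mV, dtype=float)
    m = np.asarray(gate_values.get("m", 1.0), dtype=float)
    h = np.asarray(gate_values.get("h", 1.0), dtype=float)
    out = clamp.g_max_nS * m * h * (v - clamp.v_rev_mV)
    return out if out.ndim else float(out)


# -- parameter file interchange -------------------------------------------


def _gate_to_dict(g: GateSpec) -> dict:
    tau = {k: v for k, v in vars(g.tau).items()}
    return {"half_mV": g.half_mV, "slope_mV": g.slope_mV,
            "power": g.power, "tau": tau}


def _gate_from_dict(d: dict) -> GateSpec:
    return GateSpec(half_mV=d["half_mV"], slope_mV=d["slope_mV"],
                    power=d.get("power", 1), tau=TauSpec(**d["tau"]))


def channels_to_yaml(path: str | Path,
                     defs: dict[str, GatingParams] | None = None) -> None:
    """Write channel gating parameters as a YAML file (shipped defaults)."""
    defs = defs or _CHANNEL_DEFS
    doc = {}
    for name, gating in defs.items():
        entry = {"m": _gate_to_dict(gating.m)}
        if gating.h is not None:
            entry["h"] = _gate_to_dict(gating.h)
        doc[name] = entry
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def channels_from_yaml(path: str | Path) -> dict[str, GatingParams]:
    """Read channel gating parameters back from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"channel parameter file not found: {path}")
    doc = yaml.safe_load(path.read_text())
    out = {}
    for name, entry in doc.items():
        out[name] = GatingParams(
            m=_gate_from_dict(entry["m"]),
            h=_gate_from_dict(entry["h"]) if "h" in entry else None,
        )
    return out
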