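"""Run configuration: one declarative YAML file drives a full experiment.

The config has four sections — ``generator`` (distances, shape overrides,
dt), ``scenario`` (name, optional channel-parameter file, GHK overrides),
``experiment`` (kind and its grids) and ``output`` — plus a ``seed``.
Every field has a documented default and unknown keys are rejected, so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .channels import GHKConfig, build_scenario, channels_from_yaml
from .waveform import BAPShapeParams

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one experiment run."""

    experiment: str = "state_comparison"
    scenario: str = "HN_HI"
    preceding: str = "native"
    distances_um: tuple[float, ...] = (24.0,)
    dt_ms: float = 0.0005
    shape_overrides: dict[str, float] = field(default_factory=dict)
    ghk_overrides: dict[str, float] = field(default_factory=dict)
    channel_file: str | None = None
    offsets_mV: tuple[float, ...] | None = None
    extensions_ms: tuple[float, ...] | None = None
    phases_deg: tuple[float, ...] | None = None
    interpulse_ms: tuple[float, ...] | None = None
    act_scale_factors: tuple[float, ...] | None = None
    inact_taus_ms: tuple[float, ...] | None = None
    out_dir: str = "results"
    seed: int = 0

    def shape_params(self) -> BAPShapeParams:
        return dataclasses.replace(BAPShapeParams(), **self.shape_overrides)

    def ghk(self) -> GHKConfig:
        return dataclasses.replace(GHKConfig(), **self.ghk_overrides)

    def scenario_config(self):
        ghk = self.ghk()
        if self.channel_file is not None:
            # a channel-parameter file overrides the shipped gating tables
            defs = channels_from_yaml(self.channel_file)
            from .channels import ChannelModel, ScenarioConfig
            if self.scenario == "HN_HI":
                channels = (ChannelModel("HN", defs["HN"], 0.5),
                            ChannelModel("HI", defs["HI"], 0.5))
            elif self.scenario == "HI_only":
                channels = (ChannelModel("HI", defs["HI"], 1.0),)
            elif self.scenario == "HN_only":
                channels = (ChannelModel("HN", defs["HN"], 1.0),)
            else:
                raise ValueError(f"unknown scenario {self.scenario!r}")
            return ScenarioConfig(name=self.scenario, channels=channels, ghk=ghk)
        return build_scenario(self.scenario, ghk)


_SECTIONS = {
    "generator": {"distances_um", "dt_ms", "shape_overrides"},
    "scenario": {"name", "channel_file", "ghk_overrides"},
    "experiment": {"kind", "preceding", "offsets_mV", "extensions_ms",
                   "phases_deg", "interpulse_ms", "act_scale_factors",
                   "inact_taus_ms"},
    "output": {"directory"},
}


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration.

    Unknown sections or keys raise ``ValueError`` naming the offending
    key; referenced files must exist.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    unknown = set(doc) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"{path}: unknown config section(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for section, keys in _SECTIONS.items():
        sub = doc.get(section) or {}
        bad = set(sub) - keys
        if bad:
            raise ValueError(
                f"{path}: unknown key(s) {sorted(bad)} in section {section!r}"
            )
    gen = doc.get("generator") or {}
    if "distances_um" in gen:
        kwargs["distances_um"] = tuple(float(d) for d in gen["distances_um"])
    if "dt_ms" in gen:
        kwargs["dt_ms"] = float(gen["dt_ms"])
    if "shape_overrides" in gen:
        valid = {f.name for f in dataclasses.fields(BAPShapeParams)}
        bad = set(gen["shape_overrides"]) - valid
        if bad:
            raise ValueError(f"{path}: unknown shape override(s) {sorted(bad)}")
        kwargs["shape_overrides"] = dict(gen["shape_overrides"])
    scen = doc.get("scenario") or {}
    if "name" in scen:
        kwargs["scenario"] = str(scen["name"])
    if "channel_file" in scen:
        cf = Path(scen["channel_file"])
        if not cf.exists():
            raise ValueError(f"{path}: channel parameter file not found: {cf}")
        kwargs["channel_file"] = str(cf)
    if "ghk_overrides" in scen:
        valid = {f.name for f in dataclasses.fields(GHKConfig)}
        bad = set(scen["ghk_overrides"]) - valid
        if bad:
            raise ValueError(f"{path}: unknown GHK override(s) {sorted(bad)}")
        kwargs["ghk_overrides"] = dict(scen["ghk_overrides"])
    exp = doc.get("experiment") or {}
    if "kind" in exp:
        kwargs["experiment"] = str(exp["kind"])
    if "preceding" in exp:
        kwargs["preceding"] = str(exp["preceding"])
    for key in ("offsets_mV", "extensions_ms", "phases_deg", "interpulse_ms",
                "act_scale_factors", "inact_taus_ms"):
        if key in exp and exp[key] is not None:
            kwargs[key] = tuple(float(x) for x in exp[key])
    out = doc.get("output") or {}
    if "directory" in out:
        kwargs["out_dir"] = str(out["directory"])
    if "seed" in doc:
        kwargs["seed"] = int(doc["seed"])
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a configuration, for run manifests."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
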