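"""Uniformly sampled voltage-command traces and aligned state pairs.

The basic container of the package is :class:`VoltageTrace`: a membrane
potential command sampled on a uniform time grid (milliseconds / millivolts),
the signal a voltage-clamp amplifier is asked to play back. A
:class:`BAPStatePair` bundles the two commands recorded from the same
dendritic location at a depolarized and a hyperpolarized somatic state,
aligned at their maximum rate of rise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "VoltageTrace",
    "BAPStatePair",
    "read_trace",
    "write_trace",
]

#: physically plausible bounds for a membrane-potential command (mV)
V_MIN = -150.0
V_MAX = 80.0


@dataclass(frozen=True)
class VoltageTrace:
    """A uniformly sampled membrane-potential command.

    Parameters
    ----------
    dt
        Sampling interval in ms; strictly positive.
    samples
        Voltages in mV, at least two samples, all finite and inside
        ``[-150, +80]`` mV.
    t0
        Time of the first sample in ms (the generator puts the aligned
        maximum rate of rise at t = 0).
    meta
        Free-form provenance tags (distance, state, protocol ...).
    """

    dt: float
    samples: np.ndarray
    t0: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("a trace needs at least 2 samples in a 1-d array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace contains non-finite voltages")
        if samples.min() < V_MIN or samples.max() > V_MAX:
            raise ValueError(
                f"voltages outside the plausible [{V_MIN}, {V_MAX}] mV range"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Total covered time in ms (``(n - 1) * dt``)."""
        return (self.n - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.n)

    def index_at(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms (clipped to the trace)."""
        i = int(round((t_ms - self.t0) / self.dt))
        return min(max(i, 0), self.n - 1)

    def with_samples(self, samples: np.ndarray, **meta: Any) -> "VoltageTrace":
        """Copy of this trace with new samples and updated meta tags."""
        return replace(self, samples=samples, meta={**self.meta, **meta})

    def max_rate_of_rise_index(self) -> int:
        """Sample index of the maximum first difference (earliest on ties)."""
        dv = np.diff(self.samples)
        return int(np.argmax(dv))


@dataclass(frozen=True)
class BAPStatePair:
    """A depolarized/hyperpolarized bAP command pair from one location.

    Both traces share ``dt`` and length and are aligned so that the
    maximum rate of rise falls on the same sample index
    (``align_index``); the depolarized baseline is the more positive one.
    """

    depolarized: VoltageTrace
    hyperpolarized: VoltageTrace
    distance_um: float
    align_index: int

    def __post_init__(self) -> None:
        d, h = self.depolarized, self.hyperpolarized
        if d.dt != h.dt:
            raise ValueError("pair traces must share dt")
        if d.n != h.n:
            raise ValueError("pair traces must share length")
        if not 0 <= self.align_index < d.n:
            raise ValueError("align_index outside trace")
        # equality allowed: splicing the preceding potential equalizes them
        if d.samples[0] < h.samples[0]:
            raise ValueError("depolarized baseline must not be below hyperpolarized")

    @property
    def dt(self) -> float:
        return self.depolarized.dt

    def difference(self) -> np.ndarray:
        """Hyperpolarized-minus-depolarized voltage difference (mV)."""
        return self.hyperpolarized.samples - self.depolarized.samples


# -- plain-text interchange ------------------------------------------------

_HEADER = "time_ms\tvoltage_mV"
#: tolerated sampling jitter when reading a trace back from text (ms)
_JITTER = 1e-6


def write_trace(trace: VoltageTrace, path: str | Path) -> None:
    """Write a trace as two-column delimited text.

    Header line plus fixed-precision columns (time to 6 decimals, voltage
    to 4), so repeated writes of the same trace are byte-identical.
    """
    path = Path(path)
    lines = [_HEADER]
    for t, v in zip(trace.times, trace.samples):
        lines.append(f"{t:.6f}\t{v:.4f}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> VoltageTrace:
    """Read a two-column (time_ms, voltage_mV) text trace.

    Lines starting with ``#`` are comments. The time column must be
    uniformly sampled to within 1e-6 ms, otherwise a ``ValueError`` is
    raised rather than silently resampling.
    """
    path = Path(path)
    times: list[float] = []
    volts: list[float] = []
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {line!r}")
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                if times:  # numeric rows already seen -> genuinely bad row
                    raise ValueError(f"{path}: non-numeric row {line!r}")
                continue  # header line
            times.append(t)
            volts.append(v)
    if len(times) < 2:
        raise ValueError(f"{path}: fewer than two samples")
    t = np.asarray(times)
    dts = np.diff(t)
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > _JITTER:
        raise ValueError(f"{path}: non-uniform sampling (jitter > {_JITTER} ms)")
    return VoltageTrace(dt=dt, samples=np.asarray(volts), t0=float(t[0]),
                        meta={"source": str(path)})
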