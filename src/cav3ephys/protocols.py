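"""Voltage-clamp stimulation protocols.

Each protocol is a holding potential plus an ordered list of segments; one
segment may be sweep-varying, in which case its command voltage is taken
per sweep from ``sweep_voltages``.  All standard protocols hold at -90 mV:

* ``iv_activation`` — 100-ms steps from -90 to +60 mV (5-mV increments,
  0.2 Hz) for the current–voltage / conductance–voltage family.
* ``ssi`` — 1-s conditioning prepulses from -90 to +20 mV followed by a
  50-ms test pulse to -20 mV (0.1 Hz) for steady-state inactivation.
* ``kinetics_pulse`` — a single 100-ms depolarization to 0 mV.
* ``density_pulse`` — a single 100-ms pulse to -10 mV for current density.
* ``ph_pulse_train`` — repeated 200-ms pulses to -20 mV (0.1 Hz) used
  when comparing extracellular pH conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Segment",
    "VoltageProtocol",
    "iv_activation_protocol",
    "ssi_protocol",
    "kinetics_protocol",
    "density_protocol",
    "ph_protocol",
    "PROTOCOL_FACTORIES",
]

DEFAULT_SAMPLE_INTERVAL_MS = 0.1


@dataclass(frozen=True)
class Segment:
    duration_ms: float
    voltage_mv: Optional[float]  # None => sweep-varying segment

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class VoltageProtocol:
    name: str
    holding_potential: float
    segments: Tuple[Segment, ...]
    sweep_voltages: Tuple[float, ...]
    test_segment: int
    inter_sweep_interval_s: float
    sample_interval_ms: float = DEFAULT_SAMPLE_INTERVAL_MS

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.sample_interval_ms <= 0:
            raise ValueError("sample interval must be positive")
        if not 0 <= self.test_segment < len(self.segments):
            raise ValueError("test_segment index out of range")
        if self.name in ("iv_activation", "ssi"):
            v = np.asarray(self.sweep_voltages)
            if len(v) > 1 and not np.all(np.diff(v) > 0):
                raise ValueError(f"{self.name} sweep voltages must be strictly increasing")

    @property
    def n_sweeps(self) -> int:
        return max(1, len(self.sweep_voltages))

    def segment_voltages(self, sweep_index: int) -> Tuple[float, ...]:
        """Command voltage of every segment for one sweep."""
        out = []
        for seg in self.segments:
            if seg.voltage_mv is None:
                out.append(float(self.sweep_voltages[sweep_index]))
            else:
                out.append(seg.voltage_mv)
        return tuple(out)

    def segment_bounds_ms(self) -> Tuple[Tuple[float, float], ...]:
        edges = np.concatenate([[0.0], np.cumsum([s.duration_ms for s in self.segments])])
        return tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))

    def test_window_ms(self) -> Tuple[float, float]:
        """(start, end) of the segment whose peak current is measured."""
        return self.segment_bounds_ms()[self.test_segment]


def _steps(lo: float, hi: float, step: float) -> Tuple[float, ...]:
    n = int(round((hi - lo) / step)) + 1
    return tuple(lo + i * step for i in range(n))


def iv_activation_protocol(step_mv: float = 5.0, hold_ms: float = 20.0) -> VoltageProtocol:
    return VoltageProtocol(
        name="iv_activation",
        holding_potential=-90.0,
        segments=(
            Segment(hold_ms, -90.0),
            Segment(100.0, None),
            Segment(hold_ms, -90.0),
        ),
        sweep_voltages=_steps(-90.0, 60.0, step_mv),
        test_segment=1,
        inter_sweep_interval_s=5.0,  # 0.2 Hz
    )


def ssi_protocol(step_mv: float = 5.0, hold_ms: float = 20.0) -> VoltageProtocol:
    return VoltageProtocol(
        name="ssi",
        holding_potential=-90.0,
        segments=(
            Segment(hold_ms, -90.0),
            Segment(1000.0, None),  # conditioning prepulse
            Segment(50.0, -20.0),  # fixed test pulse
            Segment(hold_ms, -90.0),
        ),
        sweep_voltages=_steps(-90.0, 20.0, step_mv),
        test_segment=2,
        inter_sweep_interval_s=10.0,  # 0.1 Hz
    )


def kinetics_protocol(hold_ms: float = 20.0) -> VoltageProtocol:
    return VoltageProtocol(
        name="kinetics_pulse",
        holding_potential=-90.0,
        segments=(Segment(hold_ms, -90.0), Segment(100.0, 0.0), Segment(hold_ms, -90.0)),
        sweep_voltages=(0.0,),
        test_segment=1,
        inter_sweep_interval_s=10.0,
    )


def density_protocol(hold_ms: float = 20.0) -> VoltageProtocol:
    return VoltageProtocol(
        name="density_pulse",
        holding_potential=-90.0,
        segments=(Segment(hold_ms, -90.0), Segment(100.0, -10.0), Segment(hold_ms, -90.0)),
        sweep_voltages=(-10.0,),
        test_segment=1,
        inter_sweep_interval_s=10.0,
    )


def ph_protocol(n_pulses: int = 5, hold_ms: float = 20.0) -> VoltageProtocol:
    """Pulse train used for a single pH condition (one sweep per pulse)."""
    return VoltageProtocol(
        name="ph_pulse_train",
        holding_potential=-90.0,
        segments=(Segment(hold_ms, -90.0), Segment(200.0, None), Segment(hold_ms, -90.0)),
        sweep_voltages=tuple([-20.0] * n_pulses),
        test_segment=1,
        inter_sweep_interval_s=10.0,
    )


PROTOCOL_FACTORIES = {
    "iv_activation": iv_activation_protocol,
    "ssi": ssi_protocol,
    "kinetics_pulse": kinetics_protocol,
    "density_pulse": density_protocol,
    "ph_pulse_train": ph_protocol,
}
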