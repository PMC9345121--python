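"""Two-gate Hodgkin–Huxley description of a T-type (Cav3.3) calcium channel.

The channel is modelled with one activation gate ``m`` and one inactivation
gate ``h``.  Both relax first-order toward voltage-dependent steady states:

    m_inf(V) = 1 / (1 + exp((V05_act - V) / k_act))       (increasing)
    h_inf(V) = 1 / (1 + exp((V - V05_inact) / k_inact))   (decreasing)

with time constants tau_act and tau_inact.  The macroscopic current is
ohmic, ``I = gmax * m * h * (V - erev)`` (pA for gmax in nS and V in mV),
inward (negative) for test potentials below the reversal potential.

Extracellular pH rescales the maximal conductance and the inactivation
time constant via per-construct factor maps keyed by pH value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "GatingParams",
    "steady_state_activation",
    "steady_state_availability",
    "apply_ph",
    "peak_gate_product",
    "time_to_peak",
    "REFERENCE_PH",
]

REFERENCE_PH = 7.4

# Conditions of the standard pH pulse train: 200-ms steps to -20 mV from a
# holding potential of -90 mV.  Used to convert a target relative peak
# current into a conductance scale (see apply_ph).
PH_TEST_MV = -20.0
PH_HOLD_MV = -90.0
PH_PULSE_MS = 200.0


@dataclass(frozen=True)
class GatingParams:
    """Ground-truth biophysical parameters of one channel construct.

    Units: conductance nS, potentials mV, slope factors mV, time
    constants ms.  ``ph_conductance_factor`` maps pH to the relative peak
    current at that pH (the quantity reported experimentally as
    I_pHX / I_pH7.4); ``ph_tau_inact_factor`` maps pH to the relative
    inactivation time constant.
    """

    construct_label: str
    gmax: float
    erev: float
    act_v05: float
    act_slope: float
    inact_v05: float
    inact_slope: float
    tau_act: float
    tau_inact: float
    ph_conductance_factor: Mapping[float, float] = field(
        default_factory=lambda: {REFERENCE_PH: 1.0}
    )
    ph_tau_inact_factor: Mapping[float, float] = field(
        default_factory=lambda: {REFERENCE_PH: 1.0}
    )

    def __post_init__(self) -> None:
        if self.gmax < 0:
            raise ValueError(f"gmax must be >= 0, got {self.gmax}")
        if self.act_slope <= 0 or self.inact_slope <= 0:
            raise ValueError("slope factors must be positive")
        if self.tau_act <= 0 or self.tau_inact <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_inact <= self.tau_act:
            raise ValueError("tau_inact must exceed tau_act")
        for name, fmap in (
            ("ph_conductance_factor", self.ph_conductance_factor),
            ("ph_tau_inact_factor", self.ph_tau_inact_factor),
        ):
            if any(v <= 0 for v in fmap.values()):
                raise ValueError(f"{name} values must be positive")
        ref = self.ph_conductance_factor.get(REFERENCE_PH, 1.0)
        if not math.isclose(ref, 1.0):
            raise ValueError("conductance factor at reference pH 7.4 must be 1")


def steady_state_activation(v, p: GatingParams):
    """Steady-state open probability of the activation gate, m_inf(V).

    Increasing logistic of membrane potential; 0.5 at ``p.act_v05``.
    Accepts scalars or arrays.
    """
    return expit((np.asarray(v, dtype=float) - p.act_v05) / p.act_slope)


def steady_state_availability(v, p: GatingParams):
    """Steady-state availability of the inactivation gate, h_inf(V).

    Decreasing logistic of membrane potential; 0.5 at ``p.inact_v05``.
    """
    return expit((p.inact_v05 - np.asarray(v, dtype=float)) / p.inact_slope)


def peak_gate_product(
    p: GatingParams,
    v_test: float = PH_TEST_MV,
    v_hold: float = PH_HOLD_MV,
    duration_ms: float = PH_PULSE_MS,
    dt_ms: float = 0.01,
) -> float:
    """Peak of m(t)*h(t) during a single step from ``v_hold`` to ``v_test``.

    Both gates start at steady state for the holding potential and relax
    exponentially toward the test-potential steady states, so the product
    is evaluated in closed form on a dense grid.
    """
    t = np.arange(0.0, duration_ms + dt_ms, dt_ms)
    m0 = float(steady_state_activation(v_hold, p))
    h0 = float(steady_state_availability(v_hold, p))
    m_inf = float(steady_state_activation(v_test, p))
    h_inf = float(steady_state_availability(v_test, p))
    m = m_inf + (m0 - m_inf) * np.exp(-t / p.tau_act)
    h = h_inf + (h0 - h_inf) * np.exp(-t / p.tau_inact)
    return float(np.max(m * h))


def time_to_peak(tau_act: float, tau_inact: float) -> float:
    """Stationary point of (1 - exp(-t/tau_act)) * exp(-t/tau_inact).

    Closed form t_peak = tau_act * ln(1 + tau_inact / tau_act); describes
    the time of peak current for a step from full availability into a
    fully inactivating potential.
    """
    return tau_act * math.log1p(tau_inact / tau_act)


def apply_ph(p: GatingParams, ph: float) -> GatingParams:
    """Return the construct's parameters under extracellular pH ``ph``.

    ``tau_inact`` is multiplied by the construct's tau factor at that pH.
    ``gmax`` is scaled so that the *measured* relative peak current under
    the standard pH pulse (200 ms to -20 mV from -90 mV) equals the
    construct's conductance factor at that pH: when the tau factor is 1
    this is a plain multiplication of gmax by the factor; when slowed
    inactivation by itself would raise the peak, the kinetic gain is
    divided out so the simulated peak ratio reproduces the target.
    """
    if ph not in p.ph_conductance_factor or ph not in p.ph_tau_inact_factor:
        raise KeyError(f"no pH factors defined for pH {ph} on {p.construct_label}")
    peak_factor = p.ph_conductance_factor[ph]
    tau_factor = p.ph_tau_inact_factor[ph]
    if ph == REFERENCE_PH:
        return p
    scaled = replace(p, tau_inact=p.tau_inact * tau_factor)
    if tau_factor == 1.0:
        kinetic_gain = 1.0
    else:
        kinetic_gain = peak_gate_product(scaled) / peak_gate_product(p)
    return replace(scaled, gmax=p.gmax * peak_factor / kinetic_gain)
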