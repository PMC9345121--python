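"""Ground-truth parameter sets for the wild-type channel and the five
hemiplegic-migraine-associated Cav3.3 variants (R111G, M128L, D302G,
R307H, Q1158H).

Voltage-dependence, kinetics, current-density and pH values are the
published whole-cell characterization means for each construct.
Activation slope factors were not reported for R111G, D302G, R307H and
Q1158H; those default to the wild-type slope (5.8 mV) and are flagged in
``SLOPE_DEFAULTED``.

The maximal conductance of each construct is not a reported quantity;
it is calibrated so that a default cohort's mean current density
(pA/pF) at the standard -10 mV density pulse equals the construct's
reported mean.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from functools import lru_cache
from typing import Dict, Tuple

from .gating import GatingParams, REFERENCE_PH, peak_gate_product
from .simulate import CohortVariability

__all__ = [
    "CONSTRUCT_LABELS",
    "WT_LABEL",
    "DENSITY_TARGETS_PA_PF",
    "SLOPE_DEFAULTED",
    "construct_params",
    "default_constructs",
]

WT_LABEL = "WT"
CONSTRUCT_LABELS: Tuple[str, ...] = ("WT", "R111G", "M128L", "D302G", "R307H", "Q1158H")

DEFAULT_EREV_MV = 45.0  # ohmic reversal for 10 mM external Ca2+
DENSITY_PULSE_MV = -10.0
DENSITY_PULSE_MS = 100.0
WT_ACT_SLOPE = 5.8

# construct -> (density pA/pF, act_v05, act_slope|None, inact_v05,
#               inact_slope, tau_act, tau_inact)
_TABLE = {
    "WT": (208.4, -20.6, 5.8, -47.1, 6.9, 4.6, 40.9),
    "R111G": (153.0, -21.3, None, -47.0, 7.2, 4.8, 35.6),
    "M128L": (196.0, -23.3, 5.1, -45.0, 6.8, 4.8, 45.3),
    "D302G": (120.5, -21.3, None, -49.5, 7.4, 5.9, 39.0),
    "R307H": (104.2, -19.8, None, -45.7, 7.2, 8.0, 60.3),
    "Q1158H": (133.1, -17.6, None, -43.3, 7.9, 7.3, 56.0),
}

# construct -> pH -> relative peak current (I_pHX / I_pH7.4)
_PH_PEAK = {
    "WT": {6.5: 0.54, 8.0: 1.29},
    "R307H": {6.5: 0.68, 8.0: 1.25},
    "Q1158H": {6.5: 0.75, 8.0: 1.06},
}

# construct -> pH -> relative inactivation time constant
_PH_TAU = {
    "Q1158H": {8.0: 1.38},
}

DENSITY_TARGETS_PA_PF: Dict[str, float] = {k: v[0] for k, v in _TABLE.items()}
SLOPE_DEFAULTED = frozenset(k for k, v in _TABLE.items() if v[2] is None)


@lru_cache(maxsize=1)
def _mean_inverse_capacitance() -> float:
    """E[1/C] (1/pF) under the default positive-truncated normal capacitance."""
    from scipy import stats

    var = CohortVariability()
    mu, sd = var.capacitance_mean_pf, var.capacitance_sd_pf
    lo = (var.capacitance_min_pf - mu) / sd
    dist = stats.truncnorm(lo, np.inf, loc=mu, scale=sd)
    return float(dist.expect(lambda c: 1.0 / c))


@lru_cache(maxsize=None)
def construct_params(label: str, erev: float = DEFAULT_EREV_MV) -> GatingParams:
    """Calibrated :class:`GatingParams` for one construct."""
    if label not in _TABLE:
        raise KeyError(f"unknown construct {label!r}; known: {CONSTRUCT_LABELS}")
    density, act_v05, act_slope, inact_v05, inact_slope, tau_act, tau_inact = _TABLE[label]
    ph_peak = {REFERENCE_PH: 1.0, **_PH_PEAK.get(label, {})}
    ph_tau = {REFERENCE_PH: 1.0, 6.5: 1.0, 8.0: 1.0, **_PH_TAU.get(label, {})}
    p = GatingParams(
        construct_label=label,
        gmax=1.0,
        erev=erev,
        act_v05=act_v05,
        act_slope=WT_ACT_SLOPE if act_slope is None else act_slope,
        inact_v05=inact_v05,
        inact_slope=inact_slope,
        tau_act=tau_act,
        tau_inact=tau_inact,
        ph_conductance_factor=ph_peak,
        ph_tau_inact_factor=ph_tau,
    )
    # gmax so the *cohort mean* density hits the reported value under the
    # default capacitance dispersion: mean density is gmax*peak*E[1/C],
    # and E[1/C] exceeds 1/mean(C) for a dispersed cohort (Jensen)
    peak_per_ns = peak_gate_product(
        p, v_test=DENSITY_PULSE_MV, v_hold=-90.0, duration_ms=DENSITY_PULSE_MS
    ) * abs(DENSITY_PULSE_MV - erev)
    gmax = density / (peak_per_ns * _mean_inverse_capacitance())
    return replace(p, gmax=gmax)


def default_constructs(erev: float = DEFAULT_EREV_MV) -> Dict[str, GatingParams]:
    """All six constructs, wild type first."""
    return {label: construct_params(label, erev) for label in CONSTRUCT_LABELS}
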