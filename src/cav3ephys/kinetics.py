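"""Exponential-product kinetics fits and window-current areas.

The transient evoked by a depolarizing step is fitted with the product of
a single-exponential activation and a single-exponential inactivation,

    I(t) = C * (1 - exp(-(t - t0)/tau_act)) * exp(-(t - t0)/tau_inact),

where ``C`` is the y-intercept scale of the decay.  A fitted sustained
fraction lets the decay relax toward a small plateau instead of zero, so
tau_inact stays unbiased at test potentials where steady-state
availability has not vanished (the fraction fits ~0 for a strongly
inactivating pulse and the equation reduces to the pure product).

The window current is
the area under the pointwise minimum of the normalized activation and
availability Boltzmann curves — the voltage band where channels are both
activatable and not inactivated, hence a tonic calcium influx.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .gating import time_to_peak
from .simulate import Sweep
from .voltage import BoltzmannFit

__all__ = [
    "KineticsFit",
    "WindowCurrentResult",
    "fit_kinetics",
    "window_area",
    "window_ratio",
    "DEFAULT_WINDOW_RANGE_MV",
    "DEFAULT_GRID_STEP_MV",
]

DEFAULT_WINDOW_RANGE_MV = (-90.0, 20.0)
DEFAULT_GRID_STEP_MV = 0.01


@dataclass(frozen=True)
class KineticsFit:
    tau_act: float  # ms
    tau_inact: float  # ms
    amplitude_c: float  # pA (y-intercept scale C)
    t0: float  # ms, pulse-onset delay
    rss: float
    converged: bool
    sustained_fraction: float = 0.0  # residual (window) fraction of the decay


@dataclass(frozen=True)
class WindowCurrentResult:
    area: float  # mV * (dimensionless fraction)
    v_range: Tuple[float, float]
    grid_step: float
    ratio_vs_reference: Optional[float] = None


def _product_model(t, c, tau_a, tau_i, t0, f_ss=0.0):
    dt = np.clip(t - t0, 0.0, None)
    decay = f_ss + (1.0 - f_ss) * np.exp(-dt / tau_i)
    return c * (1.0 - np.exp(-dt / tau_a)) * decay


def _solve_tau_act(t_peak: float, tau_i: float) -> float:
    """Invert t_peak = tau_a * ln(1 + tau_i/tau_a) for tau_a (fixed point)."""
    tau_a = max(t_peak / 3.0, 1e-3)
    for _ in range(60):
        nxt = t_peak / math.log1p(tau_i / tau_a)
        if abs(nxt - tau_a) < 1e-10:
            tau_a = nxt
            break
        tau_a = nxt
    return tau_a


def fit_kinetics(sweep: Sweep, test_window: Optional[Tuple[float, float]] = None) -> KineticsFit:
    """Fit the exponential-product equation to one depolarizing sweep.

    The test segment is located as the first segment more depolarized
    than the initial holding level unless ``test_window`` is given.
    The current is baseline-subtracted and sign-rectified so the fitted
    transient is positive; initial guesses follow the closed-form
    time-to-peak relation and a log-linear regression of the decay tail.
    Optimizer failure is reported via ``converged=False``, never raised.
    """
    t = sweep.time_ms
    if test_window is None:
        hold_v = sweep.segment_voltages[0]
        bounds = np.flatnonzero(np.abs(np.diff(sweep.command_mv)) > 1e-9)
        start = None
        for b in bounds:
            if sweep.command_mv[b + 1] > hold_v + 1e-9:
                start = t[b + 1]
                after = bounds[bounds > b]
                end = t[after[0]] if after.size else t[-1]
                break
        if start is None:
            raise ValueError("sweep has no depolarizing segment")
        test_window = (float(start), float(end))
    start, end = test_window
    hold_v = sweep.command_mv[0]
    pre = sweep.current_pa[(t < start) & (np.abs(sweep.command_mv - hold_v) < 1e-9)]
    baseline = float(np.mean(pre)) if pre.size else 0.0
    mask = (t >= start) & (t <= end)
    tt = t[mask]
    y = sweep.current_pa[mask] - baseline
    if tt.size < 10:
        raise ValueError("test segment too short for a kinetics fit")
    sign = -1.0 if y[np.argmax(np.abs(y))] < 0 else 1.0
    y = sign * y  # rectified: transient is positive

    def failed() -> KineticsFit:
        return KineticsFit(float("nan"), float("nan"), float("nan"), float("nan"),
                           float("nan"), False, float("nan"))

    peak = float(np.max(y))
    if peak <= 0:
        return failed()
    i_pk = int(np.argmax(y))
    t_pk = float(tt[i_pk] - start)
    # tail log-linear regression for tau_inact
    tail = slice(min(i_pk + 5, tt.size - 5), tt.size)
    yt = y[tail]
    pos = yt > peak * 1e-4
    if np.count_nonzero(pos) >= 5:
        coef = np.polyfit(tt[tail][pos], np.log(yt[pos]), 1)
        tau_i0 = -1.0 / coef[0] if coef[0] < 0 else 5.0 * t_pk
    else:
        tau_i0 = 5.0 * max(t_pk, 1.0)
    tau_i0 = float(np.clip(tau_i0, 0.5, 1e4))
    tau_a0 = float(np.clip(_solve_tau_act(max(t_pk, 1e-2), tau_i0), 0.05, 1e3))
    c0 = peak / max(
        _product_model(np.array([start + t_pk]), 1.0, tau_a0, tau_i0, start)[0], 1e-6
    )
    # the sustained fraction lets the decay relax toward a non-zero
    # plateau -- the window-current level at test potentials where the
    # availability curve has not reached zero; it fits ~0 for a strongly
    # inactivating pulse and keeps tau_inact unbiased otherwise
    try:
        popt, _ = curve_fit(
            _product_model, tt, y,
            p0=[c0, tau_a0, tau_i0, start, 0.005],
            bounds=(
                [0.0, 1e-3, 1e-3, start - 2.0, 0.0],
                [np.inf, 1e4, 1e5, start + 10.0, 0.5],
            ),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return failed()
    c, tau_a, tau_i, t0, f_ss = (float(x) for x in popt)
    rss = float(np.sum((y - _product_model(tt, *popt)) ** 2))
    return KineticsFit(
        tau_act=tau_a, tau_inact=tau_i, amplitude_c=sign * c, t0=t0,
        rss=rss, converged=np.isfinite(rss), sustained_fraction=f_ss,
    )


def _logistic(v, v05, slope, sign):
    return 1.0 / (1.0 + np.exp(sign * (v05 - v) / slope))


def window_area(
    act: BoltzmannFit,
    inact: BoltzmannFit,
    v_range: Tuple[float, float] = DEFAULT_WINDOW_RANGE_MV,
    grid_step: float = DEFAULT_GRID_STEP_MV,
) -> WindowCurrentResult:
    """Trapezoid area under min(activation, availability) over ``v_range``.

    Units: mV × dimensionless fraction.  The activation fit must be
    increasing and the availability fit decreasing.
    """
    lo, hi = v_range
    if hi <= lo:
        raise ValueError("invalid voltage range")
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    if act.orientation != "activation" or inact.orientation != "inactivation":
        raise ValueError("window_area needs one activation and one inactivation fit")
    v = np.arange(lo, hi + grid_step / 2, grid_step)
    act_curve = _logistic(v, act.v05, act.slope, 1.0)
    inact_curve = _logistic(v, inact.v05, inact.slope, -1.0)
    area = float(np.trapezoid(np.minimum(act_curve, inact_curve), v))
    return WindowCurrentResult(area=area, v_range=(lo, hi), grid_step=grid_step)


def window_ratio(variant: WindowCurrentResult, reference: WindowCurrentResult) -> float:
    """Window-area ratio of a variant against the reference channel."""
    if variant.v_range != reference.v_range or variant.grid_step != reference.grid_step:
        raise ValueError("window results must share voltage range and grid step")
    if reference.area <= 0:
        raise ValueError("reference window area is zero")
    return variant.area / reference.area
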