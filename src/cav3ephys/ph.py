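"""Within-cell extracellular-pH modulation analysis.

Peak-current and inactivation-kinetics changes are expressed as ratios of
the test-pH condition against the reference condition (pH 7.4) measured
in the same cell.  Ratios use the steady-state block of each condition:
the last ``n_steady`` pulses of the train, averaged.  Cohorts of ratios
are compared with a paired t-test (within construct, against no change)
and a one-way ANOVA with Tukey's HSD across constructs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .kinetics import fit_kinetics
from .simulate import Recording
from .voltage import peak_current

__all__ = [
    "PhPairedMeasure",
    "PairedTestResult",
    "AnovaTukeyResult",
    "ph_ratios",
    "paired_test",
    "across_construct_test",
    "N_STEADY_SWEEPS",
]

N_STEADY_SWEEPS = 3


@dataclass(frozen=True)
class PhPairedMeasure:
    cell_id: str
    construct_label: str
    ph_test: float
    peak_ratio: float  # I_pHX / I_pH7.4
    tau_ratio: float  # tau_inact(pHX) / tau_inact(pH7.4)


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n: int
    mean_difference: float


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairwise_p: Mapping[Tuple[str, str], float]


def _steady_peak(rec: Recording, n_steady: int) -> float:
    window = rec.protocol.test_window_ms()
    peaks = [abs(peak_current(sw, window).i_peak) for sw in rec.sweeps[-n_steady:]]
    return float(np.mean(peaks))


def _steady_tau_inact(rec: Recording, n_steady: int) -> float:
    taus = []
    for sw in rec.sweeps[-n_steady:]:
        fit = fit_kinetics(sw)
        if fit.converged:
            taus.append(fit.tau_inact)
    if not taus:
        raise ValueError(f"no convergent kinetics fit for cell {rec.cell_id}")
    return float(np.mean(taus))


def ph_ratios(
    rec_ref: Recording,
    rec_test: Recording,
    n_steady: int = N_STEADY_SWEEPS,
    fit_tau: bool = True,
) -> PhPairedMeasure:
    """Paired peak-current and tau_inact ratios for one cell.

    ``rec_ref`` must be the pH 7.4 recording and ``rec_test`` the same
    cell under the test pH with the same protocol.  Set ``fit_tau=False``
    to skip the kinetics fits (tau_ratio is then NaN).
    """
    if rec_ref.cell_id != rec_test.cell_id:
        raise ValueError("paired recordings must come from the same cell")
    if rec_ref.protocol.name != rec_test.protocol.name:
        raise ValueError("paired recordings must share the stimulation protocol")
    if rec_ref.ph == rec_test.ph:
        raise ValueError("reference and test recordings have the same pH")
    peak_ref = _steady_peak(rec_ref, n_steady)
    if peak_ref <= 0:
        raise ValueError("reference peak current is zero")
    peak_ratio = _steady_peak(rec_test, n_steady) / peak_ref
    if fit_tau:
        tau_ratio = _steady_tau_inact(rec_test, n_steady) / _steady_tau_inact(rec_ref, n_steady)
    else:
        tau_ratio = float("nan")
    return PhPairedMeasure(
        cell_id=rec_ref.cell_id,
        construct_label=rec_ref.construct_label,
        ph_test=rec_test.ph,
        peak_ratio=peak_ratio,
        tau_ratio=tau_ratio,
    )


def paired_test(ratios: Sequence[float], null_value: float = 1.0) -> PairedTestResult:
    """Two-sided paired t-test of per-cell ratios against ``null_value``.

    Equivalent to the classical paired t-test on per-cell differences.
    Zero variance of the differences is an error (the statistic is
    undefined), as is n < 2.
    """
    x = np.asarray(ratios, dtype=float)
    if x.size < 2:
        raise ValueError("paired test needs at least 2 pairs")
    d = x - null_value
    if np.ptp(d) < 1e-15:
        raise ValueError("zero variance of paired differences; t undefined")
    res = stats.ttest_1samp(d, 0.0)
    return PairedTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size),
        mean_difference=float(np.mean(d)),
    )


def across_construct_test(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey HSD pairwise comparisons across constructs.

    ``groups`` maps construct label to its per-cell ratios.  Every group
    needs n >= 2; identical constant groups make F undefined and raise.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, a in zip(labels, arrays):
        if a.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    if all(np.ptp(a) < 1e-15 for a in arrays):
        raise ValueError("all groups constant; F statistic undefined")
    f_res = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairwise: Dict[Tuple[str, str], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairwise[(labels[i], labels[j])] = float(tukey.pvalue[i, j])
    n_total = sum(a.size for a in arrays)
    return AnovaTukeyResult(
        f_statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        df_between=len(labels) - 1,
        df_within=n_total - len(labels),
        pairwise_p=pairwise,
    )
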