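"""Replicate-aware cohort summaries and group comparisons.

Per-cell values nested within biological replicates (transfection days)
are summarized SuperPlot-style: the grand mean and SEM pool all cells,
while per-batch means are carried for display.  Wild-type vs. variant
comparisons use the classical equal-variance Student's t-test (Welch by
flag) with the significance tiers *** (p <= 0.001), ** (0.001 < p <=
0.01), * (0.01 < p <= 0.05), ns otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "SuperPlotSummary",
    "ComparisonResult",
    "superplot_summary",
    "significance_tier",
    "unpaired_t",
]

MIN_RECOMMENDED_N = 5


@dataclass(frozen=True)
class SuperPlotSummary:
    construct_label: str
    parameter_name: str
    per_cell_values: Tuple[Tuple[float, str, int], ...]  # (value, batch, hours)
    per_batch_means: Tuple[Tuple[str, float], ...]
    grand_mean: float
    sem: float
    n_cells: int
    sem_defined: bool


@dataclass(frozen=True)
class ComparisonResult:
    parameter_name: str
    group_a: str
    group_b: str
    t_statistic: float
    p_value: float
    significance_tier: str


def superplot_summary(
    values: Sequence[Tuple[float, str, int]],
    construct_label: str = "",
    parameter_name: str = "",
) -> SuperPlotSummary:
    """Pooled mean +/- SEM over cells, with per-batch means for display.

    ``values`` is a sequence of (value, replicate_batch, hours) tuples.
    A single cell yields SEM 0 with ``sem_defined=False``.
    """
    if not values:
        raise ValueError("empty input")
    vals = np.asarray([v[0] for v in values], dtype=float)
    batches: Dict[str, List[float]] = {}
    for v, batch, _hours in values:
        batches.setdefault(batch, []).append(v)
    n = vals.size
    sem_defined = n > 1
    sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if sem_defined else 0.0
    return SuperPlotSummary(
        construct_label=construct_label,
        parameter_name=parameter_name,
        per_cell_values=tuple((float(v), b, int(h)) for v, b, h in values),
        per_batch_means=tuple(
            (b, float(np.mean(vs))) for b, vs in sorted(batches.items())
        ),
        grand_mean=float(np.mean(vals)),
        sem=sem,
        n_cells=n,
        sem_defined=sem_defined,
    )


def significance_tier(p: float) -> str:
    """Tier partition of (0, 1]: closed upper bounds at 0.001, 0.01, 0.05."""
    if not np.isfinite(p):
        return "ns"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def unpaired_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    parameter_name: str = "",
    label_a: str = "a",
    label_b: str = "b",
    welch: bool = False,
) -> ComparisonResult:
    """Two-sided Student's t-test (equal variance; Welch via ``welch=True``).

    Groups below n = 5 trigger a warning (small-sample conclusions are
    fragile) but are still tested; both groups constant and equal yields
    the t = 0, p = 1 convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if min(a.size, b.size) < MIN_RECOMMENDED_N:
        warnings.warn(
            f"group n < {MIN_RECOMMENDED_N}; comparison is underpowered", stacklevel=2
        )
    if np.ptp(a) < 1e-15 and np.ptp(b) < 1e-15:
        if abs(float(np.mean(a)) - float(np.mean(b))) < 1e-15:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float("inf") * np.sign(np.mean(a) - np.mean(b)), 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        parameter_name=parameter_name,
        group_a=label_a,
        group_b=label_b,
        t_statistic=t_stat,
        p_value=p,
        significance_tier=significance_tier(p),
    )
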