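"""Rare-variant allelic burden analysis.

Given a table of rare protein-coding variants with case and control
minor-allele frequencies, the burden statistic aggregates alternate
alleles across all variants: the case count sums observed alternate
alleles over variants (``round(MAF_i * 2 * N)`` per variant, which for
heterozygous carriers equals the carrier count), and the same estimation
is applied to each control cohort, whose individual-level genotypes are
summarized only by per-variant MAFs.  The aggregated 2x2 table
(alternate/reference x case/control) is compared with a Pearson
chi-square statistic (no continuity correction) whose p-value is the
upper tail of the chi-square(1) distribution, plus an odds ratio on the
aggregated allele frequencies.  A Fisher exact option exists for small
counts.

The ten CACNA1I variants found in the 187-proband hemiplegic-migraine
cohort ship as a TSV fixture (``cav3ephys.data``), with per-variant MAFs
for the gnomAD non-Finnish-European and UK Biobank control cohorts and
in-silico predictor verdicts passed through as opaque annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

__all__ = [
    "VariantRecord",
    "BurdenCounts",
    "BurdenResult",
    "bundled_variant_table",
    "read_variant_table",
    "filter_rare",
    "aggregate_counts",
    "burden_test",
    "DEFAULT_N_CASE",
    "DEFAULT_CONTROL_N",
]

DEFAULT_N_CASE = 187
DEFAULT_CONTROL_N = {"gnomad_nfe_maf": 50_000, "ukbiobank_maf": 43_000}

_REQUIRED_COLUMNS = ("locus", "aa_change", "case_maf")
_NON_CONTROL_MAF = {"case_maf"}


@dataclass(frozen=True)
class VariantRecord:
    sample_ids: Tuple[str, ...]
    locus: str  # chromosome:position, 1-based
    protein_change: str
    coding_change: str
    predictor_annotations: Mapping[str, str]
    case_maf: float
    control_mafs: Mapping[str, float]
    rsid: str


@dataclass(frozen=True)
class BurdenCounts:
    case_alt: int
    case_total: int
    ctrl_alt: int
    ctrl_total: int
    n_variants: int

    def __post_init__(self) -> None:
        if self.case_total <= 0 or self.ctrl_total <= 0:
            raise ValueError("allele totals must be positive")
        if self.case_alt > self.case_total or self.ctrl_alt > self.ctrl_total:
            raise ValueError("alternate counts exceed totals")


@dataclass(frozen=True)
class BurdenResult:
    case_freq: float
    ctrl_freq: float
    odds_ratio: float
    chi2: float
    p_value: float
    cohort_label: str


def bundled_variant_table() -> Path:
    """Path of the packaged CACNA1I variant TSV."""
    return Path(resources.files("cav3ephys").joinpath("data/cacna1i_variants.tsv"))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def read_variant_table(path: str | Path) -> List[VariantRecord]:
    """Parse a variant TSV into records.

    Requires columns ``locus``, ``aa_change``, ``case_maf`` and at least
    one control MAF column (any other ``*_maf``).  Malformed rows are
    reported with their line numbers in a single error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    control_cols = [
        c for c in df.columns if c.endswith("_maf") and c not in _NON_CONTROL_MAF
    ]
    if not control_cols:
        raise ValueError("no control MAF column (expected at least one '*_maf')")
    maf_cols = ["case_maf", *control_cols]
    predictor_cols = [
        c
        for c in df.columns
        if c not in maf_cols and c not in ("sample_ids", "locus", "aa_change", "coding", "rsid")
    ]
    records: List[VariantRecord] = []
    problems: List[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        mafs: Dict[str, float] = {}
        for col in maf_cols:
            raw = row[col].strip()
            try:
                val = float(raw)
            except ValueError:
                problems.append(f"line {line_no}: unparseable {col} value {raw!r}")
                continue
            if not 0.0 <= val <= 0.5:
                problems.append(f"line {line_no}: {col}={val} outside [0, 0.5]")
                continue
            mafs[col] = val
        if len(mafs) < len(maf_cols):
            continue
        if ":" not in row["locus"]:
            problems.append(f"line {line_no}: unparseable locus {row['locus']!r}")
            continue
        records.append(
            VariantRecord(
                sample_ids=tuple(s for s in row.get("sample_ids", "").split(",") if s),
                locus=row["locus"],
                protein_change=row["aa_change"],
                coding_change=row.get("coding", ""),
                predictor_annotations={c: row[c] for c in predictor_cols},
                case_maf=mafs["case_maf"],
                control_mafs={c: mafs[c] for c in control_cols},
                rsid=row.get("rsid", ""),
            )
        )
    if problems:
        raise ValueError("malformed variant rows: " + "; ".join(problems))
    return records


def filter_rare(
    records: Sequence[VariantRecord],
    threshold: float = 0.01,
    columns: Optional[Sequence[str]] = None,
) -> List[VariantRecord]:
    """Keep variants whose tested control MAFs are all below ``threshold``.

    ``columns`` defaults to every control cohort present on the records.
    """
    if not 0 < threshold <= 0.5:
        raise ValueError("threshold must lie in (0, 0.5]")
    out = []
    for rec in records:
        cols = list(rec.control_mafs) if columns is None else list(columns)
        for col in cols:
            if col not in rec.control_mafs:
                raise KeyError(f"unknown control MAF column {col!r} on {rec.protein_change}")
        if all(rec.control_mafs[c] < threshold for c in cols):
            out.append(rec)
    return out


def aggregate_counts(
    records: Sequence[VariantRecord],
    n_case: int,
    control_cohort: str,
    n_ctrl: int,
) -> BurdenCounts:
    """Aggregate alternate-allele counts across variants for case and control.

    Per variant, alternate alleles are estimated as
    ``round(MAF * 2 * N)`` (nearest integer, ties away from zero); the
    total allele count is ``2 * N * V`` for ``V`` variants.
    """
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("cohort sizes must be positive")
    if not records:
        raise ValueError("no variants to aggregate (totals would be zero)")
    case_alt = 0
    ctrl_alt = 0
    for rec in records:
        if control_cohort not in rec.control_mafs:
            raise ValueError(
                f"variant {rec.protein_change} lacks control MAF column {control_cohort!r}"
            )
        case_alt += _round_half_away(rec.case_maf * 2 * n_case)
        ctrl_alt += _round_half_away(rec.control_mafs[control_cohort] * 2 * n_ctrl)
    v = len(records)
    return BurdenCounts(
        case_alt=case_alt,
        case_total=2 * n_case * v,
        ctrl_alt=ctrl_alt,
        ctrl_total=2 * n_ctrl * v,
        n_variants=v,
    )


def burden_test(
    counts: BurdenCounts,
    cohort_label: str = "control",
    method: str = "chi2",
) -> BurdenResult:
    """Compare aggregated case vs. control allele frequencies.

    ``method='chi2'`` (default) uses the Pearson statistic on the 2x2
    alternate/reference x case/control table without continuity
    correction; its p-value is the upper tail of chi-square with 1 df.
    ``method='fisher'`` substitutes Fisher's exact test (one-sided,
    greater burden in cases) for small counts.
    """
    case_ref = counts.case_total - counts.case_alt
    ctrl_ref = counts.ctrl_total - counts.ctrl_alt
    f_case = counts.case_alt / counts.case_total
    f_ctrl = counts.ctrl_alt / counts.ctrl_total
    if counts.case_alt + counts.ctrl_alt == 0 or case_ref + ctrl_ref == 0:
        raise ValueError("degenerate 2x2 margin; odds ratio undefined")
    if f_case in (0.0, 1.0) or f_ctrl in (0.0, 1.0):
        odds_ratio = float("inf") if f_ctrl in (0.0,) else 0.0
    else:
        odds_ratio = (f_case / (1 - f_case)) / (f_ctrl / (1 - f_ctrl))
    table = [[counts.case_alt, case_ref], [counts.ctrl_alt, ctrl_ref]]
    if method == "chi2":
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        chi2, p = float(chi2), float(p)
    elif method == "fisher":
        _, p = stats.fisher_exact(table, alternative="greater")
        chi2, p = float("nan"), float(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return BurdenResult(
        case_freq=f_case,
        ctrl_freq=f_ctrl,
        odds_ratio=float(odds_ratio),
        chi2=chi2,
        p_value=p,
        cohort_label=cohort_label,
    )
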