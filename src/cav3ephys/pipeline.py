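"""End-to-end simulate -> analyze -> compare pipeline.

The master seed fans out via ``numpy.random.SeedSequence`` spawning: one
child per (construct, protocol) cohort, then one grandchild per cell, so
every cohort and cell is independently reproducible.  Per-cell fitted
parameters are summarized as the mean over cells (matching per-cell
mean +/- SEM reporting), never as a fit to pooled points.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import burden as burden_mod
from .cohort_stats import superplot_summary, unpaired_t
from .constructs import CONSTRUCT_LABELS, WT_LABEL, construct_params
from .gating import REFERENCE_PH
from .kinetics import fit_kinetics, window_area, window_ratio
from .ph import ph_ratios
from .protocols import (
    density_protocol,
    iv_activation_protocol,
    kinetics_protocol,
    ph_protocol,
    ssi_protocol,
)
from .simulate import (
    CohortVariability,
    DEFAULT_NOISE_SD_PA,
    Recording,
    generate_cohort,
    generate_ph_pairs,
)
from .voltage import build_availability, build_gv, current_density, fit_boltzmann

__all__ = [
    "analyze_iv",
    "analyze_ssi",
    "analyze_kinetics",
    "characterize_construct",
    "ph_cohort_ratios",
    "run_pipeline",
    "DEFAULT_CONFIG",
]

SCHEMA_VERSION = 1

DEFAULT_CONFIG: Dict = {
    "constructs": list(CONSTRUCT_LABELS),
    "n_cells": 12,
    "seed": 0,
    "noise_sd": DEFAULT_NOISE_SD_PA,
    "analyses": ["density", "activation", "ssi", "kinetics", "window", "ph"],
    "ph_values": [6.5, 8.0],
    "out_dir": None,
}


def analyze_iv(rec: Recording, erev: float = 45.0):
    """Activation Boltzmann fit from one cell's I–V family."""
    return fit_boltzmann(build_gv(rec, erev=erev), "activation")


def analyze_ssi(rec: Recording):
    """Availability Boltzmann fit from one cell's SSI family."""
    return fit_boltzmann(build_availability(rec), "inactivation")


def analyze_kinetics(rec: Recording):
    """Exponential-product kinetics fit from one cell's 0-mV pulse."""
    return fit_kinetics(rec.sweeps[0])


def characterize_construct(
    label: str,
    n_cells: int,
    seed: int | np.random.SeedSequence,
    noise_sd: float = DEFAULT_NOISE_SD_PA,
    variability: Optional[CohortVariability] = None,
    analyses: Sequence[str] = ("density", "activation", "ssi", "kinetics"),
) -> pd.DataFrame:
    """Simulate a cohort of one construct and fit every requested quantity.

    Returns one row per cell with columns among ``density``, ``act_v05``,
    ``act_slope``, ``inact_v05``, ``inact_slope``, ``tau_act``,
    ``tau_inact`` plus cell metadata.
    """
    params = construct_params(label)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    proto_seeds = ss.spawn(4)
    cohorts: Dict[str, List[Recording]] = {}
    if "density" in analyses:
        cohorts["density"] = generate_cohort(
            params, density_protocol(), n_cells, variability, proto_seeds[0], noise_sd
        )
    if "activation" in analyses:
        cohorts["activation"] = generate_cohort(
            params, iv_activation_protocol(), n_cells, variability, proto_seeds[1], noise_sd
        )
    if "ssi" in analyses:
        cohorts["ssi"] = generate_cohort(
            params, ssi_protocol(), n_cells, variability, proto_seeds[2], noise_sd
        )
    if "kinetics" in analyses:
        cohorts["kinetics"] = generate_cohort(
            params, kinetics_protocol(), n_cells, variability, proto_seeds[3], noise_sd
        )

    rows = []
    for i in range(n_cells):
        meta = next(iter(cohorts.values()))[i]
        row: Dict = {
            "construct": label,
            "cell_id": f"{label}_c{i:03d}",
            "replicate_batch": meta.replicate_batch,
            "hours_post_transfection": meta.hours_post_transfection,
        }
        if "density" in cohorts:
            row["density"] = current_density(cohorts["density"][i]).density
        if "activation" in cohorts:
            fit = analyze_iv(cohorts["activation"][i])
            row["act_v05"] = fit.v05 if fit.converged else np.nan
            row["act_slope"] = fit.slope if fit.converged else np.nan
        if "ssi" in cohorts:
            fit = analyze_ssi(cohorts["ssi"][i])
            row["inact_v05"] = fit.v05 if fit.converged else np.nan
            row["inact_slope"] = fit.slope if fit.converged else np.nan
        if "kinetics" in cohorts:
            kin = analyze_kinetics(cohorts["kinetics"][i])
            row["tau_act"] = kin.tau_act if kin.converged else np.nan
            row["tau_inact"] = kin.tau_inact if kin.converged else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def ph_cohort_ratios(
    label: str,
    ph_test: float,
    n_cells: int,
    seed: int | np.random.SeedSequence,
    noise_sd: float = DEFAULT_NOISE_SD_PA,
    variability: Optional[CohortVariability] = None,
    fit_tau: bool = True,
) -> pd.DataFrame:
    """Per-cell paired peak and tau ratios for one construct at one test pH."""
    params = construct_params(label)
    pairs = generate_ph_pairs(
        params, ph_protocol(), n_cells, ph_test, variability, seed, noise_sd
    )
    rows = []
    for ref, test in pairs:
        m = ph_ratios(ref, test, fit_tau=fit_tau)
        rows.append(
            {
                "construct": label,
                "cell_id": m.cell_id,
                "ph_test": ph_test,
                "peak_ratio": m.peak_ratio,
                "tau_ratio": m.tau_ratio,
            }
        )
    return pd.DataFrame(rows)


_PARAM_COLUMNS = (
    "density",
    "act_v05",
    "act_slope",
    "inact_v05",
    "inact_slope",
    "tau_act",
    "tau_inact",
)


def run_pipeline(config: Optional[Mapping] = None) -> Dict:
    """Simulate, analyze, and compare every requested construct.

    Returns the JSON-ready summary dict; when ``out_dir`` is set, also
    writes ``density.tsv``, ``gv_fits.tsv``, ``ssi_fits.tsv``,
    ``kinetics.tsv``, ``window.tsv``, ``ph_ratios.tsv`` and
    ``summary.json``.  Failures are isolated per construct under the
    summary's ``errors`` key rather than aborting the run.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    labels = list(cfg["constructs"])
    analyses = list(cfg["analyses"])
    master = np.random.SeedSequence(int(cfg["seed"]))
    construct_seeds = dict(zip(CONSTRUCT_LABELS, master.spawn(len(CONSTRUCT_LABELS))))
    fit_analyses = [a for a in ("density", "activation", "ssi", "kinetics") if a in analyses]

    summary: Dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": int(cfg["seed"]),
        "n_cells": int(cfg["n_cells"]),
        "constructs": {},
        "comparisons": {},
        "errors": {},
    }
    tables: Dict[str, pd.DataFrame] = {}
    per_construct: Dict[str, pd.DataFrame] = {}

    for label in labels:
        try:
            df = characterize_construct(
                label,
                int(cfg["n_cells"]),
                construct_seeds[label],
                float(cfg["noise_sd"]),
                analyses=fit_analyses,
            )
            per_construct[label] = df
            entry = {}
            for col in _PARAM_COLUMNS:
                if col in df:
                    sp = superplot_summary(
                        list(
                            zip(df[col], df["replicate_batch"], df["hours_post_transfection"])
                        ),
                        construct_label=label,
                        parameter_name=col,
                    )
                    entry[col] = {
                        "mean": sp.grand_mean,
                        "sem": sp.sem,
                        "n": sp.n_cells,
                        "per_batch_means": dict(sp.per_batch_means),
                    }
            summary["constructs"][label] = entry
        except Exception as exc:  # isolate per-construct failures
            summary["errors"][label] = f"{type(exc).__name__}: {exc}"

    # wild-type comparisons with significance tiers
    if WT_LABEL in per_construct:
        wt = per_construct[WT_LABEL]
        for label in labels:
            if label == WT_LABEL or label not in per_construct:
                continue
            comp_entry = {}
            for col in _PARAM_COLUMNS:
                if col in wt and col in per_construct[label]:
                    a = wt[col].dropna()
                    b = per_construct[label][col].dropna()
                    if len(a) >= 2 and len(b) >= 2:
                        import warnings as _w

                        with _w.catch_warnings():
                            _w.simplefilter("ignore")
                            res = unpaired_t(a, b, col, WT_LABEL, label)
                        comp_entry[col] = {
                            "t": res.t_statistic,
                            "p": res.p_value,
                            "tier": res.significance_tier,
                        }
            summary["comparisons"][label] = comp_entry

    # window currents from cohort-mean Boltzmann parameters
    if "window" in analyses:
        from .voltage import BoltzmannFit

        win_rows = []
        windows = {}
        for label in labels:
            df = per_construct.get(label)
            if df is None or "act_v05" not in df or "inact_v05" not in df:
                continue
            act = BoltzmannFit(
                float(df["act_v05"].mean()), float(df["act_slope"].mean()),
                "activation", 0.0, True, len(df),
            )
            inact = BoltzmannFit(
                float(df["inact_v05"].mean()), float(df["inact_slope"].mean()),
                "inactivation", 0.0, True, len(df),
            )
            windows[label] = window_area(act, inact)
        for label, win in windows.items():
            ratio = (
                window_ratio(win, windows[WT_LABEL]) if WT_LABEL in windows else float("nan")
            )
            win_rows.append(
                {
                    "construct": label,
                    "area": win.area,
                    "ratio_vs_WT": ratio,
                    "v_low": win.v_range[0],
                    "v_high": win.v_range[1],
                    "grid_step": win.grid_step,
                }
            )
            summary["constructs"].setdefault(label, {})["window"] = {
                "area": win.area,
                "ratio_vs_WT": ratio,
            }
        tables["window"] = pd.DataFrame(win_rows)

    # pH modulation for constructs with defined factors
    if "ph" in analyses:
        ph_rows = []
        for label in labels:
            factors = construct_params(label).ph_conductance_factor
            for ph_val in cfg["ph_values"]:
                if ph_val not in factors or ph_val == REFERENCE_PH:
                    continue
                child = construct_seeds[label].spawn(1)[0]
                df = ph_cohort_ratios(
                    label, ph_val, int(cfg["n_cells"]), child, float(cfg["noise_sd"])
                )
                ph_rows.append(df)
                summary["constructs"].setdefault(label, {}).setdefault("ph", {})[
                    str(ph_val)
                ] = {
                    "peak_ratio_mean": float(df["peak_ratio"].mean()),
                    "tau_ratio_mean": float(df["tau_ratio"].mean()),
                    "n": int(len(df)),
                }
        if ph_rows:
            tables["ph_ratios"] = pd.concat(ph_rows, ignore_index=True)

    out_dir = cfg.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        all_cells = (
            pd.concat(per_construct.values(), ignore_index=True)
            if per_construct
            else pd.DataFrame()
        )
        if "density" in all_cells:
            all_cells[
                ["construct", "cell_id", "replicate_batch", "hours_post_transfection", "density"]
            ].to_csv(out / "density.tsv", sep="\t", index=False)
        if "act_v05" in all_cells:
            all_cells[
                ["construct", "cell_id", "replicate_batch", "act_v05", "act_slope"]
            ].to_csv(out / "gv_fits.tsv", sep="\t", index=False)
        if "inact_v05" in all_cells:
            all_cells[
                ["construct", "cell_id", "replicate_batch", "inact_v05", "inact_slope"]
            ].to_csv(out / "ssi_fits.tsv", sep="\t", index=False)
        if "tau_act" in all_cells:
            all_cells[
                ["construct", "cell_id", "replicate_batch", "tau_act", "tau_inact"]
            ].to_csv(out / "kinetics.tsv", sep="\t", index=False)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
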