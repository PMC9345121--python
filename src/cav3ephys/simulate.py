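"""Synthetic whole-cell voltage-clamp recordings.

The forward model evolves the two gates of :mod:`cav3ephys.gating` with an
exact per-segment exponential update (command voltage is piecewise
constant, so the first-order relaxations have closed-form solutions and no
ODE-solver error exists).  Gaussian recording noise is added per sample.

Cell-to-cell variability emulates independent transfections: per-cell
maximal conductance is lognormal around the construct value, capacitance
is a positive-truncated normal, and both half-activation voltages receive
a small normal jitter.  Cells are assigned round-robin to replicate
batches (transfection days) and alternating 24/48-h recording time
points.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .gating import (
    GatingParams,
    REFERENCE_PH,
    apply_ph,
    steady_state_activation,
    steady_state_availability,
)
from .protocols import VoltageProtocol

__all__ = [
    "Sweep",
    "Recording",
    "CohortVariability",
    "simulate_sweep",
    "simulate_recording",
    "generate_cohort",
    "generate_ph_pairs",
    "save_recording",
    "load_recording",
    "DEFAULT_NOISE_SD_PA",
]

DEFAULT_NOISE_SD_PA = 5.0
DEFAULT_BATCH_LABELS = ("tx_day_1", "tx_day_2", "tx_day_3")


@dataclass(frozen=True)
class Sweep:
    """One voltage-clamp sweep: uniformly sampled current vs. time."""

    time_ms: np.ndarray
    current_pa: np.ndarray
    command_mv: np.ndarray
    segment_voltages: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.time_ms) == len(self.current_pa) == len(self.command_mv)):
            raise ValueError("time, current, and command arrays must align")
        if not np.all(np.isfinite(self.current_pa)):
            raise ValueError("current contains non-finite samples")


@dataclass(frozen=True)
class Recording:
    """All sweeps of one protocol from one cell, with cell metadata."""

    cell_id: str
    construct_label: str
    capacitance_pf: float
    ph: float
    sweeps: Tuple[Sweep, ...]
    replicate_batch: str
    hours_post_transfection: int
    protocol: VoltageProtocol
    rng_seed: int
    params: Optional[GatingParams] = None  # per-cell ground truth, kept for analysis checks

    def __post_init__(self) -> None:
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")


@dataclass(frozen=True)
class CohortVariability:
    """Dispersion of the simulated cohort (defaults emulate the spread of
    per-cell scatter seen across biological replicates)."""

    gmax_cv: float = 0.3
    capacitance_mean_pf: float = 12.0
    capacitance_sd_pf: float = 3.0
    v05_jitter_sd_mv: float = 1.5
    capacitance_min_pf: float = 3.0  # physical floor; whole-cell recordings
                                     # from smaller cells are not usable

    def __post_init__(self) -> None:
        if self.gmax_cv < 0 or self.capacitance_sd_pf < 0 or self.v05_jitter_sd_mv < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if self.capacitance_mean_pf <= 0:
            raise ValueError("capacitance mean must be positive")
        if not 0 <= self.capacitance_min_pf < self.capacitance_mean_pf:
            raise ValueError("capacitance floor must sit below the mean")


def simulate_sweep(
    segments: Sequence[Tuple[float, float]],
    p: GatingParams,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    sample_interval_ms: float = 0.1,
    holding_potential: Optional[float] = None,
) -> Sweep:
    """Simulate one sweep over piecewise-constant ``(duration_ms, voltage_mv)`` segments.

    Gates start at steady state for ``holding_potential`` (default: the
    first segment's voltage) and relax exponentially within each segment.
    Current is ``gmax * m * h * (V - erev)`` pA, inward negative, with
    additive Gaussian noise of standard deviation ``noise_sd`` pA.
    """
    if not segments:
        raise ValueError("empty segment list")
    if sample_interval_ms <= 0:
        raise ValueError("sample interval must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    v_hold = segments[0][1] if holding_potential is None else holding_potential
    m = float(steady_state_activation(v_hold, p))
    h = float(steady_state_availability(v_hold, p))

    times: List[np.ndarray] = []
    currents: List[np.ndarray] = []
    commands: List[np.ndarray] = []
    t_offset = 0.0
    for duration, v in segments:
        if duration <= 0:
            raise ValueError("segment duration must be positive")
        n = int(round(duration / sample_interval_ms))
        t_local = (np.arange(n) + 1) * sample_interval_ms
        m_inf = float(steady_state_activation(v, p))
        h_inf = float(steady_state_availability(v, p))
        m_t = m_inf + (m - m_inf) * np.exp(-t_local / p.tau_act)
        h_t = h_inf + (h - h_inf) * np.exp(-t_local / p.tau_inact)
        i_t = p.gmax * m_t * h_t * (v - p.erev)
        times.append(t_offset + t_local)
        currents.append(i_t)
        commands.append(np.full(n, v))
        m, h = float(m_t[-1]), float(h_t[-1])
        t_offset += n * sample_interval_ms

    current = np.concatenate(currents)
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, size=current.size)
    return Sweep(
        time_ms=np.concatenate(times),
        current_pa=current,
        command_mv=np.concatenate(commands),
        segment_voltages=tuple(v for _, v in segments),
    )


def simulate_recording(
    p: GatingParams,
    protocol: VoltageProtocol,
    cell_id: str = "cell_000",
    capacitance_pf: float = 12.0,
    ph: float = REFERENCE_PH,
    noise_sd: float = DEFAULT_NOISE_SD_PA,
    seed: int | np.random.SeedSequence | None = None,
    replicate_batch: str = DEFAULT_BATCH_LABELS[0],
    hours_post_transfection: int = 48,
) -> Recording:
    """Run every sweep of ``protocol`` on one cell at the given pH."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    p_eff = apply_ph(p, ph) if ph != REFERENCE_PH else p
    sweeps = []
    for i in range(protocol.n_sweeps):
        seg_v = protocol.segment_voltages(i)
        segs = [(seg.duration_ms, v) for seg, v in zip(protocol.segments, seg_v)]
        sweeps.append(
            simulate_sweep(
                segs,
                p_eff,
                noise_sd=noise_sd,
                seed=rng,
                sample_interval_ms=protocol.sample_interval_ms,
                holding_potential=protocol.holding_potential,
            )
        )
    return Recording(
        cell_id=cell_id,
        construct_label=p.construct_label,
        capacitance_pf=capacitance_pf,
        ph=ph,
        sweeps=tuple(sweeps),
        replicate_batch=replicate_batch,
        hours_post_transfection=hours_post_transfection,
        protocol=protocol,
        rng_seed=int(ss.entropy) if isinstance(ss.entropy, int) else 0,
        params=p_eff,
    )


def _draw_cell_params(
    fixture: GatingParams, variability: CohortVariability, rng: np.random.Generator
) -> Tuple[GatingParams, float]:
    """One cell's ground-truth parameters and capacitance."""
    if variability.gmax_cv > 0:
        sigma2 = np.log1p(variability.gmax_cv**2)
        # lognormal with mean equal to the fixture gmax
        gmax = fixture.gmax * np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2)))
    else:
        gmax = fixture.gmax
    cap = -1.0
    while cap <= variability.capacitance_min_pf:
        cap = rng.normal(variability.capacitance_mean_pf, variability.capacitance_sd_pf)
    act_v05 = fixture.act_v05 + rng.normal(0.0, variability.v05_jitter_sd_mv)
    inact_v05 = fixture.inact_v05 + rng.normal(0.0, variability.v05_jitter_sd_mv)
    cell_p = replace(fixture, gmax=float(gmax), act_v05=float(act_v05), inact_v05=float(inact_v05))
    return cell_p, float(cap)


def generate_cohort(
    fixture: GatingParams,
    protocol: VoltageProtocol,
    n_cells: int,
    variability: CohortVariability | None = None,
    seed: int | np.random.SeedSequence | None = None,
    noise_sd: float = DEFAULT_NOISE_SD_PA,
    ph: float = REFERENCE_PH,
    batch_labels: Sequence[str] = DEFAULT_BATCH_LABELS,
) -> List[Recording]:
    """Simulate ``n_cells`` independent cells of one construct under one protocol.

    Fully reproducible from ``seed``: the master seed is split into one
    independent stream per cell, so any sub-cohort is reproducible too.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if variability is None:
        variability = CohortVariability()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cell_seeds = ss.spawn(n_cells)
    recordings = []
    for i, cell_ss in enumerate(cell_seeds):
        rng = np.random.default_rng(cell_ss)
        cell_p, cap = _draw_cell_params(fixture, variability, rng)
        p_eff = apply_ph(cell_p, ph) if ph != REFERENCE_PH else cell_p
        sweeps = []
        for k in range(protocol.n_sweeps):
            seg_v = protocol.segment_voltages(k)
            segs = [(seg.duration_ms, v) for seg, v in zip(protocol.segments, seg_v)]
            sweeps.append(
                simulate_sweep(
                    segs,
                    p_eff,
                    noise_sd=noise_sd,
                    seed=rng,
                    sample_interval_ms=protocol.sample_interval_ms,
                    holding_potential=protocol.holding_potential,
                )
            )
        recordings.append(
            Recording(
                cell_id=f"{fixture.construct_label}_c{i:03d}",
                construct_label=fixture.construct_label,
                capacitance_pf=cap,
                ph=ph,
                sweeps=tuple(sweeps),
                replicate_batch=batch_labels[i % len(batch_labels)],
                hours_post_transfection=24 if i % 2 == 0 else 48,
                protocol=protocol,
                rng_seed=i,
                params=p_eff,
            )
        )
    return recordings


def generate_ph_pairs(
    fixture: GatingParams,
    protocol: VoltageProtocol,
    n_cells: int,
    ph_test: float,
    variability: CohortVariability | None = None,
    seed: int | np.random.SeedSequence | None = None,
    noise_sd: float = DEFAULT_NOISE_SD_PA,
) -> List[Tuple[Recording, Recording]]:
    """Paired recordings (reference pH 7.4, test pH) from the same cells.

    Each pair shares the cell's drawn parameters and capacitance; only the
    pH-dependent conductance/kinetics scaling and the noise differ.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if variability is None:
        variability = CohortVariability()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pairs = []
    for i, cell_ss in enumerate(ss.spawn(n_cells)):
        rng = np.random.default_rng(cell_ss)
        cell_p, cap = _draw_cell_params(fixture, variability, rng)
        recs = []
        for ph in (REFERENCE_PH, ph_test):
            p_eff = apply_ph(cell_p, ph)
            sweeps = []
            for k in range(protocol.n_sweeps):
                seg_v = protocol.segment_voltages(k)
                segs = [(seg.duration_ms, v) for seg, v in zip(protocol.segments, seg_v)]
                sweeps.append(
                    simulate_sweep(
                        segs,
                        p_eff,
                        noise_sd=noise_sd,
                        seed=rng,
                        sample_interval_ms=protocol.sample_interval_ms,
                        holding_potential=protocol.holding_potential,
                    )
                )
            recs.append(
                Recording(
                    cell_id=f"{fixture.construct_label}_c{i:03d}",
                    construct_label=fixture.construct_label,
                    capacitance_pf=cap,
                    ph=ph,
                    sweeps=tuple(sweeps),
                    replicate_batch=DEFAULT_BATCH_LABELS[i % len(DEFAULT_BATCH_LABELS)],
                    hours_post_transfection=24 if i % 2 == 0 else 48,
                    protocol=protocol,
                    rng_seed=i,
                    params=p_eff,
                )
            )
        pairs.append((recs[0], recs[1]))
    return pairs


# ---------------------------------------------------------------------------
# serialization: JSON header + CSV trace per recording


def save_recording(rec: Recording, out_dir: str | Path) -> Tuple[Path, Path]:
    """Write ``<out_dir>/<construct>/<cell_id>.{json,csv}``.

    The CSV holds ``time_ms, sweep_index, command_mV, current_pA``; the
    JSON header carries cell metadata and the protocol definition.
    """
    out = Path(out_dir) / rec.construct_label
    out.mkdir(parents=True, exist_ok=True)
    stem = out / f"{rec.cell_id}_ph{rec.ph:g}_{rec.protocol.name}"
    header = {
        "cell_id": rec.cell_id,
        "construct_label": rec.construct_label,
        "capacitance_pf": rec.capacitance_pf,
        "ph": rec.ph,
        "replicate_batch": rec.replicate_batch,
        "hours_post_transfection": rec.hours_post_transfection,
        "rng_seed": rec.rng_seed,
        "protocol": {
            "name": rec.protocol.name,
            "holding_potential": rec.protocol.holding_potential,
            "segments": [
                {"duration_ms": s.duration_ms, "voltage_mv": s.voltage_mv}
                for s in rec.protocol.segments
            ],
            "sweep_voltages": list(rec.protocol.sweep_voltages),
            "test_segment": rec.protocol.test_segment,
            "inter_sweep_interval_s": rec.protocol.inter_sweep_interval_s,
            "sample_interval_ms": rec.protocol.sample_interval_ms,
        },
    }
    json_path = stem.with_suffix(".json")
    json_path.write_text(json.dumps(header, indent=1))
    csv_path = stem.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ms", "sweep_index", "command_mV", "current_pA"])
        for k, sw in enumerate(rec.sweeps):
            for t, v, i in zip(sw.time_ms, sw.command_mv, sw.current_pa):
                w.writerow([f"{t:.4f}", k, f"{v:g}", f"{i:.6f}"])
    return json_path, csv_path


def load_recording(json_path: str | Path) -> Recording:
    """Load a recording previously written by :func:`save_recording`."""
    from .protocols import Segment, VoltageProtocol  # local to avoid cycle at import

    json_path = Path(json_path)
    header = json.loads(json_path.read_text())
    proto_d = header["protocol"]
    protocol = VoltageProtocol(
        name=proto_d["name"],
        holding_potential=proto_d["holding_potential"],
        segments=tuple(Segment(s["duration_ms"], s["voltage_mv"]) for s in proto_d["segments"]),
        sweep_voltages=tuple(proto_d["sweep_voltages"]),
        test_segment=proto_d["test_segment"],
        inter_sweep_interval_s=proto_d["inter_sweep_interval_s"],
        sample_interval_ms=proto_d["sample_interval_ms"],
    )
    csv_path = json_path.with_suffix(".csv")
    data = np.genfromtxt(csv_path, delimiter=",", names=True)
    sweeps = []
    for k in range(protocol.n_sweeps):
        mask = data["sweep_index"] == k
        seg_v = protocol.segment_voltages(k)
        sweeps.append(
            Sweep(
                time_ms=data["time_ms"][mask],
                current_pa=data["current_pA"][mask],
                command_mv=data["command_mV"][mask],
                segment_voltages=seg_v,
            )
        )
    return Recording(
        cell_id=header["cell_id"],
        construct_label=header["construct_label"],
        capacitance_pf=header["capacitance_pf"],
        ph=header["ph"],
        sweeps=tuple(sweeps),
        replicate_batch=header["replicate_batch"],
        hours_post_transfection=header["hours_post_transfection"],
        protocol=protocol,
        rng_seed=header["rng_seed"],
    )
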