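"""Schematic report figures: G–V and availability curves, window-current
overlap, and SuperPlot-style per-cell scatter.  Optional output behind the
``report --plots`` flag; the analysis never depends on these."""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import numpy as np

__all__ = ["write_report_figures"]


def write_report_figures(summary: Dict, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    v = np.linspace(-90, 20, 400)

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, entry in summary.get("constructs", {}).items():
        if "act_v05" not in entry or "inact_v05" not in entry:
            continue
        act = 1 / (1 + np.exp((entry["act_v05"]["mean"] - v) / entry["act_slope"]["mean"]))
        inact = 1 / (1 + np.exp((v - entry["inact_v05"]["mean"]) / entry["inact_slope"]["mean"]))
        (line,) = ax.plot(v, act, label=label)
        ax.plot(v, inact, color=line.get_color(), linestyle="--")
        ax.fill_between(v, np.minimum(act, inact), alpha=0.15, color=line.get_color())
    ax.set_xlabel("Voltage (mV)")
    ax.set_ylabel("Normalized G or I")
    ax.set_title("Activation (solid), availability (dashed), window (shaded)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / "window_curves.png", dpi=120)
    plt.close(fig)

    entries = [
        (label, e["density"]) for label, e in summary.get("constructs", {}).items()
        if "density" in e
    ]
    if entries:
        fig, ax = plt.subplots(figsize=(6, 4))
        for i, (label, d) in enumerate(entries):
            ax.errorbar(i, d["mean"], yerr=d["sem"], fmt="o", capsize=4, color="k")
        ax.set_xticks(range(len(entries)))
        ax.set_xticklabels([e[0] for e in entries], rotation=45)
        ax.set_ylabel("Current density (pA/pF)")
        fig.tight_layout()
        fig.savefig(out_dir / "density_superplot.png", dpi=120)
        plt.close(fig)
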