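"""Static figures: per-residue rotamer histograms and the OC vs T*dS
quadrant plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import PipelineResult
from .torsions import ResidueId

__all__ = ["plot_histogram", "plot_quadrants"]


def plot_histogram(result: PipelineResult, rid: ResidueId,
                   path: str | Path) -> None:
    """Side-by-side solution/crystal rotamer probability bars for one
    residue, with the X-ray state marked on the axis."""
    ps = result.distributions_solution[rid].probabilities
    pc = result.distributions_crystal[rid].probabilities
    states = np.arange(1, len(ps) + 1)
    fig, ax = plt.subplots(figsize=(4, 3))
    width = 0.4
    ax.bar(states - width / 2, ps, width, color="black", label="solution")
    ax.bar(states + width / 2, pc, width, color="white", edgecolor="black",
           label="crystal")
    if rid in result.xray:
        ax.plot(result.xray[rid].state_id, -0.03, "o", color="red",
                clip_on=False, label="X-ray")
    cmp = result.comparisons[rid]
    ax.set_title(f"{rid}  OC={cmp.oc:.2f}  TdS={cmp.t_delta_s_conf:.2f}")
    ax.set_xlabel("rotamer state")
    ax.set_ylabel("probability")
    ax.set_xticks(states)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_quadrants(result: PipelineResult, path: str | Path,
                   oc_boundary: float = 0.5,
                   tds_boundary: float = 0.5) -> None:
    """Scatter of (T*dS, OC) per residue; filled points are contacting."""
    fig, ax = plt.subplots(figsize=(4, 4))
    for rid, cmp in result.comparisons.items():
        ann = result.annotations.get(rid)
        contacting = bool(ann.contacting) if ann else False
        ax.plot(cmp.t_delta_s_conf, cmp.oc, "o",
                mfc="black" if contacting else "none", mec="black", ms=5)
    ax.axhline(oc_boundary, color="grey", lw=0.8)
    ax.axvline(-tds_boundary, color="grey", lw=0.8)
    ax.axvline(tds_boundary, color="grey", lw=0.8)
    ax.set_xlabel(r"T$\Delta$S$_{conf}$ (kcal/mol)")
    ax.set_ylabel("OC")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
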