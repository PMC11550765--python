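"""Tabular, JSON and plot outputs for analyses and elimination traces."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .analysis import Analysis
from .elimination import EliminationTrace

__all__ = [
    "profiles_frame",
    "trace_frame",
    "kcurve_frame",
    "write_json_summary",
    "plot_profiles",
]


def profiles_frame(analysis: Analysis) -> pd.DataFrame:
    """Per-residue table: chain, seq_number, aa, T, O, R, M."""
    refs = analysis.model.refs
    return pd.DataFrame(
        {
            "chain": [r.chain_id for r in refs],
            "seq_number": [r.seq_number for r in refs],
            "aa": [r.aa_code for r in refs],
            "T": analysis.t.values,
            "O": analysis.o.values,
            "R": analysis.r.values,
            "M": analysis.m.values,
        }
    )


def trace_frame(trace: EliminationTrace) -> pd.DataFrame:
    """Elimination trace table: step, chain, seq_number, aa, gap, rd_after."""
    return pd.DataFrame(
        {
            "step": range(1, len(trace.steps) + 1),
            "chain": [s.ref.chain_id for s in trace.steps],
            "seq_number": [s.ref.seq_number for s in trace.steps],
            "aa": [s.ref.aa_code for s in trace.steps],
            "gap": [s.gap for s in trace.steps],
            "rd_after": [s.rd_after for s in trace.steps],
        }
    )


def kcurve_frame(analysis: Analysis) -> pd.DataFrame:
    """The D_KL(O|M(K)) grid-search curve as a two-column table."""
    return pd.DataFrame(analysis.kfit.curve, columns=["K", "DKL_OM"])


def write_json_summary(summary: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return path


def plot_profiles(analysis: Analysis, path, dpi: int = 150) -> Path:
    """T/O/M overlay against residue index, one panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = range(1, len(analysis.model) + 1)
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.plot(idx, analysis.t.values, color="tab:blue", lw=1.2, label="T (theoretical)")
    ax.plot(idx, analysis.o.values, color="tab:red", lw=1.2, label="O (observed)")
    ax.plot(
        idx, analysis.m.values, color="tab:green", lw=1.2, ls="--",
        label=f"M (K = {analysis.kfit.k_rounded:.1f})",
    )
    ax.set_xlabel("residue index")
    ax.set_ylabel("hydrophobicity (normalized)")
    ax.set_title(
        f"{analysis.model.id}: RD = {analysis.result.rd:.3f}, "
        f"K = {analysis.kfit.k_rounded:.1f}"
    )
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
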