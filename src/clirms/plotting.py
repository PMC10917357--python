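"""Optional plots: per-residue cross-link bar charts and RNA interval tracks.

Every plotted quantity is also available as TSV from the pipeline; plots
are a convenience, never the primary output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .digest import SequenceRecord
from .mapping import ResidueXlMap, RnaInterval

__all__ = ["plot_residue_map", "plot_rna_intervals"]


def plot_residue_map(xmap: ResidueXlMap, path: str | Path) -> Path:
    """Bar chart of spectral counts along the protein sequence."""
    positions = list(range(1, xmap.length + 1))
    counts = [xmap.counts.get(p, 0) for p in positions]
    fig, ax = plt.subplots(figsize=(max(6, xmap.length / 12), 3))
    ax.bar(positions, counts, width=1.0, color="#30678d")
    ax.set_xlabel(f"{xmap.protein_id} residue")
    ax.set_ylabel("cross-link spectral count")
    ax.set_xlim(0.5, xmap.length + 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_rna_intervals(
    intervals: Sequence[RnaInterval], rna: SequenceRecord, path: str | Path,
    offset: int = 0,
) -> Path:
    """Stacked interval track of candidate adduct windows on the RNA."""
    fig, ax = plt.subplots(figsize=(max(6, len(rna) / 6), 2 + 0.25 * len(intervals)))
    for row, iv in enumerate(sorted(intervals, key=lambda i: (i.start, i.end))):
        ax.hlines(row, iv.start - 0.4, iv.end + 0.4, lw=6, color="#c0504d")
        ax.text(iv.end + 0.6, row, iv.composition, va="center", fontsize=7)
    ax.set_yticks([])
    ax.set_xticks(range(1 + offset, len(rna) + 1 + offset))
    ax.set_xticklabels(list(rna.sequence), fontsize=6)
    ax.set_xlabel(f"{rna.id} position")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
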