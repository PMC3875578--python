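"""Figure-style plots: mismatch rate vs position, per-template panels."""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .mismatch_profile import PositionProfileSet, per_template_distribution
from .strand_coords import StrandClass


def plot_rate_by_position(
    profile: PositionProfileSet, path: str | Path, max_position: int | None = None
) -> None:
    """Per-position mismatch rate for first- and second-strand reads."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for s, color in (
        (StrandClass.FIRST_STRAND, "tab:red"),
        (StrandClass.SECOND_STRAND, "tab:blue"),
    ):
        hi = max_position or profile.max_position(s)
        xs, ys = [], []
        for p in range(1, hi + 1):
            cov = int(profile.coverage(s, p).sum())
            if cov == 0:
                continue
            mm = int(profile.mismatch_counts(s, p).sum())
            xs.append(p)
            ys.append(mm / cov)
        ax.plot(xs, ys, label=s.value.replace("_", " "), color=color)
    ax.axvspan(0.5, 7.5, color="0.9", label="hexamer region")
    ax.set_xlabel("synthesis position (from 5' priming site)")
    ax.set_ylabel("mismatch rate")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_per_template_panels(
    profile: PositionProfileSet,
    path: str | Path,
    positions: Sequence[int] = (1, 3, 15, 50),
) -> None:
    """Stacked incorporated-base distributions per template at selected positions."""
    s = StrandClass.FIRST_STRAND
    fig, axes = plt.subplots(1, len(positions), figsize=(3 * len(positions), 3.5),
                             sharey=True)
    colors = {"A": "tab:green", "C": "tab:blue", "G": "tab:orange", "T": "tab:red"}
    for ax, p in zip(axes, positions):
        panel = per_template_distribution(profile, s, p)
        for x, (letter, cell) in enumerate(panel.items()):
            dist = cell["distribution"]
            if dist is None:
                continue
            bottom = 0.0
            for inc, pct in dist.items():
                frac = cell["rate"] * pct / 100.0
                ax.bar(x, frac, bottom=bottom, color=colors[inc],
                       label=f"to {inc}" if x == 0 else None)
                bottom += frac
        ax.set_xticks(range(4), list(panel))
        ax.set_title(f"position {p}")
    axes[0].set_ylabel("mismatch rate (stacked by incorporated base)")
    handles, labels = axes[0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
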