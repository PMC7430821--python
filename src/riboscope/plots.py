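"""Figure generation for the CLI subcommands.

Every figure is a derived view of a TSV the same command wrote; no number
appears only in a plot.  The Agg backend keeps plotting headless.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def save_periodicity(profile, path, length: Optional[int] = None) -> None:
    key = length if length is not None else "all"
    fig, axes = plt.subplots(1, 2, figsize=(9, 3), sharey=True)
    for ax, (anchor, table) in zip(axes, (("start", profile.start_counts),
                                          ("stop", profile.stop_counts))):
        counts = table.get(key)
        if counts is None:
            continue
        pos = profile.positions
        colors = np.where(pos % 3 == 0, "#c0392b", "#7f8c8d")
        ax.bar(pos, counts, color=colors, width=0.9)
        ax.set_xlabel(f"5' end relative to {anchor} codon (nt)")
        ax.set_title(f"reads of length {key}")
    axes[0].set_ylabel("read count")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_frame_bars(fractions: Sequence[float], path) -> None:
    fig, ax = plt.subplots(figsize=(3.5, 3))
    ax.bar([0, 1, 2], fractions, color=["#2980b9", "#95a5a6", "#95a5a6"])
    ax.set_xticks([0, 1, 2])
    ax.set_xlabel("reading frame")
    ax.set_ylabel("fraction of P-sites")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_length_hist(hist: Mapping[int, int], path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3))
    lengths = sorted(hist)
    ax.bar(lengths, [hist[L] for L in lengths], color="#2c3e50")
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("reads")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_region_counts(stats, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    regions = ["exon", "intron", "intergenic"]
    ax.bar(regions, [stats.counts[r] for r in regions],
           color=["#27ae60", "#f39c12", "#c0392b"])
    ax.set_ylabel("reads")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_profile(profile, path, ylabel: str = "relative density",
                 hline: Optional[float] = None) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 3))
    ax.plot(profile.positions, profile.mean, color="#2980b9", lw=1.2)
    ax.fill_between(profile.positions, profile.ci_lower, profile.ci_upper,
                    color="#2980b9", alpha=0.25, linewidth=0)
    if hline is not None:
        ax.axhline(hline, color="#c0392b", ls=":")
    ax.set_xlabel(f"position ({profile.unit}) relative to {profile.anchor}")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_polarity_violin(scores_by_sample: Mapping[str, Sequence[float]], path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    labels = sorted(scores_by_sample)
    ax.violinplot([list(scores_by_sample[k]) for k in labels], showmedians=True)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel("polarity score")
    ax.axhline(0, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_enrichment(profile_values: np.ndarray, path, threshold: float = 2.0,
                    title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5.5, 3))
    ax.plot(np.arange(1, len(profile_values) + 1), profile_values,
            color="#2c3e50", lw=1.2)
    ax.axhline(threshold, color="#c0392b", ls=":")
    ax.set_xlabel("codon")
    ax.set_ylabel("IP / total ratio")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
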