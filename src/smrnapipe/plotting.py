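"""Advisory plots: size histograms, per-chromosome fold tracks, and
per-locus methylation bar panels.  Acceptance rests on the tables; these
figures mirror them for visual inspection."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_size_profiles",
    "plot_chromosome_tracks",
    "plot_methylation_panel",
]

_COLORS = {"mut": "#c0392b", "wt": "#2e86c1"}


def plot_size_profiles(profiles: dict[str, pd.DataFrame], path) -> None:
    """Grouped bars of read-length fractions (18-26 nt) per library."""
    fig, ax = plt.subplots(figsize=(6, 4))
    width = 0.35
    for i, (genotype, df) in enumerate(sorted(profiles.items())):
        df = df[df["length"] != "other"]
        lengths = df["length"].astype(int)
        ax.bar(
            np.arange(len(lengths)) + i * width,
            df["fraction"],
            width,
            label=genotype,
            color=_COLORS.get(genotype),
        )
    ax.set_xticks(np.arange(len(lengths)) + width / 2)
    ax.set_xticklabels(lengths)
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("fraction of 18-26 nt reads")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_chromosome_tracks(track: pd.DataFrame, path) -> None:
    """Per-chromosome log2 fold-value tracks over 100 bp windows."""
    chroms = sorted(track["chrom"].unique())
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(8, 1.6 * len(chroms)), sharex=True, squeeze=False
    )
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = track[track["chrom"] == chrom]
        ax.plot(sub["position"], sub["fold_value"], lw=0.4, color="#555555")
        ax.axhline(2, color="#c0392b", lw=0.5, ls="--")
        ax.axhline(-2, color="#2e86c1", lw=0.5, ls="--")
        ax.set_ylabel(chrom, fontsize=8)
    axes.ravel()[-1].set_xlabel("position (bp)")
    fig.suptitle("smRNA cluster log2(mut/wt) per 100 bp window", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_methylation_panel(
    summary: pd.DataFrame, diffs: pd.DataFrame, path
) -> None:
    """Per-locus grouped bars of percent methylation per context/genotype."""
    loci = sorted(summary["locus_id"].unique())
    contexts = ("CG", "CHG", "CHH")
    fig, axes = plt.subplots(
        1, len(contexts), figsize=(3.2 * len(contexts), 3.5), sharey=True
    )
    for ax, context in zip(axes, contexts):
        sub = summary[summary["context"] == context]
        x = np.arange(len(loci))
        for i, genotype in enumerate(("wt", "mut")):
            vals = [
                sub[(sub["locus_id"] == l) & (sub["genotype"] == genotype)]["percent"].mean()
                for l in loci
            ]
            ax.bar(x + i * 0.4, vals, 0.4, label=genotype, color=_COLORS[genotype])
        ax.set_title(context)
        ax.set_xticks(x + 0.2)
        ax.set_xticklabels(loci, rotation=90, fontsize=6)
    axes[0].set_ylabel("% methylation")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
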