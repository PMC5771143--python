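"""Figures: per-codon occupancy bars, per-ORF traces, terminus blocks,
correlation heat-maps.  Figures are side effects of the pipeline, never
inputs; everything they show is also written as TSV."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .clustering import DistanceMatrix
from .profiles import OrfDistribution
from .reference import CODONS
from .terminus import BlockSet


def plot_codon_occupancy(results: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of mean fractional occupancy per codon vs. the comparison
    level, with significant codons marked by a cross below the axis."""
    fig, ax = plt.subplots(figsize=(16, 4))
    x = np.arange(64)
    if "abundance_fraction" in results.columns:
        obs, refv = results["mean_fraction"], results["abundance_fraction"]
        ref_label = "mtDNA abundance"
    else:
        obs, refv = results["mean_treatment"], results["mean_control"]
        ref_label = "control"
    ax.bar(x - 0.2, refv, width=0.4, label=ref_label, color="firebrick")
    ax.bar(x + 0.2, obs, width=0.4, label="footprints", color="steelblue")
    sig = results["significant"].to_numpy(dtype=bool)
    if sig.any():
        ax.scatter(x[sig], np.full(sig.sum(), -0.002), marker="x", color="blue", clip_on=False)
    ax.set_xticks(x)
    ax.set_xticklabels(results["codon"], rotation=90, fontsize=6)
    ax.set_ylabel("fraction of reads")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_orf_distributions(dists: list[OrfDistribution], out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for d in dists:
        fig, ax = plt.subplots(figsize=(8, 2.5))
        ax.plot(np.arange(len(d.values)), d.values, lw=0.8)
        ax.set_xlabel("codon position")
        ax.set_ylabel("fractional abundance")
        ax.set_title(d.gene_id)
        fig.tight_layout()
        p = out / f"distribution_{d.gene_id}.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    return paths


def plot_terminus_blocks(blocks: BlockSet, path: str | Path, first_nt: int = 20) -> None:
    """Stacked 5'-start blocks: one bar per start position, depth = fraction,
    drawn over the first ``first_nt`` nt of each group."""
    fig, ax = plt.subplots(figsize=(8, 3))
    y = 0.0
    for g in sorted(blocks.groups.values(), key=lambda g: g.position):
        ax.barh(
            y + g.fraction / 2,
            width=first_nt,
            left=g.position,
            height=g.fraction,
            edgecolor="black",
            color="mediumseagreen",
        )
        y += g.fraction
    ax.set_xlabel("reference position (nt)")
    ax.set_ylabel("cumulative fraction")
    ax.set_title(blocks.gene_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_correlation_heatmap(dm: DistanceMatrix, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    corr = 1.0 - dm.D
    im = ax.imshow(corr, vmin=min(0, corr.min()), vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(dm.labels)))
    ax.set_yticks(range(len(dm.labels)))
    ax.set_xticklabels(dm.labels, rotation=90, fontsize=7)
    ax.set_yticklabels(dm.labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
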