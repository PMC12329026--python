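"""Quick-look figures for the pipeline's summary tables (matplotlib)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_support_distribution(matrix, path) -> None:
    """Per-replicate crosslink-support histograms with threshold lines.

    Counts are log-spaced-binned: per-site crosslink support is approximately
    log-normal, so the below-threshold population is visible as the left mode.
    """
    n = len(matrix.replicates)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (j, rep) in zip(axes, enumerate(matrix.replicates)):
        col = matrix.counts[:, j]
        positive = col[col > 0]
        if positive.size:
            bins = np.logspace(0, np.log10(max(positive.max(), 2)), 20)
            ax.hist(positive, bins=bins, color="0.6")
            ax.set_xscale("log")
        thr = matrix.thresholds.get(rep)
        if thr is not None and np.isfinite(thr):
            ax.axvline(thr, color="tab:blue", lw=1.5, label=f"threshold {int(thr)}")
            ax.legend(frameon=False, fontsize=8)
        ax.set_title(rep)
        ax.set_xlabel("crosslinks per site")
    axes[0].set_ylabel("binding sites")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_positional_density(offsets, density, kmer: str, path) -> None:
    """Motif start-offset density relative to binding-site centres."""
    fig, ax = plt.subplots(figsize=(5, 2.5))
    ax.plot(offsets, density, color="tab:red")
    ax.axvline(0, color="0.7", lw=0.8)
    ax.set_xlabel("offset from site centre (nt)")
    ax.set_ylabel("density")
    ax.set_title(kmer)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_region_distribution(dist, path) -> None:
    """Observed site shares per region next to the genomic-length background."""
    labels = sorted(set(dist.site_percent) | set(dist.background_percent))
    x = np.arange(len(labels))
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(x - 0.2, [dist.site_percent.get(l, 0) for l in labels], 0.4, label="binding sites")
    ax.bar(x + 0.2, [dist.background_percent.get(l, 0) for l in labels], 0.4, label="feature length")
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("percent")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
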