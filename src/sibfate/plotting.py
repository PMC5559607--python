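"""Minimal static figures for the binned analyses."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_bin_summaries(bins, ylabel: str, path=None):
    """Bar plot of a binned proportion with the null level and significance
    asterisks."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    centers = [0.5 * (b.lo + b.hi) for b in bins]
    width = bins[0].hi - bins[0].lo if bins else 0.1
    fracs = [b.fraction for b in bins]
    ax.bar(centers, fracs, width=width * 0.9, color="#5b8db8", edgecolor="black")
    nulls = [b.null_fraction for b in bins]
    if any(np.isfinite(v) for v in nulls):
        ax.plot(centers, nulls, color="orange", lw=2, label="chance level")
    for b, c in zip(bins, centers):
        if b.n:
            ax.text(c, 0.02, str(b.n), ha="center", color="white", fontsize=8)
        if b.significant:
            ax.text(c, (b.fraction or 0) + 0.03, "*", ha="center", fontsize=14)
    ax.set_xlabel("predicted relative cell-cycle position")
    ax.set_ylabel(ylabel)
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_interval_correlations(intervals, path=None):
    """Per-interval sibling resuscitation correlations with bootstrap CIs."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    xs, rs, los, his, labels = [], [], [], [], []
    for i, iv in enumerate(intervals):
        labels.append(f"{iv.lo:g}–{iv.hi:g}\n(n={iv.n})")
        if iv.computable:
            xs.append(i)
            rs.append(iv.result.r)
            los.append(iv.result.r - iv.result.ci_low)
            his.append(iv.result.ci_high - iv.result.r)
    ax.errorbar(xs, rs, yerr=[los, his], fmt="o", capsize=4, color="#30506d")
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xticks(range(len(intervals)), labels)
    ax.set_xlabel("cycle-position interval")
    ax.set_ylabel("sibling resuscitation Pearson r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
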