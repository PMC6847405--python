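"""Minimal plotting helpers (pileup and D_toStart histogram)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_pileup(pileup, path: str, window: int = 40) -> None:
    """Read 3'-end counts around the anti-SD core."""
    lo = max(0, pileup.query.core_offset - window)
    hi = min(len(pileup.counts), pileup.query.core_offset + window)
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.bar(range(lo, hi), pileup.counts[lo:hi], width=0.9, color="0.3")
    ax.set_xlabel("query position")
    ax.set_ylabel("read 3' ends")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_d_histogram(d_values, path: str, optimal_range=None) -> None:
    fig, ax = plt.subplots(figsize=(6, 3))
    if d_values:
        lo, hi = min(d_values), max(d_values)
        ax.hist(d_values, bins=range(lo, hi + 2), color="0.3", rwidth=0.9)
    if optimal_range:
        ax.axvspan(optimal_range[0], optimal_range[1] + 1, alpha=0.2, color="tab:red")
    ax.set_xlabel("D_toStart (nt)")
    ax.set_ylabel("matches")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
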