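"""Static report figures: Δt boxplots and timestamp-correlation scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_dt_boxplots(dt_pen, dt_ecg, path, *, labels=("pen", "ecg")) -> None:
    """Side-by-side boxplots of the two Δt-vectors."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot([np.asarray(dt_ecg), np.asarray(dt_pen)], tick_labels=[labels[1], labels[0]])
    ax.set_ylabel("Δt (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_timestamp_correlation(pen_t, ecg_t, path, *, regression=None) -> None:
    """Matched pen-vs-reference beat timestamps with the identity line."""
    pen_t = np.asarray(pen_t)
    ecg_t = np.asarray(ecg_t)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(ecg_t, pen_t, ".", ms=3, label="matched beats")
    lims = [min(ecg_t.min(), pen_t.min()), max(ecg_t.max(), pen_t.max())]
    ax.plot(lims, lims, "k--", lw=1, label="y = x")
    if regression is not None:
        slope, intercept = regression
        xs = np.asarray(lims)
        ax.plot(xs, slope * xs + intercept, "r-", lw=1, label=f"y = {slope:.3f}x + {intercept:.3f}")
    ax.set_xlabel("reference beat time (s)")
    ax.set_ylabel("pen beat time (s)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
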