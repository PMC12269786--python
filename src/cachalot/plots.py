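"""Distribution plots for survey reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .sizing import CLASS_LABELS

_CLASS_COLORS = dict(zip(CLASS_LABELS, ("#74add1", "#fdae61", "#d73027")))


def plot_length_distribution(individuals: pd.DataFrame, path: str | Path) -> None:
    """Histogram of estimated body lengths coloured by age/sex class."""
    sized = individuals.dropna(subset=["length_m"])
    fig, ax = plt.subplots(figsize=(7, 4))
    for label in CLASS_LABELS:
        sub = sized[sized["class_label"] == label]
        if len(sub):
            ax.hist(
                sub["length_m"], bins=18, range=(7, 17), alpha=0.75,
                label=f"{label} (n={len(sub)})", color=_CLASS_COLORS[label],
            )
    ax.axvline(9.0, color="k", ls="--", lw=0.8)
    ax.axvline(12.0, color="k", ls="--", lw=0.8)
    ax.set_xlabel("estimated body length (m)")
    ax.set_ylabel("individuals")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_size_profile(profile: pd.DataFrame, path: str | Path) -> None:
    """Mean ± SD of member length as a function of aggregation size."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        profile["size"], profile["mean_length_m"], yerr=profile["sd_length_m"],
        fmt="o-", capsize=3, color="#2c7fb8",
    )
    ax.set_xlabel("aggregation size (individuals)")
    ax.set_ylabel("mean member length (m)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
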