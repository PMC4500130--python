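"""Plot helpers: stability-confidence curves and t50 histograms."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .stability import ConfidenceCurve

__all__ = ["plot_confidence_curves", "plot_histogram"]


def plot_confidence_curves(
    curves: Mapping[str, Mapping[str, ConfidenceCurve]], path: str | Path
) -> None:
    """One panel per metabolite, long and short target curves overlaid."""
    mets = list(curves)
    fig, axes = plt.subplots(
        len(mets), 1, figsize=(6, 2.4 * max(len(mets), 1)), squeeze=False
    )
    for ax, met in zip(axes.ravel(), mets):
        for kind, style in (("long", "-"), ("short", "--")):
            c = curves[met].get(kind)
            if c is None:
                continue
            ax.plot(
                c.temperatures,
                c.confidences,
                style,
                label=f"{kind} ({c.target_halflife:g} s)",
            )
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel("confidence")
        ax.set_title(met, fontsize=9)
        ax.legend(fontsize=7)
    axes.ravel()[-1].set_xlabel("temperature (K)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_histogram(histogram: pd.DataFrame, path: str | Path) -> None:
    """Side-by-side bars of t50 counts per 10 K bin (label = lower edge)."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    if not histogram.empty:
        x = histogram["bin_lower_K"].to_numpy()
        w = 4.0
        ax.bar(x - w / 2, histogram["count_long"], width=w, label="long target")
        ax.bar(x + w / 2, histogram["count_short"], width=w, label="short target")
    ax.set_xlabel("t50 bin lower edge (K)")
    ax.set_ylabel("metabolites")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
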