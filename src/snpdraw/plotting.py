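"""Figures for the panel experiments: MAE-vs-size strips and metric
distribution overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_panel_ladder", "plot_metric_distributions"]

_KIND_COLOURS = {"augmented": "tab:blue", "random": "tab:orange", "targeted": "tab:blue"}


def plot_panel_ladder(results: pd.DataFrame, out_path=None):
    """Strip plot of validation MAE per panel size and kind.

    ``results`` is the tidy table from
    :func:`snpdraw.evaluation.panel_ladder_experiment`.
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    sizes = sorted(results["size"].unique())
    rng = np.random.default_rng(0)
    for k, kind in enumerate(sorted(results["kind"].unique())):
        sub = results[results["kind"] == kind]
        x = [sizes.index(s) + (k - 0.5) * 0.25 for s in sub["size"]]
        x = np.asarray(x) + rng.uniform(-0.05, 0.05, len(x))
        ax.scatter(x, sub["val_mae"], s=18, alpha=0.7,
                   color=_KIND_COLOURS.get(kind, None), label=kind)
    ax.set_xticks(range(len(sizes)), [str(s) for s in sizes])
    ax.set_xlabel("panel size (number of SNPs)")
    ax.set_ylabel("validation MAE")
    ax.legend(title="panel kind")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def plot_metric_distributions(samples: dict[str, np.ndarray], metric_name: str = "FSI",
                              out_path=None):
    """Overlaid histograms of a shape metric under different sources
    (predicted / decoded mean / original images)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, values in samples.items():
        ax.hist(np.asarray(values, dtype=float), bins=20, density=True,
                histtype="step", linewidth=1.6, label=label)
    ax.set_xlabel(metric_name)
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
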