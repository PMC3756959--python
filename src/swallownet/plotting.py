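"""Figure helpers: connectivity heat map and the sweep-comparison panel grid."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import SWEEP_METRICS, SweepResult

__all__ = ["plot_connectivity_matrix", "plot_sweep_comparison"]

_METRIC_TITLES = {
    "Eglob": "Global efficiency $E_{glob}$",
    "Lp": "Characteristic path length $L_p$",
    "K_mean": "Node degree $K$",
    "Cp": "Clustering coefficient $C_p$",
    "Eloc": "Local efficiency $E_{loc}$",
    "beta": r"Hierarchy $\beta$",
}


def plot_connectivity_matrix(
    matrix: np.ndarray, labels=None, out_path: str | Path = "connectivity.png"
) -> Path:
    """Heat map of a (group-mean) connectivity matrix."""
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(np.asarray(matrix), cmap="jet", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="connectivity strength")
    if labels is not None and len(labels) <= 30:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=5)
        ax.set_yticks(range(len(labels)), labels, fontsize=5)
    ax.set_title("Mean inter-regional connectivity")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path


def plot_sweep_comparison(
    sweep_roi: SweepResult,
    sweep_whole: SweepResult,
    comparison,
    out_path: str | Path = "sweep_comparison.png",
    alpha: float = 0.05,
) -> Path:
    """Six-panel metric-versus-threshold figure, both scopes, significance stars."""
    fig, axes = plt.subplots(2, 3, figsize=(13, 7), sharex=True)
    for ax, metric in zip(axes.ravel(), SWEEP_METRICS):
        for sweep, color, label in (
            (sweep_whole, "tab:blue", "whole brain"),
            (sweep_roi, "tab:red", "swallowing ROIs"),
        ):
            grouped = sweep.table.replace([np.inf, -np.inf], np.nan).groupby("threshold")[metric]
            mean = grouped.mean()
            sem = grouped.sem()
            ax.errorbar(mean.index, mean, yerr=sem, color=color, label=label, lw=1.2)
        sig = comparison[(comparison["metric"] == metric) & comparison["significant"]]
        if not sig.empty:
            finite = sweep_whole.table.replace([np.inf, -np.inf], np.nan)[metric].dropna()
            y = finite.max() if not finite.empty else 1.0
            ax.plot(sig["threshold"], np.full(len(sig), y), "k*", ms=5)
        ax.set_title(_METRIC_TITLES[metric], fontsize=10)
        ax.set_xlabel("sparsity threshold r")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
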