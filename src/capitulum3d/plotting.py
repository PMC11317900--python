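"""Diagnostic plots for the 3D estimation results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .integrate_cluster import PositionEvaluation


def plot_error_vs_axis(evaluation: PositionEvaluation, path, ylabel: str = "position error (px)"):
    """Scatter of per-point error against radial distance from the rotation axis.

    Points near the axis sit at the crowded receptacle apex, where a single
    global clustering threshold tends to fail; errors there are expected to
    exceed those of peripheral points.
    """
    if evaluation.axis_distances is None:
        raise ValueError("evaluation carries no axis distances")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(evaluation.axis_distances, evaluation.errors, s=12, alpha=0.7)
    ax.set_xlabel("distance from rotation axis (px)")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_cluster_count_sweep(counts: dict[float, int], path):
    """Cluster count versus termination threshold d."""
    ds = sorted(counts)
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(ds, [counts[d] for d in ds], marker="o")
    ax.set_xlabel("threshold d (px)")
    ax.set_ylabel("number of clusters")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
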