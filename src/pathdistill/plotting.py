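"""Optional matplotlib views of the abstention diagnostics.

Matplotlib is imported lazily; install the ``plot`` extra to use these.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_wrong_confidence_histogram(
    counts_by_model: dict[str, Sequence[int]],
    bin_edges: Sequence[float],
    task: str,
    path: str | Path,
) -> None:
    """Side-by-side bars of wrong-prediction confidence per model."""
    plt = _pyplot()
    edges = np.asarray(bin_edges, dtype=float)
    centers = (edges[:-1] + edges[1:]) / 2
    width = np.diff(edges).min() * 0.8 / max(len(counts_by_model), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, (model, counts) in enumerate(counts_by_model.items()):
        ax.bar(centers + i * width, counts, width=width, label=model)
    ax.set_xlabel("prediction confidence (max softmax)")
    ax.set_ylabel("wrong predictions")
    ax.set_title(f"Confidence of wrong predictions — {task}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_size_curve(
    sizes: Sequence[int],
    means: dict[str, Sequence[float]],
    stds: dict[str, Sequence[float]] | None,
    path: str | Path,
    cutoff: float = 0.97,
) -> None:
    """Overconfident-wrong count versus ensemble size, one line per task."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    for task, m in means.items():
        m = np.asarray(m, dtype=float)
        ax.plot(sizes, m, marker="o", label=task)
        if stds and task in stds:
            s = np.asarray(stds[task], dtype=float)
            ax.fill_between(sizes, m - s, m + s, alpha=0.2)
    ax.set_xlabel("ensemble size")
    ax.set_ylabel(f"wrong predictions with confidence > {cutoff}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
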