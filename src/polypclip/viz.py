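"""Diagnostic figures: confusion-matrix heatmap and 2-D embedding scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.decomposition import PCA

from .corpus import ConfusionMatrix

__all__ = ["plot_confusion", "plot_embedding_scatter", "plot_augmentation_grid"]


def plot_confusion(cm: ConfusionMatrix, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(len(cm.classes)), cm.classes, rotation=30, ha="right")
    ax.set_yticks(range(len(cm.classes)), cm.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(len(cm.classes)):
        for j in range(len(cm.classes)):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center",
                    color="black")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_embedding_scatter(
    embeddings: np.ndarray, labels: list[str], path: str | Path
) -> None:
    """PCA projection of image embeddings colored by class."""
    xy = PCA(n_components=2).fit_transform(np.asarray(embeddings))
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for cls in sorted(set(labels)):
        mask = np.array([l == cls for l in labels])
        ax.scatter(xy[mask, 0], xy[mask, 1], s=18, alpha=0.6, label=cls)
    ax.legend()
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_augmentation_grid(
    before: list[np.ndarray], after: list[np.ndarray], path: str | Path
) -> None:
    n = len(before)
    fig, axes = plt.subplots(2, n, figsize=(1.6 * n, 3.4))
    for i in range(n):
        axes[0, i].imshow(before[i])
        axes[1, i].imshow(after[i])
        for ax in (axes[0, i], axes[1, i]):
            ax.set_xticks([])
            ax.set_yticks([])
    axes[0, 0].set_ylabel("original")
    axes[1, 0].set_ylabel("augmented")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
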