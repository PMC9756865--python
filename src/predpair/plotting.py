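"""Matplotlib figure helpers (heatmaps, PR curves, decile histograms)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_matrix(
    M: np.ndarray,
    path,
    title: str = "",
    true_pairs=None,
    cmap: str = "viridis",
) -> None:
    """Heatmap of a certainty/score/saliency matrix.

    ``true_pairs`` marks reference base pairs with open rectangles, as in
    structure-comparison figures.
    """
    fig, ax = plt.subplots(figsize=(6, 5.4))
    im = ax.imshow(np.asarray(M), cmap=cmap, origin="upper")
    fig.colorbar(im, ax=ax, shrink=0.85)
    if true_pairs:
        for i, j in true_pairs:
            for a, b in ((i, j), (j, i)):
                ax.add_patch(
                    plt.Rectangle((b - 0.5, a - 0.5), 1, 1, fill=False,
                                  edgecolor="black", linewidth=0.8)
                )
    ax.set_xlabel("partner position")
    ax.set_ylabel("query position")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pr_curve(curves: dict, path) -> None:
    """One or more PR curves, keyed by label, from ``pr_curve`` frames."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for label, df in curves.items():
        ax.plot(df["recall"], df["precision"], marker=".", ms=3, lw=1, label=label)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decile_histogram(hist: np.ndarray, path, title: str = "") -> None:
    """Predicted-paired counts per accessibility decile (1 = least accessible)."""
    hist = np.asarray(hist)
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.bar(np.arange(1, len(hist) + 1), hist, color="#4878a8")
    ax.set_xlabel("accessibility decile (1 = least accessible)")
    ax.set_ylabel("predicted paired nucleotides")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_history(history, path) -> None:
    """Training/validation loss and accuracy per epoch."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
    axes[0].plot(history["epoch"], history["loss"], label="train")
    if history["val_loss"].notna().any():
        axes[0].plot(history["epoch"], history["val_loss"], label="validation")
    axes[0].set_xlabel("epoch")
    axes[0].set_ylabel("cross-entropy loss")
    axes[0].legend()
    axes[1].plot(history["epoch"], history["accuracy"], label="train")
    if history["val_accuracy"].notna().any():
        axes[1].plot(history["epoch"], history["val_accuracy"], label="validation")
    axes[1].set_xlabel("epoch")
    axes[1].set_ylabel("top-1 accuracy")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
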