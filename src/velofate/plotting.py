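"""Minimal plots: trend with uncertainty band, circular fate embedding."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .downstream import CircularEmbedding, TrendFit


def plot_trend(
    fit: TrendFit,
    path: str | Path,
    tau: np.ndarray | None = None,
    y: np.ndarray | None = None,
    title: str | None = None,
) -> None:
    """Fitted trend with its residual-s.d. band, optionally over raw points."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    if tau is not None and y is not None:
        ax.scatter(tau, y, s=4, alpha=0.3, color="grey", linewidths=0)
    ax.plot(fit.test_grid, fit.fitted, color="C0", lw=2)
    ax.fill_between(
        fit.test_grid, fit.fitted - fit.band, fit.fitted + fit.band,
        color="C0", alpha=0.2, linewidth=0,
    )
    ax.set_xlabel("pseudotime")
    ax.set_ylabel("expression")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_circular(
    embedding: CircularEmbedding,
    path: str | Path,
    color: np.ndarray | None = None,
    lineage_names: list[str] | None = None,
) -> None:
    """Cells inside the unit circle, colored by an optional scalar."""
    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="lightgrey", lw=1)
    sc = ax.scatter(
        embedding.coords[:, 0], embedding.coords[:, 1],
        c=color, s=6, cmap="viridis", linewidths=0,
    )
    if color is not None:
        fig.colorbar(sc, ax=ax, shrink=0.8)
    for t, angle in enumerate(embedding.angles):
        name = lineage_names[t] if lineage_names else f"lineage {t}"
        ax.annotate(
            name, (1.08 * np.cos(angle), 1.08 * np.sin(angle)),
            ha="center", va="center", fontsize=8,
        )
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
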