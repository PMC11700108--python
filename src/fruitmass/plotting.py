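"""Diagnostic plots: 1:1 scatter, marginal histograms, correlation heat map."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def scatter_identity(measured, estimated, path, title: str = "") -> None:
    """Measured vs estimated weight with the 1:1 line."""
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(estimated, measured, s=8, alpha=0.5, edgecolors="none")
    lo = min(measured.min(), estimated.min())
    hi = max(measured.max(), estimated.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="1:1 line")
    ax.set_xlabel("estimated weight (g)")
    ax.set_ylabel("measured weight (g)")
    if title:
        ax.set_title(title)
    ax.legend()
    _save(fig, path)


def cohort_histograms(records: pd.DataFrame, path, title: str = "") -> None:
    cols = list(records.columns)
    fig, axes = plt.subplots(1, len(cols), figsize=(4 * len(cols), 3.2))
    for ax, col in zip(np.atleast_1d(axes), cols):
        ax.hist(records[col], bins=30, color="tab:green", alpha=0.8)
        ax.set_xlabel(col)
    if title:
        fig.suptitle(title)
    _save(fig, path)


def correlation_heatmap(r: pd.DataFrame, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.2, 3.8))
    im = ax.imshow(r.values, vmin=-1, vmax=1, cmap="RdYlGn")
    ax.set_xticks(range(len(r.columns)), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(r.index)), r.index)
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            ax.text(j, i, f"{r.values[i, j]:.2f}", ha="center", va="center")
    fig.colorbar(im, ax=ax)
    if title:
        ax.set_title(title)
    _save(fig, path)


def _save(fig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
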