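"""Optional figure rendering: Kaplan-Meier curves and PCA embeddings."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

SUBTYPE_COLORS = {"A": "#3b4cc0", "B": "#b40426", "control": "#2ca02c"}


def km_plot(curves: dict, path: str | Path, title: str = "") -> None:
    """Step plot of per-group survival curves."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, table in sorted(curves.items()):
        ax.step(
            table["time"], table["survival"], where="post",
            label=f"subtype {group}",
            color=SUBTYPE_COLORS.get(str(group)),
        )
    ax.set_xlabel("time (days)")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_plot(embedding, groups, path: str | Path, title: str = "") -> None:
    """PC1/PC2 scatter colored by group, with 95% confidence ellipses."""
    coords = embedding.coordinates
    fig, ax = plt.subplots(figsize=(5, 4))
    for level in sorted(set(groups)):
        sel = np.asarray(groups) == level
        ax.scatter(
            coords.iloc[sel, 0], coords.iloc[sel, 1], s=12,
            label=str(level), color=SUBTYPE_COLORS.get(str(level)),
        )
    for level, ell in embedding.ellipses.items():
        vals, vecs = np.linalg.eigh(ell["cov"])
        theta = np.linspace(0, 2 * np.pi, 200)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        pts = ell["mean"][:, None] + ell["radius"] * vecs @ (
            np.sqrt(np.maximum(vals, 0))[:, None] * circle
        )
        ax.plot(pts[0], pts[1], lw=1,
                color=SUBTYPE_COLORS.get(str(level), "gray"))
    evr = embedding.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
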