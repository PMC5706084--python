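"""Optional plot exports: scree plots and component score scatters."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .pca import PCAResult, SAMPLES_AS_VARIABLES

__all__ = ["scree_plot", "score_scatter"]


def scree_plot(result: PCAResult, path, max_components: int = 15) -> None:
    """Eigenvalue-versus-rank plot used to choose how many PCs to keep."""
    lam = result.eigenvalues[:max_components]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(range(1, len(lam) + 1), lam, "o-")
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    ax.set_title(f"scree ({result.orientation})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def score_scatter(result: PCAResult, path, highlight=(), components=(1, 2)) -> None:
    """Positions in the plane of two leading components, outliers labelled.

    For the samples-as-variables orientation each position's coordinate is
    its loading scaled by sqrt(eigenvalue); flagged positions are annotated.
    """
    i, j = components
    if result.orientation == SAMPLES_AS_VARIABLES:
        coords = result.variable_coordinates(max(i, j))
    else:
        coords = result.scores
    x, y = coords.iloc[:, i - 1], coords.iloc[:, j - 1]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.scatter(x, y, s=12, color="0.4")
    for p in highlight:
        if p in coords.index:
            ax.scatter([x[p]], [y[p]], s=30, color="crimson")
            ax.annotate(p, (x[p], y[p]), fontsize=8)
    ax.set_xlabel(f"PC{i}")
    ax.set_ylabel(f"PC{j}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
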