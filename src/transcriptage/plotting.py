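"""Simple figure helpers: index profile with CI band, REL small multiples,
stage-similarity line panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np

from .indices import RelMatrix, StageIndexProfile
from .similarity import SimilarityGrid


def plot_profile(profile: StageIndexProfile, ax=None):
    """Index value per stage, with the bootstrap band if present."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    x = np.arange(len(profile.stage_ids))
    if profile.ci_low is not None:
        ax.fill_between(x, profile.ci_low, profile.ci_high, alpha=0.3, color="grey",
                        label="bootstrap CI")
    ax.plot(x, profile.values, marker="o", color="crimson", label=profile.index_kind)
    ax.set_xticks(x, profile.stage_ids, rotation=45, ha="right")
    ax.set_xlabel("developmental stage")
    ax.set_ylabel(profile.index_kind)
    ax.legend(frameon=False)
    return ax


def plot_rel(rel: RelMatrix, ncols: int = 4):
    """One panel per phylostratum of its REL trajectory."""
    rows = rel.rel.index
    nrows = int(np.ceil(len(rows) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows),
                             sharex=True, sharey=True, squeeze=False)
    x = np.arange(rel.rel.shape[1])
    for ax, ps in zip(axes.ravel(), rows):
        ax.plot(x, rel.rel.loc[ps], marker=".", color="steelblue")
        ax.set_title(f"ps{ps}", fontsize=9)
        ax.set_ylim(-0.05, 1.05)
    for ax in axes.ravel()[len(rows):]:
        ax.set_visible(False)
    fig.supxlabel("stage index")
    fig.supylabel("REL")
    fig.tight_layout()
    return fig


def plot_similarity(grid: SimilarityGrid):
    """One line per species-A stage of its rho across species-B stages,
    the maximum marked with a point."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(grid.rho.shape[1])
    for _, row in grid.rho.iterrows():
        ax.plot(x, row.values, alpha=0.7)
        if not row.isna().all():
            j = int(np.nanargmax(row.values))
            ax.plot(j, row.values[j], "o", color="black", ms=4)
    ax.set_xticks(x, grid.rho.columns, rotation=45, ha="right")
    ax.set_xlabel("stage (species B)")
    ax.set_ylabel("Spearman rho")
    ax.set_title(f"n = {grid.n_orthologs} orthologs")
    fig.tight_layout()
    return fig
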