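"""Plotting: spatial correlation network, similarity matrix, intensity profile.

Edges of the network are coloured on a blue-to-purple gradient mapping
low-to-high Pearson r, the rendering convention used for interface
connectivity figures.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
from matplotlib.colors import LinearSegmentedColormap, Normalize

__all__ = ["BLUE_PURPLE", "plot_network", "plot_similarity_matrix", "plot_profile"]

#: low r -> blue, high r -> purple
BLUE_PURPLE = LinearSegmentedColormap.from_list("blue_purple", ["#1f4fff", "#7d1fa8"])

_COMPARTMENT_COLORS = {"host": "#55a868", "implant": "#dd8452"}


def plot_network(graph: nx.Graph, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """ROIs as circles at their centroids, correlated pairs as gradient lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    threshold = graph.graph.get("threshold", 0.1)
    norm = Normalize(vmin=threshold, vmax=1.0)
    for i, j, data in graph.edges(data=True):
        xi, yi = graph.nodes[i].get("x", 0.0), graph.nodes[i].get("y", 0.0)
        xj, yj = graph.nodes[j].get("x", 0.0), graph.nodes[j].get("y", 0.0)
        ax.plot(
            [xi, xj], [yi, yj],
            color=BLUE_PURPLE(norm(data.get("r", threshold))),
            linewidth=1.0, zorder=1,
        )
    for n, data in graph.nodes(data=True):
        ax.scatter(
            data.get("x", 0.0), data.get("y", 0.0),
            s=60, zorder=2, edgecolors="black", linewidths=0.5,
            color=_COMPARTMENT_COLORS.get(data.get("compartment", ""), "#888888"),
        )
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_aspect("equal")
    return ax


def plot_similarity_matrix(
    ordered_matrix: np.ndarray,
    ordering: Optional[Sequence[int]] = None,
    ax: Optional[plt.Axes] = None,
) -> plt.Axes:
    """Reordered correlation matrix; strongly correlated block at top-left."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(ordered_matrix, vmin=-1, vmax=1, cmap="magma", interpolation="nearest")
    plt.colorbar(im, ax=ax, label="Pearson r")
    if ordering is not None:
        ax.set_xticks(range(len(ordering)))
        ax.set_xticklabels([str(k) for k in ordering], fontsize=5, rotation=90)
        ax.set_yticks(range(len(ordering)))
        ax.set_yticklabels([str(k) for k in ordering], fontsize=5)
    return ax


def plot_profile(profile, threshold: Optional[float] = None, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Mean intensity vs signed distance to the boundary."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(profile.distances_um, profile.values, color="#333333")
    ax.axvline(0.0, color="red", linestyle="--", label="implant boundary")
    if threshold is not None:
        ax.axhline(threshold, color="blue", linestyle=":", label="detection threshold")
    ax.set_xlabel("distance from boundary (um, + into host)")
    ax.set_ylabel("mean intensity")
    ax.legend(fontsize=8)
    return ax
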