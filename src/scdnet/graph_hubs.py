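"""Weighted betweenness centrality, hub detection and hub-transition sets.

Edges of a weighted adjacency are mapped to lengths 1/w (zero weights are
non-edges), all-pairs shortest paths are counted with fractional credit
for ties (Brandes' algorithm via networkx) and the unnormalized
betweenness of every node is returned.  Hubs are nodes whose betweenness
is at least 1.5 sample standard deviations above the mean; hub turnover
between two groups is expressed as a Venn partition (shared / lost in
group B / gained in group B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import ROIAtlas
from .connectivity import ConnectivityMatrix

__all__ = [
    "BCVector",
    "HubSet",
    "VennPartition",
    "weighted_betweenness",
    "detect_hubs",
    "venn_partition",
    "hub_table",
    "plot_venn",
]


@dataclass
class BCVector:
    """Per-node betweenness values in atlas order."""

    values: np.ndarray
    roi_order: list[str]
    band: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.roi_order):
            raise ValueError("values must be 1-D and match roi_order")
        if np.any(self.values < 0):
            raise ValueError("betweenness values are non-negative")


@dataclass
class HubSet:
    """Hubs of one group network in one band with the threshold used."""

    group: str
    band: str
    hubs: frozenset[str]
    threshold: float
    bc_mean: float
    bc_sd: float
    note: str | None = None


@dataclass(frozen=True)
class VennPartition:
    """Hub turnover between groups A (reference) and B.

    ``exclusive_a`` are hubs lost in group B, ``exclusive_b`` hubs gained.
    """

    shared: frozenset[str]
    exclusive_a: frozenset[str]
    exclusive_b: frozenset[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.shared), len(self.exclusive_a), len(self.exclusive_b))


def weighted_betweenness(
    adjacency: ConnectivityMatrix | np.ndarray,
    roi_order: list[str] | None = None,
    length: str = "inverse",
) -> BCVector:
    """Unnormalized weighted betweenness centrality of every node.

    ``length`` selects the weight-to-length mapping: ``inverse`` (1/w,
    default) or ``log`` (-log w).  Endpoints of a path are excluded, ties
    receive fractional credit, and node pairs with no connecting path
    contribute nothing (disconnected graphs are allowed).
    """
    if isinstance(adjacency, ConnectivityMatrix):
        values = adjacency.values
        roi_order = list(adjacency.roi_order)
        band = adjacency.band
    else:
        values = np.asarray(adjacency, dtype=float)
        if roi_order is None:
            roi_order = [f"n{i}" for i in range(values.shape[0])]
        band = None
    n = values.shape[0]
    if n < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    if not np.allclose(values, values.T):
        raise ValueError("adjacency must be symmetric")

    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        w = values[i, j]
        if w > 0:
            ell = 1.0 / w if length == "inverse" else -np.log(w)
            if ell <= 0:  # -log(1) = 0: treat as an infinitesimally short edge
                ell = 1e-12
            g.add_edge(int(i), int(j), length=ell)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return BCVector(
        values=np.array([bc[i] for i in range(n)]),
        roi_order=roi_order,
        band=band,
    )


def detect_hubs(
    bc: BCVector,
    k: float = 1.5,
    group: str = "",
    band: str | None = None,
) -> HubSet:
    """Hubs = nodes with BC >= mean + k * SD (SD with ddof=1, ties included).

    A constant BC vector (SD = 0) yields an empty hub set with a note:
    the rule cannot single out nodes when all are equally central.
    """
    vals = bc.values
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    band = band if band is not None else (bc.band or "")
    if sd == 0.0:
        return HubSet(
            group=group, band=band, hubs=frozenset(),
            threshold=mean, bc_mean=mean, bc_sd=0.0,
            note="constant betweenness: hub rule degenerate, no hubs reported",
        )
    threshold = mean + k * sd
    hubs = frozenset(
        roi for roi, v in zip(bc.roi_order, vals) if v >= threshold
    )
    return HubSet(
        group=group, band=band, hubs=hubs,
        threshold=threshold, bc_mean=mean, bc_sd=sd,
    )


def venn_partition(hubs_a: HubSet, hubs_b: HubSet) -> VennPartition:
    """Shared / exclusive hub sets between two groups (same band)."""
    if hubs_a.band != hubs_b.band:
        raise ValueError(
            f"band mismatch: {hubs_a.band!r} vs {hubs_b.band!r}"
        )
    a, b = set(hubs_a.hubs), set(hubs_b.hubs)
    return VennPartition(
        shared=frozenset(a & b),
        exclusive_a=frozenset(a - b),
        exclusive_b=frozenset(b - a),
    )


def hub_table(hub_sets: list[HubSet], atlas: ROIAtlas) -> pd.DataFrame:
    """Tidy per-hub table with lobe annotations from the atlas."""
    rows = []
    for hs in hub_sets:
        for roi in sorted(hs.hubs):
            rows.append(
                {
                    "group": hs.group,
                    "band": hs.band,
                    "roi": roi,
                    "lobe": atlas.lobe_of(roi),
                    "threshold": hs.threshold,
                }
            )
    return pd.DataFrame(rows, columns=["group", "band", "roi", "lobe", "threshold"])


def plot_venn(partition: VennPartition, labels: tuple[str, str], path) -> None:
    """Two-circle Venn diagram of hub turnover rendered with matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    n_shared, n_a, n_b = partition.counts
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.add_patch(Circle((-0.45, 0), 1.0, alpha=0.4, color="tab:blue"))
    ax.add_patch(Circle((0.45, 0), 1.0, alpha=0.4, color="tab:orange"))
    ax.text(-0.95, 0, str(n_a), ha="center", va="center", fontsize=16)
    ax.text(0.0, 0, str(n_shared), ha="center", va="center", fontsize=16)
    ax.text(0.95, 0, str(n_b), ha="center", va="center", fontsize=16)
    ax.text(-0.85, 1.15, labels[0], ha="center", fontsize=11)
    ax.text(0.85, 1.15, labels[1], ha="center", fontsize=11)
    ax.set_xlim(-1.8, 1.8)
    ax.set_ylim(-1.4, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)
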