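"""Synthetic hub-structured brain networks with controllable rewiring.

These generators stand in for real resting-state source networks: they
plant known hubs (so hub detection can be benchmarked against ground
truth) and derive one group's network from the other by rewiring a
controllable fraction of edges (so network-similarity measures can be
checked for monotone degradation).

A base weighted graph is drawn at a target density over the atlas nodes
(with a random spanning chain to guarantee connectivity) and every edge
incident to a planted hub has its weight multiplied by ``hub_boost``
(clipped to 1).  Under the 1/weight length convention, boosted edges are
short, which routes shortest paths through the planted hubs and raises
their betweenness.  Rewiring is nested: a seed-determined edge order is
fixed and a fraction f relocates the first floor(f * E) edges of that
order to new node pairs, so larger fractions strictly extend smaller
ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..atlas import ROIAtlas
from ..connectivity import ConnectivityMatrix

__all__ = ["NetworkSpec", "generate_hub_network"]


@dataclass(frozen=True)
class NetworkSpec:
    """Recipe for a pair of group networks with planted hubs."""

    atlas: ROIAtlas
    planted_hubs: dict[str, frozenset[str]]  # group -> hub ROI ids
    base_density: float = 0.3
    hub_boost: float = 3.0
    rewiring_fraction: float = 0.0
    weight_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.base_density <= 1.0):
            raise ValueError("base_density must lie in (0, 1]")
        if not (0.0 <= self.rewiring_fraction <= 1.0):
            raise ValueError("rewiring_fraction must lie in [0, 1]")
        if self.hub_boost <= 0:
            raise ValueError("hub_boost must be positive")
        lo, hi = self.weight_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("weight_range must satisfy 0 < lo <= hi <= 1")
        roi_ids = set(self.atlas.roi_ids)
        for group, hubs in self.planted_hubs.items():
            extra = set(hubs) - roi_ids
            if extra:
                raise ValueError(f"group {group!r} hubs not in atlas: {sorted(extra)}")

    @property
    def groups(self) -> list[str]:
        return list(self.planted_hubs)


def _base_graph(spec: NetworkSpec, rng: np.random.Generator) -> np.ndarray:
    """Connected random weighted graph at the target density (no boost)."""
    n = spec.atlas.n_rois
    lo, hi = spec.weight_range
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < spec.base_density
    weights = rng.uniform(lo, hi, size=iu.size)
    w[iu[mask], ju[mask]] = weights[mask]
    # random spanning chain guarantees connectivity
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        i, j = min(a, b), max(a, b)
        if w[i, j] == 0:
            w[i, j] = rng.uniform(lo, hi)
    return w + w.T


def _rewire(base: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Relocate the first floor(fraction * E) edges of a fixed random order."""
    w = base.copy()
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    present = np.flatnonzero(w[iu, ju] > 0)
    absent = np.flatnonzero(w[iu, ju] == 0)
    order = rng.permutation(present)  # consumed once: nested across fractions
    targets = rng.permutation(absent)
    n_rewire = int(np.floor(fraction * present.size))
    n_rewire = min(n_rewire, targets.size)
    for k in range(n_rewire):
        src = order[k]
        dst = targets[k]
        i, j = iu[src], ju[src]
        a, b = iu[dst], ju[dst]
        w[a, b] = w[b, a] = w[i, j]
        w[i, j] = w[j, i] = 0.0
    return w


def _boost(w: np.ndarray, hubs: frozenset[str], spec: NetworkSpec) -> np.ndarray:
    out = w.copy()
    idx = [i for i, r in enumerate(spec.atlas.roi_ids) if r in hubs]
    for i in idx:
        out[i, :] *= spec.hub_boost
        out[:, i] = out[i, :]
    # hub-hub edges get boosted once, not twice
    for i in idx:
        for j in idx:
            if i < j and w[i, j] > 0:
                out[i, j] = out[j, i] = w[i, j] * spec.hub_boost
    return np.clip(out, 0.0, 1.0)


def generate_hub_network(
    spec: NetworkSpec, group: str, band: str = "delta"
) -> ConnectivityMatrix:
    """Weighted adjacency for one group with that group's hubs boosted.

    The first group of ``spec.planted_hubs`` is the reference; any other
    group's network is derived from the same base graph with
    ``spec.rewiring_fraction`` of the edges relocated before its own hub
    boost is applied.  Identical spec + seed give byte-identical output.
    """
    if group not in spec.planted_hubs:
        raise KeyError(f"unknown group {group!r}")
    if spec.hub_boost <= 1 and spec.planted_hubs[group]:
        warnings.warn(
            "hub_boost <= 1 does not guarantee planted-hub recovery",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    base = _base_graph(spec, rng)
    # the rewiring draw is consumed deterministically even for the
    # reference group so that every group sees the same base randomness
    rewire_rng = np.random.default_rng(spec.seed + 1)
    if group == spec.groups[0]:
        w = base
    else:
        w = _rewire(base, spec.rewiring_fraction, rewire_rng)
    w = _boost(w, spec.planted_hubs[group], spec)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(
        band=band,
        values=w,
        roi_order=spec.atlas.roi_ids,
        level="group-average",
        subject_id=None,
    )
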