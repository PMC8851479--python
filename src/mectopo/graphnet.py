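"""Spring-loaded graph model of pairwise class distances.

The four cell classes (grid, hd, border, ov) form a complete graph whose
edge weights are the inverse of the normalized interclass NN distances, so
anatomically close classes attract more strongly.  A force-directed
(Fruchterman-Reingold) layout is run from random initial positions; the
separation ratio measures how far the grid node ends up from the other
three relative to how spread out those three are among themselves.  A
weight-permutation null redistributes the six observed weights over the six
edges before each layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from ._util import spawn_seed

NODES = ("grid", "hd", "border", "ov")
#: canonical edge order: (grid,hd), (grid,ov), (grid,border), (hd,ov), (hd,border), (ov,border)
EDGES = (
    ("grid", "hd"), ("grid", "ov"), ("grid", "border"),
    ("hd", "ov"), ("hd", "border"), ("ov", "border"),
)


@dataclass(frozen=True)
class ClassGraph:
    """Complete 4-node class graph; weights in canonical edge order."""

    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.weights) != len(EDGES):
            raise ValueError(f"expected {len(EDGES)} edge weights")
        if any((not np.isfinite(w)) or w <= 0 for w in self.weights):
            raise ValueError("edge weights must be positive and finite")

    @classmethod
    def from_normalized_distances(cls, distances: Sequence[float] | Mapping[tuple[str, str], float]):
        """Build the graph with edge weight = 1 / normalized NN distance."""
        if isinstance(distances, Mapping):
            d = [distances[e] if e in distances else distances[(e[1], e[0])] for e in EDGES]
        else:
            d = list(distances)
        return cls(tuple(1.0 / float(x) for x in d))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(NODES)
        for (u, v), w in zip(EDGES, self.weights):
            g.add_edge(u, v, weight=float(w))
        return g


def spring_layout(graph: ClassGraph, n_iter: int = 1000, seed: int = 0) -> dict[str, np.ndarray]:
    """Force-directed 2-D layout from random initial node positions.

    Fruchterman-Reingold with optimal distance k = 1/sqrt(n_nodes) and linear
    cooling: attraction scales with edge weight, repulsion acts between all
    node pairs.  Deterministic for a fixed seed.
    """
    pos = nx.spring_layout(
        graph.to_networkx(), k=1.0 / np.sqrt(len(NODES)), iterations=n_iter,
        seed=int(seed), weight="weight", dim=2,
    )
    return {node: np.asarray(p, float) for node, p in pos.items()}


def separation_ratio(coords: Mapping[str, np.ndarray], focal: str = "grid") -> float:
    """Distance of the focal node to the others' centroid over their mean spacing.

    ratio = ||p_focal - centroid(others)|| / mean pairwise distance among the
    other nodes; NaN when the non-focal nodes coincide.  Invariant to rigid
    motions and uniform scaling of the coordinates.
    """
    others = [np.asarray(coords[n], float) for n in coords if n != focal]
    if len(others) < 2:
        raise ValueError("need at least two non-focal nodes")
    p = np.asarray(coords[focal], float)
    centroid = np.mean(others, axis=0)
    intra = [np.linalg.norm(others[i] - others[j])
             for i in range(len(others)) for j in range(i + 1, len(others))]
    mean_intra = float(np.mean(intra))
    if mean_intra == 0:
        return float("nan")
    return float(np.linalg.norm(p - centroid) / mean_intra)


@dataclass
class PermutationNull:
    ratios: np.ndarray
    median: float


def weight_permutation_null(
    weights: Sequence[float],
    n_perm: int = 1000,
    n_iter: int = 1000,
    seed: int = 0,
    focal: str = "grid",
) -> PermutationNull:
    """Separation-ratio distribution under random permutation of edge weights.

    Each permutation shuffles the six observed weights over the six edges,
    runs a fresh layout from random initial positions, and records the ratio.
    """
    w = np.asarray(list(weights), float)
    if len(w) != len(EDGES):
        raise ValueError(f"expected {len(EDGES)} weights")
    rng = spawn_seed(seed, 11)
    ratios = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(w))
        g = ClassGraph(tuple(w[perm]))
        layout_seed = int(rng.integers(0, 2**31 - 1))
        ratios[i] = separation_ratio(spring_layout(g, n_iter, layout_seed), focal)
    return PermutationNull(ratios, float(np.median(ratios)))
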