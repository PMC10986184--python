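"""Persistent homology of brain graphs: filtrations and Betti curves.

A participant's brain graph has the parcellation regions as nodes and the
retained tracts as weighted edges (weights are min/max-normalized w-scores
or untransformed GFA; missing tracts carry weight 0).  The graph filtration
retains, at threshold lambda, exactly the edges with weight strictly greater
than lambda — so edges are progressively removed from the smallest to the
largest weight as lambda sweeps upward, and zero-weight (missing) tracts are
absent at every non-negative threshold.

Betti-0 (number of connected components, isolated nodes included) is
computed with an incremental union-find over the sorted edge weights;
Betti-1 (number of independent cycles) follows analytically from the Euler
characteristic, beta1 = beta0 - V + E.  Along the filtration beta0 is
non-decreasing and beta1 non-increasing.

The component count changes only at the edge weights of the maximum-weight
spanning tree of the graph (the "minimum spanning tree" of the associated
distance graph, as in single-linkage clustering); the grid can be augmented
with the union of participants' spanning-tree weights to capture every
merge point exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .wscore import WScoreTable


class UnionFind:
    """Disjoint-set forest with path compression and union by size."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n
        self.n_components = n

    def find(self, a: int) -> int:
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.n_components -= 1
        return True


@dataclass
class ParticipantGraph:
    """Weighted undirected graph on a fixed node set."""

    participant_id: str
    node_labels: List[str]
    edges_i: np.ndarray  # int indices
    edges_j: np.ndarray
    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.weights)


@dataclass
class FiltrationGrid:
    thresholds: np.ndarray
    provenance: str = "linear-100"

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("filtration thresholds must be strictly increasing")
        self.thresholds = t


@dataclass
class BettiCurve:
    participant_id: str
    grid: FiltrationGrid
    betti0: np.ndarray
    betti1: np.ndarray
    edge_count: np.ndarray
    n_nodes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": self.participant_id,
            "threshold": self.grid.thresholds,
            "betti0": self.betti0,
            "betti1": self.betti1,
            "n_edges": self.edge_count,
        })


def graphs_from_wtable(
    wtable: WScoreTable,
    node_labels: Optional[Sequence[str]] = None,
) -> Dict[str, ParticipantGraph]:
    """One weighted graph per participant from a (normalized) w-score table.

    Edge weights are taken as-is; missing entries must already be encoded as
    zeros (see :func:`tractopo.wscore.minmax_normalize`).
    """
    t = wtable.table
    parts = t["target_id"].str.partition("--")
    region_a = parts[0].to_numpy()
    region_b = parts[2].to_numpy()
    if node_labels is None:
        node_labels = sorted(set(region_a) | set(region_b))
    pos = {lab: k for k, lab in enumerate(node_labels)}
    ii = np.array([pos[a] for a in region_a])
    jj = np.array([pos[b] for b in region_b])
    w = t["w"].to_numpy(float)
    w = np.where(np.isfinite(w), w, 0.0)
    graphs = {}
    for pid, idx in t.groupby("participant_id", sort=True).indices.items():
        graphs[str(pid)] = ParticipantGraph(
            participant_id=str(pid),
            node_labels=list(node_labels),
            edges_i=ii[idx], edges_j=jj[idx], weights=w[idx])
    return graphs


def spanning_tree_weights(
    graph: ParticipantGraph, literal_minimum: bool = False
) -> np.ndarray:
    """Edge weights of the maximum-weight spanning forest (Kruskal).

    These are exactly the thresholds at which components merge in the
    filtration.  ``literal_minimum=True`` returns the minimum-weight
    spanning forest instead.
    """
    order = np.argsort(graph.weights, kind="stable")
    if not literal_minimum:
        order = order[::-1]
    uf = UnionFind(graph.n_nodes)
    out = []
    for k in order:
        if uf.union(int(graph.edges_i[k]), int(graph.edges_j[k])):
            out.append(graph.weights[k])
    return np.sort(np.asarray(out, dtype=float))


def build_grid(
    graphs: Dict[str, ParticipantGraph],
    n_linear: int = 100,
    augment_mst: bool = False,
    literal_minimum: bool = False,
) -> FiltrationGrid:
    """Linear grid over the pooled weight range, optionally augmented with
    the union of participants' spanning-tree edge weights."""
    if not graphs:
        raise ValueError("no graphs given")
    all_w = np.concatenate([g.weights for g in graphs.values()])
    if all_w.size == 0:
        raise ValueError("graphs carry no edges")
    lo, hi = float(all_w.min()), float(all_w.max())
    if hi <= lo:
        raise ValueError("all edge weights identical; filtration is degenerate")
    thresholds = np.linspace(lo, hi, n_linear)
    provenance = f"linear-{n_linear}"
    if augment_mst:
        mst = np.concatenate(
            [spanning_tree_weights(g, literal_minimum) for g in graphs.values()])
        thresholds = np.unique(np.concatenate([thresholds, mst]))
        provenance = "mst-augmented"
    return FiltrationGrid(np.unique(thresholds), provenance)


def betti0(
    edges_i: np.ndarray, edges_j: np.ndarray, weights: np.ndarray,
    n_nodes: int, lam: float,
) -> int:
    """Connected components of the subgraph with edge weight > lam."""
    uf = UnionFind(n_nodes)
    for i, j, w in zip(edges_i, edges_j, weights):
        if w > lam:
            uf.union(int(i), int(j))
    return uf.n_components


def betti1(
    edges_i: np.ndarray, edges_j: np.ndarray, weights: np.ndarray,
    n_nodes: int, lam: float,
) -> int:
    """Independent cycles via Euler: beta1 = beta0 - V + E(lam)."""
    b0 = betti0(edges_i, edges_j, weights, n_nodes, lam)
    e = int((weights > lam).sum())
    return b0 - n_nodes + e


def betti_curve(graph: ParticipantGraph, grid: FiltrationGrid) -> BettiCurve:
    """Betti-0/1 curves over the grid via one incremental union-find sweep.

    The thresholds are visited from the largest down; lowering lambda only
    ever adds edges, so components can be merged incrementally in a single
    pass over the weight-sorted edge list.
    """
    thr = grid.thresholds
    V = graph.n_nodes
    order = np.argsort(graph.weights, kind="stable")[::-1]
    w_sorted = graph.weights[order]
    uf = UnionFind(V)
    b0 = np.empty(len(thr), dtype=int)
    e_count = np.empty(len(thr), dtype=int)
    ptr = 0
    for k in range(len(thr) - 1, -1, -1):
        lam = thr[k]
        while ptr < len(w_sorted) and w_sorted[ptr] > lam:
            idx = order[ptr]
            uf.union(int(graph.edges_i[idx]), int(graph.edges_j[idx]))
            ptr += 1
        b0[k] = uf.n_components
        e_count[k] = ptr
    b1 = b0 - V + e_count
    return BettiCurve(participant_id=graph.participant_id, grid=grid,
                      betti0=b0, betti1=b1, edge_count=e_count, n_nodes=V)


def betti_curves(
    graphs: Dict[str, ParticipantGraph], grid: FiltrationGrid,
) -> Dict[str, BettiCurve]:
    return {pid: betti_curve(g, grid) for pid, g in graphs.items()}


def curves_frame(curves: Dict[str, BettiCurve]) -> pd.DataFrame:
    """Long-format export: participant, threshold, beta0, beta1, E."""
    return pd.concat([c.to_frame() for c in curves.values()],
                     ignore_index=True)
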