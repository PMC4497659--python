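"""Spanning trees, pruning complexity (H function) and the maximally
regular graph.

A distance matrix over N nodes is read as the complete weighted graph on
those nodes.  Its minimum spanning tree (MST) keeps only the N−1 strongest
(shortest) links needed to hold the system together; the edges skipped
while building it, in ascending-distance order, are the candidate links for
the maximally regular graph (MRG): they are added back one at a time and
the variant with the highest hubness H is kept.

H is computed from an iterative pruning trace.  Each pruning cycle
simultaneously removes every node of degree ≤ 1 (with its incident edges);
the number removed at cycle i is the cycle's *gradient* Nd_i.  Runs of
equal gradient form classes; the cycles adjacent to a change of gradient
are the *change states*.  With

* ``mu``  = mean nodes removed per cycle,
* ``phi`` = mean gradient over the change states (the whole-trace mean when
  the gradient never changes),
* ``A``   = number of edges,

the hubness index is ``H = mu * (phi - 1) / A``.  A pure hub (star) removes
almost everything in one cycle and scores high; a chain sheds two leaves
per cycle and scores low.  Pruning stops when no degree-≤1 node remains, so
a 2-core (every node on a cycle) is never consumed; a graph with no leaves
at all has an empty trace and H = 0 — densely cyclic graphs are minimally
hub-oriented by this measure, which is what drives the MRG to add only a
few strong chords rather than fill the graph in.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "kruskal_mst",
    "count_spanning_trees",
    "pruning_trace",
    "h_function",
    "maximally_regular_graph",
    "PruningTrace",
    "HReport",
    "MRGResult",
    "export_graph",
    "load_edge_list",
    "tree_center",
]


def _as_distance_frame(D) -> pd.DataFrame:
    frame = pd.DataFrame(D)
    arr = frame.to_numpy(float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.isfinite(arr).all():
        raise ValueError("distance matrix has non-finite entries")
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    return frame


def _sorted_edges(frame: pd.DataFrame) -> list[tuple[float, int, int]]:
    # deterministic order: (weight, min index, max index)
    arr = frame.to_numpy(float)
    n = len(arr)
    return sorted((float(arr[i, j]), i, j) for i in range(n) for j in range(i + 1, n))


def kruskal_mst(D) -> tuple[nx.Graph, list[tuple[str, str, float]]]:
    """Minimum spanning tree of a labelled distance matrix (Kruskal).

    Edges are scanned in ascending (weight, node-index) order, which makes
    ties reproducible.  Returns the tree as a :class:`networkx.Graph` (edge
    attribute ``weight``, graph attribute ``total_weight``) together with
    the skipped cycle-forming edges in the order they were encountered.
    """
    frame = _as_distance_frame(D)
    names = [str(c) for c in frame.columns]
    parent = list(range(len(names)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = nx.Graph()
    tree.add_nodes_from(names)
    skipped: list[tuple[str, str, float]] = []
    total = 0.0
    for wgt, i, j in _sorted_edges(frame):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.add_edge(names[i], names[j], weight=wgt)
            total += wgt
        else:
            skipped.append((names[i], names[j], wgt))
    tree.graph["total_weight"] = total
    return tree, skipped


def count_spanning_trees(n_nodes: int) -> int:
    """Number of labelled spanning trees of the complete graph: V^(V−2)."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return n_nodes ** (n_nodes - 2)


@dataclass
class PruningTrace:
    """Outcome of iterative leaf pruning."""

    removed_per_cycle: list[int]           # gradient sequence Nd_i
    change_states: list[int]               # cycle indices adjacent to a gradient change
    n_nodes: int
    core_size: int                         # nodes surviving in a 2-core (0 for forests)

    @property
    def cycles(self) -> int:
        return len(self.removed_per_cycle)

    @property
    def removed_total(self) -> int:
        return sum(self.removed_per_cycle)

    @property
    def mu(self) -> float:
        """Mean nodes removed per pruning cycle."""
        if not self.removed_per_cycle:
            return 0.0
        return self.removed_total / self.cycles

    @property
    def stg(self) -> float:
        """Summed gradient over the change states."""
        return float(sum(self.removed_per_cycle[c] for c in self.change_states))

    @property
    def phi(self) -> float:
        """Mean gradient at the change states (whole-trace mean if the
        gradient never changes)."""
        if not self.removed_per_cycle:
            return 0.0
        if self.change_states:
            return self.stg / len(self.change_states)
        return self.mu


def pruning_trace(G: nx.Graph) -> PruningTrace:
    """Iteratively remove all degree-≤1 nodes per cycle until none remain."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if G.number_of_nodes() > 1 and not nx.is_connected(G):
        warnings.warn("pruning a disconnected graph; components prune in parallel",
                      stacklevel=2)
    degree = dict(G.degree())
    adjacency = {u: set(G.neighbors(u)) for u in G.nodes}
    live = set(G.nodes)
    removed: list[int] = []
    while live:
        leaves = {u for u in live if degree[u] <= 1}
        if not leaves:
            break  # 2-core: every surviving node sits on a cycle
        removed.append(len(leaves))
        for u in leaves:
            for nb in adjacency[u]:
                if nb in live and nb not in leaves:
                    degree[nb] -= 1
        live -= leaves
    change_set: set[int] = set()
    for c in range(1, len(removed)):
        if removed[c] != removed[c - 1]:
            change_set.update((c - 1, c))
    changes = sorted(change_set)
    return PruningTrace(
        removed_per_cycle=removed,
        change_states=changes,
        n_nodes=G.number_of_nodes(),
        core_size=len(live),
    )


@dataclass
class HReport:
    h: float
    mu: float
    phi: float
    n_edges: int
    trace: PruningTrace


def h_function(G: nx.Graph) -> HReport:
    """Hubness index ``H = mu * (phi - 1) / A`` of a graph (see module
    docstring for the pruning-trace quantities)."""
    trace = pruning_trace(G)
    a = G.number_of_edges()
    if a == 0 or trace.cycles == 0:
        return HReport(0.0, trace.mu, trace.phi, a, trace)
    h = trace.mu * (trace.phi - 1.0) / a
    return HReport(h, trace.mu, trace.phi, a, trace)


@dataclass
class MRGResult:
    """Maximally regular graph and the H curve that selected it."""

    graph: nx.Graph
    mst: nx.Graph
    skipped: list[tuple[str, str, float]]
    h_curve: list[float]                    # H_i for i = 0 .. R added edges
    r_star: int                             # edges added at the maximum
    has_mrg: bool                           # False when no edge was skipped

    @property
    def h0(self) -> float:
        return self.h_curve[0]

    @property
    def h_star(self) -> float:
        return self.h_curve[self.r_star]

    @property
    def r(self) -> int:
        return len(self.skipped)


def maximally_regular_graph(D) -> MRGResult:
    """Add MST-skipped edges back one at a time (strongest first) and keep
    the graph with the highest H; ties resolve to the fewest added edges.

    With two nodes nothing is ever skipped (R = 0); the result is then the
    MST itself with ``has_mrg=False``.
    """
    mst, skipped = kruskal_mst(D)
    current = mst.copy()
    h_curve = [h_function(current).h]
    best_h, best_i = h_curve[0], 0
    for i, (u, v, wgt) in enumerate(skipped, start=1):
        current.add_edge(u, v, weight=wgt)
        h = h_function(current).h
        h_curve.append(h)
        if h > best_h:
            best_h, best_i = h, i
    graph = mst.copy()
    for u, v, wgt in skipped[:best_i]:
        graph.add_edge(u, v, weight=wgt)
    return MRGResult(graph=graph, mst=mst, skipped=skipped, h_curve=h_curve,
                     r_star=best_i, has_mrg=bool(skipped))


# ---------------------------------------------------------------------------
# export / import


def export_graph(G: nx.Graph, path: str | Path, fmt: str = "edgelist") -> Path:
    """Write a graph as ``edgelist`` (CSV: source,target,weight), ``graphml``
    or ``dot``.  The edge-list round-trips losslessly via
    :func:`load_edge_list`."""
    path = Path(path)
    if fmt == "edgelist":
        with open(path, "w", newline="") as fh:
            out = csv.writer(fh)
            out.writerow(["source", "target", "weight"])
            for u, v, data in G.edges(data=True):
                out.writerow([u, v, repr(float(data.get("weight", 1.0)))])
    elif fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("graph G {\n")
            for u in G.nodes:
                fh.write(f'  "{u}";\n')
            for u, v, data in G.edges(data=True):
                fh.write(f'  "{u}" -- "{v}" [weight={float(data.get("weight", 1.0)):g}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
    return path


def load_edge_list(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:3] != ["source", "target", "weight"]:
            raise ValueError("not an autocmap edge-list file")
        for u, v, wgt in reader:
            g.add_edge(u, v, weight=float(wgt))
    return g


def tree_center(G: nx.Graph) -> str:
    """Center of a connected graph: the node of maximum degree, ties broken
    by minimum eccentricity, then by name."""
    degrees = dict(G.degree())
    top = max(degrees.values())
    candidates = [u for u, d in degrees.items() if d == top]
    if len(candidates) > 1:
        ecc = nx.eccentricity(G)
        candidates.sort(key=lambda u: (ecc[u], str(u)))
    return str(candidates[0])
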