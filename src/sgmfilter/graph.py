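"""Gapped spectrum graphs over a mass interval.

Nodes are the fragment masses of one interval, sorted ascending.  A directed
edge runs from a lower-mass node ``u`` to a higher-mass node ``v`` when the
integer mass difference is at most ``alpha * scale`` (plus tolerance) and is
explainable as the total mass of at least one amino-acid string, checked
against the precomputed composition table.  Each node keeps only its ``d``
outgoing edges with the smallest mass labels, which caps the out-degree and
hence the number of paths the search must consider.

Because edge labels are differences of node masses, the labels along any path
telescope: every path between two fixed nodes carries the same total mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from .alphabet import CompositionTable, discretize_mass
from .intervals import MassInterval
from .spectrum import FragmentScores

__all__ = [
    "SpectrumGraph",
    "TerminalSets",
    "build_spectrum_graph",
    "terminal_sets",
    "enumerate_blocked_patterns",
]


@dataclass
class SpectrumGraph:
    """A DAG of fragment masses with integer gap labels."""

    masses: np.ndarray
    int_masses: np.ndarray
    scores: np.ndarray
    #: adjacency: edges[i] = list of (target index, integer label), label-sorted
    edges: List[List[Tuple[int, int]]]
    out_degree_cap: int
    scale: int = 100
    orientation: str = "forward"
    graph_id: str = "g0"

    @property
    def n_nodes(self) -> int:
        return int(self.masses.size)

    def edge_list(self) -> List[Tuple[int, int, int]]:
        return [(u, v, lab) for u, adj in enumerate(self.edges) for v, lab in adj]


@dataclass
class TerminalSets:
    """Admissible start (V_s) and end (V_t) node index sets."""

    V_s: Set[int]
    V_t: Set[int]


def build_spectrum_graph(
    interval: MassInterval,
    table: CompositionTable,
    alpha: float,
    epsilon: float,
    d: int,
    scores: Optional[FragmentScores] = None,
    graph_id: str = "g0",
) -> SpectrumGraph:
    """Build the gapped spectrum graph of one mass interval.

    ``alpha`` is the maximum explained gap (Da), ``epsilon`` the mass error
    tolerance (Da, discretized to ``round(epsilon * scale)`` integer units)
    and ``d`` the out-degree cap.  Node scores are taken from ``scores`` via
    the interval's source fragment indices (default: mass-count score 1).
    """
    if d <= 0:
        raise ValueError(f"out-degree cap d must be positive, got {d}")
    scale = table.alphabet.scale
    tol = discretize_mass(epsilon, scale)
    max_label = discretize_mass(alpha, scale) + tol
    if max_label > table.max_mass:
        raise ValueError(
            f"composition table covers masses up to {table.max_mass} but "
            f"edges may be labeled up to {max_label}; rebuild the table"
        )
    masses = np.asarray(interval.masses, dtype=float)
    int_masses = np.array([discretize_mass(m, scale) for m in masses], dtype=int)
    if scores is not None:
        node_scores = np.asarray(scores.scores, dtype=float)[interval.source_indices]
    else:
        node_scores = np.ones(masses.size)
    edges: List[List[Tuple[int, int]]] = []
    n = masses.size
    for u in range(n):
        adj: List[Tuple[int, int]] = []
        for v in range(u + 1, n):
            lab = int(int_masses[v] - int_masses[u])
            if lab <= 0:
                continue
            if lab > max_label:
                break
            if table.has_composition(lab):
                adj.append((v, lab))
        adj.sort(key=lambda e: (e[1], e[0]))
        edges.append(adj[:d])
    return SpectrumGraph(
        masses=masses,
        int_masses=int_masses,
        scores=node_scores,
        edges=edges,
        out_degree_cap=d,
        scale=scale,
        orientation=interval.orientation,
        graph_id=graph_id,
    )


def terminal_sets(graph: SpectrumGraph, beta: float) -> TerminalSets:
    """Nodes within ``beta`` Da of the graph's mass extremes.

    Edge labels telescope, so the total labeled mass of any path from the
    lightest node to ``v`` equals the node-mass difference; V_s and V_t are
    therefore computed directly from integer mass differences.
    """
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    if graph.n_nodes == 0:
        raise ValueError("graph has no nodes")
    bound = discretize_mass(beta, graph.scale)
    im = graph.int_masses
    V_s = {i for i in range(graph.n_nodes) if im[i] - im[0] <= bound}
    V_t = {i for i in range(graph.n_nodes) if im[-1] - im[i] <= bound}
    return TerminalSets(V_s=V_s, V_t=V_t)



def enumerate_blocked_patterns(
    graph: SpectrumGraph, s: int, t: int
) -> List[List[int]]:
    """All directed s -> t paths as their edge-label sequences.

    Deterministic DFS, smaller labels first.  ``s == t`` yields the single
    empty pattern.  Used as the brute-force counterpart of the suffix-tree
    search in tests.
    """
    if not (0 <= s < graph.n_nodes and 0 <= t < graph.n_nodes):
        raise ValueError("s and t must be node indices of the graph")
    out: List[List[int]] = []
    path: List[int] = []

    def dfs(u: int) -> None:
        if u == t:
            out.append(list(path))
            return
        for v, lab in graph.edges[u]:
            if v > t:
                continue
            path.append(lab)
            dfs(v)
            path.pop()

    dfs(s)
    return out
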