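"""Plain-text graph I/O and basic graph utilities.

Graphs are simple (no self-loops, no duplicate edges), optionally directed,
with opaque node labels. Undirected edges are stored in a single canonical
orientation (smaller label first) so that edge-set comparisons and file
output are deterministic.

The on-disk format is a whitespace-separated edge list: two node labels per
line, ``#`` starts a comment, extra columns are ignored. Node attribute
tables (heights, coordinates) are TSV with the node label in the first
column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

Node = str  # labels are opaque; any sortable hashable works in-memory
Edge = Tuple[Node, Node]


class GraphFormatError(ValueError):
    """Raised on a malformed edge-list line."""


def _canonical(u, v, directed: bool) -> Tuple:
    if directed:
        return (u, v)
    return (u, v) if u <= v else (v, u)


@dataclass
class Graph:
    """A simple graph: node set, canonical edge set, optional coordinates.

    Parameters
    ----------
    nodes : set of node labels.
    edges : set of (u, v) pairs; for undirected graphs stored with u <= v.
    directed : whether edges are ordered pairs.
    coords : optional map node -> real vector of spatial features.
    """

    nodes: Set[Node] = field(default_factory=set)
    edges: Set[Edge] = field(default_factory=set)
    directed: bool = False
    coords: Optional[Dict[Node, np.ndarray]] = None

    def __post_init__(self) -> None:
        canon = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside node set")
            canon.add(_canonical(u, v, self.directed))
        self.edges = canon

    # -- basic queries -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    def has_edge(self, u, v) -> bool:
        return _canonical(u, v, self.directed) in self.edges

    def degrees(self) -> Dict[Node, int]:
        """Degree of every node (total degree in the directed case)."""
        deg = {v: 0 for v in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def adjacency(self) -> Dict[Node, Set[Node]]:
        """Undirected adjacency (symmetrized for directed graphs)."""
        adj: Dict[Node, Set[Node]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def out_adjacency(self) -> Dict[Node, Set[Node]]:
        adj: Dict[Node, Set[Node]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
        return adj

    # -- conversions ---------------------------------------------------
    def to_networkx(self):
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g, coords=None) -> "Graph":
        return cls(
            nodes=set(g.nodes()),
            edges={(u, v) for u, v in g.edges() if u != v},
            directed=g.is_directed(),
            coords=coords,
        )

    @classmethod
    def from_edges(cls, edges: Iterable[Edge], directed: bool = False,
                   extra_nodes: Iterable[Node] = ()) -> "Graph":
        edges = list(edges)
        nodes = {u for e in edges for u in e} | set(extra_nodes)
        return cls(nodes=nodes, edges=set(edges), directed=directed)


def read_edge_list(path, directed: bool = False) -> Graph:
    """Read a whitespace-separated edge list.

    Duplicate lines are collapsed, self-loop lines dropped with a warning,
    columns beyond the first two ignored. Malformed lines raise
    :class:`GraphFormatError` naming the line number.
    """
    nodes: Set[Node] = set()
    edges: Set[Edge] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(tokens)}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                nodes.add(u)
                continue
            nodes.update((u, v))
            edges.add(_canonical(u, v, directed))
    return Graph(nodes=nodes, edges=edges, directed=directed)


def write_edge_list(graph: Graph, path) -> None:
    """Write one canonical edge per line in stable lexicographic order."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_heights(path) -> Dict[Node, float]:
    """Read a TSV ``node<TAB>height`` table; integral heights become ints."""
    heights: Dict[Node, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GraphFormatError(f"{path}:{lineno}: expected node and height")
            h = float(tokens[1])
            heights[tokens[0]] = int(h) if h.is_integer() else h
    return heights


def write_heights(heights: Mapping[Node, float], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for node in sorted(heights):
            fh.write(f"{node}\t{heights[node]}\n")


def read_coords(path) -> Dict[Node, np.ndarray]:
    """Read a TSV ``node<TAB>x1<TAB>x2...`` coordinate table."""
    coords: Dict[Node, np.ndarray] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GraphFormatError(f"{path}:{lineno}: expected node and coordinates")
            coords[tokens[0]] = np.asarray([float(t) for t in tokens[1:]])
    return coords


def filter_min_degree(graph: Graph, threshold: int, iterative: bool = False) -> Graph:
    """Drop nodes with degree <= threshold (single pass on input degrees).

    The pass uses degrees in the *input* graph: a node kept because its
    original degree exceeded the threshold stays even if all its neighbours
    were removed. ``iterative=True`` instead peels until stable (a k-core
    style filter); the single-pass rule is the default used for data
    preprocessing.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = graph
    while True:
        deg = g.degrees()
        keep = {v for v in g.nodes if deg[v] > threshold}
        out = Graph(
            nodes=keep,
            edges={(u, v) for u, v in g.edges if u in keep and v in keep},
            directed=g.directed,
            coords=None if g.coords is None else {v: g.coords[v] for v in keep if v in g.coords},
        )
        if not iterative or out.n == g.n:
            return out
        g = out


def giant_component(graph: Graph) -> Graph:
    """Induced subgraph on the largest connected component.

    Ties between equal-sized components are broken toward the component
    containing the smallest node label. Directed graphs use weakly
    connected components.
    """
    if graph.n == 0:
        raise ValueError("empty graph")
    g = graph.to_networkx()
    comps = (nx.weakly_connected_components(g) if graph.directed
             else nx.connected_components(g))
    # tie-break: size descending, then smallest minimum node label
    best = min(comps, key=lambda comp: (-len(comp), min(comp)))
    keep = set(best)
    return Graph(
        nodes=keep,
        edges={(u, v) for u, v in graph.edges if u in keep and v in keep},
        directed=graph.directed,
        coords=None if graph.coords is None else {v: graph.coords[v] for v in keep if v in graph.coords},
    )
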