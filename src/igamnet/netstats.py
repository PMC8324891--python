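"""Closed-form expectations and empirical statistics for IGAM networks.

The model admits simple exact moment formulas because every pair of nodes
at levels (r, s) shares the connection probability c^(-1 - min(r, s)).
The library returns the exact finite sums; the familiar asymptotic forms
(expected degree Theta(b^(H+1)/c^(h+1)), expected edges Theta(b^2H / c^H),
clustering O(c^-H)) follow from them and are exercised in the test suite
rather than exposed as values.

Empirical counterparts (per-level degree slope, triangle census under both
clustering conventions, giant-component diameter, cut conductance) operate
on arbitrary graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import networkx as nx
import numpy as np

from .graphio import Graph, giant_component
from .igam_core import (HeightAssignment, IGAM2Params, IGAMParams,
                        edge_prob_igam2, tree_level_sizes)


@dataclass
class TriangleCensus:
    """Triangle and wedge counts with both clustering conventions.

    ``gcc_ratio`` divides triangles by wedges directly (T_C / T_R);
    ``gcc_standard`` is the usual transitivity 3 * T_C / T_R. A wedge
    (path on 3 nodes) is counted once per centre node, so each triangle
    contributes 3 wedges.
    """

    triangles: int
    wedges: int

    @property
    def gcc_ratio(self) -> float:
        return self.triangles / self.wedges if self.wedges else 0.0

    @property
    def gcc_standard(self) -> float:
        return 3.0 * self.triangles / self.wedges if self.wedges else 0.0


# ----------------------------------------------------------------------
# closed forms
# ----------------------------------------------------------------------

def expected_degree(params: IGAMParams, h: int,
                    level_sizes: Optional[Sequence[int]] = None) -> float:
    """Expected degree of a node at level h: sum_r n_r * c^(-min(h,r)-1).

    The sum counts the node's own level with full multiplicity b^h (the
    sampler excludes the self-pair, an O(1) discrepancy kept for parity
    with the closed form). ``level_sizes`` overrides the perfect-tree
    sizes, e.g. for a partial last level.
    """
    if not 0 <= h <= params.H:
        raise ValueError(f"level h={h} outside [0, {params.H}]")
    sizes = level_sizes if level_sizes is not None else tree_level_sizes(params.b, H=params.H)
    return float(sum(n_r * params.c ** (-min(h, r) - 1.0)
                     for r, n_r in enumerate(sizes)))


def expected_edges(params: IGAMParams,
                   level_sizes: Optional[Sequence[int]] = None) -> float:
    """Exact expected edge count of the sampler (each unordered pair once)."""
    sizes = level_sizes if level_sizes is not None else tree_level_sizes(params.b, H=params.H)
    total = 0.0
    for r, nr in enumerate(sizes):
        total += nr * (nr - 1) / 2.0 * params.c ** (-1.0 - r)
        for s in range(r + 1, len(sizes)):
            total += nr * sizes[s] * params.c ** (-1.0 - r)
    return total


def expected_edges_igam2(params: IGAM2Params,
                         level_sizes: Optional[Sequence[int]] = None) -> float:
    """Exact expected edge count under the two-scale law g."""
    sizes = level_sizes if level_sizes is not None else tree_level_sizes(params.b, H=params.H)
    total = 0.0
    for r, nr in enumerate(sizes):
        total += nr * (nr - 1) / 2.0 * edge_prob_igam2(r, r, params)
        for s in range(r + 1, len(sizes)):
            total += nr * sizes[s] * edge_prob_igam2(r, s, params)
    return total


def expected_triangles(params: IGAMParams,
                       level_sizes: Optional[Sequence[int]] = None) -> float:
    """Exact expected triangle count: sum over node triples of f*f*f.

    Aggregated over level triples (r <= s <= t) with the correct number of
    node triples per block, so the cost is O(H^3) not O(n^3).
    """
    sizes = level_sizes if level_sizes is not None else tree_level_sizes(params.b, H=params.H)
    c = params.c
    total = 0.0
    L = len(sizes)
    for r in range(L):
        for s in range(r, L):
            for t in range(s, L):
                if r == s == t:
                    ntrip = math.comb(sizes[r], 3)
                elif r == s:
                    ntrip = math.comb(sizes[r], 2) * sizes[t]
                elif s == t:
                    ntrip = sizes[r] * math.comb(sizes[s], 2)
                else:
                    ntrip = sizes[r] * sizes[s] * sizes[t]
                # triangle prob for heights r <= s <= t: f(r,s) f(r,t) f(s,t)
                beta = c ** (-3.0 - 2.0 * r - s)
                total += ntrip * beta
    return total


# ----------------------------------------------------------------------
# empirical statistics
# ----------------------------------------------------------------------

def level_degree_slope(graph: Graph, heights: HeightAssignment) -> float:
    """OLS slope of log mean degree per level against the level index.

    Under the model this estimates -log(c) (degrees follow a Zipf law in
    the rank c^h). Levels with zero mean degree are excluded; at least two
    usable levels are required.
    """
    deg = graph.degrees()
    L = heights.H + 1
    counts = [0] * L
    totals = [0.0] * L
    for v, h in heights.heights.items():
        counts[int(h)] += 1
        totals[int(h)] += deg[v]
    xs, ys = [], []
    for h in range(L):
        if counts[h] and totals[h] > 0:
            xs.append(h)
            ys.append(math.log(totals[h] / counts[h]))
    if len(xs) < 2:
        raise ValueError("need at least 2 levels with positive mean degree")
    slope, _ = np.polyfit(np.asarray(xs, float), np.asarray(ys, float), 1)
    return float(slope)


def triangle_census(graph: Graph) -> TriangleCensus:
    """Exact triangle and wedge counts (undirected view of the graph)."""
    g = graph.to_networkx()
    if graph.directed:
        g = g.to_undirected()
    triangles = sum(nx.triangles(g).values()) // 3
    wedges = sum(d * (d - 1) // 2 for _, d in g.degree())
    return TriangleCensus(triangles=triangles, wedges=wedges)


def diameter_giant(graph: Graph) -> int:
    """BFS diameter of the giant connected component."""
    if graph.n == 0:
        raise ValueError("empty graph")
    gc = giant_component(graph)
    g = gc.to_networkx()
    if graph.directed:
        g = g.to_undirected()
    return int(nx.diameter(g)) if gc.n > 1 else 0


def cut_conductance(graph: Graph, s_set: Set) -> float:
    """Boundary edges of the cut divided by the smaller side's node count.

    This is the expansion-style conductance phi(S) = e(S, S-bar) /
    min(|S|, |S-bar|) used for the core-periphery cut, not the
    volume-normalized variant.
    """
    if not s_set or not s_set < graph.nodes:
        raise ValueError("S must be a nonempty proper subset of the nodes")
    boundary = sum(1 for u, v in graph.edges if (u in s_set) != (v in s_set))
    return boundary / min(len(s_set), graph.n - len(s_set))
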