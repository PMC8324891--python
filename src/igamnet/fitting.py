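"""Maximum-likelihood fitting of the IGAM edge law to an observed graph.

The search over tree topologies is avoided by the degree-ordering
heuristic: nodes are sorted by decreasing sample degree and poured into
the levels of a hypothetical b-ary tree (1 node at level 0, b at level 1,
b^2 at level 2, ..., last level possibly partial). For each candidate
fanout b the scale factor c is estimated by ordinary least squares of the
per-level log total degree z_h on the level index h — under the model the
total degree at level h scales like b^h * c^(-h) * const, so the slope a
estimates log(b/c) and c = b * exp(-a). Fits with c >= b or c <= 1 are
rejected. The candidate maximizing the Bernoulli log-likelihood

    l = sum_{(u,v) in E} log f(u,v) + sum_{(u,v) not in E} log(1 - f(u,v))

wins. The all-pairs term is aggregated over level pairs (all pairs at
levels (r, s) share one probability), so the exact likelihood costs
O(L^2 + m) per candidate rather than O(n^2). The "approx" mode keeps only
the O(m) odds term sum_E log(f/(1-f)); it drops a term that still depends
on (b, h, c), so model selection can differ between modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .graphio import Graph
from .igam_core import HeightAssignment, edge_prob_igam, tree_level_sizes

LikelihoodMode = Literal["exact", "approx"]


class FitRejected(ValueError):
    """A candidate fanout produced no admissible scale factor."""


@dataclass
class LevelDegreeProfile:
    """Per-level degree bookkeeping for one candidate fanout."""

    counts: List[int]                  # nodes per level
    total_degree: List[float]          # sum of sample degrees per level
    mean_degree: List[float]
    log_total: List[Optional[float]]   # z_h; None where the total is 0

    @classmethod
    def from_graph(cls, graph: Graph, heights: HeightAssignment) -> "LevelDegreeProfile":
        deg = graph.degrees()
        L = heights.H + 1
        counts = [0] * L
        total = [0.0] * L
        for v, h in heights.heights.items():
            counts[int(h)] += 1
            total[int(h)] += deg[v]
        mean = [t / c if c else 0.0 for t, c in zip(total, counts)]
        log_total = [math.log(t) if t > 0 else None for t in total]
        return cls(counts=counts, total_degree=total, mean_degree=mean, log_total=log_total)


@dataclass
class FitResult:
    b_star: int
    c_star: float
    heights: HeightAssignment
    slope: float
    intercept: float
    r_squared: float
    log_likelihood: float
    likelihood_mode: LikelihoodMode
    profile: LevelDegreeProfile = field(repr=False, default=None)


def degree_order(graph: Graph) -> List:
    """Nodes by decreasing sample degree, ties by ascending label."""
    deg = graph.degrees()
    return sorted(graph.nodes, key=lambda v: (-deg[v], v))


def assign_heights_by_rank(ordered_nodes: Sequence, b: int) -> HeightAssignment:
    """Pour ranked nodes into b-ary tree levels: 1, b, b^2, ... (last partial)."""
    if b < 2:
        raise ValueError("fanout b must be >= 2")
    if not ordered_nodes:
        raise ValueError("empty node list")
    sizes = tree_level_sizes(b, n=len(ordered_nodes))
    heights: Dict[object, float] = {}
    it = iter(ordered_nodes)
    for h, size in enumerate(sizes):
        for _ in range(size):
            heights[next(it)] = h
    return HeightAssignment(heights=heights, H=len(sizes) - 1, mode="integer")


def fit_scale_factor(profile: LevelDegreeProfile, b: int
                     ) -> Tuple[float, float, float, float]:
    """OLS of z_h on h over levels with positive total degree.

    Returns (c, slope, intercept, r_squared) with c = b * exp(-slope).
    Raises :class:`FitRejected` when fewer than 2 usable levels remain or
    the implied c falls outside (1, b).
    """
    xs = [h for h, z in enumerate(profile.log_total) if z is not None]
    ys = [profile.log_total[h] for h in xs]
    if len(xs) < 2:
        raise FitRejected(f"only {len(xs)} level(s) with positive degree")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    if np.std(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    c = b * math.exp(-slope)
    # boundary cases (slope numerically 0 or ln b) count as rejections
    if c >= b * (1.0 - 1e-12):
        raise FitRejected(f"c = {c:.4g} >= b = {b}")
    if c <= 1.0 + 1e-12:
        raise FitRejected(f"c = {c:.4g} <= 1")
    return float(c), float(slope), float(intercept), r2


def log_likelihood(graph: Graph, heights: HeightAssignment, c: float,
                   mode: LikelihoodMode = "exact") -> float:
    """Bernoulli log-likelihood of the graph under f with the given heights.

    exact: edge term + non-edge term, with the all-pairs part aggregated by
    level pair. approx: only sum_E log(f / (1 - f)).
    """
    if c <= 1:
        raise ValueError("scale factor c must exceed 1")
    if mode not in ("exact", "approx"):
        raise ValueError(f"unknown likelihood mode {mode!r}")
    missing = graph.nodes - set(heights.heights)
    if missing:
        raise ValueError(f"{len(missing)} node(s) lack a height")

    edge_term = 0.0
    for u, v in graph.edges:
        f = edge_prob_igam(heights[u], heights[v], c)
        edge_term += math.log(f) - math.log1p(-f)
    if mode == "approx":
        return edge_term

    # all-pairs sum of log(1 - f), grouped by level pair
    if heights.mode == "integer":
        sizes = heights.level_sizes()
        allpairs = 0.0
        for r, nr in enumerate(sizes):
            for s in range(r, len(sizes)):
                ns = sizes[s]
                npairs = nr * (nr - 1) // 2 if s == r else nr * ns
                if npairs:
                    allpairs += npairs * math.log1p(-(c ** (-1.0 - r)))
    else:
        hs = sorted(heights.heights.values())
        allpairs = 0.0
        for i, h in enumerate(hs[:-1]):
            allpairs += (len(hs) - 1 - i) * math.log1p(-(c ** (-1.0 - h)))
    return edge_term + allpairs


def fit_igam(graph: Graph, b_range: Optional[Sequence[int]] = None,
             mode: Literal["exact", "approx", "auto"] = "auto") -> FitResult:
    """Algorithm-1 fit: scan fanouts, regress c per fanout, keep the ML best.

    ``b_range`` defaults to 2..min(n-1, 64); pass an explicit range for the
    full 2..n-1 scan. ``mode="auto"`` uses the exact likelihood for graphs
    with at most 2000 nodes and the O(m) approximation above that.
    Deterministic: ties in likelihood keep the first (smallest) fanout.
    """
    if graph.n < 3 or graph.m < 1:
        raise ValueError("need at least 3 nodes and 1 edge to fit")
    if b_range is None:
        b_range = range(2, min(graph.n - 1, 64) + 1)
    if mode == "auto":
        mode = "exact" if graph.n <= 2000 else "approx"

    order = degree_order(graph)
    best: Optional[FitResult] = None
    for b in b_range:
        heights = assign_heights_by_rank(order, b)
        profile = LevelDegreeProfile.from_graph(graph, heights)
        try:
            c, slope, intercept, r2 = fit_scale_factor(profile, b)
        except FitRejected:
            continue
        ll = log_likelihood(graph, heights, c, mode=mode)
        if best is None or ll > best.log_likelihood:
            best = FitResult(b_star=b, c_star=c, heights=heights, slope=slope,
                             intercept=intercept, r_squared=r2,
                             log_likelihood=ll, likelihood_mode=mode,
                             profile=profile)
    if best is None:
        raise FitRejected("no admissible fit: every fanout was rejected")
    return best
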