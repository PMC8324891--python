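"""Dominating-set machinery: coverage curves, greedy maximum coverage,
prestige ordering, the almost-dominating-set (ADS) exponent, and the
model's closed-form domination probabilities.

A node is *dominated* by a set S if it belongs to S or is adjacent to a
member of S (closed-neighbourhood convention; an ``open_neighborhood``
switch is available where the stricter definition is wanted). A kappa-ADS
is a set dominating at least kappa * n nodes. The ADS exponent of a
ranking is p = log(k) / log(n) where k is the smallest prefix of the
ranking that dominates kappa * n nodes; p < 1 signals a sublinear core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .graphio import Graph
from .igam_core import HeightAssignment


@dataclass
class CoverageCurve:
    """An ordered core-candidate list with cumulative dominated fractions."""

    order: List
    covered_fraction: List[float]
    reached_target: bool = True

    def __post_init__(self):
        fracs = self.covered_fraction
        if any(b < a - 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise ValueError("covered_fraction must be nondecreasing")
        if fracs and fracs[-1] > 1 + 1e-12:
            raise ValueError("covered_fraction cannot exceed 1")

    def prefix_reaching(self, kappa: float) -> Optional[int]:
        """Smallest prefix length whose coverage is >= kappa, or None."""
        for k, frac in enumerate(self.covered_fraction, start=1):
            if frac >= kappa - 1e-12:
                return k
        return None


@dataclass
class CorePeripherySplit:
    """Level-threshold split: core = {v : h(v) <= tau}, periphery the rest."""

    tau: int
    core: Set
    periphery: Set

    @classmethod
    def from_heights(cls, heights: HeightAssignment, tau: int) -> "CorePeripherySplit":
        core = {v for v, h in heights.heights.items() if h <= tau}
        periphery = set(heights.heights) - core
        return cls(tau=tau, core=core, periphery=periphery)


def _dominated(adj: Dict, core: Set, open_neighborhood: bool) -> Set:
    covered = set()
    for v in core:
        covered.update(adj[v])
    if not open_neighborhood:
        covered.update(core)
    return covered


def coverage_fraction(graph: Graph, core: Set, open_neighborhood: bool = False) -> float:
    """Fraction of nodes in the core or adjacent to it."""
    if not core <= graph.nodes:
        raise ValueError("core must be a subset of the node set")
    if graph.n == 0:
        return 0.0
    adj = graph.adjacency()
    return len(_dominated(adj, core, open_neighborhood)) / graph.n


def coverage_curve_from_order(graph: Graph, order: Sequence,
                              open_neighborhood: bool = False) -> CoverageCurve:
    """Cumulative dominated fraction along a fixed node ordering."""
    adj = graph.adjacency()
    covered: Set = set()
    fracs: List[float] = []
    n = graph.n
    for v in order:
        if not open_neighborhood:
            covered.add(v)
        covered.update(adj[v])
        fracs.append(len(covered) / n)
    return CoverageCurve(order=list(order), covered_fraction=fracs)


def greedy_max_coverage(graph: Graph, kappa: Optional[float] = None,
                        max_size: Optional[int] = None,
                        open_neighborhood: bool = False) -> CoverageCurve:
    """Greedy (1 - 1/e)-maximum-coverage core construction.

    At each step the not-yet-dominated node whose closed neighbourhood
    dominates the most new nodes is added (the chosen node and everything
    it dominates are then removed from the residual network, so covered
    nodes never become candidates). Ties break toward the ascending node
    label. Stops when the kappa target is met, the size budget is spent,
    or nothing remains uncovered; an unmet target sets
    ``reached_target=False`` instead of raising.
    """
    if kappa is not None and not (0 < kappa <= 1):
        raise ValueError("kappa must lie in (0, 1]")
    adj = graph.adjacency()
    n = graph.n
    covered: Set = set()
    order: List = []
    fracs: List[float] = []
    while True:
        if kappa is not None and len(covered) >= kappa * n - 1e-12:
            break
        if max_size is not None and len(order) >= max_size:
            break
        uncovered = graph.nodes - covered
        if not uncovered:
            break
        candidates = uncovered if not open_neighborhood else (graph.nodes - set(order))
        if not candidates:
            break
        best_v, best_gain = None, -1
        for v in sorted(candidates):
            gain = sum(1 for w in adj[v] if w not in covered)
            if not open_neighborhood and v not in covered:
                gain += 1  # the candidate dominates itself
            if gain > best_gain:
                best_v, best_gain = v, gain
        order.append(best_v)
        if not open_neighborhood:
            covered.add(best_v)
        covered.update(adj[best_v])
        fracs.append(len(covered) / n)
    reached = kappa is None or (bool(fracs) and fracs[-1] >= kappa - 1e-12) or n == 0
    return CoverageCurve(order=order, covered_fraction=fracs, reached_target=reached)


def prestige_order_coverage(graph: Graph,
                            heights: Optional[HeightAssignment] = None,
                            open_neighborhood: bool = False) -> CoverageCurve:
    """Coverage curve of the prestige ordering.

    With fitted/known heights the order is ascending height; without, the
    equivalent descending initial degree. Ties break by ascending label
    (matching the fitting module's degree ordering).
    """
    if heights is not None:
        order = sorted(graph.nodes, key=lambda v: (heights[v], v))
    else:
        deg = graph.degrees()
        order = sorted(graph.nodes, key=lambda v: (-deg[v], v))
    return coverage_curve_from_order(graph, order, open_neighborhood)


def ads_exponent(curve: CoverageCurve, n: int, kappa: float = 0.8) -> float:
    """ADS exponent p = log(k)/log(n) for the smallest kappa-reaching prefix k."""
    if not (0 < kappa <= 1):
        raise ValueError("kappa must lie in (0, 1]")
    k = curve.prefix_reaching(kappa)
    if k is None:
        raise ValueError(f"target coverage {kappa} unreachable along this curve")
    if n < 2:
        return 0.0
    return math.log(k) / math.log(n)


def uncovered_probability(b: int, c: float, tau: int) -> float:
    """Probability that a node at height h > tau has no neighbour in levels 0..tau.

    Exact product prod_{r=0}^{tau} (1 - c^(-r-1))^(b^r); independent of the
    node's own height as long as it exceeds tau.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if not (1 < c < b):
        raise ValueError("require 1 < c < b")
    log_q = 0.0
    for r in range(tau + 1):
        log_q += (b ** r) * math.log1p(-(c ** (-r - 1.0)))
    return math.exp(log_q)


def theoretical_core_height(b: int, c: float, H: int) -> int:
    """Core height tau = ceil(log(2 c H log b) / log(b / c)), clamped to [0, H].

    At this depth the top levels dominate all but an o(n) remainder with
    high probability; natural logarithms throughout.
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    if not (1 < c < b):
        raise ValueError("require 1 < c < b")
    tau = math.ceil(math.log(2.0 * c * H * math.log(b)) / math.log(b / c))
    return max(0, min(H, tau))


def simulate_uncovered(b: int, c: float, tau: int, n_sims: int,
                       rng: np.random.Generator) -> float:
    """Monte-Carlo estimate of :func:`uncovered_probability`.

    Each simulation draws the Bernoulli links from one periphery node to
    every node in levels 0..tau and records whether none fired.
    """
    sizes = np.array([b ** r for r in range(tau + 1)])
    probs = np.array([c ** (-r - 1.0) for r in range(tau + 1)])
    # link count into level r is Binomial(size_r, p_r); undominated iff all zero
    counts = np.vstack([rng.binomial(sizes[r], probs[r], size=n_sims)
                        for r in range(tau + 1)])
    return int(np.sum(counts.sum(axis=0) == 0)) / n_sims


def compare_coverage(graph: Graph) -> Tuple[float, float]:
    """Slope gamma and R^2 of log prestige-coverage % on log greedy-coverage %.

    Both orderings are run to full coverage; prefixes are matched by size
    and restricted to strictly positive coverages. Mirrors the log-log
    comparison of greedy maximum coverage against the prestige rule.
    """
    greedy = greedy_max_coverage(graph)
    prestige = prestige_order_coverage(graph)
    k = min(len(greedy.covered_fraction), len(prestige.covered_fraction))
    x = np.array(greedy.covered_fraction[:k]) * 100.0
    y = np.array(prestige.covered_fraction[:k]) * 100.0
    mask = (x > 0) & (y > 0)
    x, y = np.log(x[mask]), np.log(y[mask])
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate coverage curves: no spread in coverage")
    slope, _ = np.polyfit(x, y, 1)
    if np.ptp(y) == 0:
        r2 = 1.0 if np.allclose(y, x) else 0.0
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return float(slope), r2


def brute_force_max_coverage(graph: Graph, k: int,
                             open_neighborhood: bool = False) -> Tuple[Set, int]:
    """Exhaustive best k-subset by dominated count (oracle for small graphs)."""
    adj = graph.adjacency()
    best_set: Set = set()
    best_cov = -1
    for combo in combinations(sorted(graph.nodes), k):
        cov = len(_dominated(adj, set(combo), open_neighborhood))
        if cov > best_cov:
            best_set, best_cov = set(combo), cov
    return best_set, best_cov
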