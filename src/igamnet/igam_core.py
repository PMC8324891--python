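"""Influencer-guided attachment (IGAM) edge laws and network samplers.

The IGAM family builds a network on the nodes of a hidden perfect b-ary
"skeleton" tree of height H. A node's level h(v) in the tree is its
*inverse prestige* (the root, level 0, is the most prestigious node). Every
unordered pair of distinct nodes is then linked independently with a
probability that decays geometrically in the level of the *more*
prestigious endpoint:

    f(u, v) = c^(-1 - min{h(u), h(v)}),    1 < c < b.

The skeleton tree contributes no edges of its own — it only defines the
height function. Variants implemented here:

* IGAM2: a two-scale law g with a denser core block (scale c1 for pairs
  entirely within levels 0..H0, scale c2 otherwise), 1 < c1 <= c2 < b.
* directed: ordered pairs, xi(u -> v) = c^(-1 - h(v)) (the head's height).
* continuous: heights drawn i.i.d. from the CDF (b^t - 1)/(b^H - 1) on
  [0, H]; the edge law f is unchanged.
* delta-IGAM: the min in f is replaced by the power mean M_delta of the two
  heights; M_delta -> min as delta -> -infinity.

Sampling is blocked by level pair: all pairs at levels (r, s) share one
probability, so a binomial count is drawn and that many pairs are chosen
uniformly without replacement. This is distributionally identical to (but
much faster than) flipping every pair, which is also available as
``method="naive"`` for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Literal, Optional, Tuple

import numpy as np

from .graphio import Graph


# ----------------------------------------------------------------------
# parameter containers
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class IGAMParams:
    """Model constants: integer fanout b >= 2, scale 1 < c < b, height H >= 0."""

    b: int
    c: float
    H: int

    def __post_init__(self):
        if self.b < 2:
            raise ValueError("fanout b must be >= 2")
        if not (1.0 < self.c < self.b):
            raise ValueError(f"scale factor c must lie in (1, b); got c={self.c}, b={self.b}")
        if self.H < 0:
            raise ValueError("height H must be >= 0")


@dataclass(frozen=True)
class IGAM2Params:
    """Two-scale variant: 1 < c1 <= c2 < b, core threshold 0 <= H0 <= H."""

    b: int
    c1: float
    c2: float
    H0: int
    H: int

    def __post_init__(self):
        if self.b < 2:
            raise ValueError("fanout b must be >= 2")
        if not (1.0 < self.c1 <= self.c2 < self.b):
            raise ValueError("require 1 < c1 <= c2 < b")
        if not (0 <= self.H0 <= self.H):
            raise ValueError("require 0 <= H0 <= H")


@dataclass
class HeightAssignment:
    """Node -> inverse-prestige level; integer levels 0..H or reals in [0, H]."""

    heights: Dict[object, float]
    H: int
    mode: Literal["integer", "real"] = "integer"

    def __post_init__(self):
        for v, h in self.heights.items():
            if h < 0 or h > self.H:
                raise ValueError(f"height {h} of node {v!r} outside [0, {self.H}]")
            if self.mode == "integer" and int(h) != h:
                raise ValueError(f"non-integer height {h} in integer mode")

    def __getitem__(self, node):
        return self.heights[node]

    def level_sizes(self) -> List[int]:
        """Node count per integer level 0..H (integer mode only)."""
        if self.mode != "integer":
            raise ValueError("level sizes defined for integer heights only")
        sizes = [0] * (self.H + 1)
        for h in self.heights.values():
            sizes[int(h)] += 1
        return sizes

    def nodes_at_level(self, h: int) -> List[object]:
        return sorted(v for v, hv in self.heights.items() if hv == h)


# ----------------------------------------------------------------------
# height construction
# ----------------------------------------------------------------------

def tree_level_sizes(b: int, H: Optional[int] = None, n: Optional[int] = None) -> List[int]:
    """Level sizes 1, b, b^2, ... of a b-ary tree, the last possibly partial.

    Exactly one of H (perfect tree) or n (total node count, smallest
    sufficient height) must be given.
    """
    if b < 2:
        raise ValueError("fanout b must be >= 2")
    if (H is None) == (n is None):
        raise ValueError("give exactly one of H, n")
    if H is not None:
        if H < 0:
            raise ValueError("H must be >= 0")
        return [b ** h for h in range(H + 1)]
    if n < 1:
        raise ValueError("n must be >= 1")
    sizes: List[int] = []
    remaining = n
    h = 0
    while remaining > 0:
        take = min(b ** h, remaining)
        sizes.append(take)
        remaining -= take
        h += 1
    return sizes


def tree_heights(b: int, H: Optional[int] = None, n: Optional[int] = None) -> HeightAssignment:
    """Height assignment of a (possibly truncated) perfect b-ary tree.

    Nodes are labelled 0..n-1 in breadth-first order, so level h occupies
    the contiguous index range [(b^h - 1)/(b - 1), ...).
    """
    sizes = tree_level_sizes(b, H=H, n=n)
    heights: Dict[object, float] = {}
    node = 0
    for h, size in enumerate(sizes):
        for _ in range(size):
            heights[node] = h
            node += 1
    return HeightAssignment(heights=heights, H=len(sizes) - 1, mode="integer")


# ----------------------------------------------------------------------
# edge-probability laws
# ----------------------------------------------------------------------

def edge_prob_igam(hu: float, hv: float, c: float) -> float:
    """f(u, v) = c^(-1 - min(h(u), h(v))); symmetric, in (0, 1)."""
    if c <= 1:
        raise ValueError("scale factor c must exceed 1")
    if hu < 0 or hv < 0:
        raise ValueError("heights must be nonnegative")
    return float(c ** (-1.0 - min(hu, hv)))


def edge_prob_igam2(hu: float, hv: float, params: IGAM2Params) -> float:
    """Two-scale law g: scale c1 inside the core block (max height <= H0), c2 otherwise."""
    if hu < 0 or hv < 0:
        raise ValueError("heights must be nonnegative")
    scale = params.c1 if max(hu, hv) <= params.H0 else params.c2
    return float(scale ** (-1.0 - min(hu, hv)))


def edge_prob_directed(hu: float, hv: float, c: float) -> Tuple[float, float]:
    """Directed law: (P[u -> v], P[v -> u]) with xi(x -> y) = c^(-1 - h(y)).

    The more probable direction points toward the smaller height, i.e.
    low-prestige nodes preferentially link *to* high-prestige nodes.
    """
    if c <= 1:
        raise ValueError("scale factor c must exceed 1")
    if hu < 0 or hv < 0:
        raise ValueError("heights must be nonnegative")
    return float(c ** (-1.0 - hv)), float(c ** (-1.0 - hu))


def generalized_mean(hu: float, hv: float, delta: float) -> float:
    """Power mean M_delta(hu, hv) = ((hu^d + hv^d)/2)^(1/d).

    delta = 0 is the geometric-mean limit; for delta < 0 a zero argument
    gives M = 0 (the limiting value).
    """
    if hu < 0 or hv < 0:
        raise ValueError("heights must be nonnegative")
    if delta == 0:
        return float(np.sqrt(hu * hv))
    if delta < 0 and (hu == 0 or hv == 0):
        return 0.0
    lo, hi = sorted((hu, hv))
    if lo == hi:
        return float(lo)
    # anchor on the extreme that dominates (hi for delta>0, lo for delta<0)
    # so that t = delta*log(other/anchor) <= 0, and evaluate
    # M = anchor * exp(log1p(expm1(t)/2)/delta) in expm1/log1p form, which
    # passes smoothly through the geometric mean as delta -> 0
    anchor, other = (hi, lo) if delta > 0 else (lo, hi)
    ratio = other / anchor  # may be 0 (underflow) or inf (overflow); both safe
    t = delta * math.log(ratio) if ratio > 0 else -math.inf
    if math.isinf(t):
        em = -1.0
    else:
        em = math.expm1(t)
    return float(anchor * math.exp(math.log1p(em / 2.0) / delta))


def edge_prob_delta(hu: float, hv: float, c: float, delta: float) -> float:
    """delta-IGAM law f_delta = c^(-1 - M_delta(hu, hv)); -> f as delta -> -inf."""
    if c <= 1:
        raise ValueError("scale factor c must exceed 1")
    return float(c ** (-1.0 - generalized_mean(hu, hv, delta)))


# ----------------------------------------------------------------------
# blocked pair sampling helpers
# ----------------------------------------------------------------------

def _unrank_within(t: np.ndarray, m: int) -> Tuple[np.ndarray, np.ndarray]:
    """Map linear indices t to pairs (i < j) over {0..m-1} in row-major order."""
    t = t.astype(np.int64)
    # cumulative pairs before first-index i: i*(2m - i - 1)/2
    i = np.floor(((2 * m - 1) - np.sqrt((2 * m - 1) ** 2 - 8.0 * t)) / 2.0).astype(np.int64)
    # guard against float rounding
    for _ in range(2):
        cum = i * (2 * m - i - 1) // 2
        i = np.where(cum > t, i - 1, i)
        cum = i * (2 * m - i - 1) // 2
        nxt = (i + 1) * (2 * m - i - 2) // 2
        i = np.where(t >= nxt, i + 1, i)
    cum = i * (2 * m - i - 1) // 2
    j = i + 1 + (t - cum)
    return i, j


def _sample_block_pairs(rng: np.random.Generator, n_r: int, n_s: int,
                        p: float, same_level: bool) -> Tuple[np.ndarray, np.ndarray]:
    """Binomial count of edges in one level block, then uniform distinct pairs."""
    total = n_r * (n_r - 1) // 2 if same_level else n_r * n_s
    if total == 0 or p <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    k = int(rng.binomial(total, p))
    if k == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    t = rng.choice(total, size=k, replace=False)
    if same_level:
        return _unrank_within(t, n_r)
    return t // n_s, t % n_s


def _level_offsets(sizes: Iterable[int]) -> List[int]:
    offsets = [0]
    for s in sizes:
        offsets.append(offsets[-1] + s)
    return offsets


def _sample_blockmodel(rng: np.random.Generator, sizes: List[int],
                       prob: "callable") -> set:
    """Sample edges of a level blockmodel with pair law prob(r, s)."""
    offsets = _level_offsets(sizes)
    edges = set()
    L = len(sizes)
    for r in range(L):
        for s in range(r, L):
            i, j = _sample_block_pairs(rng, sizes[r], sizes[s], prob(r, s), same_level=(r == s))
            u = i + offsets[r]
            v = j + offsets[s]
            edges.update(zip((np.minimum(u, v)).tolist(), (np.maximum(u, v)).tolist()))
    return edges


def _sample_naive(rng: np.random.Generator, heights: HeightAssignment,
                  pair_prob: "callable") -> set:
    """Flip every unordered pair independently (reference sampler)."""
    nodes = sorted(heights.heights)
    edges = set()
    for idx, u in enumerate(nodes):
        for v in nodes[idx + 1:]:
            if rng.random() < pair_prob(heights[u], heights[v]):
                edges.add((u, v))
    return edges


# ----------------------------------------------------------------------
# samplers
# ----------------------------------------------------------------------

def sample_igam(params: IGAMParams, n: Optional[int] = None, seed: int = 0,
                method: Literal["blocked", "naive"] = "blocked") -> Tuple[Graph, HeightAssignment]:
    """Sample an IGAM network.

    Without ``n`` the node count is the full tree size (b^(H+1) - 1)/(b - 1);
    with ``n`` the last level is partial. Tree edges are never added
    deterministically; a parent-child pair is an edge only if the
    independent Bernoulli draw under f says so.
    """
    rng = np.random.default_rng(seed)
    ha = tree_heights(params.b, H=params.H if n is None else None, n=n)
    sizes = ha.level_sizes()
    if method == "naive":
        edges = _sample_naive(rng, ha, lambda hu, hv: edge_prob_igam(hu, hv, params.c))
    else:
        edges = _sample_blockmodel(rng, sizes,
                                   lambda r, s: params.c ** (-1.0 - min(r, s)))
    graph = Graph(nodes=set(ha.heights), edges=edges, directed=False)
    return graph, ha


def sample_igam2(params: IGAM2Params, n: Optional[int] = None, seed: int = 0,
                 method: Literal["blocked", "naive"] = "blocked") -> Tuple[Graph, HeightAssignment]:
    """Sample an IGAM2 network (two-scale core-periphery law g)."""
    rng = np.random.default_rng(seed)
    ha = tree_heights(params.b, H=params.H if n is None else None, n=n)
    sizes = ha.level_sizes()
    if method == "naive":
        edges = _sample_naive(rng, ha, lambda hu, hv: edge_prob_igam2(hu, hv, params))
    else:
        edges = _sample_blockmodel(rng, sizes,
                                   lambda r, s: edge_prob_igam2(r, s, params))
    graph = Graph(nodes=set(ha.heights), edges=edges, directed=False)
    return graph, ha


def sample_directed(params: IGAMParams, n: Optional[int] = None,
                    seed: int = 0) -> Tuple[Graph, HeightAssignment]:
    """Sample the directed extension: each ordered pair (u, v), u != v,
    is an edge independently with probability xi(u -> v) = c^(-1 - h(v))."""
    rng = np.random.default_rng(seed)
    ha = tree_heights(params.b, H=params.H if n is None else None, n=n)
    sizes = ha.level_sizes()
    offsets = _level_offsets(sizes)
    edges = set()
    L = len(sizes)
    for s in range(L):  # head level: probability depends on s only
        p = params.c ** (-1.0 - s)
        for r in range(L):  # tail level
            n_r, n_s = sizes[r], sizes[s]
            if r != s:
                total = n_r * n_s
                k = int(rng.binomial(total, p)) if total else 0
                if k:
                    t = rng.choice(total, size=k, replace=False)
                    i, j = t // n_s, t % n_s
                    edges.update(zip((i + offsets[r]).tolist(), (j + offsets[s]).tolist()))
            else:
                total = n_s * (n_s - 1)
                k = int(rng.binomial(total, p)) if total else 0
                if k:
                    t = rng.choice(total, size=k, replace=False)
                    i = t // (n_s - 1)
                    j0 = t % (n_s - 1)
                    j = j0 + (j0 >= i)
                    edges.update(zip((i + offsets[s]).tolist(), (j + offsets[s]).tolist()))
    graph = Graph(nodes=set(ha.heights), edges=edges, directed=True)
    return graph, ha


def continuous_heights(b: int, H: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n i.i.d. heights with CDF (b^t - 1)/(b^H - 1) on [0, H].

    Inverse transform: h = log_b(1 + U * (b^H - 1)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.random(n)
    return np.log1p(u * (float(b) ** H - 1.0)) / np.log(b)


def sample_continuous(params: IGAMParams, n: int, seed: int = 0) -> Tuple[Graph, HeightAssignment]:
    """Continuous-height IGAM: real heights from the latent CDF, edge law f."""
    rng = np.random.default_rng(seed)
    h = continuous_heights(params.b, params.H, n, rng)
    order = np.argsort(h, kind="stable")  # ascending height
    edges = set()
    for pos, i in enumerate(order[:-1]):
        p = params.c ** (-1.0 - h[i])  # i is the more prestigious endpoint
        later = order[pos + 1:]
        hits = later[rng.random(later.size) < p]
        for j in hits:
            a, bb = (int(i), int(j)) if i < j else (int(j), int(i))
            edges.add((a, bb))
    ha = HeightAssignment(heights={int(i): float(h[i]) for i in range(n)},
                          H=params.H, mode="real")
    graph = Graph(nodes=set(range(n)), edges=edges, directed=False)
    return graph, ha


def sample_coupled_igam2(params: IGAM2Params, seed: int = 0
                         ) -> Tuple[Graph, Graph, Graph]:
    """Jointly sample (G', G, G'') with E(G') subset E(G) subset E(G'').

    G' ~ IGAM(b, c2, H), G ~ IGAM2(params), G'' ~ IGAM(b, c1, H). One
    uniform variate per pair thresholded at g' <= g <= g'' realizes the
    textbook nested coupling: conditional on a pair being absent from the
    sparser graph it enters the denser one with probability
    (g - g')/(1 - g'), so each marginal is exact while the edge sets are
    nested by construction.
    """
    rng = np.random.default_rng(seed)
    ha = tree_heights(params.b, H=params.H)
    sizes = ha.level_sizes()
    offsets = _level_offsets(sizes)
    e_lo, e_mid, e_hi = set(), set(), set()
    L = len(sizes)
    for r in range(L):
        for s in range(r, L):
            p_lo = params.c2 ** (-1.0 - r)                       # g'  (sparse)
            p_mid = edge_prob_igam2(r, s, params)                # g
            p_hi = params.c1 ** (-1.0 - r)                       # g'' (dense)
            assert p_lo <= p_mid <= p_hi
            if r == s:
                i, j = np.triu_indices(sizes[r], k=1)
            else:
                i, j = np.meshgrid(np.arange(sizes[r]), np.arange(sizes[s]), indexing="ij")
                i, j = i.ravel(), j.ravel()
            u = rng.random(i.size)
            gi = i + offsets[r]
            gj = j + offsets[s]
            lo = np.minimum(gi, gj)
            hi = np.maximum(gi, gj)
            e_lo.update(zip(lo[u < p_lo].tolist(), hi[u < p_lo].tolist()))
            e_mid.update(zip(lo[u < p_mid].tolist(), hi[u < p_mid].tolist()))
            e_hi.update(zip(lo[u < p_hi].tolist(), hi[u < p_hi].tolist()))
    nodes = set(ha.heights)
    return (Graph(nodes=nodes, edges=e_lo),
            Graph(nodes=nodes, edges=e_mid),
            Graph(nodes=nodes, edges=e_hi))
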