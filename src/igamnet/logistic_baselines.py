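"""Logistic core-periphery baselines for domination comparisons.

Three reference edge laws against which the IGAM domination curves are
compared:

* Logistic-CP: every node carries a real coreness score theta_v; an edge
  (u, v) appears with probability sigma(theta_u + theta_v) where sigma is
  the logistic link. Core nodes have theta >= 0, peripheral nodes
  theta < 0, so core-core pairs are the most likely edges.
* Logistic-JB: the spatial variant; given node coordinates and a pairwise
  kernel K (Euclidean distance by default) the argument of the link gains
  a -epsilon * K(u, v) penalty, epsilon >= 0.
* Logistic-TH: a ranking pi over nodes and the smooth step
  sigma_{s,t}(x) = 1/(1 + exp(-s (x - t))) applied to the pairwise max of
  the ranks normalized to [0, 1]; defaults s = 10, t = 1/2. The ranking
  itself is inferred by a nonlinear spectral fixed-point iteration whose
  per-node update aggregates a power mean of the current values over the
  neighbourhood.

Each law's formula lives in exactly one function so a transcription
correction is a one-line change. Score fitting maximizes the Bernoulli
likelihood with a small L2 ridge (scores are otherwise unbounded on
separable graphs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Set, Tuple

import numpy as np
from scipy.optimize import minimize

from .domination import CoverageCurve, coverage_curve_from_order
from .graphio import Graph


class ConvergenceError(RuntimeError):
    """Iteration budget exhausted; carries the best iterate found."""

    def __init__(self, message, best=None, residual=None):
        super().__init__(message)
        self.best = best
        self.residual = residual


@dataclass
class CorenessScores:
    """Fitted coreness scores theta (and kernel weight epsilon if spatial)."""

    theta: Dict[object, float]
    epsilon: float = 0.0
    kernel: Optional[Callable] = None
    log_likelihood: float = float("nan")


@dataclass
class RankingTH:
    """Ranking values pi (higher = more prestigious) with step parameters."""

    pi: Dict[object, float]
    s: float = 10.0
    t: float = 0.5

    def order(self) -> List:
        """Nodes by descending rank value, ties by ascending label."""
        return sorted(self.pi, key=lambda v: (-self.pi[v], v))


# ----------------------------------------------------------------------
# edge laws (one formula per function)
# ----------------------------------------------------------------------

def sigma_st(x: float, s: float = 10.0, t: float = 0.5) -> float:
    """Smooth Heaviside step sigma_{s,t}(x) = 1 / (1 + exp(-s (x - t)))."""
    return float(1.0 / (1.0 + np.exp(-s * (np.asarray(x, float) - t))))


def logistic_cp_prob(theta_u: float, theta_v: float) -> float:
    """Logistic-CP law: sigma(theta_u + theta_v)."""
    return float(1.0 / (1.0 + math.exp(-(theta_u + theta_v))))


def euclidean_kernel(x_u: np.ndarray, x_v: np.ndarray) -> float:
    """Default spatial kernel K(u, v) = ||x_u - x_v||_2."""
    return float(np.linalg.norm(np.asarray(x_u, float) - np.asarray(x_v, float)))


def logistic_jb_prob(theta_u: float, theta_v: float, x_u, x_v,
                     epsilon: float, kernel: Callable = euclidean_kernel) -> float:
    """Logistic-JB law: sigma(theta_u + theta_v - epsilon * K(u, v))."""
    if x_u is None or x_v is None:
        raise ValueError("spatial mode requires coordinates for both endpoints")
    return float(1.0 / (1.0 + math.exp(-(theta_u + theta_v - epsilon * kernel(x_u, x_v)))))


def logistic_th_prob(pi_u: float, pi_v: float, n: int,
                     s: float = 10.0, t: float = 0.5) -> float:
    """Logistic-TH law: sigma_{s,t} of the larger normalized rank.

    Ranks are normalized by n so the step argument lies in [0, 1]; the max
    mirrors the smoothed-maximum kernel of the ranking model.
    """
    return sigma_st(max(pi_u, pi_v) / n, s=s, t=t)


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _pairwise_nll(theta: np.ndarray, A: np.ndarray, KD: Optional[np.ndarray],
                  epsilon: float, ridge: float) -> Tuple[float, np.ndarray, float]:
    """Negative Bernoulli log-likelihood over unordered pairs, with gradient."""
    n = len(theta)
    S = theta[:, None] + theta[None, :]
    if KD is not None:
        S = S - epsilon * KD
    P = 1.0 / (1.0 + np.exp(-S))
    iu = np.triu_indices(n, k=1)
    a, p, sarg = A[iu], P[iu], S[iu]
    # log sigma(s) = -log(1 + e^{-s}); log(1 - sigma(s)) = -s - log(1 + e^{-s})
    log1pe = np.logaddexp(0.0, -sarg)
    ll = np.sum(a * (-log1pe) + (1 - a) * (-sarg - log1pe))
    nll = -ll + ridge * float(theta @ theta)
    R = P - A
    np.fill_diagonal(R, 0.0)
    grad_theta = R.sum(axis=1) + 2.0 * ridge * theta
    grad_eps = 0.0
    if KD is not None:
        grad_eps = -float(np.sum(R[iu] * KD[iu]))  # d(-ll)/d epsilon
    return float(nll), grad_theta, grad_eps


def fit_coreness(graph: Graph, spatial: bool = False,
                 kernel: Callable = euclidean_kernel, ridge: float = 1e-3,
                 max_iter: int = 500) -> CorenessScores:
    """Fit coreness scores by regularized maximum likelihood (L-BFGS-B).

    Deterministic: initialization at theta = 0 (and epsilon = 0 in spatial
    mode, constrained nonnegative). Raises :class:`ConvergenceError`
    carrying the best iterate if the optimizer's budget is exhausted
    without convergence.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v in graph.edges:
        A[index[u], index[v]] = A[index[v], index[u]] = 1.0
    KD = None
    if spatial:
        if graph.coords is None:
            raise ValueError("spatial mode requires node coordinates")
        X = np.vstack([np.asarray(graph.coords[v], float) for v in nodes])
        diff = X[:, None, :] - X[None, :, :]
        KD = np.linalg.norm(diff, axis=-1)

    def objective(z):
        theta = z[:n]
        eps = z[n] if spatial else 0.0
        nll, gt, ge = _pairwise_nll(theta, A, KD, eps, ridge)
        grad = np.concatenate([gt, [ge]]) if spatial else gt
        return nll, grad

    z0 = np.zeros(n + (1 if spatial else 0))
    bounds = [(None, None)] * n + ([(0.0, None)] if spatial else [])
    res = minimize(objective, z0, jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": max_iter})
    theta = {v: float(res.x[index[v]]) for v in nodes}
    scores = CorenessScores(theta=theta,
                            epsilon=float(res.x[n]) if spatial else 0.0,
                            kernel=kernel if spatial else None,
                            log_likelihood=-float(res.fun))
    if not res.success:
        raise ConvergenceError(f"coreness fit did not converge: {res.message}",
                               best=scores)
    return scores


def sample_logistic_cp(theta: Dict[object, float], seed: int = 0) -> Graph:
    """Sample a graph from the Logistic-CP law with planted scores."""
    rng = np.random.default_rng(seed)
    nodes = sorted(theta)
    n = len(nodes)
    th = np.array([theta[v] for v in nodes])
    P = 1.0 / (1.0 + np.exp(-(th[:, None] + th[None, :])))
    iu = np.triu_indices(n, k=1)
    hits = rng.random(len(iu[0])) < P[iu]
    edges = {(nodes[i], nodes[j]) for i, j in zip(iu[0][hits], iu[1][hits])}
    return Graph(nodes=set(nodes), edges=edges)


def th_ranking(graph: Graph, alpha: float = 10.0, tol: float = 1e-10,
               max_iter: int = 2000, s: float = 10.0, t: float = 0.5) -> RankingTH:
    """Nonlinear spectral ranking: fixed point of a power-mean update.

    Each step replaces x_u by the sum over neighbours v of the alpha-power
    mean ((x_u^alpha + x_v^alpha)/2)^(1/alpha) and renormalizes; large
    alpha approximates aggregation by the pairwise max. O(m) per step.
    """
    if graph.n == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    src = np.array([index[u] for u, v in graph.edges] +
                   [index[v] for u, v in graph.edges], dtype=np.int64)
    dst = np.array([index[v] for u, v in graph.edges] +
                   [index[u] for u, v in graph.edges], dtype=np.int64)
    x = np.full(n, 1.0 / math.sqrt(n))
    residual = float("inf")
    for _ in range(max_iter):
        xa = x ** alpha
        contrib = ((xa[src] + xa[dst]) / 2.0) ** (1.0 / alpha)
        new = np.zeros(n)
        np.add.at(new, src, contrib)
        norm = np.linalg.norm(new)
        if norm == 0:  # edgeless graph: uniform ranking is the fixed point
            new = np.full(n, 1.0 / math.sqrt(n))
            norm = 1.0
            new_x = new
        else:
            new_x = new / norm
        residual = float(np.linalg.norm(new_x - x))
        x = new_x
        if residual < tol:
            return RankingTH(pi={v: float(x[index[v]]) for v in nodes}, s=s, t=t)
    raise ConvergenceError(f"ranking iteration did not converge (residual {residual:.3g})",
                           best=RankingTH(pi={v: float(x[index[v]]) for v in nodes}, s=s, t=t),
                           residual=residual)


def domination_from_scores(graph: Graph, scores) -> CoverageCurve:
    """Coverage curve of the ranking induced by a fitted model.

    Accepts a :class:`CorenessScores`, a :class:`RankingTH`, or a plain
    node -> value mapping; nodes are added in decreasing score order,
    ties by ascending label.
    """
    if isinstance(scores, CorenessScores):
        values = scores.theta
    elif isinstance(scores, RankingTH):
        values = scores.pi
    else:
        values = scores
    missing = graph.nodes - set(values)
    if missing:
        raise ValueError(f"{len(missing)} node(s) lack a score")
    order = sorted(graph.nodes, key=lambda v: (-values[v], v))
    return coverage_curve_from_order(graph, order)
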