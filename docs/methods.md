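# Methods

## The generative model

A network on n nodes is generated from a hidden perfect b-ary tree of
height H (node count (b^(H+1)−1)/(b−1); a partial last level when n is
given explicitly). A node's level h(v) ∈ {0, …, H} is its inverse
prestige. Each unordered pair of distinct nodes becomes an edge
independently with probability f(u, v) = c^(−1−min{h(u), h(v)}),
1 < c < b. Two modelling choices deserve emphasis:

* **Tree edges are never added deterministically.** The tree exists only
  to define heights. A parent–child pair that happens to be linked by the
  Bernoulli draw is kept: censoring it would break the pairwise
  independence on which every closed form below relies, and the model's
  asymptotic properties are unaffected either way.
* **The law depends only on the more prestigious endpoint.** This is what
  makes the top levels dominate: a node at any height below τ escapes all
  of levels 0..τ with probability q = ∏_{r=0}^{τ} (1−c^(−r−1))^(b^r),
  independent of its own height.

Variants: IGAM2 replaces the single scale by (c₁, c₂) with
1 < c₁ ≤ c₂ < b — pairs lying entirely within levels 0..H₀ use the denser
scale c₁, all others c₂, giving the block ordering core–core >
core–periphery > periphery–periphery. The directed extension draws each
ordered pair (u, v) with probability c^(−1−h(v)) (the head's height), so
edges preferentially point *toward* prestige. The continuous variant draws
heights i.i.d. from the CDF (b^t−1)/(b^H−1) on [0, H] (inverse transform
h = log_b(1 + U(b^H−1))) and keeps the same f. The δ-law replaces the min
with the power mean M_δ = ((h_u^δ + h_v^δ)/2)^(1/δ), recovering the min as
δ → −∞ and the geometric mean at δ = 0; it is evaluated in
expm1/log1p form so the interpolation through δ = 0 is numerically smooth.

## Sampling

All level-structured samplers are blocked: every pair at levels (r, s)
shares one probability, so the edge count of a block is drawn
Binomial(#pairs, p) and that many pairs are chosen uniformly without
replacement (index unranking, no pair enumeration). This is
distributionally identical to flipping each pair — the package keeps a
naive per-pair sampler and the test suite checks the two edge-count
distributions against each other by a χ² test — and makes n ≈ 3⁸ networks
cheap. One `numpy` Generator seeded by the caller drives everything;
identical (params, seed) give identical graphs.

The coupled sampler draws one uniform variate per pair and thresholds it
at g′ ≤ g ≤ g″ (the IGAM(b, c₂, H), IGAM2, IGAM(b, c₁, H) laws). This
realizes the nested conditional coupling — conditional on absence from the
sparser graph, presence in the denser one has probability
(g−g′)/(1−g′) — so the three marginals are exact while the edge sets are
nested by construction.

## Fitting

The fanout/height search is heuristic by design: nodes are sorted by
decreasing sample degree (ties by ascending label, for determinism) and
poured into the levels of a hypothetical b-ary tree. For each candidate b,
the per-level log total degree z_h is regressed on h; under the model
z_h ≈ const + h·ln(b/c), so ĉ = b·e^(−slope). Candidates with ĉ ≥ b or
ĉ ≤ 1 are rejected (boundary cases count as rejections, with a 1e−12
relative guard against float rounding at slope 0). The winner maximizes
the Bernoulli log-likelihood.

Two likelihood modes are exposed:

* **exact** — edge sum of log f plus non-edge sum of log(1−f). The
  all-pairs term is aggregated over level pairs, so a candidate costs
  O(L² + m), not O(n²). Default for graphs up to 2000 nodes.
* **approx** — the O(m) odds form Σ_E log(f/(1−f)) alone. The dropped
  all-pairs term *does* depend on (b, h, c), so model selection can differ
  between modes.

In practice the modes differ materially for model selection: the
regression estimate of c carries a finite-size bias (the z_h curve
steepens near h = H because per-node degree flattens there), and the exact
likelihood's large non-edge term amplifies that bias into a preference for
smaller fanouts. The odds-form likelihood is robust to it: on networks
sampled at (b=3, c=2, H=6) it recovers b\*=3 in 10/10 seeds with
|c\*−2| ≤ 0.18. Parameter-recovery checks therefore run in approx mode;
both modes satisfy the exact-vs-odds identity test.

For the same reason, claims about the degree power law are asymptotic:
d log d̄_h/dh → −ln c holds in the low levels (the Zipf regime), while an
all-level OLS slope converges to a closed-form value that is steeper at
finite H (0.493 vs ln(b/c) = 0.405 at b=3, c=2, H=6). Tests that compare a
sampled slope to ±ln c restrict to levels 0..H−3; tests of the all-level
slope compare against the exact finite-H expectation.

## Domination

A node is dominated by S if it is in S or adjacent to S (closed
neighbourhoods; an open-neighbourhood switch exists for the stricter
definition). The greedy maximum-coverage core follows residual semantics:
the chosen node and everything it dominates are removed from the network,
so candidates are always not-yet-dominated nodes. On the path a–b–c–d this
yields the order [b, d] rather than the textbook unrestricted greedy's
[b, c]; coverage values agree, and on small instances (the brute-force
sweep n ≤ 12, k ≤ 3) the residual variant still attains the (1−1/e)
guarantee. Ties break toward the ascending node label everywhere.

The ADS exponent of a ranking is p = log(k)/log(n) for the smallest prefix
k dominating κ·n nodes (κ defaults to 0.8); p < 1 certifies a sublinear
core. The theoretical core height τ is rounded up and clamped to [0, H].
The prestige-vs-greedy comparison regresses log coverage % on log
coverage % at matched prefix sizes, reporting the slope γ and R².

## Logistic baselines

Three reference rankings for domination-curve comparisons:

* **Coreness scores**: edge law σ(θ_u + θ_v); fitted by L-BFGS-B on the
  pairwise Bernoulli likelihood with L2 ridge 10⁻³ (needed on separable
  graphs), deterministic initialization at 0. The spatial variant
  subtracts ε·K(u, v) (Euclidean kernel by default, ε ≥ 0 constrained in
  the optimizer).
* **Spectral ranking**: fixed-point iteration x ← normalize(Σ_{v∼u}
  M_α(x_u, x_v)) with power-mean exponent α = 10 (a smooth proxy for
  pairwise max), tolerance 10⁻¹⁰. Its edge law applies the smooth step
  σ_{s,t}(x) = 1/(1+e^(−s(x−t))), s = 10, t = 1/2, to the larger of the
  two ranks normalized to [0, 1]. The max-of-ranks argument is this
  package's reading of the ranking model's smoothed-maximum construction;
  each law lives in a single function so an alternative (mean of ranks,
  different normalization) is a one-line change.

Each fitted model yields a node ordering by decreasing score and hence a
coverage curve comparable to the prestige and greedy curves.

## Statistics

All library-facing expectations are exact finite sums over level blocks
(degrees, edges, triangles), not the Θ-level asymptotic forms; the
expected-degree sum counts a node's own level with full multiplicity b^h,
an O(1) overcount relative to the sampler (which never draws self-pairs)
kept for parity with the closed form. The triangle census returns both
clustering conventions: triangles/wedges, and the standard transitivity
3·triangles/wedges. Conductance is the expansion-style
e(S, S̄)/min(|S|, |S̄|) with a node-count denominator, not volume
conductance. Diameter is exact BFS on the giant component (ties between
equal-sized components break toward the smallest member label).

## Synthetic data and what the tests show

Every test input is generated by the package's own samplers; no external
network data is used. The generated graphs match the model exactly —
independent pairwise edges, geometric prestige decay — which real networks
only approximate: real degree sequences are noisier, clustering is higher
than the pairwise-independent law predicts, and real cores need not align
with any tree. Passing tests therefore certify the implementation
(samplers match their laws, closed forms match brute-force enumeration,
the fitter recovers planted parameters, the domination machinery matches
hand-simulated and exhaustive oracles), not the model's adequacy for any
particular empirical network. Real edge lists can be analysed through the
same interfaces (`read_edge_list`, degree-threshold preprocessing with the
single-pass ≤ 4 filter, `fit_igam`, the domination curves), and the
preprocessing filter deliberately uses input-graph degrees in a single
pass rather than iterative core-peeling.

## Problem sizes

Defaults were chosen so the statistical checks are decisive at
interactive cost: moment checks use 600–2000 replicates of 4–40-node
networks; recovery uses 10 seeds of the 1093-node (H=6) configuration;
domination uses 20 seeds of the 3280-node (H=7) configuration; the greedy
oracle sweep uses 200 random instances with n ≤ 12 where exhaustive
search is exact. The acceptance script runs the full battery in well
under a minute on one CPU.

## Known limitations

* The height search never leaves the degree-ordered filling rule; tree
  topologies that disagree with the degree order are out of reach (by
  design — the exhaustive search is exponential).
* The approximate likelihood is not a consistent model-selection criterion
  in general (it drops a parameter-dependent term); it is the pragmatic
  default for recovery because of the finite-size bias discussed above.
* The logistic baseline equations are interface-stable but intentionally
  isolated: they follow the common logistic-link/smooth-step forms, and a
  different published parameterization can be swapped in per function.
* Continuous-height sampling is O(n²); it is intended for moderate n.
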