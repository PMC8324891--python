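# igamnet

Generative core–periphery random networks whose core is a **sublinear
dominating set**, with maximum-likelihood fitting, dominating-set
construction, closed-form network statistics, and logistic core–periphery
baselines.

## The model

Many real networks — trade networks, faculty-hiring networks, airline
routes, political blogs — split into a small, densely connected *core*
and a sparse *periphery* that attaches mainly to the core. The
influencer-guided attachment model (IGAM) generates such networks from a
hidden perfect *b*-ary "prestige tree" of height *H*: every node sits at
a level *h(v)* (the root, level 0, is the most prestigious), and each
pair of distinct nodes is linked independently with probability

```
f(u, v) = c^(-1 - min{h(u), h(v)}),        1 < c < b,
```

so the *more prestigious* endpoint sets the odds. The tree itself
contributes no edges — it only defines the height function. Instances
have Zipfian power-law degrees (expected degree ∝ 1/c^h), O(1) diameter,
and — the model's defining feature — the top τ = ⌈log(2cH·log b)/log(b/c)⌉
levels form a dominating set of size o(n): a vanishing fraction of nodes
covers the whole network.

The package implements:

* **Samplers** for the base model and its variants: a two-scale
  core–periphery law (IGAM2, with a denser core block governed by a second
  scale c₁), a directed extension (edge u→v with probability
  c^(−1−h(v))), continuous latent heights with CDF (b^t−1)/(b^H−1), a
  generalized-mean edge law (δ-IGAM), and a nested coupling that samples
  an IGAM2 network jointly with its two bounding IGAM networks.
* **Fitting**: order nodes by degree, pour them into candidate b-ary tree
  levels, estimate c from the per-level log-degree regression
  (c = b·e^(−slope)), and keep the fanout b\* maximizing the Bernoulli
  likelihood (exact O(n²)-per-candidate form, or the O(m) odds-form
  approximation).
* **Domination**: coverage curves, the greedy (1−1/e) maximum-coverage
  core, prestige-ordered cores, the κ-almost-dominating-set exponent
  p = log(core size)/log(n), and exact non-domination probabilities.
* **Statistics**: exact expected degrees/edges/triangles, clustering under
  both wedge conventions, giant-component diameter, cut conductance.
* **Baselines**: logistic coreness-score models (with an optional spatial
  kernel) and a nonlinear spectral ranking, each exposing a domination
  curve for comparison.

## Worked example

```python
from igamnet import IGAMParams, sample_igam, fit_igam

graph, heights = sample_igam(IGAMParams(b=3, c=2.0, H=6), seed=7)
result = fit_igam(graph, b_range=range(2, 7), mode="approx")
print(result.b_star, round(result.c_star, 3))
```

Running `python examples/02_fit_recovery.py` prints:

```
sampled IGAM(b=3, c=2, H=6): n=1093, m=12444
fitted fanout b* = 3 (true 3)
fitted scale  c* = 1.823 (true 2.0)
level regression: slope=0.498 (estimates ln(b/c) = 0.405), R^2=0.990
log-likelihood (approx): -35020.5
per-level node counts: [1, 3, 9, 27, 81, 243, 729]
```

The fit recovers the true fanout exactly and the scale factor to within
about 0.2 (the regression slope carries a small finite-size bias toward
steeper decay). `examples/03_dominating_core.py` shows the headline
phenomenon — at (b=3, c=1.5, H=7), n=3280, the 364 top-prestige nodes
(11% of the network) dominate 100% of it, and the 0.8-almost-dominating
set has exponent p ≈ 0.09 — while `examples/04_logistic_baselines.py`
shows the fitted prestige hierarchy matching the logistic coreness
baseline (0.8-ADS prefix 13 of n=1093) and clearly beating the spectral
ranking (prefix 96).

## Command line

A thin `igam` CLI wraps the library:

```bash
igam sample --b 3 --c 2.0 --H 5 --seed 1 --out edges.tsv --heights-out heights.tsv
igam fit edges.tsv --b-min 2 --b-max 6 --out fit.json
igam dominate edges.tsv --kappa 0.8 --out curve.tsv
igam stats edges.tsv --heights heights.tsv
igam compare edges.tsv --models igam,logistic-cp,logistic-th
igam fixture toy-likelihood --outdir fixtures/
```

Edge lists are plain whitespace-separated text (`#` comments); heights and
coordinates are TSV keyed by node label.

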