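"""Fit the edge law to a network sampled from known parameters.

The fitting algorithm orders nodes by degree, pours them into candidate
b-ary tree levels, estimates the scale factor c from the per-level
log-degree regression (c = b * exp(-slope)), and keeps the fanout with the
best likelihood. On a network sampled at (b=3, c=2) the fit should return
b*=3 and c* close to 2.
"""

from igamnet import IGAMParams, fit_igam, sample_igam

true = IGAMParams(b=3, c=2.0, H=6)
graph, _ = sample_igam(true, seed=7)
print(f"sampled IGAM(b=3, c=2, H=6): n={graph.n}, m={graph.m}")

result = fit_igam(graph, b_range=range(2, 7), mode="approx")
print(f"fitted fanout b* = {result.b_star} (true 3)")
print(f"fitted scale  c* = {result.c_star:.3f} (true 2.0)")
print(f"level regression: slope={result.slope:.3f} "
      f"(estimates ln(b/c) = 0.405), R^2={result.r_squared:.3f}")
print(f"log-likelihood ({result.likelihood_mode}): {result.log_likelihood:.1f}")
print("per-level node counts:", result.profile.counts)
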