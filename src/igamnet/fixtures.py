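"""Seeded fixture generator: small worked examples written to disk.

Every fixture is a directory of plain-text files (edge list, heights,
JSON manifest of expected values) generated deterministically from a
seed, so the whole test surface needs no downloads.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

from . import graphio, igam_core, netstats
from .graphio import Graph

FIXTURE_KINDS = ("igam", "igam2", "toy-likelihood", "coverage-toys")


def make_fixture(kind: str, seed: int, outdir) -> Dict[str, object]:
    """Write the named fixture under ``outdir``; returns its manifest.

    Kinds:

    * ``igam``: a sampled IGAM(b=3, c=2, H=5) network with heights and the
      exact expected edge count in the manifest.
    * ``igam2``: a sampled IGAM2(b=3, c1=1.5, c2=2.5, H0=2, H=5) network.
    * ``toy-likelihood``: the 4-node hand-computable likelihood example
      (heights [0, 1, 1, 1], c=2, one root-child edge).
    * ``coverage-toys``: the path P4 and the star K_{1,9} with their greedy
      coverage answers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "igam":
        params = igam_core.IGAMParams(b=3, c=2.0, H=5)
        graph, ha = igam_core.sample_igam(params, seed=seed)
        graphio.write_edge_list(graph, outdir / "edges.tsv")
        graphio.write_heights(ha.heights, outdir / "heights.tsv")
        manifest = {
            "kind": kind, "seed": seed,
            "params": {"b": 3, "c": 2.0, "H": 5},
            "n": graph.n, "m": graph.m,
            "expected_edges": netstats.expected_edges(params),
        }
    elif kind == "igam2":
        params = igam_core.IGAM2Params(b=3, c1=1.5, c2=2.5, H0=2, H=5)
        graph, ha = igam_core.sample_igam2(params, seed=seed)
        graphio.write_edge_list(graph, outdir / "edges.tsv")
        graphio.write_heights(ha.heights, outdir / "heights.tsv")
        manifest = {
            "kind": kind, "seed": seed,
            "params": {"b": 3, "c1": 1.5, "c2": 2.5, "H0": 2, "H": 5},
            "n": graph.n, "m": graph.m,
            "expected_edges": netstats.expected_edges_igam2(params),
        }
    elif kind == "toy-likelihood":
        graph = Graph.from_edges([("a", "b")], extra_nodes=["c", "d"])
        heights = {"a": 0, "b": 1, "c": 1, "d": 1}
        graphio.write_edge_list(graph, outdir / "edges.tsv")
        graphio.write_heights(heights, outdir / "heights.tsv")
        import math
        manifest = {
            "kind": kind, "seed": seed, "c": 2.0,
            "heights": heights,
            # 3 root-child pairs at f=1/2 (one present), 3 child-child at f=1/4
            "exact_log_likelihood": 3 * math.log(0.5) + 3 * math.log(0.75),
            "approx_log_likelihood": 0.0,
        }
    elif kind == "coverage-toys":
        p4 = Graph.from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        star = Graph.from_edges([("hub", f"leaf{i}") for i in range(9)])
        graphio.write_edge_list(p4, outdir / "p4.tsv")
        graphio.write_edge_list(star, outdir / "star.tsv")
        manifest = {
            "kind": kind, "seed": seed,
            "p4_greedy_order": ["b", "d"],
            "p4_greedy_curve": [0.75, 1.0],
            "star_greedy_order": ["hub"],
            "star_greedy_curve": [1.0],
        }
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
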