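"""Deterministic test fixtures: enumerable genotype spaces and handcrafted
networks.

The enumerable space at small N and K (for example N=3, K=2: C(9,2) * 2^2 =
144 genotypes) is small enough for exhaustive evaluation and serves as the
brute-force oracle for the Monte Carlo machinery: exact per-bin appearance
probabilities, exact transition kernels, and so on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterator

import numpy as np

from grnevo.model import ModelParams, RegulatoryNetwork, random_network

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "enumerate_genotype_space",
    "space_cardinality",
    "handcrafted_chain",
    "handcrafted_bistable",
]

# exhaustive enumeration guardrail
MAX_ENUMERABLE = 100_000


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: kind, size parameters, and a seed where stochastic."""

    kind: str  # random_networks | enumerable_space | handcrafted_bistable | handcrafted_chain
    n_nodes: int = 3
    n_edges: int = 2
    count: int = 1
    seed: int = 0


def space_cardinality(params: ModelParams) -> int:
    """Exact number of genotypes, C(N^2, K) * 2^K."""
    return math.comb(params.n_nodes**2, params.n_edges) * 2**params.n_edges


def enumerate_genotype_space(
    params: ModelParams,
) -> Iterator[RegulatoryNetwork]:
    """Yield every genotype of the space exactly once.

    Topologies are all K-subsets of the N^2 ordered pairs; each topology is
    combined with every assignment of +-1 signs.  Guarded to spaces of at
    most 100,000 genotypes.
    """
    total = space_cardinality(params)
    if total > MAX_ENUMERABLE:
        raise ValueError(
            f"genotype space has {total} members, above the enumeration "
            f"guardrail of {MAX_ENUMERABLE}"
        )
    n, k = params.n_nodes, params.n_edges
    for codes in combinations(range(n * n), k):
        codes_arr = np.array(codes)
        src, dst = codes_arr // n, codes_arr % n
        for signs in product((-1, 1), repeat=k):
            yield RegulatoryNetwork(params, src, dst, np.array(signs))


def handcrafted_chain(n_nodes: int = 3, **kwargs) -> RegulatoryNetwork:
    """The activating chain 0 -> 1 -> ... -> output.

    Deleting any chain edge disconnects the input from the output, so every
    edge is essential and the deletion robustness r is exactly 0.
    """
    params = ModelParams(n_nodes=n_nodes, n_edges=n_nodes - 1, **kwargs)
    src = np.arange(n_nodes - 1)
    dst = np.arange(1, n_nodes)
    return RegulatoryNetwork(params, src, dst, np.ones(n_nodes - 1, dtype=int))


def handcrafted_bistable() -> RegulatoryNetwork:
    """A minimal genuinely bistable genotype (strict hysteresis criterion).

    Built at the steep response beta=6, mu=0.5 at which an auto-activating
    gene has two stable fixed points while its external drive c stays inside
    a narrow window (|c| < ~0.069 around the threshold).  Gene 1 is the
    auto-activating core; its drive c = x0 + x4 - x3 combines the input gene
    0, a relay gene 4 (amplifying the input swing), and repression by gene 3,
    an auto-activating gene kicked ON by the input so it sits near 1.  c then
    runs from about -0.84 at I = 0 to about +0.89 at I = 1, crossing both
    saddle-node bifurcations of the core inside the swept range: the up sweep
    jumps onto the high branch where the low fixed point disappears, the down
    sweep falls off the high branch at a smaller I, and the output gene 2
    (fed by the core) shows a wide hysteresis loop -- a toggle switch.
    """
    params = ModelParams(n_nodes=5, n_edges=8, beta=6.0, mu=0.5, output_index=2)
    src = np.array([0, 4, 0, 3, 3, 0, 1, 1])
    dst = np.array([1, 1, 4, 1, 3, 3, 1, 2])
    sgn = np.array([1, 1, 1, -1, 1, 1, 1, 1])
    return RegulatoryNetwork(params, src, dst, sgn)


def generate_fixture(
    spec: FixtureSpec,
) -> list[RegulatoryNetwork]:
    """Materialize a fixture; deterministic for a fixed spec."""
    if spec.kind == "random_networks":
        rng = np.random.default_rng(spec.seed)
        params = ModelParams(n_nodes=spec.n_nodes, n_edges=spec.n_edges)
        return [random_network(params, rng) for _ in range(spec.count)]
    if spec.kind == "enumerable_space":
        params = ModelParams(n_nodes=spec.n_nodes, n_edges=spec.n_edges)
        return list(enumerate_genotype_space(params))
    if spec.kind == "handcrafted_chain":
        return [handcrafted_chain(spec.n_nodes)]
    if spec.kind == "handcrafted_bistable":
        return [handcrafted_bistable()]
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
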