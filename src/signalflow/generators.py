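"""Synthetic signed digraphs: didactic toy motifs and random network models.

The three toy fixtures are the canonical teaching cases for walk-series
influence: a 3-node activating cascade, a pair of cascades with crosstalk
converging on one readout, and a 3-node negative feedback loop whose
influence is a convergent alternating geometric series.  Random generators
(Erdos-Renyi and Barabasi-Albert) provide arbitrarily sized test networks
with a configurable fraction of inhibitory links.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import SignedDirectedNetwork

__all__ = [
    "GeneratorSpec",
    "make_fig_fixture",
    "chain",
    "erdos_renyi_signed",
    "barabasi_albert_signed",
    "gen_random",
]

_FIXTURES = {
    # 3-node activating cascade x1 -> x2 -> x3
    "a": [("x1", "x2", +1), ("x2", "x3", +1)],
    # two cascades with crosstalk converging on x6
    "b": [
        ("x1", "x2", +1),
        ("x1", "x3", +1),
        ("x2", "x4", +1),
        ("x3", "x4", +1),
        ("x3", "x5", +1),
        ("x4", "x6", +1),
        ("x5", "x6", +1),
    ],
    # 3-node negative feedback loop
    "c": [("x1", "x2", +1), ("x2", "x3", +1), ("x3", "x1", -1)],
}


def make_fig_fixture(which: str) -> SignedDirectedNetwork:
    """Toy motif fixtures: "a" cascade, "b" crosstalk, "c" negative loop."""
    try:
        links = _FIXTURES[which]
    except KeyError:
        raise ValueError(f"unknown fixture {which!r}; choose from 'a', 'b', 'c'") from None
    return SignedDirectedNetwork.from_links(links)


def chain(n: int, signs: list[int] | None = None) -> SignedDirectedNetwork:
    """Linear cascade x1 -> x2 -> ... -> xn with the given link signs (all
    activating by default)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    signs = signs if signs is not None else [+1] * (n - 1)
    if len(signs) != n - 1:
        raise ValueError(f"need {n - 1} signs for a chain of {n} nodes")
    links = [(f"x{i + 1}", f"x{i + 2}", s) for i, s in enumerate(signs)]
    return SignedDirectedNetwork.from_links(
        links, extra_nodes=[f"x{i + 1}" for i in range(n)]
    )


def _assign_signs(
    edges: list[tuple[str, str]], sign_probability: float, rng: np.random.Generator
) -> list[tuple[str, str, int]]:
    return [
        (u, v, -1 if rng.random() < sign_probability else +1) for u, v in edges
    ]


def erdos_renyi_signed(
    n: int, p: float, sign_probability: float = 0.25, seed: int = 0
) -> SignedDirectedNetwork:
    """Directed G(n, p) with each link inhibitory with ``sign_probability``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= sign_probability <= 1.0:
        raise ValueError("sign_probability must be in [0, 1]")
    g = nx.gnp_random_graph(n, p, seed=int(seed), directed=True)
    rng = np.random.default_rng(seed)
    names = {i: f"n{i}" for i in g.nodes}
    edges = [(names[u], names[v]) for u, v in sorted(g.edges)]
    return SignedDirectedNetwork.from_links(
        _assign_signs(edges, sign_probability, rng),
        extra_nodes=[names[i] for i in sorted(g.nodes)],
    )


def barabasi_albert_signed(
    n: int, m: int, sign_probability: float = 0.25, seed: int = 0
) -> SignedDirectedNetwork:
    """Preferential-attachment digraph with power-law in-degrees.

    The undirected Barabasi-Albert graph is oriented from each newly
    attached node toward the existing nodes it attaches to, so signal flows
    toward hubs.  Requires attachment parameter m < n.
    """
    if not 1 <= m < n:
        raise ValueError("require 1 <= m < n")
    g = nx.barabasi_albert_graph(n, m, seed=int(seed))
    rng = np.random.default_rng(seed)
    names = {i: f"n{i}" for i in g.nodes}
    # BA adds nodes in index order: the higher index of an edge is the newcomer
    edges = [
        (names[max(u, v)], names[min(u, v)]) for u, v in sorted(g.edges)
    ]
    return SignedDirectedNetwork.from_links(
        _assign_signs(edges, sign_probability, rng),
        extra_nodes=[names[i] for i in sorted(g.nodes)],
    )


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of a synthetic network.

    model: "erdos_renyi", "barabasi_albert", "chain", or "fig1a"/"fig1b"/"fig1c".
    parameter: edge probability (ER) or attachment count (BA); ignored otherwise.
    sign_probability: fraction of inhibitory links for the random models.
    """

    model: str
    n: int = 3
    parameter: float = 0.1
    sign_probability: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.sign_probability <= 1.0:
            raise ValueError("sign_probability must be in [0, 1]")


def gen_random(spec: GeneratorSpec) -> SignedDirectedNetwork:
    """Build the network a :class:`GeneratorSpec` describes."""
    if spec.model == "erdos_renyi":
        return erdos_renyi_signed(spec.n, spec.parameter, spec.sign_probability, spec.seed)
    if spec.model == "barabasi_albert":
        return barabasi_albert_signed(
            spec.n, int(spec.parameter), spec.sign_probability, spec.seed
        )
    if spec.model == "chain":
        return chain(spec.n)
    if spec.model.startswith("fig1") and spec.model[-1] in "abc":
        return make_fig_fixture(spec.model[-1])
    raise ValueError(f"unknown model {spec.model!r}")
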