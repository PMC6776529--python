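"""Robustness of SI-plot analysis to structural uncertainty in the topology.

Curated signaling networks are incomplete; this module quantifies how stable
candidate discovery is when the topology is randomized.  A *structural
perturbation* applies degree-preserving double-edge swaps (pick links a->b
and c->d, rewire to a->d and c->b) and link-sign flips.  The distance
between original and perturbed topologies is

    N_DL = sum_ij |A_ij - B_ij|

over the signed adjacencies (a moved link contributes 2, a flipped sign 2).
Recovery of a reference target set is summarized by R_T (the recovered
fraction) and by a hypergeometric enrichment score -log10 P(X >= k) for
finding k reference targets among N candidates drawn from M nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .influence import DivergenceError, Hyperparams, influence_exact, influence_iterative
from .network import AdjacencyMatrix, Link, SignedDirectedNetwork, to_adjacency
from .si import select_candidates, si_groups, si_profile
from .weights import normalize_link_weights

__all__ = [
    "degree_preserving_swap",
    "flip_signs",
    "perturb_network",
    "n_dl",
    "r_t",
    "hypergeom_tail",
    "enrichment_score",
    "robustness_experiment",
]


def _incident_indices(links: tuple[Link, ...], nodes: set[str]) -> list[int]:
    return [i for i, l in enumerate(links) if l.source in nodes or l.target in nodes]


def degree_preserving_swap(
    net: SignedDirectedNetwork,
    trials: int,
    rng: np.random.Generator,
    critical_nodes: set[str] | None = None,
) -> SignedDirectedNetwork:
    """Randomize connectivity by repeated double-edge swaps.

    Each trial picks links a->b and c->d and proposes a->d and c->b (signs
    travel with their source link), preserving every node's in- and
    out-degree.  A trial is rejected — and still consumed — if the rewiring
    would create a self-loop or a duplicate ordered pair.  With
    ``critical_nodes`` given, the first link is always incident to a critical
    node and the second is drawn from the remaining links.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if net.n_links < 2:
        raise ValueError("need at least 2 links to swap")
    links = list(net.links)
    pairs = {(l.source, l.target) for l in links}
    for _ in range(trials):
        if critical_nodes:
            pool1 = _incident_indices(tuple(links), critical_nodes)
            if not pool1:
                break
            i1 = pool1[rng.integers(len(pool1))]
            pool2 = [i for i in range(len(links)) if i not in set(pool1)]
            if not pool2:
                pool2 = [i for i in range(len(links)) if i != i1]
        else:
            i1 = int(rng.integers(len(links)))
            pool2 = None
        i2 = pool2[rng.integers(len(pool2))] if pool2 else int(rng.integers(len(links)))
        if i2 == i1:
            continue  # consumed, rejected
        l1, l2 = links[i1], links[i2]
        new1 = (l1.source, l2.target)
        new2 = (l2.source, l1.target)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue  # self-loop
        remaining = pairs - {(l1.source, l1.target), (l2.source, l2.target)}
        if new1 in remaining or new2 in remaining or new1 == new2:
            continue  # duplicate ordered pair
        links[i1] = Link(new1[0], new1[1], l1.sign)
        links[i2] = Link(new2[0], new2[1], l2.sign)
        pairs = remaining | {new1, new2}
    return SignedDirectedNetwork(net.nodes, tuple(links), net.outputs)


def flip_signs(
    net: SignedDirectedNetwork,
    trials: int,
    rng: np.random.Generator,
    critical_nodes: set[str] | None = None,
) -> SignedDirectedNetwork:
    """Negate the sign of a randomly chosen link, ``trials`` times.

    Topology (and hence all degrees) is unchanged.  Hitting the same link an
    even number of times restores its sign.  With ``critical_nodes`` given,
    only links incident to a critical node are eligible.
    """
    if net.n_links < 1:
        raise ValueError("need at least 1 link to flip")
    links = list(net.links)
    pool = (
        _incident_indices(net.links, critical_nodes) if critical_nodes else None
    )
    if critical_nodes and not pool:
        return net
    for _ in range(trials):
        i = pool[rng.integers(len(pool))] if pool else int(rng.integers(len(links)))
        links[i] = replace(links[i], sign=-links[i].sign)
    return SignedDirectedNetwork(net.nodes, tuple(links), net.outputs)


def perturb_network(
    net: SignedDirectedNetwork,
    level: int,
    rng: np.random.Generator,
    critical_nodes: set[str] | None = None,
    swap_probability: float = 0.5,
) -> SignedDirectedNetwork:
    """Apply one structural perturbation of the given level.

    The level is an integer intensity: 2*level trials are applied, each
    independently a double-edge swap or a sign flip with probability
    ``swap_probability`` (so a level contributes ~level swaps and ~level
    flips on average).  Level 0 returns the network unchanged.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    for _ in range(2 * level):
        if rng.random() < swap_probability:
            net = degree_preserving_swap(net, 1, rng, critical_nodes)
        else:
            net = flip_signs(net, 1, rng, critical_nodes)
    return net


def n_dl(A: AdjacencyMatrix, B: AdjacencyMatrix) -> int:
    """Number of differing links: sum of |A_ij - B_ij| over signed adjacencies."""
    if A.nodes != B.nodes:
        raise ValueError("adjacencies must share the same node order")
    return int(np.abs(A.entries - B.entries).sum())


def r_t(found: set[str], original_targets: set[str]) -> float:
    """Fraction of the reference target set recovered by the candidates."""
    original_targets = set(original_targets)
    if not original_targets:
        raise ValueError("original target set must be non-empty")
    return len(set(found) & original_targets) / len(original_targets)


def hypergeom_tail(M: int, n: int, N: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts reference targets among N candidates drawn without replacement
    from M nodes of which n are reference targets.
    """
    if not (0 <= n <= M and 0 <= N <= M):
        raise ValueError("require 0 <= n <= M and 0 <= N <= M")
    if not 0 <= k <= min(n, N):
        raise ValueError("require 0 <= k <= min(n, N)")
    return float(stats.hypergeom.sf(k - 1, M, n, N))


def enrichment_score(p_value: float) -> float:
    """-log10 of a p-value in (0, 1]."""
    if not 0.0 < p_value <= 1.0:
        raise ValueError("p-value must be in (0, 1]")
    return float(-np.log10(p_value))


@dataclass(frozen=True)
class _AnalysisSettings:
    outputs: tuple[str, ...]
    directions: dict
    fraction: float | None
    k: int | None
    hp: Hyperparams


def _discover_candidates(
    net: SignedDirectedNetwork, settings: _AnalysisSettings
) -> tuple[set[str], bool]:
    """Full SI-plot pipeline on one (possibly perturbed) topology.

    Returns (union of per-output candidate sets minus the outputs,
    converged flag).
    """
    W = normalize_link_weights(to_adjacency(net))
    converged = True
    try:
        S = influence_exact(W, settings.hp)
    except DivergenceError:
        S = influence_iterative(W, settings.hp)
        converged = S.converged
    candidates: set[str] = set()
    for output in settings.outputs:
        profile = si_profile(net, S, output)
        groups = si_groups(profile)
        cs = select_candidates(
            groups,
            output=output,
            k=settings.k,
            fraction=settings.fraction,
            direction=settings.directions.get(output, "positive"),
        )
        candidates |= set(cs.nodes)
    return candidates - set(settings.outputs), converged


def robustness_experiment(
    net: SignedDirectedNetwork,
    outputs: list[str],
    original_targets: set[str],
    *,
    levels: list[int],
    replicates: int,
    seed: int,
    fraction: float | None = 0.10,
    k: int | None = None,
    directions: dict | None = None,
    critical_mode: str = "random",
    hp: Hyperparams = Hyperparams(),
) -> pd.DataFrame:
    """Run the structural-perturbation robustness protocol.

    For every level x replicate, perturbs the topology, reruns the whole
    SI-plot pipeline (influence, SPLO, top-k/top-fraction per SPLO group,
    default top-10%), and records N_DL, R_T, the hypergeometric p-value and
    the enrichment score.  Replicate sub-streams are spawned from ``seed``,
    so the full table is reproducible bit-for-bit.

    critical_mode: "random" perturbs any links; "targets" forces each
    perturbation to touch a link of the reference targets; "outputs" a link
    of the output nodes.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if critical_mode not in ("random", "targets", "outputs"):
        raise ValueError("critical_mode must be 'random', 'targets' or 'outputs'")
    critical = {
        "random": None,
        "targets": set(original_targets),
        "outputs": set(outputs),
    }[critical_mode]
    settings = _AnalysisSettings(
        tuple(outputs), dict(directions or {}), fraction, k, hp
    )
    A = to_adjacency(net)
    streams = np.random.SeedSequence(seed).spawn(len(levels) * replicates)
    rows = []
    run = 0
    for level in levels:
        for rep in range(replicates):
            rng = np.random.default_rng(streams[run])
            run += 1
            perturbed = perturb_network(net, level, rng, critical)
            B = to_adjacency(perturbed)
            candidates, converged = _discover_candidates(perturbed, settings)
            found = candidates & set(original_targets)
            M = net.n_nodes
            p = hypergeom_tail(M, len(set(original_targets)), len(candidates), len(found))
            rows.append(
                {
                    "level": level,
                    "replicate": rep,
                    "n_dl": n_dl(A, B),
                    "n_candidates": len(candidates),
                    "n_found": len(found),
                    "r_t": r_t(candidates, set(original_targets)),
                    "p_value": p,
                    "enrichment_score": enrichment_score(p),
                    "converged": converged,
                }
            )
    return pd.DataFrame(rows)
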