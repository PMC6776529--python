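"""SI-plot analysis: SPLO, influence normalization, grouping and candidate
selection.

The SI-plot scatters each node's normalized influence on an output against
its shortest directed path length to that output (SPLO).  Control-target
candidates are the top-k or top-n% most influential nodes *within each SPLO
group*, which surfaces distal-but-influential regulators that a pure
proximity ranking would miss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .influence import InfluenceMatrix
from .network import SignedDirectedNetwork

__all__ = [
    "SIProfile",
    "CandidateSet",
    "splo",
    "normalize_influence",
    "si_profile",
    "si_groups",
    "select_candidates",
    "splo_influence_correlation",
    "plot_si",
]


def splo(net: SignedDirectedNetwork, output: str) -> dict[str, int | None]:
    """Shortest directed path length from each node to ``output``.

    Breadth-first search on the reversed links.  The output maps to 0; nodes
    with no directed path to the output map to ``None`` (explicitly
    unreachable, never a sentinel number).
    """
    if output not in net.nodes:
        raise KeyError(f"unknown output {output!r}")
    g = net.to_networkx().reverse(copy=False)
    dist = nx.single_source_shortest_path_length(g, output)
    return {node: dist.get(node) for node in net.nodes}


def normalize_influence(values: np.ndarray) -> np.ndarray:
    """Log-compress influences: sgn(S) * log2(1 + |S|/S_avg).

    S_avg is the mean of |S| over the entries with nonzero influence, so the
    argument of the logarithm is always positive and an entry at the average
    magnitude maps to +/-1.  Zeros map to zero; an all-zero row is returned
    unchanged.
    """
    values = np.asarray(values, dtype=float)
    mags = np.abs(values)
    nonzero = mags > 0
    if not nonzero.any():
        return np.zeros_like(values)
    s_avg = mags[nonzero].mean()
    return np.sign(values) * np.log2(1.0 + mags / s_avg)


@dataclass(frozen=True)
class SIProfile:
    """Per-output record of raw/normalized influence and SPLO for all nodes."""

    output: str
    nodes: tuple[str, ...]
    influence: np.ndarray          # raw S_out,j per source node j
    normalized: np.ndarray         # sgn * log2(1 + |S|/S_avg)
    splo: dict[str, int | None]    # None = unreachable

    def reachable_nodes(self, include_output: bool = False) -> list[str]:
        return [
            n
            for n in self.nodes
            if self.splo[n] is not None and (include_output or n != self.output)
        ]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node": self.nodes,
                "influence": self.influence,
                "normalized_influence": self.normalized,
                "splo": [self.splo[n] for n in self.nodes],
            }
        )


def si_profile(
    net: SignedDirectedNetwork, S: InfluenceMatrix, output: str
) -> SIProfile:
    """Assemble the SI-plot record for one output from an influence matrix."""
    idx = S.node_index()
    if output not in idx:
        raise KeyError(f"unknown output {output!r}")
    row = S.entries[idx[output], :].copy()
    return SIProfile(
        output=output,
        nodes=S.nodes,
        influence=row,
        normalized=normalize_influence(row),
        splo=splo(net, output),
    )


def si_groups(profile: SIProfile) -> dict[int, list[tuple[str, float]]]:
    """Group reachable nodes by SPLO, each group sorted by descending
    normalized influence (ties broken lexicographically by node id).

    Returns ``{splo: [(node, normalized_influence), ...]}``.  Unreachable
    nodes are excluded.
    """
    norm = dict(zip(profile.nodes, profile.normalized))
    groups: dict[int, list[tuple[str, float]]] = {}
    for node in profile.nodes:
        d = profile.splo[node]
        if d is None:
            continue
        groups.setdefault(d, []).append((node, float(norm[node])))
    for d in groups:
        groups[d].sort(key=lambda nv: (-nv[1], nv[0]))
    return dict(sorted(groups.items()))


@dataclass(frozen=True)
class CandidateSet:
    """Control-target candidates selected from SI-plot groups."""

    output: str
    rule: str                      # e.g. "top-2" or "top-10%"
    direction: str                 # "positive" or "negative"
    nodes: frozenset[str] = field(default_factory=frozenset)


def select_candidates(
    groups: dict[int, list[tuple[str, float]]],
    *,
    output: str,
    k: int | None = None,
    fraction: float | None = None,
    direction: str = "positive",
    exclude: set[str] = frozenset(),
) -> CandidateSet:
    """Per SPLO group, take the top-k (or top ceil(fraction*size)) nodes by
    normalized influence in the given direction; union over groups, minus the
    output itself and any excluded nodes.

    direction "positive" ranks by descending value (most positive first),
    "negative" by ascending value (most negative first); ties break
    lexicographically.
    """
    if (k is None) == (fraction is None):
        raise ValueError("specify exactly one of k or fraction")
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    if fraction is not None and not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    selected: set[str] = set()
    for members in groups.values():
        if direction == "positive":
            ranked = sorted(members, key=lambda nv: (-nv[1], nv[0]))
        else:
            ranked = sorted(members, key=lambda nv: (nv[1], nv[0]))
        take = k if k is not None else math.ceil(fraction * len(members))
        selected.update(node for node, _ in ranked[:take])
    selected -= {output}
    selected -= set(exclude)
    rule = f"top-{k}" if k is not None else f"top-{fraction:g}"
    return CandidateSet(output=output, rule=rule, direction=direction, nodes=frozenset(selected))


def splo_influence_correlation(profile: SIProfile) -> float:
    """Pearson correlation between SPLO and |influence| over reachable
    non-output nodes.  Raises on fewer than 3 such nodes or zero variance."""
    from scipy import stats

    nodes = profile.reachable_nodes()
    if len(nodes) < 3:
        raise ValueError("need at least 3 reachable non-output nodes")
    infl = dict(zip(profile.nodes, np.abs(profile.influence)))
    x = np.array([profile.splo[n] for n in nodes], dtype=float)
    y = np.array([infl[n] for n in nodes])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in SPLO or |influence|")
    return float(stats.pearsonr(x, y).statistic)


def plot_si(profile: SIProfile, path=None, ax=None, label_top: int = 10):
    """Scatter of normalized influence vs SPLO, labeling the strongest nodes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    nodes = profile.reachable_nodes()
    norm = dict(zip(profile.nodes, profile.normalized))
    x = [profile.splo[n] for n in nodes]
    y = [norm[n] for n in nodes]
    ax.scatter(x, y, s=20, alpha=0.8)
    for n in sorted(nodes, key=lambda n: -abs(norm[n]))[:label_top]:
        ax.annotate(n, (profile.splo[n], norm[n]), fontsize=7)
    ax.axhline(0.0, lw=0.5, color="grey")
    ax.set_xlabel("SPLO (shortest path length to output)")
    ax.set_ylabel("normalized influence")
    ax.set_title(f"SI-plot for output {profile.output}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
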