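"""Signed directed signaling networks and their adjacency matrices.

A signaling network is a directed graph whose links carry a regulatory sign:
+1 for activation, -1 for inhibition.  Networks are read from and written to
SIF-style edge lists (``source  relation  target``), the plain-text format
commonly used to exchange signaling topologies.

The adjacency matrix follows the target-row / source-column convention: entry
``(i, j)`` is the sign of the link from node ``j`` to node ``i``.  This matches
the orientation of the link-weight matrix used by the propagation model, where
``W @ x`` pushes activity from sources into targets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "Link",
    "SignedDirectedNetwork",
    "AdjacencyMatrix",
    "SifParseError",
    "NetworkValidationError",
    "read_sif",
    "parse_sif",
    "write_sif",
    "to_adjacency",
]

#: relation tokens accepted in SIF files, mapped to link signs
RELATION_TOKENS: Mapping[str, int] = {
    "activates": +1,
    "activate": +1,
    "+": +1,
    "1": +1,
    "+1": +1,
    "inhibits": -1,
    "inhibit": -1,
    "-": -1,
    "-1": -1,
    "−1": -1,  # unicode minus
}


class SifParseError(ValueError):
    """Raised when a SIF document cannot be parsed."""


class NetworkValidationError(ValueError):
    """Raised when a network violates its structural invariants."""


@dataclass(frozen=True)
class Link:
    """One signed directed link ``source -> target``."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise NetworkValidationError(
                f"link {self.source}->{self.target}: sign must be +1 or -1, got {self.sign}"
            )


@dataclass(frozen=True)
class SignedDirectedNetwork:
    """A signed directed graph with optional designated output nodes.

    Parameters
    ----------
    nodes
        Ordered unique node identifiers.  Order is preserved everywhere
        (matrix rows/columns, exports).
    links
        Signed directed links.  At most one link per ordered (source, target)
        pair.
    outputs
        Subset of ``nodes`` designated as phenotypic/readout outputs.
    """

    nodes: tuple[str, ...]
    links: tuple[Link, ...]
    outputs: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(
            self,
            "links",
            tuple(l if isinstance(l, Link) else Link(*l) for l in self.links),
        )
        object.__setattr__(self, "outputs", tuple(self.outputs))
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkValidationError("node identifiers must be unique")
        node_set = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for link in self.links:
            if link.source not in node_set or link.target not in node_set:
                raise NetworkValidationError(
                    f"link {link.source}->{link.target} references an undeclared node"
                )
            pair = (link.source, link.target)
            if pair in seen:
                raise NetworkValidationError(
                    f"duplicate link for ordered pair {link.source}->{link.target}"
                )
            seen.add(pair)
        for out in self.outputs:
            if out not in node_set:
                raise NetworkValidationError(f"output {out!r} is not a declared node")

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def node_index(self) -> dict[str, int]:
        return {node: i for i, node in enumerate(self.nodes)}

    def has_link(self, source: str, target: str) -> bool:
        return any(l.source == source and l.target == target for l in self.links)

    # -- constructors --------------------------------------------------

    @classmethod
    def from_links(
        cls,
        links: Iterable[tuple[str, str, int]],
        outputs: Iterable[str] = (),
        extra_nodes: Iterable[str] = (),
    ) -> "SignedDirectedNetwork":
        """Build a network from (source, target, sign) triples.

        Node order is order of first appearance (source before target),
        followed by ``extra_nodes`` not touched by any link.
        """
        link_objs = [Link(s, t, g) for s, t, g in links]
        nodes: list[str] = []
        seen: set[str] = set()
        for l in link_objs:
            for n in (l.source, l.target):
                if n not in seen:
                    seen.add(n)
                    nodes.append(n)
        for n in extra_nodes:
            if n not in seen:
                seen.add(n)
                nodes.append(n)
        return cls(tuple(nodes), tuple(link_objs), tuple(outputs))

    def with_outputs(self, outputs: Iterable[str]) -> "SignedDirectedNetwork":
        return SignedDirectedNetwork(self.nodes, self.links, tuple(outputs))

    # -- conversions ---------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        """Export as a networkx DiGraph with a ``sign`` edge attribute."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((l.source, l.target, {"sign": l.sign}) for l in self.links)
        return g

    def to_edge_table(self):
        """Edge list as a pandas DataFrame (source, target, sign)."""
        import pandas as pd

        return pd.DataFrame(
            [(l.source, l.target, l.sign) for l in self.links],
            columns=["source", "target", "sign"],
        )


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Signed adjacency with entries in {-1, 0, +1}.

    ``entries[i, j]`` is the sign of the link from source ``nodes[j]`` to
    target ``nodes[i]`` (0 if absent).
    """

    entries: np.ndarray
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=int)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "nodes", tuple(self.nodes))
        n = len(self.nodes)
        if entries.shape != (n, n):
            raise NetworkValidationError(
                f"adjacency shape {entries.shape} does not match {n} nodes"
            )
        if not np.isin(entries, (-1, 0, 1)).all():
            raise NetworkValidationError("adjacency entries must be in {-1, 0, +1}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self) -> dict[str, int]:
        return {node: i for i, node in enumerate(self.nodes)}

    def out_degrees(self) -> np.ndarray:
        """Out-degree of each node (column counts of nonzero entries)."""
        return np.count_nonzero(self.entries, axis=0)

    def in_degrees(self) -> np.ndarray:
        """In-degree of each node (row counts of nonzero entries)."""
        return np.count_nonzero(self.entries, axis=1)

    def to_network(self, outputs: Iterable[str] = ()) -> SignedDirectedNetwork:
        """Lossless inverse of :func:`to_adjacency` (links ordered by source)."""
        links = []
        cols, rows = np.nonzero(self.entries.T)  # iterate source-major
        for j, i in zip(cols, rows):
            links.append(Link(self.nodes[j], self.nodes[i], int(self.entries[i, j])))
        return SignedDirectedNetwork(self.nodes, tuple(links), tuple(outputs))


# ---------------------------------------------------------------------------
# SIF input/output
# ---------------------------------------------------------------------------


def parse_sif(text: str, outputs: Iterable[str] = ()) -> SignedDirectedNetwork:
    """Parse a SIF document given as text.

    Each non-empty, non-comment line is either ``source relation target``
    (whitespace/tab separated) or a bare node identifier declaring an
    isolated node.  Comment lines start with ``#``.
    """
    links: list[tuple[str, str, int]] = []
    declared: list[str] = []
    seen_pairs: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) == 1:
            declared.append(fields[0])
            continue
        if len(fields) != 3:
            raise SifParseError(
                f"line {lineno}: expected 'source relation target' (3 fields), "
                f"got {len(fields)}: {line!r}"
            )
        source, relation, target = fields
        sign = RELATION_TOKENS.get(relation.lower())
        if sign is None:
            raise SifParseError(f"line {lineno}: unknown relation token {relation!r}")
        if (source, target) in seen_pairs:
            raise SifParseError(
                f"line {lineno}: duplicate link {source}->{target}"
            )
        seen_pairs.add((source, target))
        links.append((source, target, sign))
    return SignedDirectedNetwork.from_links(links, outputs=outputs, extra_nodes=declared)


def read_sif(path_or_text: str | os.PathLike, outputs: Iterable[str] = ()) -> SignedDirectedNetwork:
    """Read a network from a SIF file path, or parse SIF content directly.

    A single-line string naming an existing file is treated as a path;
    anything else is parsed as document text.
    """
    if isinstance(path_or_text, os.PathLike):
        return parse_sif(Path(path_or_text).read_text(), outputs=outputs)
    if "\n" not in path_or_text and Path(path_or_text).exists():
        return parse_sif(Path(path_or_text).read_text(), outputs=outputs)
    return parse_sif(path_or_text, outputs=outputs)


def write_sif(net: SignedDirectedNetwork, path: str | os.PathLike | None = None) -> str:
    """Serialize a network to SIF text; optionally also write it to ``path``.

    Linked nodes appear through their links; isolated nodes are preserved as
    bare-identifier lines so that ``read_sif(write_sif(net))`` round-trips.
    """
    lines = []
    linked: set[str] = set()
    for l in net.links:
        relation = "activates" if l.sign > 0 else "inhibits"
        lines.append(f"{l.source}\t{relation}\t{l.target}")
        linked.update((l.source, l.target))
    for node in net.nodes:
        if node not in linked:
            lines.append(node)
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


def to_adjacency(net: SignedDirectedNetwork) -> AdjacencyMatrix:
    """Signed adjacency of a network; entry (i, j) is the sign of j -> i."""
    n = net.n_nodes
    idx = net.node_index()
    entries = np.zeros((n, n), dtype=int)
    for l in net.links:
        entries[idx[l.target], idx[l.source]] = l.sign
    return AdjacencyMatrix(entries, net.nodes)
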