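"""Degree-normalized link weights for the propagation model.

Each link weight is the link sign scaled by the geometric mean of the source
out-degree and target in-degree::

    W_ij = sign_ij / sqrt(d_out(j) * d_in(i))

High-degree hubs therefore distribute proportionally less signal per link.
Degrees are counted on the unweighted adjacency (link presence); subsequent
weight edits such as mutation modeling never trigger a degree recount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import AdjacencyMatrix

__all__ = ["WeightMatrix", "normalize_link_weights", "set_link_weight"]


@dataclass(frozen=True)
class WeightMatrix:
    """Real link-weight matrix, same target-row/source-column orientation as
    :class:`~signalflow.network.AdjacencyMatrix`."""

    entries: np.ndarray
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "nodes", tuple(self.nodes))
        n = len(self.nodes)
        if entries.shape != (n, n):
            raise ValueError(f"weight shape {entries.shape} does not match {n} nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self) -> dict[str, int]:
        return {node: i for i, node in enumerate(self.nodes)}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.entries, index=self.nodes, columns=self.nodes)


def normalize_link_weights(adj: AdjacencyMatrix, mean: str = "geometric") -> WeightMatrix:
    """Normalize link weights by the incident degrees.

    Parameters
    ----------
    adj
        Signed adjacency.  Every linked endpoint has degree >= 1 by
        construction, so no division by zero can occur.
    mean
        ``"geometric"`` (default): |W_ij| = 1/sqrt(d_out(j) * d_in(i)).
        ``"arithmetic"``: |W_ij| = 2/(d_out(j) + d_in(i)).
    """
    d_out = adj.out_degrees().astype(float)
    d_in = adj.in_degrees().astype(float)
    signs = adj.entries.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if mean == "geometric":
            scale = 1.0 / np.sqrt(np.outer(d_in, d_out))
        elif mean == "arithmetic":
            scale = 2.0 / np.add.outer(d_in, d_out)
        else:
            raise ValueError(f"unknown mean {mean!r}; use 'geometric' or 'arithmetic'")
    entries = np.zeros_like(signs)
    mask = signs != 0  # degrees at linked positions are >= 1, so scale is finite there
    entries[mask] = signs[mask] * scale[mask]
    return WeightMatrix(entries, adj.nodes)


def set_link_weight(
    W: WeightMatrix, source: str, target: str, factor: float
) -> WeightMatrix:
    """Return a new matrix with the weight of ``source -> target`` multiplied
    by ``factor``.  The link must exist."""
    idx = W.node_index()
    try:
        i, j = idx[target], idx[source]
    except KeyError as exc:
        raise KeyError(f"unknown node {exc.args[0]!r}") from None
    if W.entries[i, j] == 0.0:
        raise ValueError(f"no link {source}->{target}")
    entries = W.entries.copy()
    entries[i, j] *= factor
    return WeightMatrix(entries, W.nodes)
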