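"""Interventions: drug-like basal inhibition and mutation-style weight edits.

Two intervention families are modeled:

* **Basal interventions** change the basal-activity vector ``b`` only (e.g.
  an inhibitor clamps a target's basal activity to a strongly negative
  value).  The weight matrix, and hence the influence matrix, is untouched;
  only steady-state activities move.

* **Weight edits** model genetic alterations by rescaling the in- and
  out-link weights of the affected protein on the already-normalized weight
  matrix.  A constitutively activating mutation removes the in-links (the
  mutant ignores upstream signals) and amplifies the out-links; a
  loss-of-function alteration attenuates both.

Edits are applied after link-weight normalization and never recompute
degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .weights import WeightMatrix

__all__ = [
    "Intervention",
    "apply_basal_inhibition",
    "apply_constitutive_activation",
    "apply_attenuation",
    "apply_interventions",
]

DEFAULT_INHIBITION_BASAL = -10.0
DEFAULT_ACTIVATION_OUT_FACTOR = 10.0


def _index_of(nodes: tuple[str, ...], node: str) -> int:
    try:
        return nodes.index(node)
    except ValueError:
        raise KeyError(f"unknown node {node!r}") from None


def apply_basal_inhibition(
    b: np.ndarray,
    nodes: tuple[str, ...],
    node: str,
    value: float = DEFAULT_INHIBITION_BASAL,
) -> np.ndarray:
    """Set the basal activity of ``node`` to ``value`` (default -10),
    leaving every other entry and all link weights unchanged."""
    b = np.asarray(b, dtype=float)
    if b.shape != (len(nodes),):
        raise ValueError(f"basal vector has shape {b.shape}, expected ({len(nodes)},)")
    out = b.copy()
    out[_index_of(nodes, node)] = value
    return out


def apply_constitutive_activation(
    W: WeightMatrix,
    node: str,
    out_factor: float = DEFAULT_ACTIVATION_OUT_FACTOR,
) -> WeightMatrix:
    """Constitutively activating mutation: remove the in-links of ``node``
    and multiply its out-link weights by ``out_factor`` (default 10)."""
    k = _index_of(W.nodes, node)
    entries = W.entries.copy()
    entries[k, :] = 0.0  # in-links removed: mutant ignores upstream signal
    entries[:, k] *= out_factor
    return WeightMatrix(entries, W.nodes)


def apply_attenuation(
    W: WeightMatrix, node: str, in_factor: float, out_factor: float
) -> WeightMatrix:
    """Scale the in-link weights of ``node`` by ``in_factor`` and its
    out-link weights by ``out_factor``.

    Covers loss-of-function alterations (e.g. both factors 0.001 for a 99.9%
    attenuation) as well as asymmetric edits such as (0, 100) for a
    constitutive activation expressed as factors.
    """
    if in_factor < 0 or out_factor < 0:
        raise ValueError("attenuation factors must be >= 0")
    k = _index_of(W.nodes, node)
    entries = W.entries.copy()
    entries[k, :] *= in_factor
    entries[:, k] *= out_factor
    return WeightMatrix(entries, W.nodes)


@dataclass(frozen=True)
class Intervention:
    """A single-node intervention, composable as an ordered list.

    kind:
        ``basal_inhibition`` (parameter ``value``, default -10),
        ``constitutive_activation`` (``out_factor``, default 10),
        ``attenuation`` (``in_factor``, ``out_factor``), or
        ``custom_edit`` (both factors, no defaults).
    """

    node: str
    kind: str
    parameters: dict = field(default_factory=dict)

    _KINDS = ("basal_inhibition", "constitutive_activation", "attenuation", "custom_edit")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown intervention kind {self.kind!r}")

    def apply(
        self, W: WeightMatrix, b: np.ndarray
    ) -> tuple[WeightMatrix, np.ndarray]:
        p = self.parameters
        if self.kind == "basal_inhibition":
            return W, apply_basal_inhibition(
                b, W.nodes, self.node, p.get("value", DEFAULT_INHIBITION_BASAL)
            )
        if self.kind == "constitutive_activation":
            return (
                apply_constitutive_activation(
                    W, self.node, p.get("out_factor", DEFAULT_ACTIVATION_OUT_FACTOR)
                ),
                b,
            )
        # attenuation / custom_edit
        return (
            apply_attenuation(W, self.node, p["in_factor"], p["out_factor"]),
            b,
        )


def apply_interventions(
    W: WeightMatrix, b: np.ndarray, interventions: list[Intervention]
) -> tuple[WeightMatrix, np.ndarray]:
    """Apply an ordered list of interventions; inputs are not mutated."""
    b = np.asarray(b, dtype=float).copy()
    for iv in interventions:
        W, b = iv.apply(W, b)
    return W, b
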