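"""Goal-directed scoring of control targets via the composite measure.

A control goal specifies, per output, a desired direction of change and an
intervention type (inhibition or activation of the target).  For a target
with influence vector S = (S_o1, ..., S_om) on the outputs and goal vector
G in {-1, +1}^m, the composite measure is

    CM = (prod_o sgn(S_o * G_o)) * (1 + CD),   CD = 1 - cos(S, G)

Promising targets have positive CM close to 1 (influence vector aligned with
the goal in every coordinate); negative CM flags targets that drive some
output the wrong way.  For the canonical two-output all-(+1) goal this
reduces to sgn(S_1)*sgn(S_2)*(1 + CD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .influence import Hyperparams, InfluenceMatrix, steady_state
from .perturbations import apply_basal_inhibition
from .weights import WeightMatrix

__all__ = [
    "ControlGoal",
    "CompositeScore",
    "composite_measure",
    "score_nodes",
    "rank_by_goal",
    "signal_flow_verification",
]

#: hyperparameters used for activity-level (signal-flow) verification runs
SIGNAL_FLOW_HYPERPARAMS = Hyperparams(alpha=0.5, beta=0.5)


@dataclass(frozen=True)
class ControlGoal:
    """Desired direction of change per output, achieved by inhibiting or
    activating a single target."""

    outputs: tuple[str, ...]
    directions: tuple[int, ...]  # +1 increase, -1 decrease, per output
    intervention: str = "inhibition"

    def __post_init__(self) -> None:
        object.__setattr__(self, "outputs", tuple(self.outputs))
        object.__setattr__(self, "directions", tuple(self.directions))
        if len(self.outputs) < 1:
            raise ValueError("a control goal needs at least one output")
        if len(self.directions) != len(self.outputs):
            raise ValueError("one direction per output required")
        if any(d not in (-1, +1) for d in self.directions):
            raise ValueError("directions must be +1 or -1")
        if self.intervention not in ("inhibition", "activation"):
            raise ValueError("intervention must be 'inhibition' or 'activation'")

    @property
    def goal_vector(self) -> np.ndarray:
        """Desired sign of the target's influence on each output.

        Inhibiting a target moves each output opposite to the influence sign,
        so for inhibition the goal coordinate is the negated desired
        direction; for activation it is the direction itself.
        """
        g = np.array(self.directions, dtype=float)
        return -g if self.intervention == "inhibition" else g


@dataclass(frozen=True)
class CompositeScore:
    node: str
    influences: tuple[float, ...]  # S on each output, goal order
    cd: float | None               # cosine distance to goal; None if S = 0
    cm: float                      # 0 for no-effect nodes
    category: str                  # "promising" | "undesirable" | "no_effect"


def composite_measure(s_vec: np.ndarray, goal: np.ndarray) -> tuple[float | None, float]:
    """Cosine distance CD and composite measure CM of one influence vector.

    A zero coordinate makes the sign product 0, hence CM = 0 ("no effect");
    an all-zero vector has undefined CD (returned as None) and CM = 0.
    """
    s_vec = np.asarray(s_vec, dtype=float)
    goal = np.asarray(goal, dtype=float)
    if s_vec.shape != goal.shape:
        raise ValueError("influence vector and goal vector differ in length")
    norm = np.linalg.norm(s_vec)
    if norm == 0.0:
        return None, 0.0
    cd = 1.0 - float(s_vec @ goal) / (norm * float(np.linalg.norm(goal)))
    sign_product = float(np.prod(np.sign(s_vec * goal)))
    return cd, sign_product * (1.0 + cd)


def score_nodes(
    S: InfluenceMatrix, goal: ControlGoal, exclude: set[str] = frozenset()
) -> list[CompositeScore]:
    """Composite score of every node (minus the outputs and ``exclude``)."""
    idx = S.node_index()
    rows = [idx[o] for o in goal.outputs]
    g = goal.goal_vector
    scores = []
    skip = set(goal.outputs) | set(exclude)
    for j, node in enumerate(S.nodes):
        if node in skip:
            continue
        s_vec = S.entries[rows, j]
        cd, cm = composite_measure(s_vec, g)
        category = "promising" if cm > 0 else ("undesirable" if cm < 0 else "no_effect")
        scores.append(
            CompositeScore(node, tuple(float(v) for v in s_vec), cd, cm, category)
        )
    return scores


def rank_by_goal(scores: list[CompositeScore]) -> list[CompositeScore]:
    """Order scores for reporting: promising targets first, ascending CM
    (smaller positive CM = influence vector closer to the goal); then
    undesirable targets, least misaligned first (descending CM); no-effect
    nodes last.  Ties break lexicographically; input order is irrelevant."""
    promising = sorted(
        (s for s in scores if s.category == "promising"), key=lambda s: (s.cm, s.node)
    )
    undesirable = sorted(
        (s for s in scores if s.category == "undesirable"),
        key=lambda s: (-s.cm, s.node),
    )
    no_effect = sorted((s for s in scores if s.category == "no_effect"), key=lambda s: s.node)
    return promising + undesirable + no_effect


@dataclass(frozen=True)
class ActivityChangeReport:
    """Steady-state activities before/after an intervention, per output."""

    target: str
    outputs: tuple[str, ...]
    baseline: tuple[float, ...]
    perturbed: tuple[float, ...]

    @property
    def deltas(self) -> tuple[float, ...]:
        return tuple(p - b for p, b in zip(self.perturbed, self.baseline))

    @property
    def signs(self) -> tuple[int, ...]:
        return tuple(int(np.sign(d)) for d in self.deltas)


def signal_flow_verification(
    W: WeightMatrix,
    target: str,
    outputs: tuple[str, ...],
    hp: Hyperparams = SIGNAL_FLOW_HYPERPARAMS,
    basal_value: float = -10.0,
    baseline_b: np.ndarray | None = None,
) -> ActivityChangeReport:
    """Verify a predicted control by simulating activity levels.

    Computes steady-state activities with and without a basal intervention at
    the target (default: inhibition at -10, alpha = beta = 0.5) and reports
    the per-output change.  The default baseline basal activity is 1 at every
    node; by linearity the reported deltas do not depend on the baseline.
    """
    n = W.n_nodes
    b0 = np.ones(n) if baseline_b is None else np.asarray(baseline_b, dtype=float)
    b1 = apply_basal_inhibition(b0, W.nodes, target, basal_value)
    x0 = steady_state(W, b0, hp)
    x1 = steady_state(W, b1, hp)
    idx = {node: i for i, node in enumerate(W.nodes)}
    rows = [idx[o] for o in outputs]
    return ActivityChangeReport(
        target=target,
        outputs=tuple(outputs),
        baseline=tuple(float(x0[i]) for i in rows),
        perturbed=tuple(float(x1[i]) for i in rows),
    )
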