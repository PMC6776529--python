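"""Linear activity propagation and the influence matrix.

The propagation model is the discrete linear recursion

    x(t+1) = alpha * W @ x(t) + beta * b

with activity vector x, basal activities b, normalized link weights W, and
mixing hyperparameters alpha (signal-flow proportion) and beta (basal
proportion).  The influence S_ij = dx_i/db_j measures how a sustained basal
perturbation of source j moves the steady-state activity of node i.  It is
the weighted sum over all directed walks from j to i,

    S = beta * (I + alpha*W + alpha^2*W^2 + ...),

which converges to the resolvent S* = beta * (I - alpha*W)^{-1} whenever the
spectral radius of alpha*W is below 1.  Three routes are provided: the closed
form (``influence_exact``), a fixed-point iteration whose t-th iterate equals
the order-t partial sum (``influence_iterative``), and a brute-force walk
enumeration intended as a small-network test oracle
(``influence_series_oracle``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .weights import WeightMatrix

__all__ = [
    "Hyperparams",
    "InfluenceMatrix",
    "DivergenceError",
    "spectral_radius",
    "propagate",
    "influence_exact",
    "influence_iterative",
    "influence_series_oracle",
    "steady_state",
]


class DivergenceError(RuntimeError):
    """The walk series diverges (spectral radius of alpha*W >= 1); the closed
    form is unavailable.  Use the iterative method with a bounded number of
    iterations instead."""


@dataclass(frozen=True)
class Hyperparams:
    """Propagation hyperparameters.

    alpha : float in (0, 1)
        Proportion of incoming signal flow in the next activity level.
    beta : float in (0, 1)
        Proportion of basal activity.
    tol : float
        Frobenius-norm stopping threshold for the iterative method.
    max_iter : int
        Iteration cap (also bounds series unrolling).
    """

    alpha: float = 0.9
    beta: float = 0.1
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if self.tol <= 0.0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class InfluenceMatrix:
    """Influence of every source (column) on every node (row).

    ``entries[i, j]`` is S_ij.  ``method`` records how it was computed
    ("exact", "iterative", or "series"); ``iterations`` the number of
    iterations / the truncation order actually used.
    """

    entries: np.ndarray
    nodes: tuple[str, ...]
    method: str
    alpha: float
    beta: float
    iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", np.asarray(self.entries, dtype=float))
        object.__setattr__(self, "nodes", tuple(self.nodes))

    def node_index(self) -> dict[str, int]:
        return {node: i for i, node in enumerate(self.nodes)}

    def influence_on(self, output: str) -> dict[str, float]:
        """Influence of every source node on ``output`` (row of S)."""
        i = self.node_index()[output]
        return {node: float(self.entries[i, j]) for j, node in enumerate(self.nodes)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        """S[target, source] by node name."""
        target, source = pair
        idx = self.node_index()
        return float(self.entries[idx[target], idx[source]])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.entries, index=self.nodes, columns=self.nodes)


def spectral_radius(M: np.ndarray) -> float:
    """Largest eigenvalue magnitude of a square matrix."""
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        return 0.0
    return float(np.abs(np.linalg.eigvals(M)).max())


def propagate(
    W: WeightMatrix, b: np.ndarray, hp: Hyperparams, steps: int
) -> np.ndarray:
    """Run the propagation recursion for ``steps`` steps.

    Returns the trajectory as an array of shape ``(steps + 1, N)`` with
    x(0) = 0 in the first row, so x(1) = beta*b.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    b = np.asarray(b, dtype=float)
    n = W.n_nodes
    if b.shape != (n,):
        raise ValueError(f"basal vector has shape {b.shape}, expected ({n},)")
    traj = np.zeros((steps + 1, n))
    for t in range(steps):
        traj[t + 1] = hp.alpha * (W.entries @ traj[t]) + hp.beta * b
    return traj


def _check_convergent(W: WeightMatrix, hp: Hyperparams) -> None:
    rho = spectral_radius(hp.alpha * W.entries)
    if rho >= 1.0:
        raise DivergenceError(
            f"spectral radius of alpha*W is {rho:.6g} >= 1; the walk series "
            "diverges and the closed form is unavailable. Use "
            "influence_iterative with a bounded number of iterations."
        )


def influence_exact(W: WeightMatrix, hp: Hyperparams = Hyperparams()) -> InfluenceMatrix:
    """Closed-form influence S* = beta * (I - alpha*W)^{-1}.

    Raises :class:`DivergenceError` when the series does not converge
    (spectral radius of alpha*W >= 1).
    """
    _check_convergent(W, hp)
    n = W.n_nodes
    A = np.eye(n) - hp.alpha * W.entries
    S = np.linalg.solve(A, hp.beta * np.eye(n))
    return InfluenceMatrix(S, W.nodes, "exact", hp.alpha, hp.beta)


def influence_iterative(
    W: WeightMatrix, hp: Hyperparams = Hyperparams()
) -> InfluenceMatrix:
    """Fixed-point iteration S <- alpha*W @ S + beta*I starting from S = beta*I.

    The t-th iterate equals the order-t partial sum of the walk series, so on
    acyclic networks the iteration terminates exactly once the longest path
    is exhausted.  Stops when the Frobenius norm of the update falls below
    ``hp.tol`` or after ``hp.max_iter`` iterations (``converged=False``).
    """
    n = W.n_nodes
    I = np.eye(n)
    S = hp.beta * I
    iterations = 0
    converged = False
    for t in range(1, hp.max_iter + 1):
        S_next = hp.alpha * (W.entries @ S) + hp.beta * I
        delta = float(np.linalg.norm(S_next - S))
        S = S_next
        iterations = t
        if delta < hp.tol:
            converged = True
            break
    return InfluenceMatrix(
        S, W.nodes, "iterative", hp.alpha, hp.beta, iterations, converged
    )


def influence_series_oracle(
    W: WeightMatrix,
    hp: Hyperparams = Hyperparams(),
    L: int = 10,
    max_walks: int = 2_000_000,
) -> InfluenceMatrix:
    """Brute-force walk enumeration of the order-L partial sum (test oracle).

    Explicitly enumerates every directed walk of length <= L and accumulates
    beta * alpha^len * (product of weights along the walk).  No matrix powers
    are involved, so the result is an independent check on the other two
    routes.  Intended for small networks only; raises if the walk count
    exceeds ``max_walks``.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    n = W.n_nodes
    S = np.zeros((n, n))
    np.fill_diagonal(S, hp.beta)  # length-0 walks
    # successor lists: out_edges[j] = [(i, weight_ij), ...]
    out_edges: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    rows, cols = np.nonzero(W.entries)
    for i, j in zip(rows, cols):
        out_edges[j].append((int(i), float(W.entries[i, j])))
    walk_budget = max_walks
    for start in range(n):
        # depth-first enumeration of walks leaving `start`
        stack: list[tuple[int, int, float]] = [(start, 0, 1.0)]
        while stack:
            node, length, prod = stack.pop()
            if length == L:
                continue
            for succ, w in out_edges[node]:
                walk_budget -= 1
                if walk_budget < 0:
                    raise RuntimeError(
                        f"walk enumeration exceeded {max_walks} walks; "
                        "reduce L or the network size"
                    )
                p = prod * hp.alpha * w
                S[succ, start] += hp.beta * p
                stack.append((succ, length + 1, p))
    return InfluenceMatrix(S, W.nodes, "series", hp.alpha, hp.beta, L)


def steady_state(
    W: WeightMatrix, b: np.ndarray, hp: Hyperparams = Hyperparams()
) -> np.ndarray:
    """Steady-state activities: the solution of x = alpha*W x + beta*b.

    By linearity this equals S* @ b.  Raises :class:`DivergenceError` when
    the recursion does not converge.
    """
    _check_convergent(W, hp)
    b = np.asarray(b, dtype=float)
    n = W.n_nodes
    if b.shape != (n,):
        raise ValueError(f"basal vector has shape {b.shape}, expected ({n},)")
    return np.linalg.solve(np.eye(n) - hp.alpha * W.entries, hp.beta * b)
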