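"""Nonlinear ODE model of signaling networks and its steady-state forms.

The system state ``x`` holds log2-ratio responses of proteins, phospho-proteins
and phenotypes relative to an unperturbed control.  Node ``i`` evolves as

    dx_i/dt = eps_i * tanh( sum_{j != i} w_ij * x_j + u_i ) - alpha_i * x_i

where ``w_ij`` quantifies the influence of node ``j`` on the rate of change of
node ``i``, ``u_i`` is a constant external force encoding a targeted drug
perturbation, ``eps_i`` bounds the maximal rate of change (saturation scale of
the sigmoid) and ``alpha_i`` is the restoration rate pulling the node back to
its unperturbed level.  Self-interactions are forbidden (zero diagonal) and
"activity" nodes -- unmeasured stand-ins for drug-target activity -- have no
upstream regulators (zero rows).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "NodeRole",
    "NodeSpec",
    "NetworkModel",
    "PerturbationDataset",
    "Trajectory",
    "CostConfig",
    "rhs_eval",
    "simulate_to_steady_state",
    "predict_steady_state_decoupled",
    "model_cost",
    "encode_activity_node",
]


class NodeRole(str, enum.Enum):
    PROTEIN = "protein"
    PHENOTYPE = "phenotype"
    ACTIVITY = "activity"


@dataclass(frozen=True)
class NodeSpec:
    """A model variable: a measured (phospho-)protein, a phenotype readout, or
    an unmeasured drug-target activity node (exported with prefix ``a``)."""

    name: str
    role: NodeRole = NodeRole.PROTEIN

    @property
    def display_name(self) -> str:
        return ("a" + self.name) if self.role == NodeRole.ACTIVITY else self.name

    @property
    def is_measured(self) -> bool:
        return self.role != NodeRole.ACTIVITY


@dataclass
class NetworkModel:
    """An executable network model: nodes, interaction matrix and kinetic
    parameters.

    ``W[i, j]`` is the influence of node ``j`` on the rate of change of node
    ``i`` (units of inverse pseudo-time).  ``alpha`` and ``epsilon`` are the
    per-node restoration rates and saturation scales.
    """

    nodes: list[NodeSpec]
    W: np.ndarray
    alpha: np.ndarray | None = None
    epsilon: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.nodes)
        names = [nd.name for nd in self.nodes]
        if len(set(names)) != n:
            raise ValueError("node names must be unique")
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}, got {self.W.shape}")
        if self.alpha is None:
            self.alpha = np.ones(n)
        if self.epsilon is None:
            self.epsilon = np.ones(n)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.alpha.shape != (n,) or self.epsilon.shape != (n,):
            raise ValueError("alpha and epsilon must be length-N vectors")
        if np.any(self.alpha <= 0) or np.any(self.epsilon <= 0):
            raise ValueError("alpha and epsilon must be strictly positive")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("self-interactions are forbidden (diagonal of W must be 0)")
        act = [i for i, nd in enumerate(self.nodes) if nd.role == NodeRole.ACTIVITY]
        if act and np.any(self.W[act, :] != 0):
            raise ValueError("activity nodes may not have upstream regulators (rows must be 0)")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_names(self) -> list[str]:
        return [nd.name for nd in self.nodes]

    def node_index(self, name: str) -> int:
        return self.node_names.index(name)

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            nodes=list(self.nodes),
            W=self.W.copy(),
            alpha=self.alpha.copy(),
            epsilon=self.epsilon.copy(),
        )

    def n_edges(self) -> int:
        return int(np.count_nonzero(self.W))

    # --- serialization -----------------------------------------------------

    def to_dict(self, **metadata) -> dict:
        return {
            "nodes": [{"name": nd.name, "role": nd.role.value} for nd in self.nodes],
            "W": self.W.tolist(),
            "alpha": self.alpha.tolist(),
            "epsilon": self.epsilon.tolist(),
            "metadata": metadata,
        }

    def to_json(self, path, **metadata) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(**metadata), fh, indent=1)

    @classmethod
    def from_dict(cls, doc: dict) -> "NetworkModel":
        nodes = [NodeSpec(d["name"], NodeRole(d["role"])) for d in doc["nodes"]]
        return cls(
            nodes=nodes,
            W=np.array(doc["W"], dtype=float),
            alpha=np.array(doc["alpha"], dtype=float),
            epsilon=np.array(doc["epsilon"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "NetworkModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PerturbationDataset:
    """Paired response matrix X* (N x M log2-ratios) and perturbation matrix U
    (N x M external forces), plus node roles and condition labels.

    ``clamp_mask[i, mu]`` marks nodes held fixed during condition ``mu``
    (genetic-alteration-style perturbations); clamped nodes do not contribute
    a model equation in that condition.
    """

    nodes: list[NodeSpec]
    X_star: np.ndarray
    U: np.ndarray
    condition_labels: list[str] | None = None
    clamp_mask: np.ndarray | None = None
    excluded_conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X_star = np.asarray(self.X_star, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        n = len(self.nodes)
        if self.X_star.ndim != 2 or self.X_star.shape[0] != n:
            raise ValueError("X_star must be N x M")
        if self.U.shape != self.X_star.shape:
            raise ValueError("U must have the same shape as X_star")
        if not (np.all(np.isfinite(self.X_star)) and np.all(np.isfinite(self.U))):
            raise ValueError("all dataset entries must be finite")
        m = self.X_star.shape[1]
        if self.condition_labels is None:
            self.condition_labels = [f"c{k}" for k in range(m)]
        if len(self.condition_labels) != m:
            raise ValueError("condition_labels length must match number of columns")
        if self.clamp_mask is None:
            self.clamp_mask = np.zeros((n, m), dtype=bool)
        self.clamp_mask = np.asarray(self.clamp_mask, dtype=bool)
        if self.clamp_mask.shape != (n, m):
            raise ValueError("clamp_mask must be N x M")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_conditions(self) -> int:
        return self.X_star.shape[1]

    @property
    def node_names(self) -> list[str]:
        return [nd.name for nd in self.nodes]

    def subset_conditions(self, cols: Sequence[int]) -> "PerturbationDataset":
        cols = list(cols)
        return PerturbationDataset(
            nodes=list(self.nodes),
            X_star=self.X_star[:, cols],
            U=self.U[:, cols],
            condition_labels=[self.condition_labels[c] for c in cols],
            clamp_mask=self.clamp_mask[:, cols],
        )


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # T x N
    converged: bool
    oscillatory: bool

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def rhs_eval(model: NetworkModel, x: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Time derivative dx/dt = eps*tanh(W x + u) - alpha*x."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    n = model.n_nodes
    if x.shape != (n,) or u.shape != (n,):
        raise ValueError(f"x and u must be length-{n} vectors")
    return model.epsilon * np.tanh(model.W @ x + u) - model.alpha * x


def simulate_to_steady_state(
    model: NetworkModel,
    u: np.ndarray,
    clamp: Mapping[str | int, float] | None = None,
    x0: np.ndarray | None = None,
    tol: float = 1e-8,
    t_max: float = 1e4,
) -> Trajectory:
    """Integrate the model under constant force ``u`` until max|dx/dt| < tol.

    Clamped nodes (by name or index) are held at their fixed values
    throughout: their derivative is zeroed, which models genetic-style
    perturbations.  A trajectory that reaches ``t_max`` unconverged is flagged
    oscillatory when the state amplitude over the last 10% of the run exceeds
    10*tol.
    """
    from scipy.integrate import solve_ivp

    if tol <= 0:
        raise ValueError("tol must be positive")
    n = model.n_nodes
    u = np.asarray(u, dtype=float)
    if u.shape != (n,):
        raise ValueError(f"u must be a length-{n} vector")
    clamp_idx = np.array([], dtype=int)
    clamp_val = np.array([], dtype=float)
    if clamp:
        idx, val = [], []
        for key, v in clamp.items():
            idx.append(model.node_index(key) if isinstance(key, str) else int(key))
            val.append(float(v))
        clamp_idx = np.array(idx, dtype=int)
        clamp_val = np.array(val, dtype=float)

    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    if clamp_idx.size:
        x[clamp_idx] = clamp_val

    W, alpha, eps = model.W, model.alpha, model.epsilon

    def rhs(_t, y):
        dy = eps * np.tanh(W @ y + u) - alpha * y
        if clamp_idx.size:
            dy[clamp_idx] = 0.0
        return dy

    times = [0.0]
    states = [x.copy()]
    t, window = 0.0, 20.0
    converged = False
    while t < t_max:
        t_end = min(t + window, t_max)
        sol = solve_ivp(rhs, (t, t_end), x, method="LSODA", rtol=1e-9, atol=1e-10,
                        dense_output=False)
        if not sol.success:  # pragma: no cover - integrator failure is exceptional
            break
        times.extend(sol.t[1:].tolist())
        states.extend(sol.y.T[1:])
        x = sol.y[:, -1].copy()
        t = sol.t[-1]
        if np.max(np.abs(rhs(t, x))) < tol:
            converged = True
            break
        window = min(window * 2, t_max / 4)

    times_arr = np.array(times)
    states_arr = np.array(states)
    oscillatory = False
    if not converged:
        tail = times_arr >= times_arr[-1] - 0.1 * (times_arr[-1] - times_arr[0])
        amp = np.max(states_arr[tail].max(axis=0) - states_arr[tail].min(axis=0))
        oscillatory = bool(amp > 10 * tol)
    return Trajectory(times=times_arr, states=states_arr,
                      converged=converged, oscillatory=oscillatory)


def predict_steady_state_decoupled(
    model: NetworkModel, x_star_column: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Decoupled steady-state prediction x_hat_i = tanh(sum_j w_ij x*_j + u_i).

    Observed neighbor values replace the self-consistent solution, so each row
    of W constrains its target node independently.  Assumes alpha = eps = 1
    (the inference stage's convention).
    """
    x_star = np.asarray(x_star_column, dtype=float)
    u = np.asarray(u, dtype=float)
    n = model.n_nodes
    if x_star.shape != (n,) or u.shape != (n,):
        raise ValueError(f"x_star_column and u must be length-{n} vectors")
    return np.tanh(model.W @ x_star + u)


@dataclass(frozen=True)
class CostConfig:
    """Weights of the configuration cost: ``error_weight`` multiplies the
    summed squared steady-state residuals (the inverse temperature of the
    probability model) and ``complexity_weight`` is the L0 penalty per nonzero
    edge."""

    error_weight: float = 2.0
    complexity_weight: float = 5.0

    def __post_init__(self) -> None:
        if self.error_weight <= 0 or self.complexity_weight < 0:
            raise ValueError("cost weights must be positive")


def model_cost(model: NetworkModel, data: PerturbationDataset, cfg: CostConfig) -> float:
    """Error-plus-complexity cost of a configuration W on a dataset.

    C = error_weight * sum_{i,mu} (x_hat_i^mu - x*_i^mu)^2
        + complexity_weight * #{(i,j): i != j, w_ij != 0}

    using the decoupled steady-state predictions; clamped (i, mu) cells are
    excluded from the error sum.
    """
    X_hat = np.tanh(model.W @ data.X_star + data.U)
    resid2 = (X_hat - data.X_star) ** 2
    resid2[data.clamp_mask] = 0.0
    off_diag = ~np.eye(model.n_nodes, dtype=bool)
    n_edges = int(np.count_nonzero(model.W[off_diag]))
    return float(cfg.error_weight * resid2.sum() + cfg.complexity_weight * n_edges)


def encode_activity_node(
    residual_fraction: float, alpha: float = 1.0, epsilon: float = 1.0
) -> tuple[float, float]:
    """Encode a drug's effect on an unmeasured target activity.

    Given the treated/untreated ratio of a presumed downstream effector
    (e.g. 0.55 for 55% residual phosphorylation), the drug's force is
    u = log2(ratio) and the activity-node response is x = (eps/alpha)*tanh(u).
    """
    if residual_fraction <= 0:
        raise ValueError("residual_fraction must be positive")
    u = math.log2(residual_fraction)
    x = (epsilon / alpha) * math.tanh(u)
    return u, x
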