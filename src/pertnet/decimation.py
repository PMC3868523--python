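"""BP-guided decimation: instantiate explicit discrete models from marginals.

Decimation alternates two moves: sample an (edge, value) pair with probability
proportional to its marginal mass and pin it to a delta distribution; then
re-run BP (warm-started) so the remaining marginals adapt to the fixed choice.
Repeating until every free parameter is pinned yields one explicit interaction
matrix; repeating with different seeds yields an ensemble of distinct models.
Because rows of W are decoupled, decimation proceeds row by row — an exact
factorization of the joint sampling process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bp_engine import BeliefState, BPConfig, MarginalSet, ValueGrid, init_belief_state, run_bp
from .core_model import NetworkModel, PerturbationDataset, simulate_to_steady_state

__all__ = [
    "DecimationTrace",
    "ModelEnsemble",
    "decimation_step",
    "instantiate_model",
    "generate_ensemble",
    "ensemble_train_error",
]


@dataclass
class DecimationTrace:
    """Order in which edges were fixed, the value chosen for each, and the
    number of BP sweeps needed to re-converge after each fix."""

    order: list[tuple[int, int, float]] = field(default_factory=list)
    bp_reconvergence_sweeps: list[int] = field(default_factory=list)
    seed: int = 0
    flagged: bool = False  # BP failed to reconverge at some point


@dataclass
class ModelEnsemble:
    """A ranked collection of instantiated (optionally refined) models."""

    models: list[NetworkModel]
    train_errors: list[float]
    traces: list[DecimationTrace]
    ranked: bool = False

    def __len__(self) -> int:
        return len(self.models)

    def rank_and_keep(self, n_keep: int) -> "ModelEnsemble":
        order = np.argsort(self.train_errors, kind="stable")[:n_keep]
        return ModelEnsemble(
            models=[self.models[i] for i in order],
            train_errors=[self.train_errors[i] for i in order],
            traces=[self.traces[i] for i in order],
            ranked=True,
        )


def decimation_step(
    marginals: MarginalSet,
    state: BeliefState,
    rng: np.random.Generator,
    rows: list[int] | None = None,
) -> tuple[tuple[int, int], float, BeliefState]:
    """Sample one (edge, value) pair proportional to marginal mass and freeze
    it.  Returns the chosen edge, its value, and the updated state."""
    free = ~state.frozen
    if rows is not None:
        mask = np.zeros_like(free)
        mask[rows, :] = True
        free = free & mask
    if not free.any():
        raise ValueError("no unfrozen edges remain")
    weights = np.where(free[:, :, None], marginals.P, 0.0).ravel()
    total = weights.sum()
    if total <= 0:  # degenerate marginals: fall back to uniform over free values
        weights = np.where(free[:, :, None], 1.0, 0.0).ravel()
        total = weights.sum()
    flat = rng.choice(weights.size, p=weights / total)
    k = state.grid.K
    i, j, k_idx = np.unravel_index(flat, (state.n_nodes, state.n_nodes, k))
    new_state = state.copy()
    new_state.freeze_edge(int(i), int(j), int(k_idx))
    return (int(i), int(j)), float(state.grid.values[k_idx]), new_state


def instantiate_model(
    data: PerturbationDataset,
    grid: ValueGrid,
    cfg: BPConfig,
    seed: int,
    initial: BeliefState | None = None,
    rescue_damping: float = 0.5,
) -> tuple[NetworkModel, DecimationTrace]:
    """Decimate every free parameter of every row, re-running BP to full
    tolerance (warm-started) after each fix.  The returned model carries the
    discrete W with alpha = eps = 1."""
    cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(seed)
    state = (initial.copy() if initial is not None
             else init_belief_state(data, grid, cfg.seed))
    trace = DecimationTrace(seed=seed)
    n = data.n_nodes

    for i in range(n):
        if state.frozen[i].all():
            continue
        marginals, state = run_bp(data, grid, cfg, initial=state, rows=[i])
        while not state.frozen[i].all():
            (ri, rj), omega, state = decimation_step(marginals, state, rng, rows=[i])
            trace.order.append((ri, rj, omega))
            marginals, state = run_bp(data, grid, cfg, initial=state, rows=[i])
            if not marginals.converged and cfg.damping < rescue_damping:
                retry = replace(cfg, damping=rescue_damping)
                marginals, state = run_bp(data, grid, retry, initial=state, rows=[i])
                if not marginals.converged:
                    trace.flagged = True
            trace.bp_reconvergence_sweeps.append(marginals.sweeps_used)

    W = np.where(state.frozen_idx >= 0, grid.values[state.frozen_idx], 0.0)
    np.fill_diagonal(W, 0.0)
    model = NetworkModel(nodes=list(data.nodes), W=W)
    return model, trace


def _simulated_train_error(
    model: NetworkModel, data: PerturbationDataset, sim_tol: float = 1e-8
) -> float:
    """Summed squared error between fully-coupled simulated steady states and
    the observed responses, over measured cells; infinite when any condition
    fails to converge."""
    err = 0.0
    for mu in range(data.n_conditions):
        clamp = {
            int(i): float(data.X_star[i, mu])
            for i in np.nonzero(data.clamp_mask[:, mu])[0]
        }
        traj = simulate_to_steady_state(model, data.U[:, mu], clamp=clamp or None,
                                        tol=sim_tol)
        if not traj.converged:
            return float("inf")
        resid = traj.final_state - data.X_star[:, mu]
        resid[data.clamp_mask[:, mu]] = 0.0
        err += float(resid @ resid)
    return err


def ensemble_train_error(model: NetworkModel, data: PerturbationDataset) -> float:
    return _simulated_train_error(model, data)


def generate_ensemble(
    data: PerturbationDataset,
    grid: ValueGrid,
    cfg: BPConfig,
    n_generate: int,
    n_keep: int,
    refine: bool = False,
    refine_config=None,
    initial: BeliefState | None = None,
) -> ModelEnsemble:
    """Instantiate ``n_generate`` models with distinct seeds, optionally
    refine each by gradient descent, rank by simulated training error and keep
    the best ``n_keep``.  Seeds are ``cfg.seed + 1..n_generate`` so the result
    is independent of any parallel execution order."""
    if n_keep > n_generate:
        raise ValueError("n_keep must be <= n_generate")
    models, errors, traces = [], [], []
    for r in range(n_generate):
        seed = int(cfg.seed) + 1 + r
        model, trace = instantiate_model(data, grid, cfg, seed=seed, initial=initial)
        if refine:
            from .refine_gd import RefinementConfig, refine_model

            rcfg = refine_config or RefinementConfig()
            model, err = refine_model(model, data, rcfg)
        else:
            err = _simulated_train_error(model, data)
        models.append(model)
        errors.append(err)
        traces.append(trace)
    ens = ModelEnsemble(models=models, train_errors=errors, traces=traces)
    return ens.rank_and_keep(n_keep)
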