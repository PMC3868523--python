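"""Metropolis Monte Carlo search over discrete interaction configurations.

The baseline against which BP is compared: configurations W on the value grid
are explored by single-entry proposals under the error-plus-complexity cost,
with Metropolis acceptance min(1, exp(-dC/T)).  At T = 1 the chain samples the
same Boltzmann distribution whose marginals BP approximates, so thinned
samples provide empirical per-edge value frequencies for cross-checks.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .bp_engine import MarginalSet, ValueGrid
from .core_model import NodeRole, PerturbationDataset

__all__ = ["MCConfig", "MCResult", "mc_search", "mc_marginals",
           "mc_result_to_ensemble"]


@dataclass(frozen=True)
class MCConfig:
    grid: ValueGrid
    temperature: float = 1.0
    max_steps: int = 50_000
    plateau_window: int = 5_000  # stop when the running minimum stalls this long
    burn_in: int = 1_000
    thin: int = 50
    n_chains: int = 1
    n_best: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class MCResult:
    best_indices: list[np.ndarray]  # grid-index matrices, lowest cost first
    best_costs: list[float]
    cost_traces: list[np.ndarray]
    retained: list[np.ndarray]  # thinned post-burn-in samples (grid indices)
    grid: ValueGrid
    free_mask: np.ndarray
    wall_time: float = 0.0


def _config_cost(
    idx: np.ndarray,
    grid: ValueGrid,
    data: PerturbationDataset,
    error_weight: float,
    complexity_weight: float,
) -> float:
    W = grid.values[idx]
    X_hat = np.tanh(W @ data.X_star + data.U)
    resid2 = (X_hat - data.X_star) ** 2
    resid2[data.clamp_mask] = 0.0
    n_edges = int(np.count_nonzero(W)) - int(np.count_nonzero(np.diag(W)))
    return float(error_weight * resid2.sum() + complexity_weight * n_edges)


def _free_mask(data: PerturbationDataset) -> np.ndarray:
    n = data.n_nodes
    mask = ~np.eye(n, dtype=bool)
    for i, nd in enumerate(data.nodes):
        if nd.role == NodeRole.ACTIVITY:
            mask[i, :] = False
    return mask


def mc_search(
    data: PerturbationDataset,
    cfg: MCConfig,
    error_weight: float = 2.0,
    complexity_weight: float = 5.0,
    downhill_only: bool = False,
) -> MCResult:
    """Run seeded Metropolis chains over the discrete configuration space.

    Each proposal changes a single free entry to a random grid value; higher
    cost moves are accepted with probability exp(-dC/T) (never, when
    ``downhill_only``).  A chain terminates at ``max_steps`` or when its
    running-minimum cost has not improved for ``plateau_window`` proposals.
    Multi-chain runs are concatenations of single chains with consecutive
    seeds.
    """
    t0 = time.perf_counter()
    grid = cfg.grid
    free = _free_mask(data)
    free_ij = np.argwhere(free)
    zero_k = grid.zero_index

    best: list[tuple[float, np.ndarray]] = []
    traces: list[np.ndarray] = []
    retained: list[np.ndarray] = []

    for chain in range(cfg.n_chains):
        rng = np.random.default_rng(cfg.seed + chain)
        idx = np.full((data.n_nodes, data.n_nodes), zero_k, dtype=int)
        for i, j in free_ij:
            idx[i, j] = rng.integers(grid.K)
        cost = _config_cost(idx, grid, data, error_weight, complexity_weight)
        trace = [cost]
        run_min, since_improve = cost, 0
        for step in range(cfg.max_steps):
            pick = free_ij[rng.integers(len(free_ij))]
            i, j = int(pick[0]), int(pick[1])
            old_k = idx[i, j]
            new_k = int(rng.integers(grid.K))
            if new_k == old_k:
                trace.append(cost)
                continue
            idx[i, j] = new_k
            new_cost = _config_cost(idx, grid, data, error_weight, complexity_weight)
            dC = new_cost - cost
            if dC <= 0 or (
                not downhill_only and rng.random() < np.exp(-dC / cfg.temperature)
            ):
                cost = new_cost
            else:
                idx[i, j] = old_k
            trace.append(cost)
            if cost < run_min - 1e-12:
                run_min, since_improve = cost, 0
            else:
                since_improve += 1
                if since_improve >= cfg.plateau_window:
                    break
            if step >= cfg.burn_in and step % cfg.thin == 0:
                retained.append(idx.copy())
            if len(best) < cfg.n_best or cost <= best[-1][0]:
                best.append((cost, idx.copy()))
                best = _dedup_best(best, cfg.n_best)
        traces.append(np.array(trace))

    best = _dedup_best(best, cfg.n_best)
    if not retained:  # very short chains: retain the best configurations
        retained = [b for _, b in best]
    return MCResult(
        best_indices=[b for _, b in best],
        best_costs=[c for c, _ in best],
        cost_traces=traces,
        retained=retained,
        grid=grid,
        free_mask=free,
        wall_time=time.perf_counter() - t0,
    )


def _dedup_best(best: list[tuple[float, np.ndarray]], n: int) -> list[tuple[float, np.ndarray]]:
    seen = set()
    out = []
    for cost, idx in sorted(best, key=lambda b: b[0]):
        key = idx.tobytes()
        if key not in seen:
            seen.add(key)
            out.append((cost, idx))
        if len(out) == n:
            break
    return out


def mc_result_to_ensemble(result: MCResult, data: PerturbationDataset):
    """Package the best MC configurations as a ModelEnsemble so they share
    the decimation ensemble's directory layout and evaluation tooling."""
    from .core_model import NetworkModel
    from .decimation import DecimationTrace, ModelEnsemble

    models = [
        NetworkModel(nodes=list(data.nodes), W=result.grid.values[idx])
        for idx in result.best_indices
    ]
    traces = [DecimationTrace(seed=k) for k in range(len(models))]
    return ModelEnsemble(models=models, train_errors=list(result.best_costs),
                         traces=traces, ranked=True)


def mc_marginals(result: MCResult, use_retained: bool = True) -> MarginalSet:
    """Empirical per-edge value frequencies across the retained (or best)
    configurations, as a MarginalSet compatible with the BP output."""
    samples = result.retained if use_retained else result.best_indices
    if not samples:
        raise ValueError("no retained configurations")
    n = samples[0].shape[0]
    k = result.grid.K
    P = np.zeros((n, n, k))
    flat = np.stack(samples)  # (S, N, N)
    for kk in range(k):
        P[:, :, kk] = (flat == kk).mean(axis=0)
    return MarginalSet(grid=result.grid, P=P, converged=True, sweeps_used=len(samples))
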