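"""Standard benchmark protocols on synthetic generators.

Three protocols recur throughout the validation of the method and are fixed
here so that tests, examples and reports all run the same experiment:

* ``ideal_recovery_benchmark`` — near-perfect inference from maximally
  informative (dense randomized) noise-free perturbations of a small
  generator; the regime in which BP should recover essentially every
  detectable edge with no false positives.
* ``drug_panel_benchmark`` — biologically realistic conditions: a motif-rich
  generator probed by a panel of in silico drugs applied singly and in pairs,
  scored by recall/precision of the thresholded BP average network.
* ``parameter_correlation_benchmark`` — generators of increasing size, each
  trained with as many perturbation patterns as nodes; pooled Pearson
  correlation between BP mean parameters and the true nonzero parameters.

A timing harness compares BP and Monte Carlo wall-clock convergence; its
numbers are reported, never asserted (they are hardware-dependent).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .bp_engine import BPConfig, make_value_grid, run_bp
from .evaluation import marginal_average_network, recall_precision
from .mc_baseline import MCConfig, mc_search
from .synthetic_data import (
    DrugPanelSpec,
    TopologySpec,
    design_insilico_perturbations,
    generate_topology,
    random_rich_perturbations,
    simulate_response_profiles,
)

__all__ = [
    "RecoveryResult",
    "BenchmarkResult",
    "ideal_recovery_benchmark",
    "drug_panel_benchmark",
    "parameter_correlation_benchmark",
    "knockdown_design",
    "bp_vs_mc_timing",
]

# Toy-benchmark operating point: the 41-value grid on [-2, 2] matches the
# toy-data parameter space; beta/lambda were fixed once with the
# connectivity-targeting selection procedure (~1.5 edges per node) on a
# reference toy dataset.
TOY_GRID = (-2.0, 2.0, 0.1)
TOY_BETA = 2.0
TOY_LAMBDA = 3.0


@dataclass
class RecoveryResult:
    seed: int
    n_true_edges: int
    n_missed: int
    n_false_positives: int
    recall: float
    precision: float
    sub_threshold_true_edges: int


@dataclass
class BenchmarkResult:
    recalls: list[float] = field(default_factory=list)
    precisions: list[float] = field(default_factory=list)
    details: list = field(default_factory=list)

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recalls))

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precisions))


def _detectable_generator(
    n_nodes: int, n_edges: int, seed: int, max_weak: int = 2, weak_cut: float = 0.25
):
    """Draw a generator whose edge weights are essentially all detectable at
    the standard 0.2 call threshold: at most ``max_weak`` edges below the
    cut.  Deterministic given ``seed`` (the draw is retried with an offset
    until the detectability profile holds), emulating benchmark networks
    whose interactions are meant to be recoverable in the ideal-data regime.
    """
    for attempt in range(100):
        topo = TopologySpec(n_nodes=n_nodes, n_edges=n_edges, seed=seed + 1000 * attempt)
        gen = generate_topology(topo)
        weights = np.abs(gen.W[gen.W != 0])
        if int((weights < weak_cut).sum()) <= max_weak:
            return gen
    raise RuntimeError("could not draw a detectable generator")  # pragma: no cover


def ideal_recovery_benchmark(
    seeds=(1, 2, 3),
    n_nodes: int = 10,
    n_edges: int = 15,
    patterns_per_node: int = 12,
    perturbation_strength: float = 2.0,
    threshold: float = 0.2,
) -> list[RecoveryResult]:
    """Noise-free recovery from dense randomized perturbations.

    Each seed draws a 1.5-edges-per-node generator, simulates
    ``patterns_per_node * N`` fully randomized perturbation patterns, runs BP
    at the toy operating point and scores the thresholded mean-of-marginal
    matrix against the generator.
    """
    grid = make_value_grid(*TOY_GRID)
    out = []
    for seed in seeds:
        gen = _detectable_generator(n_nodes, n_edges, seed)
        design = random_rich_perturbations(
            gen, n_patterns=patterns_per_node * n_nodes,
            strength=perturbation_strength, seed=seed + 100,
        )
        data = simulate_response_profiles(gen, design)
        cfg = BPConfig(beta=TOY_BETA, lam=TOY_LAMBDA, seed=seed)
        marginals, _ = run_bp(data, grid, cfg)
        report = recall_precision(marginal_average_network(marginals), gen, threshold)
        weights = np.abs(gen.W[gen.W != 0])
        out.append(
            RecoveryResult(
                seed=seed,
                n_true_edges=gen.n_edges(),
                n_missed=len(report.false_negatives),
                n_false_positives=len(report.false_positives),
                recall=report.recall,
                precision=report.precision,
                sub_threshold_true_edges=int((weights < threshold).sum()),
            )
        )
    return out


def drug_panel_benchmark(
    seeds=(1, 2, 3),
    n_nodes: int = 20,
    n_edges: int = 60,
    n_drugs: int = 14,
    known_off_targets: bool = True,
    noise_cv: float = 0.0,
    threshold: float = 0.2,
    grid_step: float = 0.4,
    main_target_strength: float = 2.0,
    n_restarts: int = 5,
) -> BenchmarkResult:
    """Recall/precision of the thresholded BP average network under sparse,
    drug-like perturbations (singles + all pairs, off-target effects).

    The 11-value grid on [-2, 2] spans the generator weight range; drugs
    inhibit their main target strongly (u = -2, a 75% knockdown).  Because
    the posterior in this data-limited regime is multimodal and a single BP
    run commits to one mode, the marginals of ``n_restarts`` seeded runs are
    averaged (a uniform mode mixture) before thresholding.  Oscillating
    conditions are dropped before inference, as in the data-generation
    protocol.
    """
    from .bp_engine import MarginalSet
    from .synthetic_data import NoiseSpec, add_measurement_noise

    grid = make_value_grid(-2.0, 2.0, grid_step)
    result = BenchmarkResult()
    for seed in seeds:
        gen = generate_topology(
            TopologySpec(n_nodes=n_nodes, n_edges=n_edges, seed=seed)
        )
        panel = DrugPanelSpec(n_drugs=n_drugs, seed=seed + 50,
                              main_target_strength=main_target_strength)
        design = design_insilico_perturbations(
            gen, panel, pairing="singles+pairs", known_off_targets=known_off_targets
        )
        data = simulate_response_profiles(gen, design)
        if noise_cv > 0:
            data.X_star = add_measurement_noise(
                data.X_star, NoiseSpec(cv=noise_cv, seed=seed + 200)
            )
        stack = []
        for r in range(n_restarts):
            cfg = BPConfig(beta=TOY_BETA, lam=TOY_LAMBDA, seed=seed + 1000 * r)
            ms, _ = run_bp(data, grid, cfg)
            stack.append(ms.P)
        marginals = MarginalSet(grid=grid, P=np.mean(stack, axis=0))
        report = recall_precision(marginal_average_network(marginals), gen, threshold)
        result.recalls.append(report.recall)
        result.precisions.append(report.precision)
        result.details.append(
            {
                "seed": seed,
                "n_conditions": data.n_conditions,
                "n_excluded": len(data.excluded_conditions),
                "n_missed": len(report.false_negatives),
                "n_false_positives": len(report.false_positives),
            }
        )
    return result


def knockdown_design(model, strength: float = 1.0):
    """One perturbation pattern per node: an inhibitory force u = -strength
    applied to each node in turn (M = N training patterns)."""
    from .synthetic_data import PerturbationDesign

    n = model.n_nodes
    U = -strength * np.eye(n)
    return PerturbationDesign(
        nodes=list(model.nodes),
        U_applied=U,
        U_observed=U.copy(),
        condition_labels=[f"kd{j}" for j in range(n)],
        condition_drugs=[() for _ in range(n)],
        condition_doses=[1.0] * n,
    )


def parameter_correlation_benchmark(
    sizes=(10, 20, 30, 40),
    edges_per_node: float = 1.5,
    seed: int = 0,
) -> dict:
    """Pooled correlation between BP mean parameters and true nonzero
    parameters, for generators of increasing size trained with M = N
    patterns over the 41-value grid.

    The M = N patterns are single-node knockdowns (one inhibitory force per
    node) and BP runs at the default operating point (beta = 2, lambda = 5):
    a deliberately data-limited regime, in contrast to the ideal-data
    recovery benchmark."""
    grid = make_value_grid(*TOY_GRID)
    true_vals, inferred_vals = [], []
    per_size = {}
    for idx, n in enumerate(sizes):
        gen_seed = seed + 10 * idx
        gen = generate_topology(
            TopologySpec(n_nodes=n, n_edges=int(round(edges_per_node * n)),
                         seed=gen_seed)
        )
        design = knockdown_design(gen)
        data = simulate_response_profiles(gen, design)
        cfg = BPConfig(seed=gen_seed + 2)
        marginals, _ = run_bp(data, grid, cfg)
        mean_W = marginals.mean_matrix()
        mask = gen.W != 0
        true_vals.extend(gen.W[mask].tolist())
        inferred_vals.extend(mean_W[mask].tolist())
        per_size[n] = float(np.corrcoef(gen.W[mask], mean_W[mask])[0, 1])
    pooled = float(np.corrcoef(true_vals, inferred_vals)[0, 1])
    return {"pooled_correlation": pooled, "per_size": per_size,
            "n_points": len(true_vals)}


def bp_vs_mc_timing(
    n_nodes: int = 10,
    n_edges: int = 15,
    seed: int = 0,
    mc_steps: int = 20_000,
) -> dict:
    """Wall-clock comparison of BP convergence against a Monte Carlo search
    on the same dataset and grid.  Reported for information only: the
    numbers depend on hardware and termination settings."""
    gen = generate_topology(TopologySpec(n_nodes=n_nodes, n_edges=n_edges, seed=seed))
    design = random_rich_perturbations(gen, n_patterns=n_nodes, strength=2.0,
                                       seed=seed + 1)
    data = simulate_response_profiles(gen, design)
    grid = make_value_grid(-2.0, 2.0, 0.4)

    t0 = time.perf_counter()
    marginals, _ = run_bp(data, grid, BPConfig(beta=TOY_BETA, lam=TOY_LAMBDA, seed=seed))
    bp_time = time.perf_counter() - t0

    mc_cfg = MCConfig(grid=grid, temperature=1.0, max_steps=mc_steps, seed=seed)
    result = mc_search(data, mc_cfg, error_weight=TOY_BETA, complexity_weight=TOY_LAMBDA)
    return {
        "bp_seconds": bp_time,
        "bp_sweeps": marginals.sweeps_used,
        "mc_seconds": result.wall_time,
        "mc_steps": int(sum(len(t) for t in result.cost_traces)),
        "speed_ratio_mc_over_bp": result.wall_time / max(bp_time, 1e-9),
    }
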