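"""Toy-network generation and in silico perturbation experiments.

These generators emulate the benchmark conditions used to validate the
inference engine: cascade-like hierarchical topologies containing common
signaling motifs (parallel chains, feed-forward, feedback, multiple-input),
drug panels with a strongly inhibited main target plus a few weaker off-target
effects, deterministic steady-state simulation of response profiles with
oscillating conditions excluded, and multiplicative Gaussian measurement noise
parameterized by a coefficient of variation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    NetworkModel,
    NodeRole,
    NodeSpec,
    PerturbationDataset,
    simulate_to_steady_state,
)

__all__ = [
    "TopologySpec",
    "DrugPanelSpec",
    "NoiseSpec",
    "DrugSpec",
    "PerturbationDesign",
    "generate_topology",
    "design_insilico_perturbations",
    "random_rich_perturbations",
    "simulate_response_profiles",
    "add_measurement_noise",
    "motif_census",
]

_DEFAULT_MOTIF_MIX = {
    "serial": 1.0,
    "parallel": 1.0,
    "feed_forward": 1.0,
    "feedback": 1.0,
    "multi_input": 1.0,
}


@dataclass(frozen=True)
class TopologySpec:
    """Specification of a cascade-like generator topology.

    Edge weights are signed, with magnitudes drawn uniformly from
    ``weight_magnitude_range`` (default (0, 2], the benchmark convention) and
    positive sign with probability ``sign_probability``.
    """

    n_nodes: int
    n_edges: int
    motif_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MOTIF_MIX))
    weight_magnitude_range: tuple[float, float] = (0.0, 2.0)
    sign_probability: float = 0.5
    n_phenotypes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise ValueError("n_edges exceeds the number of off-diagonal slots")
        lo, hi = self.weight_magnitude_range
        if not (0 <= lo < hi):
            raise ValueError("weight magnitudes must satisfy 0 <= lo < hi")


@dataclass(frozen=True)
class DrugPanelSpec:
    """An in silico drug panel: each drug strongly inhibits one main target
    (force -main_target_strength) and carries up to ``max_off_targets``
    weaker effects of random sign, with magnitudes a random fraction (drawn
    from ``off_target_strength_range``) of the main strength."""

    n_drugs: int
    main_target_strength: float = 1.0
    max_off_targets: int = 4
    off_target_strength_range: tuple[float, float] = (0.1, 0.5)
    dose_levels: tuple[float, ...] = (1.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_off_targets < 0:
            raise ValueError("max_off_targets must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise: multiplicative Gaussian with standard deviation
    ``cv`` (the coefficient of variation), x -> x * (1 + g)."""

    cv: float
    seed: int = 0
    mode: str = "multiplicative"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.mode not in ("multiplicative", "additive"):
            raise ValueError("mode must be 'multiplicative' or 'additive'")


def _layered_nodes(n: int, rng: np.random.Generator) -> list[list[int]]:
    n_layers = max(3, int(round(np.sqrt(n))))
    n_layers = min(n_layers, n)
    order = list(rng.permutation(n))
    layers: list[list[int]] = [[] for _ in range(n_layers)]
    for pos, node in enumerate(order):
        layers[pos % n_layers].append(int(node))
    return layers


def generate_topology(spec: TopologySpec) -> NetworkModel:
    """Build a motif-rich cascade generator with exactly ``n_edges`` signed
    edges and alpha = eps = 1.

    Nodes are arranged in layers; a forward backbone wires each node to the
    previous layer, then motifs (chosen by the mix weights) add edges until
    the budget is met: extra serial links, parallel routes, feed-forward
    shortcuts, feedback (reverse) edges and extra inputs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    layers = _layered_nodes(n, rng)
    layer_of = {}
    for li, members in enumerate(layers):
        for v in members:
            layer_of[v] = li

    edges: set[tuple[int, int]] = set()  # (source, target)

    def add_edge(s: int, t: int) -> bool:
        if s == t or (s, t) in edges:
            return False
        edges.add((s, t))
        return True

    # forward backbone: every non-root node receives one input from the
    # previous layer (trimmed if the edge budget is smaller)
    backbone = []
    for li in range(1, len(layers)):
        for v in layers[li]:
            backbone.append((int(rng.choice(layers[li - 1])), v))
    rng.shuffle(backbone)
    for s, t in backbone[: spec.n_edges]:
        add_edge(s, t)

    motif_names = list(spec.motif_mix)
    weights = np.array([spec.motif_mix[k] for k in motif_names], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(len(motif_names))
    weights = weights / weights.sum()

    def try_motif(name: str) -> bool:
        edge_list = list(edges)
        if name == "serial" and edge_list:
            # extend a chain: from a node with an input to a deeper layer
            for _ in range(10):
                s = int(rng.integers(n))
                cand = [v for v in range(n) if layer_of[v] > layer_of[s]]
                if cand and add_edge(s, int(rng.choice(cand))):
                    return True
        elif name == "parallel" and edge_list:
            # second route between the endpoints of an existing two-step path
            s, t = edge_list[int(rng.integers(len(edge_list)))]
            mids = [v for v in range(n) if v not in (s, t)]
            if mids:
                mid = int(rng.choice(mids))
                ok1 = add_edge(s, mid)
                ok2 = add_edge(mid, t)
                if ok1 or ok2:
                    return True
        elif name == "feed_forward" and edge_list:
            for _ in range(10):
                a, b = edge_list[int(rng.integers(len(edge_list)))]
                outs = [t for (s2, t) in edge_list if s2 == b]
                if outs and add_edge(a, int(rng.choice(outs))):
                    return True
        elif name == "feedback" and edge_list:
            for _ in range(10):
                a, b = edge_list[int(rng.integers(len(edge_list)))]
                if add_edge(b, a):
                    return True
        elif name == "multi_input":
            targets = [t for (_, t) in edge_list] or list(range(n))
            for _ in range(10):
                t = int(rng.choice(targets))
                s = int(rng.integers(n))
                if add_edge(s, t):
                    return True
        return False

    guard = 0
    while len(edges) < spec.n_edges and guard < 50 * spec.n_edges:
        guard += 1
        name = motif_names[int(rng.choice(len(motif_names), p=weights))]
        try_motif(name)
    # fill any remainder from free off-diagonal slots
    if len(edges) < spec.n_edges:
        free = [(s, t) for s in range(n) for t in range(n)
                if s != t and (s, t) not in edges]
        rng.shuffle(free)
        for s, t in free[: spec.n_edges - len(edges)]:
            edges.add((s, t))
    # trim overshoot from motif moves that added two edges
    if len(edges) > spec.n_edges:
        ordered = sorted(edges)
        rng.shuffle(ordered)
        edges = set(ordered[: spec.n_edges])

    lo, hi = spec.weight_magnitude_range
    W = np.zeros((n, n))
    for s, t in sorted(edges):
        mag = rng.uniform(lo, hi)
        while mag == 0.0:  # magnitudes live in (lo, hi]
            mag = rng.uniform(lo, hi)
        sign = 1.0 if rng.random() < spec.sign_probability else -1.0
        W[t, s] = sign * mag  # W[target, source]

    nodes = []
    pheno = set(range(n - spec.n_phenotypes, n))
    for v in range(n):
        role = NodeRole.PHENOTYPE if v in pheno else NodeRole.PROTEIN
        nodes.append(NodeSpec(name=f"n{v}", role=role))
    return NetworkModel(nodes=nodes, W=W)


def motif_census(model: NetworkModel) -> dict:
    """Count feedback loops (directed cycles) and feed-forward triples in the
    interaction graph — a small-subgraph scan used to check generator output."""
    import networkx as nx

    G = nx.DiGraph()
    G.add_nodes_from(range(model.n_nodes))
    tgt, src = np.nonzero(model.W)
    G.add_edges_from(zip(src.tolist(), tgt.tolist()))
    n_feedback = 0
    for _ in nx.simple_cycles(G):
        n_feedback += 1
        if n_feedback >= 1000:
            break
    n_ff = 0
    for a, b in G.edges():
        for c in G.successors(b):
            if c != a and G.has_edge(a, c):
                n_ff += 1
    return {"feedback_loops": n_feedback, "feed_forward": n_ff,
            "edges": int(np.count_nonzero(model.W))}


@dataclass(frozen=True)
class DrugSpec:
    name: str
    main_target: int
    off_targets: tuple[int, ...]
    off_forces: tuple[float, ...]
    main_force: float


@dataclass
class PerturbationDesign:
    """A designed panel of perturbation conditions.

    ``U_applied`` holds the true external forces (main plus off-target) used
    for data generation; ``U_observed`` is what the modeler is given — equal
    to ``U_applied`` when off-targets are known, otherwise main targets only.
    """

    nodes: list[NodeSpec]
    U_applied: np.ndarray
    U_observed: np.ndarray
    condition_labels: list[str]
    condition_drugs: list[tuple[str, ...]]
    condition_doses: list[float]
    drugs: list[DrugSpec] = field(default_factory=list)

    @property
    def n_conditions(self) -> int:
        return self.U_applied.shape[1]

    def drug_condition_map(self) -> dict[str, list[str]]:
        """Map each drug name to the labels of all conditions involving it."""
        out: dict[str, list[str]] = {d.name: [] for d in self.drugs}
        for label, names in zip(self.condition_labels, self.condition_drugs):
            for nm in names:
                if nm in out:
                    out[nm].append(label)
        return out


def design_insilico_perturbations(
    model: NetworkModel,
    panel: DrugPanelSpec,
    pairing: str = "singles+pairs",
    known_off_targets: bool = True,
) -> PerturbationDesign:
    """Assign drugs to distinct main targets and lay out the condition set.

    ``singles`` applies each drug alone at every dose level; ``singles+pairs``
    adds all drug pairs at the lowest dose (combination forces are element-wise
    sums of the single-drug vectors); ``random-higher-order`` replaces the
    pairs by random 3-to-5-drug combinations of equal count.
    """
    rng = np.random.default_rng(panel.seed)
    n = model.n_nodes
    candidates = [i for i, nd in enumerate(model.nodes)
                  if nd.role != NodeRole.PHENOTYPE]
    if panel.n_drugs > len(candidates):
        raise ValueError("not enough non-phenotype nodes for distinct main targets")
    mains = rng.choice(candidates, size=panel.n_drugs, replace=False)

    drugs = []
    for d, main in enumerate(mains):
        others = [i for i in candidates if i != main]
        n_off = int(rng.integers(0, panel.max_off_targets + 1))
        n_off = min(n_off, len(others))
        offs = rng.choice(others, size=n_off, replace=False) if n_off else np.array([], int)
        lo, hi = panel.off_target_strength_range
        mags = panel.main_target_strength * rng.uniform(lo, hi, size=n_off)
        signs = rng.choice([-1.0, 1.0], size=n_off)
        drugs.append(
            DrugSpec(
                name=f"d{d}",
                main_target=int(main),
                off_targets=tuple(int(o) for o in offs),
                off_forces=tuple(float(s * m) for s, m in zip(signs, mags)),
                main_force=-panel.main_target_strength,
            )
        )

    def drug_u(drug: DrugSpec, applied: bool) -> np.ndarray:
        u = np.zeros(n)
        u[drug.main_target] = drug.main_force
        if applied:
            for t, f in zip(drug.off_targets, drug.off_forces):
                u[t] += f
        return u

    cols_applied, cols_observed = [], []
    labels, cond_drugs, doses = [], [], []
    low_dose = min(panel.dose_levels)

    for dose in panel.dose_levels:
        for drug in drugs:
            cols_applied.append(dose * drug_u(drug, True))
            cols_observed.append(dose * drug_u(drug, known_off_targets))
            labels.append(f"{drug.name}@{dose:g}")
            cond_drugs.append((drug.name,))
            doses.append(float(dose))

    if pairing == "singles":
        pass
    elif pairing == "singles+pairs":
        for a, b in itertools.combinations(drugs, 2):
            cols_applied.append(low_dose * (drug_u(a, True) + drug_u(b, True)))
            cols_observed.append(
                low_dose * (drug_u(a, known_off_targets) + drug_u(b, known_off_targets))
            )
            labels.append(f"{a.name}+{b.name}")
            cond_drugs.append((a.name, b.name))
            doses.append(float(low_dose))
    elif pairing == "random-higher-order":
        n_combo = len(drugs) * (len(drugs) - 1) // 2
        for _ in range(n_combo):
            size = int(rng.integers(3, min(5, len(drugs)) + 1))
            chosen = rng.choice(len(drugs), size=size, replace=False)
            subset = [drugs[c] for c in chosen]
            cols_applied.append(low_dose * sum(drug_u(d, True) for d in subset))
            cols_observed.append(
                low_dose * sum(drug_u(d, known_off_targets) for d in subset)
            )
            labels.append("+".join(d.name for d in subset))
            cond_drugs.append(tuple(d.name for d in subset))
            doses.append(float(low_dose))
    else:
        raise ValueError(f"unknown pairing scheme: {pairing}")

    return PerturbationDesign(
        nodes=list(model.nodes),
        U_applied=np.column_stack(cols_applied),
        U_observed=np.column_stack(cols_observed),
        condition_labels=labels,
        condition_drugs=cond_drugs,
        condition_doses=doses,
        drugs=drugs,
    )


def random_rich_perturbations(
    model: NetworkModel, n_patterns: int, strength: float = 1.0, seed: int = 0
) -> PerturbationDesign:
    """Fully randomized perturbation patterns: every node receives an
    independent uniform force in [-strength, strength] in every condition —
    the information-rich regime in which inference is nearly exact."""
    rng = np.random.default_rng(seed)
    U = rng.uniform(-strength, strength, size=(model.n_nodes, n_patterns))
    labels = [f"r{k}" for k in range(n_patterns)]
    return PerturbationDesign(
        nodes=list(model.nodes),
        U_applied=U,
        U_observed=U.copy(),
        condition_labels=labels,
        condition_drugs=[() for _ in range(n_patterns)],
        condition_doses=[1.0] * n_patterns,
        drugs=[],
    )


def simulate_response_profiles(
    model: NetworkModel,
    design: PerturbationDesign,
    tol: float = 1e-8,
    t_max: float = 1e4,
) -> PerturbationDataset:
    """Simulate each condition to steady state and record the responses.

    Purely deterministic.  Conditions that oscillate (or otherwise fail to
    converge) are dropped from the dataset and listed in
    ``excluded_conditions``; X* and U stay column-aligned.
    """
    kept, excluded = [], []
    states = []
    for mu in range(design.n_conditions):
        traj = simulate_to_steady_state(model, design.U_applied[:, mu],
                                        tol=tol, t_max=t_max)
        if traj.converged:
            kept.append(mu)
            states.append(traj.final_state)
        else:
            excluded.append(design.condition_labels[mu])
    if not kept:
        raise RuntimeError("every condition oscillated; no training data produced")
    X = np.column_stack(states)
    ds = PerturbationDataset(
        nodes=list(design.nodes),
        X_star=X,
        U=design.U_observed[:, kept],
        condition_labels=[design.condition_labels[mu] for mu in kept],
        excluded_conditions=excluded,
    )
    return ds


def add_measurement_noise(X_star: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Apply Gaussian measurement noise, entrywise and seeded.

    Multiplicative mode (default): x -> x * (1 + g), g ~ N(0, cv), so cv is
    the coefficient of variation of the corrupted measurements."""
    rng = np.random.default_rng(noise.seed)
    g = rng.normal(0.0, noise.cv, size=np.shape(X_star))
    X = np.asarray(X_star, dtype=float)
    if noise.mode == "multiplicative":
        return X * (1.0 + g)
    return X + g
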