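"""Readers, writers and serialization for datasets, marginals, ensembles and
networks.

Datasets travel as a TSV trio (responses X*, forces U, node roles): tab
separated, UTF-8, header row of condition labels, first column of node names.
Models are JSON documents; average networks export to SIF and GraphML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bp_engine import MarginalSet, ValueGrid
from .core_model import NetworkModel, NodeRole, NodeSpec, PerturbationDataset
from .decimation import ModelEnsemble
from .evaluation import AverageNetwork

__all__ = [
    "read_perturbation_dataset",
    "write_perturbation_dataset",
    "write_marginals",
    "read_marginals",
    "write_ensemble",
    "read_ensemble",
    "export_network",
    "RunConfig",
]


def read_perturbation_dataset(x_path, u_path, roles_path) -> PerturbationDataset:
    """Load and validate the TSV trio (X*, U, roles).

    Node rows and condition columns must agree across the three files;
    misalignments and non-numeric cells are reported with the offending
    labels.
    """
    x_df = pd.read_csv(x_path, sep="\t", index_col=0)
    u_df = pd.read_csv(u_path, sep="\t", index_col=0)
    roles_df = pd.read_csv(roles_path, sep="\t", index_col=0)

    if x_df.index.duplicated().any():
        dupes = x_df.index[x_df.index.duplicated()].tolist()
        raise ValueError(f"duplicate node names in {x_path}: {dupes}")
    if list(x_df.index) != list(u_df.index):
        first = _first_mismatch(list(x_df.index), list(u_df.index))
        raise ValueError(f"node rows differ between X* and U (first mismatch: {first})")
    if list(x_df.columns) != list(u_df.columns):
        first = _first_mismatch(list(x_df.columns), list(u_df.columns))
        raise ValueError(f"condition columns differ between X* and U (first mismatch: {first})")
    if list(x_df.index) != list(roles_df.index):
        first = _first_mismatch(list(x_df.index), list(roles_df.index))
        raise ValueError(f"node rows differ between X* and roles (first mismatch: {first})")

    for name, df in (("X*", x_df), ("U", u_df)):
        bad = df.map(lambda v: not np.isfinite(pd.to_numeric(v, errors="coerce")))
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric or non-finite cell in {name} at "
                f"(node {df.index[i]!r}, condition {df.columns[j]!r})"
            )

    nodes = [
        NodeSpec(name=str(nm), role=NodeRole(str(r)))
        for nm, r in zip(roles_df.index, roles_df.iloc[:, 0])
    ]
    return PerturbationDataset(
        nodes=nodes,
        X_star=x_df.to_numpy(dtype=float),
        U=u_df.to_numpy(dtype=float),
        condition_labels=[str(c) for c in x_df.columns],
    )


def _first_mismatch(a: list, b: list):
    for k, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return f"position {k}: {x!r} vs {y!r}"
    return f"length {len(a)} vs {len(b)}"


def write_perturbation_dataset(
    data: PerturbationDataset, x_path, u_path, roles_path
) -> None:
    names = data.node_names
    pd.DataFrame(data.X_star, index=names, columns=data.condition_labels).to_csv(
        x_path, sep="\t"
    )
    pd.DataFrame(data.U, index=names, columns=data.condition_labels).to_csv(
        u_path, sep="\t"
    )
    pd.DataFrame(
        {"role": [nd.role.value for nd in data.nodes]}, index=names
    ).to_csv(roles_path, sep="\t")


def write_marginals(marginals: MarginalSet, path, node_names=None, fmt="tsv") -> None:
    """Export per-edge marginals: TSV with one row per (source, target) pair
    and columns for every grid probability plus mean and entropy, or JSON
    with the grid embedded."""
    from .bp_engine import marginal_entropy

    n = marginals.P.shape[0]
    names = list(node_names) if node_names else [f"n{i}" for i in range(n)]
    if fmt == "json":
        doc = {
            "grid": marginals.grid.values.tolist(),
            "node_names": names,
            "P": marginals.P.tolist(),
            "converged": marginals.converged,
            "sweeps_used": marginals.sweeps_used,
        }
        Path(path).write_text(json.dumps(doc))
        return
    mean = marginals.mean_matrix()
    ent = marginal_entropy(marginals)
    rows = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            row = {"source": names[j], "target": names[i]}
            for k, w in enumerate(marginals.grid.values):
                row[f"p[{w:g}]"] = marginals.P[i, j, k]
            row["mean"] = mean[i, j]
            row["entropy"] = ent[i, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_marginals(path) -> tuple[MarginalSet, list[str]]:
    doc = json.loads(Path(path).read_text())
    grid = ValueGrid(values=np.array(doc["grid"]))
    ms = MarginalSet(
        grid=grid,
        P=np.array(doc["P"]),
        converged=doc["converged"],
        sweeps_used=doc["sweeps_used"],
    )
    return ms, doc["node_names"]


def write_ensemble(ensemble: ModelEnsemble, directory) -> None:
    """One JSON model file per member plus a manifest TSV (rank, seed, train
    error, flags)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rank, (model, err, trace) in enumerate(
        zip(ensemble.models, ensemble.train_errors, ensemble.traces)
    ):
        fname = f"model_{rank:04d}.json"
        model.to_json(directory / fname, seed=trace.seed, rank=rank, train_error=err)
        rows.append(
            {
                "rank": rank,
                "file": fname,
                "seed": trace.seed,
                "train_error": err,
                "flagged": trace.flagged,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t", index=False)


def read_ensemble(directory) -> ModelEnsemble:
    from .decimation import DecimationTrace

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    models, errors, traces = [], [], []
    for _, row in manifest.iterrows():
        models.append(NetworkModel.from_json(directory / row["file"]))
        errors.append(float(row["train_error"]))
        traces.append(DecimationTrace(seed=int(row["seed"]), flagged=bool(row["flagged"])))
    return ModelEnsemble(models=models, train_errors=errors, traces=traces, ranked=True)


def export_network(
    avg: AverageNetwork, path, fmt: str = "sif", threshold: float = 0.0
) -> None:
    """Write an average network as SIF ("source activates|inhibits target")
    or GraphML with mean_weight and frequency edge attributes.  Edges with
    |mean weight| below the threshold are omitted; activity nodes appear with
    their 'a' prefix when node specs were provided as NodeSpec names."""
    n = avg.mean_W.shape[0]
    names = avg.node_names or [f"n{i}" for i in range(n)]
    if fmt == "sif":
        lines = []
        for i in range(n):
            for j in range(n):
                w = avg.mean_W[i, j]
                if i == j or abs(w) < threshold or w == 0:
                    continue
                verb = "activates" if w > 0 else "inhibits"
                lines.append(f"{names[j]}\t{verb}\t{names[i]}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        import networkx as nx

        G = nx.DiGraph()
        for nm in names:
            G.add_node(nm)
        for i in range(n):
            for j in range(n):
                w = avg.mean_W[i, j]
                if i == j or abs(w) < threshold or w == 0:
                    continue
                G.add_edge(
                    names[j],
                    names[i],
                    mean_weight=float(w),
                    frequency=float(avg.edge_frequency[i, j]),
                )
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"unknown export format: {fmt}")


@dataclass
class RunConfig:
    """A fully serializable description of one inference run; its hash is
    recorded in every output manifest so artifacts can be traced to the
    configuration that produced them."""

    x_path: str = ""
    u_path: str = ""
    roles_path: str = ""
    grid_low: float = -1.0
    grid_high: float = 1.0
    grid_step: float = 0.2
    beta: float = 2.0
    lam: float = 5.0
    bp_tol: float = 1e-6
    max_sweeps: int = 200
    damping: float = 0.0
    n_generate: int = 1000
    n_keep: int = 100
    refine: bool = True
    edge_threshold: float = 0.2
    seed: int = 0
    output_dir: str = "pertnet_run"
    options: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        return cls(**doc)

    def to_file(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))
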