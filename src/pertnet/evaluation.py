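"""Turning inferred models into claims.

Average networks summarize an ensemble; recall/precision score a thresholded
inferred network against a known data-generating network, with false calls
classified into compensatory motifs (upstream, symmetric, co-regulation);
leave-k-out cross-validation measures predictive power on withheld drug
conditions; and the in silico screen ranks candidate drug targets by the
predicted phenotype change across an ensemble of executable models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bp_engine import BPConfig, MarginalSet, ValueGrid
from .core_model import NetworkModel, NodeRole, PerturbationDataset, simulate_to_steady_state
from .decimation import ModelEnsemble, generate_ensemble

__all__ = [
    "AverageNetwork",
    "BenchmarkReport",
    "CrossValidationReport",
    "ScreenReport",
    "average_network",
    "marginal_average_network",
    "recall_precision",
    "classify_compensatory_motifs",
    "leave_k_out_crossvalidation",
    "insilico_screen",
]


@dataclass
class AverageNetwork:
    """Entrywise mean of W over an ensemble (or of BP marginals), with the
    fraction of models carrying each edge.  A summary artifact — not
    executable."""

    mean_W: np.ndarray
    edge_frequency: np.ndarray
    node_names: list[str] = field(default_factory=list)
    source: str = ""


def average_network(ensemble: ModelEnsemble, source: str = "ensemble") -> AverageNetwork:
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    stack = np.stack([m.W for m in ensemble.models])
    return AverageNetwork(
        mean_W=stack.mean(axis=0),
        edge_frequency=(stack != 0).mean(axis=0),
        node_names=ensemble.models[0].node_names,
        source=source,
    )


def marginal_average_network(marginals: MarginalSet, node_names=None) -> AverageNetwork:
    """The descriptive average network straight from BP marginals: per-edge
    mean value and probability of a nonzero assignment."""
    return AverageNetwork(
        mean_W=marginals.mean_matrix(),
        edge_frequency=1.0 - marginals.zero_mass_matrix(),
        node_names=list(node_names) if node_names else [],
        source="bp-marginals",
    )


@dataclass
class BenchmarkReport:
    recall: float
    precision: float
    true_positives: list[tuple[int, int]]
    false_negatives: list[tuple[int, int]]
    false_positives: list[tuple[int, int]]
    motif_labels: dict = field(default_factory=dict)
    no_calls: bool = False


def recall_precision(
    inferred: AverageNetwork | np.ndarray,
    truth: NetworkModel,
    threshold: float = 0.2,
) -> BenchmarkReport:
    """Score called edges (|mean w| >= threshold) against the generator.

    A true edge recovered with the wrong sign counts as both a false negative
    and a false positive.  An empty inferred network reports precision 1.0
    with the ``no_calls`` flag set (no calls were wrong).
    """
    W_inf = inferred.mean_W if isinstance(inferred, AverageNetwork) else np.asarray(inferred)
    W_true = truth.W
    called = np.abs(W_inf) >= threshold
    np.fill_diagonal(called, False)
    true_edges = W_true != 0

    tp, fn, fp = [], [], []
    n = W_true.shape[0]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if true_edges[i, j]:
                if called[i, j] and np.sign(W_inf[i, j]) == np.sign(W_true[i, j]):
                    tp.append((i, j))
                else:
                    fn.append((i, j))
                    if called[i, j]:  # wrong sign: also a wrong call
                        fp.append((i, j))
            elif called[i, j]:
                fp.append((i, j))

    n_true = len(tp) + len(fn)
    recall = len(tp) / n_true if n_true else 1.0
    no_calls = (len(tp) + len(fp)) == 0
    precision = 1.0 if no_calls else len(tp) / (len(tp) + len(fp))
    return BenchmarkReport(
        recall=recall,
        precision=precision,
        true_positives=tp,
        false_negatives=fn,
        false_positives=fp,
        no_calls=no_calls,
    )


def classify_compensatory_motifs(
    report: BenchmarkReport,
    truth: NetworkModel,
    zero_mass: np.ndarray | None = None,
    zero_mass_cut: float = 0.25,
) -> BenchmarkReport:
    """Label each false positive by the compensatory structure that explains
    it in the generator.

    With edge (i, j) read as source j -> target i: ``upstream`` when the truth
    connects j to i through one intermediate; ``symmetric`` when the truth has
    the reverse edge i -> j; ``co_regulation`` when some common regulator
    drives both endpoints; ``near_zero`` when the marginal's mass at zero
    exceeds the cut (the call is barely a call); else ``unexplained``.
    Precedence follows that order.
    """
    W = truth.W != 0  # W[t, s]: edge s -> t
    labels = {}
    for (i, j) in report.false_positives:
        if np.any(W[i, :] & W[:, j]):  # j -> b -> i for some b
            labels[(i, j)] = "upstream"
        elif W[j, i]:  # truth has i -> j
            labels[(i, j)] = "symmetric"
        elif np.any(W[i, :] & W[j, :]):  # some a' with a' -> i and a' -> j
            labels[(i, j)] = "co_regulation"
        elif zero_mass is not None and zero_mass[i, j] > zero_mass_cut:
            labels[(i, j)] = "near_zero"
        else:
            labels[(i, j)] = "unexplained"
    return replace_labels(report, labels)


def replace_labels(report: BenchmarkReport, labels: dict) -> BenchmarkReport:
    report.motif_labels = labels
    return report


@dataclass
class CrossValidationReport:
    predicted: np.ndarray  # pooled predictions, one entry per withheld measurement
    observed: np.ndarray
    pooled_correlation: float
    cv_error: float  # RMS prediction error per data point
    mean_absolute_error: float
    outliers: list[tuple[str, str]]  # (condition label, node name)
    per_drug: dict = field(default_factory=dict)


def leave_k_out_crossvalidation(
    data: PerturbationDataset,
    drug_conditions: dict[str, list[str]],
    grid: ValueGrid,
    cfg: BPConfig,
    n_generate: int = 20,
    n_keep: int = 10,
    refine: bool = False,
    refine_config=None,
    solo_condition: dict[str, str] | None = None,
    keep_high_dose_single: bool = False,
) -> CrossValidationReport:
    """For each drug, withhold every condition involving it except its
    low-dose solo condition, train an ensemble on the remainder, and predict
    the withheld response profiles by simulating each kept model under the
    withheld forces (averaging predictions over models).

    ``drug_conditions`` maps drug name -> labels of all conditions involving
    that drug; ``solo_condition`` maps drug name -> the label of its retained
    single-drug (low-dose) condition (default: the first listed condition).
    With ``keep_high_dose_single`` the high-dose single is retained too: any
    single-drug label is kept.
    """
    label_to_col = {lab: k for k, lab in enumerate(data.condition_labels)}
    measured = [i for i, nd in enumerate(data.nodes) if nd.is_measured]
    node_names = data.node_names

    preds, obs, outliers = [], [], []
    per_drug = {}
    sigma = float(np.std(data.X_star[measured, :]))

    for drug, labels in drug_conditions.items():
        labels = [lab for lab in labels if lab in label_to_col]
        if not labels:
            continue
        solo = solo_condition.get(drug) if solo_condition else None
        if solo is None:
            solos = [lab for lab in labels if _is_single(lab, drug_conditions)]
            if not solos:
                raise ValueError(f"drug {drug} has no single-drug condition")
            solo_keep = solos if keep_high_dose_single else solos[:1]
        else:
            solo_keep = [solo]
        withheld = [lab for lab in labels if lab not in solo_keep]
        if not withheld:
            continue
        withheld_cols = [label_to_col[lab] for lab in withheld]
        train_cols = [k for k in range(data.n_conditions) if k not in withheld_cols]
        train = data.subset_conditions(train_cols)

        ensemble = generate_ensemble(
            train, grid, cfg, n_generate=n_generate, n_keep=n_keep,
            refine=refine, refine_config=refine_config,
        )
        pred_cols = _ensemble_predict(ensemble, data, withheld_cols)
        drug_pred, drug_obs = [], []
        for ci, col in enumerate(withheld_cols):
            for node_i in measured:
                p = pred_cols[ci][node_i]
                o = data.X_star[node_i, col]
                preds.append(p)
                obs.append(o)
                drug_pred.append(p)
                drug_obs.append(o)
                if abs(p - o) > sigma:
                    outliers.append((data.condition_labels[col], node_names[node_i]))
        per_drug[drug] = {
            "n_withheld": len(withheld_cols),
            "correlation": _safe_corr(drug_pred, drug_obs),
        }

    preds_arr = np.array(preds)
    obs_arr = np.array(obs)
    return CrossValidationReport(
        predicted=preds_arr,
        observed=obs_arr,
        pooled_correlation=_safe_corr(preds_arr, obs_arr),
        cv_error=float(np.sqrt(np.mean((preds_arr - obs_arr) ** 2))),
        mean_absolute_error=float(np.mean(np.abs(preds_arr - obs_arr))),
        outliers=outliers,
        per_drug=per_drug,
    )


def _is_single(label: str, drug_conditions: dict[str, list[str]]) -> bool:
    return sum(label in labs for labs in drug_conditions.values()) == 1


def _safe_corr(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _ensemble_predict(
    ensemble: ModelEnsemble, data: PerturbationDataset, cols: list[int]
) -> list[np.ndarray]:
    """Mean simulated steady state over ensemble models for each condition."""
    out = []
    for col in cols:
        states = []
        for model in ensemble.models:
            traj = simulate_to_steady_state(model, data.U[:, col])
            if traj.converged:
                states.append(traj.final_state)
        if not states:
            states = [np.zeros(data.n_nodes)]
        out.append(np.mean(states, axis=0))
    return out


@dataclass
class ScreenReport:
    """Per-target distributions of predicted phenotype change over the
    ensemble, ranked by mean effect (most negative first)."""

    targets: list[str]
    distributions: dict  # target name -> np.ndarray over ensemble models
    mean_effects: dict  # target name -> float
    ranking: list[str]
    n_excluded: dict  # target name -> simulations excluded (non-convergent)


def insilico_screen(
    ensemble: ModelEnsemble,
    targets: list[str],
    mode: str = "clamp",
    strength: float = 1.0,
) -> ScreenReport:
    """Predict phenotype response to single-node in silico perturbations.

    ``clamp`` mode fixes the target at x = -strength (default -1, the log2
    of a 50% knockdown) in every model and simulates to steady state;
    ``force`` mode instead applies the constant u solving
    (eps/alpha) tanh(u) = -strength for the isolated node, which requires
    strength < eps/alpha.  The recorded effect is the mean steady state of
    the phenotype nodes.
    """
    if mode not in ("clamp", "force"):
        raise ValueError("mode must be 'clamp' or 'force'")
    if not len(ensemble):
        raise ValueError("ensemble is empty")
    ref = ensemble.models[0]
    pheno = [i for i, nd in enumerate(ref.nodes) if nd.role == NodeRole.PHENOTYPE]
    if not pheno:
        raise ValueError("no phenotype nodes in the ensemble models")

    distributions = {}
    n_excluded = {}
    for target in targets:
        effects = []
        excluded = 0
        for model in ensemble.models:
            ti = model.node_index(target)
            u = np.zeros(model.n_nodes)
            clamp = None
            if mode == "clamp":
                clamp = {ti: -strength}
            else:
                ratio = model.alpha[ti] * strength / model.epsilon[ti]
                if ratio >= 1:
                    raise ValueError(
                        f"force mode cannot reach x = -{strength} on node {target}: "
                        "saturation bound eps/alpha exceeded (use clamp mode)"
                    )
                u[ti] = np.arctanh(-ratio)
            traj = simulate_to_steady_state(model, u, clamp=clamp)
            if traj.converged:
                effects.append(float(np.mean(traj.final_state[pheno])))
            else:
                excluded += 1
        distributions[target] = np.array(effects)
        n_excluded[target] = excluded

    mean_effects = {
        t: (float(np.mean(d)) if d.size else float("nan"))
        for t, d in distributions.items()
    }
    ranking = sorted(targets, key=lambda t: mean_effects[t])
    return ScreenReport(
        targets=list(targets),
        distributions=distributions,
        mean_effects=mean_effects,
        ranking=ranking,
        n_excluded=n_excluded,
    )
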