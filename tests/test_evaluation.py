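"""Tests of average networks, benchmark scoring, compensatory-motif
classification, cross-validation and in silico screening."""

import numpy as np
import pytest

from pertnet import (
    AverageNetwork,
    BPConfig,
    DrugPanelSpec,
    NetworkModel,
    NodeRole,
    NodeSpec,
    TopologySpec,
    average_network,
    classify_compensatory_motifs,
    design_insilico_perturbations,
    generate_topology,
    insilico_screen,
    leave_k_out_crossvalidation,
    make_value_grid,
    recall_precision,
    simulate_response_profiles,
)
from pertnet.decimation import DecimationTrace, ModelEnsemble


def model_from_W(W, roles=None):
    n = len(W)
    roles = roles or [NodeRole.PROTEIN] * n
    nodes = [NodeSpec(f"n{i}", role=r) for i, r in enumerate(roles)]
    return NetworkModel(nodes=nodes, W=np.array(W, dtype=float))


def ensemble_of(models):
    return ModelEnsemble(
        models=models,
        train_errors=[0.0] * len(models),
        traces=[DecimationTrace(seed=k) for k in range(len(models))],
        ranked=True,
    )


class TestAverageNetwork:
    def test_single_model_average_is_itself(self):
        m = model_from_W([[0, 0.5], [-0.3, 0]])
        avg = average_network(ensemble_of([m]))
        assert np.array_equal(avg.mean_W, m.W)
        assert set(np.unique(avg.edge_frequency)) <= {0.0, 1.0}

    def test_mutual_exclusivity_signature(self):
        a = model_from_W([[0, 1.0], [0, 0]])
        b = model_from_W([[0, -1.0], [0, 0]])
        avg = average_network(ensemble_of([a, b]))
        assert avg.mean_W[0, 1] == 0.0
        assert avg.edge_frequency[0, 1] == 1.0

    def test_mean_matches_stacked_edge_table(self):
        rng = np.random.default_rng(3)
        models = []
        for _ in range(5):
            W = rng.normal(0, 1, (3, 3))
            np.fill_diagonal(W, 0)
            models.append(model_from_W(W))
        avg = average_network(ensemble_of(models))
        stacked = np.stack([m.W for m in models]).reshape(5, -1)
        assert avg.mean_W.ravel() == pytest.approx(stacked.mean(axis=0))


class TestRecallPrecision:
    def test_perfect_inference(self):
        truth = model_from_W([[0, 0.8, 0], [0, 0, -0.6], [0, 0, 0]])
        report = recall_precision(truth.W.copy(), truth, threshold=0.2)
        assert report.recall == 1.0 and report.precision == 1.0

    def test_sixty_edge_arithmetic(self):
        # 43 of 60 true edges recovered: recall 43/60
        rng = np.random.default_rng(0)
        n = 20
        truth_W = np.zeros((n, n))
        slots = [(i, j) for i in range(n) for j in range(n) if i != j]
        rng.shuffle(slots)
        for i, j in slots[:60]:
            truth_W[i, j] = 1.0
        inferred = np.zeros((n, n))
        for i, j in slots[:43]:
            inferred[i, j] = 1.0
        report = recall_precision(inferred, model_from_W(truth_W), 0.2)
        assert report.recall == pytest.approx(43 / 60)
        assert report.precision == 1.0
        assert len(report.false_negatives) == 17

    def test_empty_inference_flagged(self):
        truth = model_from_W([[0, 0.8], [0, 0]])
        report = recall_precision(np.zeros((2, 2)), truth, 0.2)
        assert report.recall == 0.0
        assert report.precision == 1.0
        assert report.no_calls

    def test_wrong_sign_counts_both_ways(self):
        truth = model_from_W([[0, 0.8], [0, 0]])
        inferred = np.array([[0, -0.8], [0, 0]])
        report = recall_precision(inferred, truth, 0.2)
        assert report.false_negatives == [(0, 1)]
        assert report.false_positives == [(0, 1)]
        assert report.recall == 0.0 and report.precision == 0.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        W_true = rng.normal(0, 1, (4, 4)) * (rng.random((4, 4)) < 0.4)
        np.fill_diagonal(W_true, 0)
        W_inf = W_true + rng.normal(0, 0.3, (4, 4))
        np.fill_diagonal(W_inf, 0)
        base = recall_precision(W_inf, model_from_W(W_true), 0.2)
        perm = np.array([2, 0, 3, 1])
        permuted = recall_precision(
            W_inf[np.ix_(perm, perm)], model_from_W(W_true[np.ix_(perm, perm)]), 0.2
        )
        assert base.recall == permuted.recall
        assert base.precision == permuted.precision


class TestCompensatoryMotifs:
    def test_upstream_motif(self):
        # truth chain A -> B -> C; inferred shortcut A -> C
        truth = model_from_W([[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
        inferred = truth.W.copy()
        inferred[2, 0] = 1.0  # A -> C
        report = recall_precision(inferred, truth, 0.2)
        report = classify_compensatory_motifs(report, truth)
        assert report.motif_labels[(2, 0)] == "upstream"

    def test_symmetric_motif(self):
        # truth C -> A; inferred A -> C
        truth = model_from_W([[0, 0], [0, 0]])
        truth.W[0, 1] = 1.0  # edge n1 -> n0
        inferred = np.zeros((2, 2))
        inferred[1, 0] = 1.0  # edge n0 -> n1 (reverse)
        report = recall_precision(inferred, truth, 0.2)
        report = classify_compensatory_motifs(report, truth)
        assert report.motif_labels[(1, 0)] == "symmetric"

    def test_co_regulation_motif(self):
        # truth A -> B and A -> C; inferred B -> C
        truth = model_from_W([[0, 0, 0], [1.0, 0, 0], [1.0, 0, 0]])
        inferred = truth.W.copy()
        inferred[2, 1] = 1.0  # B -> C
        report = recall_precision(inferred, truth, 0.2)
        report = classify_compensatory_motifs(report, truth)
        assert report.motif_labels[(2, 1)] == "co_regulation"

    def test_near_zero_and_unexplained(self):
        truth = model_from_W(np.zeros((3, 3)))
        inferred = np.zeros((3, 3))
        inferred[0, 1] = 0.5
        inferred[1, 2] = 0.5
        zero_mass = np.zeros((3, 3))
        zero_mass[0, 1] = 0.6
        report = recall_precision(inferred, truth, 0.2)
        report = classify_compensatory_motifs(report, truth, zero_mass=zero_mass,
                                              zero_mass_cut=0.25)
        assert report.motif_labels[(0, 1)] == "near_zero"
        assert report.motif_labels[(1, 2)] == "unexplained"

    def test_every_false_positive_labeled(self):
        rng = np.random.default_rng(2)
        W_true = rng.normal(0, 1, (5, 5)) * (rng.random((5, 5)) < 0.3)
        np.fill_diagonal(W_true, 0)
        truth = model_from_W(W_true)
        W_inf = rng.normal(0, 1, (5, 5)) * (rng.random((5, 5)) < 0.3)
        np.fill_diagonal(W_inf, 0)
        report = recall_precision(W_inf, truth, 0.2)
        report = classify_compensatory_motifs(report, truth)
        assert set(report.motif_labels) == set(report.false_positives)


class TestInsilicoScreen:
    def test_clamp_holds_target_and_no_path_means_no_effect(self):
        # n0 isolated from the phenotype n2; n1 drives it
        roles = [NodeRole.PROTEIN, NodeRole.PROTEIN, NodeRole.PHENOTYPE]
        W = [[0, 0, 0], [0, 0, 0], [0, -0.8, 0]]
        model = model_from_W(W, roles)
        ens = ensemble_of([model])
        report = insilico_screen(ens, ["n0", "n1"], mode="clamp", strength=1.0)
        assert report.mean_effects["n0"] == pytest.approx(0.0, abs=1e-7)
        # clamping n1 at -1 raises the phenotype through the inhibitory edge
        expected = np.tanh(0.8)
        assert report.mean_effects["n1"] == pytest.approx(expected, abs=1e-6)
        assert report.ranking == ["n0", "n1"]

    def test_clamp_fixes_target_exactly(self):
        model = model_from_W([[0.0]], roles=[NodeRole.PHENOTYPE])
        from pertnet.core_model import simulate_to_steady_state

        traj = simulate_to_steady_state(model, np.zeros(1), clamp={"n0": -1.0})
        assert traj.final_state[0] == pytest.approx(-1.0)

    def test_force_mode_saturation_bound(self):
        roles = [NodeRole.PROTEIN, NodeRole.PHENOTYPE]
        model = model_from_W([[0, 0], [0.5, 0]], roles)
        ens = ensemble_of([model])
        with pytest.raises(ValueError, match="saturation"):
            insilico_screen(ens, ["n0"], mode="force", strength=1.0)

    def test_force_mode_with_relaxed_kinetics(self):
        roles = [NodeRole.PROTEIN, NodeRole.PHENOTYPE]
        nodes = [NodeSpec(f"n{i}", role=r) for i, r in enumerate(roles)]
        model = NetworkModel(
            nodes=nodes, W=np.array([[0, 0], [0.5, 0.0]]),
            alpha=np.ones(2), epsilon=np.array([2.0, 1.0]),
        )
        ens = ensemble_of([model])
        report = insilico_screen(ens, ["n0"], mode="force", strength=1.0)
        # the isolated-node calibration drives n0 to exactly -1
        assert report.mean_effects["n0"] == pytest.approx(np.tanh(-0.5), abs=1e-6)

    def test_ranking_invariant_under_member_duplication(self):
        roles = [NodeRole.PROTEIN, NodeRole.PROTEIN, NodeRole.PHENOTYPE]
        W = [[0, 0, 0], [0.4, 0, 0], [0.9, -0.7, 0]]
        model = model_from_W(W, roles)
        single = insilico_screen(ensemble_of([model]), ["n0", "n1"])
        doubled = insilico_screen(ensemble_of([model, model]), ["n0", "n1"])
        assert single.ranking == doubled.ranking
        for t in ("n0", "n1"):
            assert single.mean_effects[t] == pytest.approx(doubled.mean_effects[t])


@pytest.fixture(scope="module")
def toy_crossval():
    """Small generator + 4-drug panel, trained with small ensembles."""
    gen = generate_topology(
        TopologySpec(n_nodes=6, n_edges=8, seed=5, n_phenotypes=1)
    )
    panel = DrugPanelSpec(n_drugs=4, max_off_targets=1,
                          dose_levels=(1.0, 2.0), seed=2)
    design = design_insilico_perturbations(gen, panel)
    data = simulate_response_profiles(gen, design)
    grid = make_value_grid(-2, 2, 0.4)
    cfg = BPConfig(beta=2.0, lam=3.0, seed=0, max_sweeps=80)
    report = leave_k_out_crossvalidation(
        data, design.drug_condition_map(), grid, cfg,
        n_generate=4, n_keep=2,
    )
    return report, data


class TestLeaveKOut:
    def test_pair_counts_match_withheld_measurements(self, toy_crossval):
        report, data = toy_crossval
        n_measured = sum(nd.is_measured for nd in data.nodes)
        # per drug: 3 pair conditions + the high-dose single are withheld
        expected = 4 * (3 + 1) * n_measured
        assert report.predicted.size == expected
        assert report.observed.size == expected

    def test_heldout_correlation_positive_on_recoverable_toy(self, toy_crossval):
        report, _ = toy_crossval
        assert report.pooled_correlation > 0.5

    def test_missing_solo_condition_raises(self):
        gen = generate_topology(TopologySpec(n_nodes=5, n_edges=6, seed=1))
        panel = DrugPanelSpec(n_drugs=3, seed=0)
        design = design_insilico_perturbations(gen, panel, pairing="singles+pairs")
        data = simulate_response_profiles(gen, design)
        # drop drug d0's solo condition from the mapping labels entirely
        dmap = design.drug_condition_map()
        data2 = data.subset_conditions(
            [k for k, lab in enumerate(data.condition_labels) if lab != "d0@1"]
        )
        grid = make_value_grid(-2, 2, 1.0)
        with pytest.raises(ValueError, match="single-drug"):
            leave_k_out_crossvalidation(
                data2, dmap, grid, BPConfig(max_sweeps=5, seed=0),
                n_generate=1, n_keep=1,
            )
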