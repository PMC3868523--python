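"""Tests of the discretized BP engine against closed forms and brute-force
enumeration of the factorized posterior."""

import itertools
import math

import numpy as np
import pytest

from pertnet import (
    BPConfig,
    NetworkModel,
    NodeRole,
    NodeSpec,
    PerturbationDataset,
    init_belief_state,
    make_value_grid,
    marginal_entropy,
    run_bp,
    search_space_magnitude,
    select_hyperparameters,
    simulate_to_steady_state,
)
from pertnet.bp_engine import (
    cavity_field_stats,
    cavity_marginal,
    factor_update,
)


def make_dataset(W, M, seed=0, roles=None, u_scale=1.0):
    """Simulate noise-free steady-state responses of a known model."""
    rng = np.random.default_rng(seed)
    n = len(W)
    roles = roles or [NodeRole.PROTEIN] * n
    nodes = [NodeSpec(f"n{i}", role=r) for i, r in enumerate(roles)]
    model = NetworkModel(nodes=nodes, W=np.array(W, dtype=float))
    U = rng.uniform(-u_scale, u_scale, (n, M))
    for i, r in enumerate(roles):  # forces only where meaningful
        if r == NodeRole.PHENOTYPE:
            U[i] = 0.0
    X = np.column_stack(
        [simulate_to_steady_state(model, U[:, m], tol=1e-10).final_state
         for m in range(M)]
    )
    return PerturbationDataset(nodes=nodes, X_star=X, U=U), model


def exact_row_marginals(data, row, grid, beta, lam):
    """Brute-force posterior marginals of one row of W by enumerating every
    grid configuration of its free parameters."""
    n = data.n_nodes
    free = [j for j in range(n) if j != row]
    K = grid.K
    g = grid.values
    P = np.zeros((len(free), K))
    entries = []
    for cfg in itertools.product(range(K), repeat=len(free)):
        w = np.zeros(n)
        for f, k in zip(free, cfg):
            w[f] = g[k]
        lp = lam * sum(g[k] == 0.0 for k in cfg)
        resid = data.X_star[row] - np.tanh(w @ data.X_star + data.U[row])
        lp -= beta * float(resid @ resid)
        entries.append((cfg, lp))
    mx = max(lp for _, lp in entries)
    z = sum(math.exp(lp - mx) for _, lp in entries)
    for cfg, lp in entries:
        p = math.exp(lp - mx) / z
        for a, k in enumerate(cfg):
            P[a, k] += p
    return {f: P[a] for a, f in enumerate(free)}


class TestValueGrid:
    @pytest.mark.parametrize(
        "low,high,step,expected_k",
        [(-1, 1, 0.2, 11), (-1, 1, 1.0, 3), (-2, 2, 0.1, 41)],
    )
    def test_grid_sizes(self, low, high, step, expected_k):
        grid = make_value_grid(low, high, step)
        assert grid.K == expected_k
        assert grid.values[grid.zero_index] == 0.0
        assert np.allclose(grid.values, -grid.values[::-1])

    def test_asymmetric_grid_rejected(self):
        with pytest.raises(ValueError):
            make_value_grid(-1, 2, 0.5)

    def test_zero_free_grid_rejected(self):
        with pytest.raises(ValueError):
            make_value_grid(-1, 1, 0.4)  # {-1,-0.6,-0.2,0.2,0.6,1}: no zero

    def test_search_space_magnitude(self):
        # N=20 nodes with 3 values per parameter: ~10^190 configurations
        assert search_space_magnitude(20, 3) == 190


class TestInitBeliefState:
    def test_seed_determinism(self):
        data, _ = make_dataset(np.zeros((3, 3)), M=4)
        grid = make_value_grid(-1, 1, 0.5)
        a = init_belief_state(data, grid, seed=42)
        b = init_belief_state(data, grid, seed=42)
        assert np.array_equal(a.factors, b.factors)

    def test_factors_normalized(self):
        data, _ = make_dataset(np.zeros((4, 4)), M=3)
        grid = make_value_grid(-1, 1, 0.2)
        state = init_belief_state(data, grid, seed=0)
        assert np.allclose(state.factors.sum(axis=3), 1.0, atol=1e-12)

    def test_activity_rows_frozen_at_zero(self):
        roles = [NodeRole.ACTIVITY, NodeRole.PROTEIN, NodeRole.PROTEIN]
        data, _ = make_dataset(np.zeros((3, 3)), M=2, roles=roles)
        grid = make_value_grid(-1, 1, 0.5)
        state = init_belief_state(data, grid, seed=0)
        assert state.frozen[0].all()
        delta = np.zeros(grid.K)
        delta[grid.zero_index] = 1.0
        assert np.allclose(state.factors[0, 1], delta)

    def test_phenotype_outgoing_optionally_forbidden(self):
        roles = [NodeRole.PROTEIN, NodeRole.PHENOTYPE]
        data, _ = make_dataset(np.zeros((2, 2)), M=2, roles=roles)
        grid = make_value_grid(-1, 1, 0.5)
        state = init_belief_state(data, grid, seed=0, forbid_phenotype_outgoing=True)
        assert state.frozen[0, 1] and state.frozen[1, 0] is not None
        assert state.frozen[:, 1].all()


class TestCavityMarginal:
    def test_uniform_factors_zero_lambda(self):
        data, _ = make_dataset(np.zeros((2, 2)), M=3)
        grid = make_value_grid(-1, 1, 0.5)
        state = init_belief_state(data, grid, seed=0)
        state.factors[0, 1, :, :] = 1.0 / grid.K
        out = cavity_marginal(state, 0, 1, exclude_condition=0, lam=0.0)
        assert np.allclose(out, 1.0 / grid.K)

    def test_uniform_factors_prior_mass_closed_form(self):
        # with flat factors the zero value carries mass e^lam / (e^lam + K - 1)
        data, _ = make_dataset(np.zeros((2, 2)), M=3)
        grid = make_value_grid(-1, 1, 0.5)
        state = init_belief_state(data, grid, seed=0)
        state.factors[0, 1, :, :] = 1.0 / grid.K
        lam = 2.0
        out = cavity_marginal(state, 0, 1, exclude_condition=1, lam=lam)
        expected = math.exp(lam) / (math.exp(lam) + grid.K - 1)
        assert out[grid.zero_index] == pytest.approx(expected, rel=1e-12)

    def test_two_conditions_excluding_one_leaves_the_other(self):
        data, _ = make_dataset(np.zeros((2, 2)), M=2)
        grid = make_value_grid(-1, 1, 0.5)
        state = init_belief_state(data, grid, seed=1)
        out = cavity_marginal(state, 0, 1, exclude_condition=0, lam=0.0)
        expected = state.factors[0, 1, 1] / state.factors[0, 1, 1].sum()
        assert np.allclose(out, expected, atol=1e-12)


class TestCavityFieldStats:
    def test_all_deltas_at_zero_give_zero_field(self):
        roles = [NodeRole.PROTEIN] * 3
        data, _ = make_dataset(np.zeros((3, 3)), M=2, roles=roles)
        grid = make_value_grid(-1, 1, 0.5)
        state = init_belief_state(data, grid, seed=0)
        delta = np.zeros(grid.K)
        delta[grid.zero_index] = 1.0
        state.factors[0, 2, :, :] = delta
        stats = cavity_field_stats(state, 0, 1, 0, data.X_star, lam=0.0)
        assert stats.mean_h == pytest.approx(0.0)
        assert stats.var_h == pytest.approx(0.0)

    def test_single_deterministic_neighbor(self):
        data, _ = make_dataset(np.zeros((3, 3)), M=2)
        data.X_star[2, 0] = 1.0
        grid = make_value_grid(-1, 1, 0.5)
        state = init_belief_state(data, grid, seed=0)
        delta = np.zeros(grid.K)
        delta[np.argmax(grid.values == 0.5)] = 1.0
        state.factors[0, 2, :, :] = delta
        stats = cavity_field_stats(state, 0, 1, 0, data.X_star, lam=0.0)
        assert stats.mean_h == pytest.approx(0.5)
        assert stats.var_h == pytest.approx(0.0, abs=1e-12)

    def test_variance_adds_over_independent_neighbors(self):
        # Monte Carlo sampling of the cavity marginals as the oracle
        data, _ = make_dataset(np.zeros((4, 4)), M=2, seed=3)
        grid = make_value_grid(-1, 1, 0.5)
        state = init_belief_state(data, grid, seed=5)
        stats = cavity_field_stats(state, 0, 1, 0, data.X_star, lam=1.0)

        rng = np.random.default_rng(0)
        draws = np.zeros(100_000)
        for j in (2, 3):
            q = cavity_marginal(state, 0, j, 0, lam=1.0)
            vals = rng.choice(grid.values, size=draws.size, p=q)
            draws += vals * data.X_star[j, 0]
        assert draws.mean() == pytest.approx(stats.mean_h, abs=0.01)
        assert draws.var() == pytest.approx(stats.var_h, abs=0.01)


class TestFactorUpdate:
    def test_two_node_system_matches_exact_sum_product(self):
        # one non-cavity source: the Gaussian integral must reproduce the
        # explicit sum over that parameter's values within quadrature error
        data, _ = make_dataset([[0, 0.5, 0], [0, 0, 0], [0, 0, 0]], M=4, seed=2)
        grid = make_value_grid(-1, 1, 0.5)
        cfg = BPConfig(beta=2.0, lam=1.0, quadrature_order=40, seed=0)
        state = init_belief_state(data, grid, seed=7)

        mu = 1
        rho = factor_update(state, 0, 1, mu, data, grid, cfg)

        q2 = cavity_marginal(state, 0, 2, mu, cfg.lam)
        g = grid.values
        exact = np.zeros(grid.K)
        for a, omega in enumerate(g):
            for b, w2 in enumerate(g):
                h = w2 * data.X_star[2, mu]
                pred = np.tanh(h + omega * data.X_star[1, mu] + data.U[0, mu])
                exact[a] += q2[b] * math.exp(
                    -cfg.beta * (data.X_star[0, mu] - pred) ** 2
                )
        exact /= exact.sum()
        # Gaussian mean-field replaces a 2-point mixture: modest tolerance
        assert 0.5 * np.abs(rho - exact).sum() < 0.05

    def test_beta_zero_gives_uniform_factor(self):
        data, _ = make_dataset(np.zeros((3, 3)), M=2)
        grid = make_value_grid(-1, 1, 0.5)
        cfg = BPConfig(beta=0.0, lam=1.0, seed=0)
        state = init_belief_state(data, grid, seed=0)
        rho = factor_update(state, 0, 1, 0, data, grid, cfg)
        assert np.allclose(rho, 1.0 / grid.K, atol=1e-12)

    def test_frozen_edge_rejected(self):
        data, _ = make_dataset(np.zeros((2, 2)), M=2)
        grid = make_value_grid(-1, 1, 0.5)
        state = init_belief_state(data, grid, seed=0)
        with pytest.raises(ValueError, match="frozen"):
            factor_update(state, 0, 0, 0, data, grid, BPConfig())


class TestRunBP:
    def test_single_free_parameter_exact(self):
        # a 2-node chain: BP is exact when each row has one free parameter
        data, _ = make_dataset([[0, 0.6], [0, 0]], M=3, seed=0)
        grid = make_value_grid(-1, 1, 0.2)
        cfg = BPConfig(beta=2.0, lam=5.0, seed=1)
        marginals, _ = run_bp(data, grid, cfg)
        assert marginals.converged
        exact = exact_row_marginals(data, 0, grid, cfg.beta, cfg.lam)
        assert np.abs(marginals.P[0, 1] - exact[1]).max() < 1e-6

    def test_three_free_parameters_close_to_enumeration(self):
        data, _ = make_dataset(
            [[0, 0.8, -0.5, 0], [0, 0, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]],
            M=8, seed=7, u_scale=1.5,
        )
        grid = make_value_grid(-1, 1, 0.5)  # K=5
        cfg = BPConfig(beta=2.0, lam=2.0, seed=3)
        marginals, _ = run_bp(data, grid, cfg)
        assert marginals.converged
        exact = exact_row_marginals(data, 0, grid, cfg.beta, cfg.lam)
        for j in (1, 2, 3):
            tv = 0.5 * np.abs(marginals.P[0, j] - exact[j]).sum()
            assert tv < 0.05

    def test_no_data_returns_prior(self):
        nodes = [NodeSpec("a"), NodeSpec("b")]
        data = PerturbationDataset(
            nodes=nodes, X_star=np.zeros((2, 0)), U=np.zeros((2, 0)),
            condition_labels=[],
        )
        grid = make_value_grid(-1, 1, 0.5)
        cfg = BPConfig(beta=2.0, lam=3.0, seed=0)
        marginals, _ = run_bp(data, grid, cfg)
        expected = math.exp(3.0) / (math.exp(3.0) + grid.K - 1)
        assert marginals.P[0, 1, grid.zero_index] == pytest.approx(expected)

    def test_beta_zero_marginals_equal_prior(self):
        data, _ = make_dataset([[0, 0.9], [0, 0]], M=5, seed=1)
        grid = make_value_grid(-1, 1, 0.5)
        cfg = BPConfig(beta=0.0, lam=2.0, seed=0)
        marginals, _ = run_bp(data, grid, cfg)
        expected = math.exp(2.0) / (math.exp(2.0) + grid.K - 1)
        assert marginals.P[0, 1, grid.zero_index] == pytest.approx(expected, rel=1e-9)

    def test_determinism(self):
        data, _ = make_dataset([[0, 0.7, 0], [0, 0, -0.4], [0, 0, 0]], M=5, seed=4)
        grid = make_value_grid(-1, 1, 0.5)
        cfg = BPConfig(seed=9)
        a, _ = run_bp(data, grid, cfg)
        b, _ = run_bp(data, grid, cfg)
        assert np.array_equal(a.P, b.P)

    def test_marginals_normalized_after_convergence(self):
        data, _ = make_dataset([[0, 0.7], [0.3, 0]], M=4, seed=2)
        grid = make_value_grid(-1, 1, 0.2)
        marginals, state = run_bp(data, grid, BPConfig(seed=0))
        assert np.allclose(marginals.P.sum(axis=2), 1.0, atol=1e-9)
        assert np.allclose(state.factors.sum(axis=3), 1.0, atol=1e-9)

    def test_compiled_and_reference_sweeps_agree(self, monkeypatch):
        # the numba sweep kernel and the numpy reference implement the same
        # update equations; their fixed points must coincide
        import pertnet.bp_engine as bpe

        if not bpe._HAVE_NUMBA:
            pytest.skip("compiled kernel unavailable; only one path to test")
        data, _ = make_dataset([[0, 0.7, 0], [0, 0, -0.4], [0, 0, 0]], M=5, seed=4)
        grid = make_value_grid(-1, 1, 0.5)
        cfg = BPConfig(seed=9, damping=0.3)
        fast, _ = run_bp(data, grid, cfg)
        monkeypatch.setattr(bpe, "_HAVE_NUMBA", False)
        slow, _ = run_bp(data, grid, cfg)
        assert np.allclose(fast.P, slow.P, atol=1e-9)

    def test_row_subset_matches_full_run(self):
        # rows are decoupled: processing one row alone reproduces that row
        data, _ = make_dataset([[0, 0.7, 0], [0, 0, -0.4], [0, 0, 0]], M=5, seed=4)
        grid = make_value_grid(-1, 1, 0.5)
        cfg = BPConfig(seed=9)
        full, _ = run_bp(data, grid, cfg)
        row0, _ = run_bp(data, grid, cfg, rows=[0])
        assert np.allclose(full.P[0], row0.P[0], atol=1e-9)


class TestMarginalEntropy:
    def test_delta_and_uniform_limits(self):
        grid = make_value_grid(-1, 1, 0.5)
        from pertnet.bp_engine import MarginalSet

        P = np.zeros((2, 2, grid.K))
        P[0, 1, 0] = 1.0  # delta
        P[1, 0, :] = 1.0 / grid.K  # uniform
        P[0, 0, grid.zero_index] = 1.0
        P[1, 1, grid.zero_index] = 1.0
        ms = MarginalSet(grid=grid, P=P)
        ent = marginal_entropy(ms)
        assert ent[0, 1] == pytest.approx(0.0)
        assert ent[1, 0] == pytest.approx(1.0)

    def test_sign_collapse_uses_three_bins(self):
        grid = make_value_grid(-1, 1, 0.5)
        from pertnet.bp_engine import MarginalSet

        P = np.full((1, 1, grid.K), 1.0 / grid.K)
        ms = MarginalSet(grid=grid, P=P)
        ent = marginal_entropy(ms, collapse="sign")
        # masses (2/5, 1/5, 2/5) over (neg, zero, pos)
        p = np.array([0.4, 0.2, 0.4])
        expected = float(-(p * np.log(p)).sum() / np.log(3))
        assert ent[0, 0] == pytest.approx(expected)

    def test_coarse_grid_yields_more_certain_marginals(self):
        # the over-confidence of a 3-value search motivates the 11-value grid
        data, _ = make_dataset([[0, 0.9, 0], [0, 0, 0.8], [0, 0, 0]], M=10, seed=6)
        cfg = BPConfig(beta=2.0, lam=1.0, seed=0)
        coarse, _ = run_bp(data, make_value_grid(-1, 1, 1.0), cfg)
        fine, _ = run_bp(data, make_value_grid(-1, 1, 0.2), cfg)
        e_coarse = marginal_entropy(coarse, collapse="sign")
        e_fine = marginal_entropy(fine, collapse="sign")
        free = ~np.eye(3, dtype=bool)
        assert e_coarse[free].mean() < e_fine[free].mean()


class TestSelectHyperparameters:
    def _toy(self):
        return make_dataset([[0, 1.0, 0], [0, 0, 0.8], [0, 0, 0]], M=8, seed=3)

    def test_large_lambda_empties_the_network(self):
        data, _ = self._toy()
        grid = make_value_grid(-1, 1, 0.5)
        cfg = BPConfig(beta=2.0, lam=50.0, seed=0)
        marginals, _ = run_bp(data, grid, cfg)
        W = marginals.most_probable_matrix(0.2)
        assert np.count_nonzero(W) == 0

    def test_edge_count_non_increasing_in_lambda(self):
        data, _ = self._toy()
        grid = make_value_grid(-1, 1, 0.5)
        counts = []
        for lam in (0.5, 2.0, 6.0, 20.0):
            marginals, _ = run_bp(data, grid, BPConfig(beta=2.0, lam=lam, seed=0))
            counts.append(np.count_nonzero(marginals.most_probable_matrix(0.2)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_default_config_is_paper_operating_point(self):
        cfg = BPConfig()
        assert cfg.beta == 2.0 and cfg.lam == 5.0

    def test_selection_returns_config_from_lattice(self):
        data, _ = self._toy()
        grid = make_value_grid(-1, 1, 0.5)
        cfg = select_hyperparameters(
            data, grid, beta_range=[2.0], lambda_range=[1.0, 4.0],
            target_connectivity=0.7, connectivity_band=0.5,
            base_config=BPConfig(seed=0, max_sweeps=60),
        )
        assert cfg.beta == 2.0 and cfg.lam in (1.0, 4.0)
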