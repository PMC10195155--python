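import numpy as np
import pytest

import exprate as xr
from exprate.likelihood import KernelBank, RateModel, RootPrior, evaluate_root_prior
from exprate.reconstruction import credible_interval
from oracle_utils import enumerate_three_tip


def _expr(x):
    return np.exp(np.asarray(x)) - 1.0


class TestCredibleInterval:
    def test_hpd_is_shortest_window(self):
        centers = np.arange(10.0)
        w = np.array([0.01, 0.02, 0.2, 0.5, 0.2, 0.02, 0.01, 0.01, 0.01, 0.02])
        lo, hi = credible_interval(w, centers, mass=0.9, method="hpd")
        assert (lo, hi) == (2.0, 4.0)

    def test_equal_tail_cuts_both_tails(self):
        centers = np.arange(100.0)
        w = np.full(100, 0.01)
        lo, hi = credible_interval(w, centers, mass=0.95, method="equal-tail")
        assert lo <= 3 and hi >= 96

    def test_point_mass_gives_degenerate_interval(self):
        centers = np.arange(5.0)
        w = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        assert credible_interval(w, centers) == (2.0, 2.0)


class TestNodePosteriors:
    def test_marginals_match_brute_force(self, three_tip_tree, small_grid, table_factory):
        grid = small_grid
        prior = evaluate_root_prior(grid)
        rates = RateModel.single(0.7)
        bank = KernelBank(three_tip_tree, grid)
        kernels = bank.branch_kernels(rates)
        xa, xb, xc = 1.3, 2.2, 3.7
        table = table_factory(["A", "B", "C"], [_expr([xa, xb, xc])])
        recon = xr.reconstruct(table, three_tip_tree, rates, grid, prior)
        tipidx = three_tip_tree.tip_index()
        _, marg = enumerate_three_tip(
            three_tip_tree, grid, kernels, prior.weights,
            {tipidx["A"]: xa, tipidx["B"]: xb, tipidx["C"]: xc},
        )
        for v in three_tip_tree.internal_nodes:
            np.testing.assert_allclose(
                recon.posteriors[v][:, 0], marg[v], atol=1e-10
            )

    def test_marginals_match_brute_force_with_missing_tip(
        self, three_tip_tree, small_grid, table_factory
    ):
        grid = small_grid
        prior = evaluate_root_prior(grid)
        rates = RateModel.single(0.9)
        kernels = KernelBank(three_tip_tree, grid).branch_kernels(rates)
        xa, xb = 0.8, 2.9
        table = table_factory(
            ["A", "B", "C"], [_expr([xa, xb, 0.0])],
            missing=[[False, False, True]],
        )
        recon = xr.reconstruct(table, three_tip_tree, rates, grid, prior)
        tipidx = three_tip_tree.tip_index()
        _, marg = enumerate_three_tip(
            three_tip_tree, grid, kernels, prior.weights,
            {tipidx["A"]: xa, tipidx["B"]: xb, tipidx["C"]: None},
        )
        for v in (*three_tip_tree.internal_nodes, tipidx["C"]):
            np.testing.assert_allclose(recon.posteriors[v][:, 0], marg[v], atol=1e-10)

    def test_observed_tip_point_is_measurement(self, three_tip_tree, table_factory):
        grid = xr.Grid(0.0, 5.0, 100)
        prior = evaluate_root_prior(grid)
        xa = 1.234
        table = table_factory(["A", "B", "C"], [_expr([xa, 2.0, 3.0])])
        recon = xr.reconstruct(table, three_tip_tree, RateModel.single(1.0), grid, prior)
        a = three_tip_tree.tip_index()["A"]
        assert recon.point[0, a] == pytest.approx(xa, abs=1e-12)
        # interval no wider than the interpolation span
        assert recon.ci_hi[0, a] - recon.ci_lo[0, a] <= grid.delta + 1e-12

    def test_symmetric_two_tip_root_posterior(self, table_factory):
        tree = xr.parse_newick("(A:1,B:1);")
        grid = xr.Grid(0.0, 6.0, 61)
        flat = RootPrior(
            shape=1.0, scale=1.0, weights=np.full(grid.n, 1.0 / grid.n), grid=grid
        )
        xa, xb = grid.centers[24], grid.centers[36]  # symmetric around center
        table = table_factory(["A", "B"], [_expr([xa, xb])])
        recon = xr.reconstruct(table, tree, RateModel.single(0.3), grid, flat, ci_method="hpd")
        root_post = recon.posteriors[0][:, 0]
        np.testing.assert_allclose(root_post, root_post[::-1], atol=1e-9)
        assert recon.point[0, 0] == pytest.approx((xa + xb) / 2, abs=1e-9)

    def test_degenerate_limit_concentrates_everywhere(self, three_tip_tree, table_factory):
        grid = xr.Grid(0.0, 5.0, 101)
        prior = evaluate_root_prior(grid)
        x = grid.centers[40]
        table = table_factory(["A", "B", "C"], [_expr([x, x, x])])
        recon = xr.reconstruct(table, three_tip_tree, RateModel.single(1e-12), grid, prior)
        for v in range(three_tip_tree.n_nodes):
            assert recon.point[0, v] == pytest.approx(x, abs=1e-9)
            assert recon.ci_hi[0, v] - recon.ci_lo[0, v] <= grid.delta + 1e-12

    def test_single_gene_wrapper(self, three_tip_tree, small_grid):
        prior = evaluate_root_prior(small_grid)
        posts = xr.node_posteriors(
            _expr([1.0, 2.0, 3.0]), np.zeros(3, bool), ["A", "B", "C"],
            three_tip_tree, RateModel.single(1.0), small_grid, prior,
        )
        assert len(posts) == three_tip_tree.n_nodes
        for p in posts:
            assert p.posterior.weights.sum() == pytest.approx(1.0)
            assert p.ci_lo <= p.point_x <= p.ci_hi


class TestChanges:
    def test_disjoint_intervals_are_credible(self, study_tree):
        # synthetic reconstruction: parent CI [1,2], child CI [3,4]
        recon = _fake_recon(study_tree, parent_ci=(1.0, 2.0), child_ci=(3.0, 4.0))
        changes = xr.call_changes(recon)
        row = changes[(changes.gene == "g1") & (changes.branch == 1)].iloc[0]
        assert row.direction == "increase" and row.credible

    def test_overlapping_intervals_not_credible(self, study_tree):
        recon = _fake_recon(study_tree, parent_ci=(1.0, 3.0), child_ci=(2.0, 4.0))
        changes = xr.call_changes(recon)
        row = changes[(changes.gene == "g1") & (changes.branch == 1)].iloc[0]
        assert row.direction == "increase" and not row.credible

    def test_sum_rule_on_simulated_data(self, study_tree, sim_dataset):
        table = sim_dataset.table.subset(range(60))
        grid = xr.build_grid(table, n=64)
        prior = evaluate_root_prior(grid)
        recon = xr.reconstruct(table, study_tree, RateModel.single(1.0), grid, prior)
        changes = xr.call_changes(recon)
        summary = xr.change_summary(changes, study_tree)
        assert (summary.increases + summary.decreases + summary.no_change
                == table.n_genes).all()
        assert (summary.credible_increases <= summary.increases).all()
        assert (summary.credible_decreases <= summary.decreases).all()

    def test_deep_branches_show_fewer_credible_changes(self, study_tree):
        # equal per-branch expected change; wider CIs deeper in the tree
        # should yield fewer credible calls on the root-adjacent branches
        config = xr.SimConfig(
            tree=study_tree, rates=RateModel.single(1.0), n_genes=400, seed=77
        )
        table, _ = xr.simulate(config)
        grid = xr.build_grid(table, n=64)
        prior = evaluate_root_prior(grid)
        recon = xr.reconstruct(table, study_tree, RateModel.single(1.0), grid, prior)
        summary = xr.change_summary(xr.call_changes(recon), study_tree)
        cred = (summary.credible_increases + summary.credible_decreases).values
        tips = set(study_tree.tips)
        tip_rate = np.mean([
            cred[i] / study_tree.lengths[b]
            for i, b in enumerate(study_tree.branches) if b in tips
        ])
        deep_rate = np.mean([
            cred[i] / study_tree.lengths[b]
            for i, b in enumerate(study_tree.branches) if b not in tips
        ])
        assert deep_rate < tip_rate

    def test_coverage_of_credible_intervals(self, study_tree):
        # 95% CIs should cover the simulator's true internal states ~95% of
        # the time (binomial noise band at this sample size)
        config = xr.SimConfig(
            tree=study_tree, rates=RateModel.single(1.0), n_genes=150, seed=31
        )
        table, states = xr.simulate(config)
        grid = xr.build_grid(table, n=128)
        prior = evaluate_root_prior(grid)
        recon = xr.reconstruct(table, study_tree, RateModel.single(1.0), grid, prior)
        internal = study_tree.internal_nodes
        truth = states[[str(v) for v in internal]].to_numpy()
        lo = recon.ci_lo[:, internal]
        hi = recon.ci_hi[:, internal]
        # half-bin slack: truth is continuous, bounds are bin centers
        covered = (truth >= lo - grid.delta / 2) & (truth <= hi + grid.delta / 2)
        rate = covered.mean()
        assert 0.90 <= rate <= 0.99


def _fake_recon(tree, parent_ci, child_ci):
    from exprate.reconstruction import ReconstructionSet

    n = tree.n_nodes
    point = np.full((1, n), np.mean(parent_ci))
    lo = np.full((1, n), parent_ci[0])
    hi = np.full((1, n), parent_ci[1])
    point[0, 1] = np.mean(child_ci)
    lo[0, 1] = child_ci[0]
    hi[0, 1] = child_ci[1]
    grid = xr.Grid(0.0, 10.0, 16)
    return ReconstructionSet(
        tree=tree, grid=grid, rates=RateModel.single(1.0),
        gene_ids=["g1"], samples=["default"],
        point=point, ci_lo=lo, ci_hi=hi, posteriors={},
    )
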