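import numpy as np
import pytest

import exprate as xr
from exprate.grid_kernel import tip_delta
from exprate.likelihood import KernelBank, RateModel, evaluate_root_prior
from oracle_utils import enumerate_three_tip


def _expr(x):
    """Log value -> linear expression with the default e_min = 1."""
    return np.exp(np.asarray(x)) - 1.0


@pytest.fixture(scope="module")
def wide_grid():
    return xr.Grid(0.0, np.log(40000.0), 400)


class TestRootPrior:
    def test_weights_sum_to_one(self, wide_grid):
        prior = evaluate_root_prior(wide_grid)
        assert prior.weights.sum() == pytest.approx(1.0)
        assert (prior.weights >= 0).all()

    def test_linear_scale_mean_is_shape_times_scale(self, wide_grid):
        prior = evaluate_root_prior(wide_grid)  # k=0.375, theta=1600
        e_centers = np.exp(wide_grid.centers) - 1.0
        mean = float(prior.weights @ e_centers)
        assert mean == pytest.approx(0.375 * 1600.0, rel=0.02)

    def test_shape_below_one_has_no_interior_linear_mode(self, wide_grid):
        prior = evaluate_root_prior(wide_grid)
        # density per unit E must be monotone decreasing for k < 1
        e_edges = np.exp(
            np.concatenate(
                (
                    [wide_grid.x_min],
                    (wide_grid.centers[:-1] + wide_grid.centers[1:]) / 2,
                    [wide_grid.x_max],
                )
            )
        ) - 1.0
        widths = np.diff(e_edges)
        density = prior.weights / widths
        assert (np.diff(density) <= 1e-12).all()

    def test_log_scale_variant_available(self, wide_grid):
        prior = evaluate_root_prior(wide_grid, prior_scale="log")
        assert prior.weights.sum() == pytest.approx(1.0)
        # the two conventions genuinely differ (Jacobian reweighting)
        lin = evaluate_root_prior(wide_grid, prior_scale="linear")
        assert np.abs(prior.weights - lin.weights).max() > 1e-4

    def test_invalid_parameters_rejected(self, wide_grid):
        with pytest.raises(ValueError):
            evaluate_root_prior(wide_grid, shape=-1.0)
        with pytest.raises(ValueError):
            evaluate_root_prior(wide_grid, prior_scale="bogus")


class TestRateModel:
    def test_single_rate_accessor(self):
        m = RateModel.single(2.0)
        assert m.sigma2(3) == 2.0
        assert m.n_params == 1

    def test_branch_model_requires_full_cover(self, three_tip_tree):
        m = RateModel.per_branch({b: 0 for b in three_tip_tree.branches})
        m.validate_for_tree(three_tip_tree)
        bad = RateModel.per_branch({1: 0, 2: 1})
        with pytest.raises(ValueError):
            bad.validate_for_tree(three_tip_tree)

    def test_restriction_detection(self):
        single = RateModel.single()
        two = RateModel.per_sample(["a", "b"])
        assert single.is_restriction_of(two)
        assert not two.is_restriction_of(single)
        branch_a = RateModel.per_branch({1: 0, 2: 0, 3: 1, 4: 1})
        branch_b = RateModel.per_branch({1: 0, 2: 1, 3: 1, 4: 0})
        assert not branch_a.is_restriction_of(branch_b)
        assert single.is_restriction_of(branch_a)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            RateModel.single(-1.0)
        with pytest.raises(ValueError):
            RateModel(kind="sample", n_params=2)


class TestPruningLikelihood:
    def test_matches_brute_force_enumeration(self, three_tip_tree, small_grid, table_factory):
        grid = small_grid
        prior = evaluate_root_prior(grid)
        rates = RateModel.single(0.7)
        bank = KernelBank(three_tip_tree, grid)
        kernels = bank.branch_kernels(rates)
        xa, xb, xc = 1.3, 2.2, 3.7
        table = table_factory(["A", "B", "C"], [_expr([xa, xb, xc])])
        ll = xr.total_log_likelihood(table, three_tip_tree, rates, grid, prior)
        tipidx = three_tip_tree.tip_index()
        ll_brute, _ = enumerate_three_tip(
            three_tip_tree, grid, kernels, prior.weights,
            {tipidx["A"]: xa, tipidx["B"]: xb, tipidx["C"]: xc},
        )
        assert ll == pytest.approx(ll_brute, abs=1e-10)

    def test_identity_limit_concentrates_at_shared_bin(self, table_factory):
        tree = xr.parse_newick("(A:1,B:1);")
        grid = xr.Grid(0.0, 5.0, 26)
        prior = evaluate_root_prior(grid)
        b = 10
        x = grid.centers[b]
        table = table_factory(["A", "B"], [_expr([x, x])])
        rates = RateModel.single(1e-12)
        ll = xr.total_log_likelihood(table, tree, rates, grid, prior)
        # density convention: each observed tip delta carries a 1/delta factor
        assert ll - 2 * np.log(1 / grid.delta) == pytest.approx(
            np.log(prior.weights[b]), abs=1e-6
        )

    def test_missing_tip_equals_marginalized_subtree(self, three_tip_tree, small_grid, table_factory):
        grid = small_grid
        prior = evaluate_root_prior(grid)
        rates = RateModel.single(0.9)
        bank = KernelBank(three_tip_tree, grid)
        kernels = bank.branch_kernels(rates)
        xa, xb = 1.1, 2.6
        table = table_factory(
            ["A", "B", "C"],
            [_expr([xa, xb, 1.0])],
            missing=[[False, False, True]],
        )
        ll = xr.total_log_likelihood(table, three_tip_tree, rates, grid, prior)
        # direct 2-tip computation: missing tip C marginalizes to an
        # all-ones message, so the root partial is T_stem (T_A dA * T_B dB)
        tipidx = three_tip_tree.tip_index()
        internal = [v for v in three_tip_tree.internal_nodes if v != 0][0]
        da = tip_delta(grid, xa) / grid.delta
        db = tip_delta(grid, xb) / grid.delta
        part = (kernels[tipidx["A"]] @ da) * (kernels[tipidx["B"]] @ db)
        direct = np.log(prior.weights @ (kernels[internal] @ part))
        assert ll == pytest.approx(direct, abs=1e-10)

    def test_all_tips_missing_rejected(self, three_tip_tree, small_grid, table_factory):
        prior = evaluate_root_prior(small_grid)
        table = table_factory(
            ["A", "B", "C"], [[1.0, 1.0, 1.0]], missing=[[True, True, True]]
        )
        with pytest.raises(ValueError, match="missing"):
            xr.total_log_likelihood(
                table, three_tip_tree, RateModel.single(1.0), small_grid, prior
            )

    def test_gene_log_likelihood_wrapper_agrees(self, three_tip_tree, small_grid):
        prior = evaluate_root_prior(small_grid)
        rates = RateModel.single(0.5)
        vals = _expr([1.0, 2.0, 3.0])
        gl = xr.gene_log_likelihood(
            vals, np.zeros(3, bool), ["A", "B", "C"], "g1",
            three_tip_tree, rates, small_grid, prior,
        )
        import exprate.phylo_io as pio

        table = pio.ExpressionTable(
            ["g1"], ["default"], [""], ["A", "B", "C"], vals[None, :],
            np.zeros((1, 3), bool),
        )
        total = xr.total_log_likelihood(table, three_tip_tree, rates, small_grid, prior)
        assert gl.log_lik == pytest.approx(total, abs=1e-12)


class TestTotalLikelihood:
    def test_two_identical_genes_double_the_loglik(self, three_tip_tree, small_grid, table_factory):
        prior = evaluate_root_prior(small_grid)
        rates = RateModel.single(1.0)
        row = _expr([1.0, 2.0, 3.0])
        one = table_factory(["A", "B", "C"], [row])
        two = table_factory(["A", "B", "C"], [row, row])
        ll1 = xr.total_log_likelihood(one, three_tip_tree, rates, small_grid, prior)
        ll2 = xr.total_log_likelihood(two, three_tip_tree, rates, small_grid, prior)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_row_order_invariance(self, three_tip_tree, small_grid, table_factory):
        prior = evaluate_root_prior(small_grid)
        rates = RateModel.single(1.0)
        rows = [_expr([1.0, 2.0, 3.0]), _expr([3.1, 0.4, 2.2]), _expr([0.1, 0.1, 4.0])]
        fwd = table_factory(["A", "B", "C"], rows)
        rev = table_factory(["A", "B", "C"], rows[::-1])
        assert xr.total_log_likelihood(fwd, three_tip_tree, rates, small_grid, prior) == \
            pytest.approx(xr.total_log_likelihood(rev, three_tip_tree, rates, small_grid, prior), rel=1e-12)

    def test_equal_rate_sample_model_matches_single(self, three_tip_tree, small_grid, table_factory):
        prior = evaluate_root_prior(small_grid)
        table = table_factory(
            ["A", "B", "C"],
            [_expr([1.0, 2.0, 3.0]), _expr([2.0, 2.5, 0.3])],
            samples=["s1", "s2"],
        )
        single = xr.total_log_likelihood(
            table, three_tip_tree, RateModel.single(0.8), small_grid, prior
        )
        multi = xr.total_log_likelihood(
            table, three_tip_tree,
            RateModel.per_sample(["s1", "s2"], values=[0.8, 0.8]),
            small_grid, prior,
        )
        assert multi == pytest.approx(single, rel=1e-12)

    def test_profile_is_smooth_and_unimodal_on_simulated_data(self, study_tree, sim_dataset):
        table = sim_dataset.table.subset(range(200))
        grid = xr.build_grid(table, n=64)
        prior = evaluate_root_prior(grid)
        bank = KernelBank(study_tree, grid)
        s2_grid = np.exp(np.linspace(np.log(0.05), np.log(20), 25))
        lls = [
            xr.total_log_likelihood(
                table, study_tree, RateModel.single(float(s)), grid, prior, kernel_bank=bank
            )
            for s in s2_grid
        ]
        lls = np.array(lls)
        assert np.all(np.isfinite(lls))
        peak = int(np.argmax(lls))
        assert 0 < peak < len(lls) - 1
        assert np.all(np.diff(lls[: peak + 1]) > 0)
        assert np.all(np.diff(lls[peak:]) < 0)
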