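"""Maximum-likelihood fitting of sigma^2 and likelihood-ratio model tests.

Rates are optimized with the Nelder-Mead simplex in log(sigma^2) coordinates
(positivity by construction), warm-started from a method-of-moments guess
(mean across genes of the tip-value variance on the log scale, divided by
tree depth).  Sample-based multi-rate models separate over sample groups and
are fitted one sample at a time; branch-based models are a joint search.
Nested models are compared with the usual chi-square likelihood-ratio test,
df equal to the difference in parameter count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .grid_kernel import Grid, build_grid
from .likelihood import (
    KernelBank,
    RateModel,
    RootPrior,
    evaluate_root_prior,
    total_log_likelihood,
)
from .phylo_io import ExpressionTable, PhyloTree

__all__ = [
    "FitResult",
    "LRTResult",
    "CalibrationResult",
    "fit",
    "likelihood_ratio_test",
    "calibrate_false_positive_rate",
]

DEFAULT_MAX_ITER = 300
CONVERGENCE_TOL = 1e-6
#: LRT statistics more negative than this indicate an optimizer failure
LRT_NEG_TOL = 1e-3
INITIAL_SIMPLEX_SPREAD = np.log(4.0)


@dataclass
class FitResult:
    rates: RateModel
    neg_log_lik: float
    n_evals: int
    n_iter: int
    converged: bool
    search_trace: list = field(default_factory=list)

    @property
    def log_lik(self) -> float:
        return -self.neg_log_lik


@dataclass
class LRTResult:
    stat: float
    df: int
    p_value: float


@dataclass
class CalibrationResult:
    proportion: float
    std_error: float
    n_datasets: int
    stats: np.ndarray


def _moment_guess(table: ExpressionTable, tree: PhyloTree, grid: Grid) -> float:
    """Scale guess for sigma^2: across-tip variance of log expression,
    averaged over genes, divided by the root-to-tip depth."""
    x = np.log(table.values + grid.e_min)
    x = np.where(table.missing, np.nan, x)
    n_obs = (~table.missing).sum(axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # genes with < 2 tips
        per_gene = np.nanvar(x, axis=1, ddof=1)
    per_gene = per_gene[n_obs >= 2]
    v = float(np.nanmean(per_gene)) if np.isfinite(per_gene).any() else np.nan
    depth = tree.depth
    if not np.isfinite(v) or v <= 0 or depth <= 0:
        return 1.0
    return max(v / depth, 1e-8)


def _nelder_mead(objective, x0: np.ndarray, max_iter: int, spread: float):
    """Minimize over log(sigma2) coordinates with a deterministic simplex."""
    ndim = x0.size
    simplex = np.tile(x0, (ndim + 1, 1))
    for i in range(ndim):
        simplex[i + 1, i] += spread
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": max_iter,
            "xatol": CONVERGENCE_TOL,
            "fatol": CONVERGENCE_TOL,
            "initial_simplex": simplex,
            "adaptive": False,
        },
    )
    return res


def fit(
    table: ExpressionTable,
    tree: PhyloTree,
    model_spec: RateModel | None = None,
    grid: Grid | None = None,
    prior: RootPrior | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Maximize the total log-likelihood over the model's sigma^2 values.

    ``model_spec`` is a :class:`RateModel` skeleton (values ignored);
    defaults to the single shared-rate model.  ``grid`` and ``prior`` default
    to the standard grid built from the table and the gamma(0.375, 1600)
    root prior.  ``seed`` is accepted for interface uniformity; the search
    itself is deterministic.  ``x0`` optionally overrides the warm start
    (sigma^2 scale, one per parameter).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    if model_spec is None:
        model_spec = RateModel.single()
    if grid is None:
        grid = build_grid(table)
    if prior is None:
        prior = evaluate_root_prior(grid)
    model_spec.validate_for_tree(tree)
    bank = KernelBank(tree, grid)

    if model_spec.kind == "sample":
        return _fit_per_sample(table, tree, model_spec, grid, prior, bank, max_iter, x0)

    guess = np.full(model_spec.n_params, _moment_guess(table, tree, grid)) if x0 is None \
        else np.asarray(x0, dtype=float)
    trace: list = []

    def objective(log_s2: np.ndarray) -> float:
        rates = model_spec.with_values(np.exp(log_s2))
        nll = -total_log_likelihood(table, tree, rates, grid, prior, kernel_bank=bank)
        trace.append((np.exp(log_s2).copy(), nll))
        return nll

    res = _nelder_mead(objective, np.log(guess), max_iter, INITIAL_SIMPLEX_SPREAD)
    if not np.isfinite(res.fun):
        raise RuntimeError("optimizer failed: non-finite likelihood at optimum")
    fitted = model_spec.with_values(np.exp(res.x))
    return FitResult(
        rates=fitted,
        neg_log_lik=float(res.fun),
        n_evals=int(res.nfev),
        n_iter=int(res.nit),
        converged=bool(res.success),
        search_trace=trace,
    )


def _fit_per_sample(table, tree, model_spec, grid, prior, bank, max_iter, x0):
    """Sample models separate over samples: fit each group independently."""
    by_sample = table.by_sample()
    missing = set(model_spec.sample_assignment) - set(by_sample)
    if missing:
        raise ValueError(f"model references samples absent from the table: {sorted(missing)}")
    extra = set(by_sample) - set(model_spec.sample_assignment)
    if extra:
        raise ValueError(f"table samples lack a rate assignment: {sorted(extra)}")

    values = np.empty(model_spec.n_params)
    total_nll = 0.0
    n_evals = n_iter = 0
    converged = True
    trace: list = []
    # several samples may share one parameter index; fit each index jointly
    # over its member samples (still a 1-D search per index)
    for pidx in range(model_spec.n_params):
        members = [s for s, i in model_spec.sample_assignment.items() if i == pidx]
        rows = [i for i, s in enumerate(table.samples) if s in members]
        sub = table.subset(rows)
        guess = _moment_guess(sub, tree, grid) if x0 is None else float(np.asarray(x0).ravel()[pidx])
        sub_trace: list = []

        def objective(log_s2: np.ndarray) -> float:
            rates = RateModel.single(float(np.exp(log_s2[0])))
            nll = -total_log_likelihood(sub, tree, rates, grid, prior, kernel_bank=bank)
            sub_trace.append((float(np.exp(log_s2[0])), nll))
            return nll

        res = _nelder_mead(objective, np.log([guess]), max_iter, INITIAL_SIMPLEX_SPREAD)
        values[pidx] = float(np.exp(res.x[0]))
        total_nll += float(res.fun)
        n_evals += int(res.nfev)
        n_iter += int(res.nit)
        converged = converged and bool(res.success)
        trace.append((pidx, sub_trace))

    fitted = model_spec.with_values(values)
    return FitResult(
        rates=fitted,
        neg_log_lik=total_nll,
        n_evals=n_evals,
        n_iter=n_iter,
        converged=converged,
        search_trace=trace,
    )


def likelihood_ratio_test(nested: FitResult, full: FitResult) -> LRTResult:
    """Chi-square LRT of a nested against a full model.

    ``stat = 2 (lnL_full - lnL_nested)``; df is the parameter-count
    difference.  Small negative statistics (optimizer jitter, |stat| <
    1e-3) are clamped to zero; larger negatives raise, signalling a failed
    full-model search.
    """
    if nested.rates.n_params >= full.rates.n_params:
        raise ValueError("nested model must have fewer parameters than the full model")
    if not nested.rates.is_restriction_of(full.rates):
        raise ValueError("models are not nested")
    stat = 2.0 * (nested.neg_log_lik - full.neg_log_lik)
    if stat < 0:
        if stat < -LRT_NEG_TOL:
            raise ValueError(
                f"likelihood-ratio statistic is negative ({stat:.6g}): "
                "the full-model optimization did not reach its optimum"
            )
        stat = 0.0
    df = full.rates.n_params - nested.rates.n_params
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(stat=float(stat), df=df, p_value=p)


def calibrate_false_positive_rate(
    sim_config,
    full_spec: RateModel,
    n_datasets: int,
    seed: int,
    nested_spec: RateModel | None = None,
    grid_n: int = 64,
    alpha: float = 0.05,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CalibrationResult:
    """Empirical type-I error of the LRT on data simulated under the nested
    (by default single-rate) model.

    Repeatedly simulates from ``sim_config`` (whose true rates must satisfy
    the nested model), fits nested and full models, and returns the fraction
    of datasets significant at ``alpha`` with its binomial standard error.
    The full branch-model search is warm-started at the nested optimum so
    the statistic is non-negative by construction.
    """
    from .simulate import simulate  # local import: simulator depends on likelihood
    from dataclasses import replace as dc_replace

    if n_datasets < 1:
        raise ValueError("n_datasets must be at least 1")
    if nested_spec is None:
        nested_spec = RateModel.single()
    rng = np.random.default_rng(seed)
    crit = stats.chi2.isf(alpha, full_spec.n_params - nested_spec.n_params)
    stats_out = np.empty(n_datasets)
    for d in range(n_datasets):
        config = dc_replace(sim_config, seed=int(rng.integers(2**31 - 1)))
        table, _ = simulate(config)
        grid = build_grid(table, n=grid_n)
        prior = evaluate_root_prior(grid, shape=config.prior_shape, scale=config.prior_scale)
        nested_fit = fit(table, config.tree, nested_spec, grid, prior, max_iter=max_iter)
        warm = None
        if full_spec.kind == "branch":
            warm = np.full(full_spec.n_params, float(nested_fit.rates.values[0]))
        full_fit = fit(table, config.tree, full_spec, grid, prior, max_iter=max_iter, x0=warm)
        lrt = likelihood_ratio_test(nested_fit, full_fit)
        stats_out[d] = lrt.stat
    prop = float(np.mean(stats_out > crit))
    se = float(np.sqrt(prop * (1 - prop) / n_datasets))
    return CalibrationResult(
        proportion=prop, std_error=se, n_datasets=n_datasets, stats=stats_out
    )
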