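"""Pruning likelihood for bounded Brownian motion on a tree.

Each gene's likelihood is computed by Felsenstein's pruning algorithm on the
discretized log-expression grid: tip partials are (interpolated) point masses
at the observed values, internal partials are elementwise products of the
children's partials pushed through the branch transition operators, and the
root partial is integrated against a root prior — by default a gamma
distribution over linear expression with shape k = 0.375 and scale
theta = 1600 (mean k*theta = 600 TPM).  The total log-likelihood is the sum
over genes; genes are independent given the tree and rates.

Log-likelihoods follow the density convention: observed tip masses carry a
1/delta factor and the root integral a delta factor, so values are comparable
across grid resolutions.  Missing tips contribute an all-ones message
(likelihood one for every ancestral state), not a normalized density.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .grid_kernel import (
    DiffusionOperator,
    DiscretizedDensity,
    Grid,
    build_diffusion_operator,
    tip_deltas,
    transition_operator,
)
from .phylo_io import DEFAULT_SAMPLE, ExpressionTable, PhyloTree

__all__ = [
    "RateModel",
    "RootPrior",
    "GeneLikelihood",
    "KernelBank",
    "evaluate_root_prior",
    "gene_log_likelihood",
    "total_log_likelihood",
]

DEFAULT_PRIOR_SHAPE = 0.375
DEFAULT_PRIOR_SCALE = 1600.0


@dataclass(frozen=True)
class RateModel:
    """Assignment of sigma^2 parameters to branches or samples.

    ``kind`` is ``"single"`` (one shared rate), ``"sample"`` (one rate per
    sample group) or ``"branch"`` (rates assigned to branch groups).
    ``values`` holds the sigma^2 parameters (log-expression^2 per unit time)
    and may be ``None`` for a model skeleton awaiting fitting.
    """

    kind: str
    n_params: int
    values: np.ndarray | None = None
    branch_assignment: dict | None = None
    sample_assignment: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single", "sample", "branch"):
            raise ValueError(f"unknown rate model kind {self.kind!r}")
        if self.n_params < 1:
            raise ValueError("a rate model needs at least one parameter")
        if self.kind == "single" and self.n_params != 1:
            raise ValueError("a single-rate model has exactly one parameter")
        if self.kind == "branch":
            if not self.branch_assignment:
                raise ValueError("branch model requires a branch assignment")
            used = set(self.branch_assignment.values())
            if used != set(range(self.n_params)):
                raise ValueError("branch assignment must use indices 0..n_params-1")
        if self.kind == "sample":
            if not self.sample_assignment:
                raise ValueError("sample model requires a sample assignment")
            used = set(self.sample_assignment.values())
            if used != set(range(self.n_params)):
                raise ValueError("sample assignment must use indices 0..n_params-1")
        if self.values is not None:
            vals = np.asarray(self.values, dtype=float)
            if vals.shape != (self.n_params,):
                raise ValueError("values length must equal n_params")
            if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
                raise ValueError("sigma2 values must be positive and finite")
            object.__setattr__(self, "values", vals)

    # -- constructors -------------------------------------------------------
    @classmethod
    def single(cls, sigma2: float | None = None) -> "RateModel":
        vals = None if sigma2 is None else np.array([sigma2], dtype=float)
        return cls(kind="single", n_params=1, values=vals)

    @classmethod
    def per_sample(
        cls, sample_names, values: np.ndarray | None = None
    ) -> "RateModel":
        names = list(sample_names)
        assignment = {name: i for i, name in enumerate(names)}
        return cls(
            kind="sample",
            n_params=len(names),
            values=None if values is None else np.asarray(values, float),
            sample_assignment=assignment,
        )

    @classmethod
    def per_branch(
        cls, branch_assignment: dict, values: np.ndarray | None = None
    ) -> "RateModel":
        n = len(set(branch_assignment.values()))
        return cls(
            kind="branch",
            n_params=n,
            values=None if values is None else np.asarray(values, float),
            branch_assignment=dict(branch_assignment),
        )

    # -- accessors ----------------------------------------------------------
    def with_values(self, values) -> "RateModel":
        return replace(self, values=np.asarray(values, dtype=float))

    def param_index(self, branch: int, sample: str) -> int:
        if self.kind == "single":
            return 0
        if self.kind == "sample":
            try:
                return self.sample_assignment[sample]
            except KeyError:
                raise KeyError(f"sample {sample!r} has no assigned rate parameter")
        try:
            return self.branch_assignment[branch]
        except KeyError:
            raise KeyError(f"branch {branch} has no assigned rate parameter")

    def sigma2(self, branch: int, sample: str = DEFAULT_SAMPLE) -> float:
        if self.values is None:
            raise ValueError("rate model has no values (skeleton)")
        return float(self.values[self.param_index(branch, sample)])

    def validate_for_tree(self, tree: PhyloTree) -> None:
        if self.kind == "branch":
            if set(self.branch_assignment) != set(tree.branches):
                raise ValueError("branch assignment must cover every branch exactly")
            if self.n_params > 2 * tree.n_tips - 2:
                raise ValueError(
                    f"at most 2n-2 = {2 * tree.n_tips - 2} branch parameters allowed"
                )

    def is_restriction_of(self, full: "RateModel") -> bool:
        """True when this model is nested in ``full`` (every group of
        ``full`` refines a group of this model)."""
        if self.n_params > full.n_params:
            return False
        if self.kind == "single":
            return True
        if self.kind != full.kind:
            return False
        ours = self.branch_assignment if self.kind == "branch" else self.sample_assignment
        theirs = full.branch_assignment if full.kind == "branch" else full.sample_assignment
        if set(ours) != set(theirs):
            return False
        seen: dict[int, int] = {}
        for key, fidx in theirs.items():
            if fidx in seen and seen[fidx] != ours[key]:
                return False
            seen[fidx] = ours[key]
        return True


@dataclass(frozen=True)
class RootPrior:
    """Discretized prior over the root's log expression."""

    shape: float
    scale: float
    weights: np.ndarray  # bin masses, sum 1
    grid: Grid

    def as_density(self) -> DiscretizedDensity:
        return DiscretizedDensity(self.grid, self.weights.copy())


def evaluate_root_prior(
    grid: Grid,
    shape: float = DEFAULT_PRIOR_SHAPE,
    scale: float = DEFAULT_PRIOR_SCALE,
    prior_scale: str = "linear",
) -> RootPrior:
    """Discretize the gamma root prior onto the log-expression grid.

    With ``prior_scale="linear"`` (default) the gamma is a distribution over
    linear expression E and each bin receives the exact gamma probability of
    its E-interval (CDF differences over the bin edges mapped through
    E = exp(x) - e_min); this matches the simulator, which draws root E from
    the same gamma.  With ``prior_scale="log"`` the gamma density is
    evaluated pointwise at the bin centers' E values without the change of
    variables — the alternative convention, exposed for comparison.
    Weights are renormalized to sum one over the grid either way.
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("prior shape and scale must be positive")
    e_min = grid.e_min
    dist = stats.gamma(a=shape, scale=scale)
    if prior_scale == "linear":
        edges = np.concatenate(
            (
                [grid.x_min],
                (grid.centers[:-1] + grid.centers[1:]) / 2.0,
                [grid.x_max + grid.delta / 2.0],
            )
        )
        e_edges = np.clip(np.exp(edges) - e_min, 0.0, None)
        cdf = dist.cdf(e_edges)
        w = np.diff(cdf)
    elif prior_scale == "log":
        e_centers = np.clip(np.exp(grid.centers) - e_min, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = dist.pdf(e_centers)
        w[~np.isfinite(w)] = 0.0
    else:
        raise ValueError("prior_scale must be 'linear' or 'log'")
    total = w.sum()
    if total <= 0:
        raise ValueError("root prior has no mass on the grid")
    return RootPrior(shape=shape, scale=scale, weights=w / total, grid=grid)


@dataclass
class GeneLikelihood:
    """Likelihood summary for one (gene, sample) row."""

    gene_id: str
    sample: str
    log_lik: float
    root_density: DiscretizedDensity


class KernelBank:
    """Cache of branch transition operators for one grid.

    The eigendecomposition of M is computed once; operators are cached by
    (branch length, sigma^2) so optimization sweeps only rebuild matrices for
    rates they have not visited.
    """

    def __init__(self, tree: PhyloTree, grid: Grid, op: DiffusionOperator | None = None):
        self.tree = tree
        self.grid = grid
        self.op = op if op is not None else build_diffusion_operator(grid.n)
        self._cache: dict[tuple[float, float], np.ndarray] = {}

    def kernel(self, length: float, sigma2: float) -> np.ndarray:
        key = (float(length), float(sigma2))
        t = self._cache.get(key)
        if t is None:
            t = transition_operator(self.op, self.grid, sigma2, length)
            self._cache[key] = t
        return t

    def branch_kernels(self, rates: RateModel, sample: str = DEFAULT_SAMPLE) -> dict:
        return {
            b: self.kernel(self.tree.lengths[b], rates.sigma2(b, sample))
            for b in self.tree.branches
        }


def _tip_messages(
    grid: Grid, x_obs: np.ndarray, missing: np.ndarray
) -> np.ndarray:
    """(n_bins, n_genes) message matrix for one tip across genes.

    Observed genes: interpolated delta scaled by 1/delta (a density in x).
    Missing genes: all-ones (likelihood one for every state).
    """
    n_genes = x_obs.shape[0]
    out = np.ones((grid.n, n_genes))
    obs = ~missing
    if obs.any():
        out[:, obs] = tip_deltas(grid, x_obs[obs]) / grid.delta
    return out


def _pruning_pass(
    x_log: np.ndarray,
    missing: np.ndarray,
    tree: PhyloTree,
    kernels: dict,
    grid: Grid,
    species_to_tip: dict,
    species: list,
    keep_partials: bool = False,
):
    """Vectorized post-order pruning over all genes at once.

    Returns (log_liks_without_prior, root_partial, partials, child_messages)
    where ``root_partial`` is (n_bins, n_genes) and log_liks accumulates the
    per-gene rescaling logs.  ``partials``/``child_messages`` are populated
    only when ``keep_partials`` (used by reconstruction).
    """
    n_genes = x_log.shape[0]
    col_of_tip = {species_to_tip[s]: j for j, s in enumerate(species)}
    logscale = np.zeros(n_genes)
    partials: dict[int, np.ndarray] = {}
    child_msgs: dict[int, np.ndarray] = {}

    for v in tree.postorder():
        if not tree.children[v]:
            j = col_of_tip[v]
            part = _tip_messages(grid, x_log[:, j], missing[:, j])
        else:
            part = None
            for c in tree.children[v]:
                msg = kernels[c] @ partials[c]
                if keep_partials:
                    child_msgs[c] = msg
                part = msg if part is None else part * msg
                if not keep_partials:
                    del partials[c]
        peak = part.max(axis=0)
        if np.any(peak <= 0):
            bad = int(np.argmax(peak <= 0))
            raise ValueError(f"zero partial likelihood for gene index {bad}")
        part = part / peak
        logscale += np.log(peak)
        partials[v] = part

    root_partial = partials[tree.root]
    return logscale, root_partial, partials, child_msgs


def _table_log_liks(
    table: ExpressionTable,
    tree: PhyloTree,
    kernels: dict,
    grid: Grid,
    prior: RootPrior,
    keep_partials: bool = False,
):
    if table.n_genes == 0:
        raise ValueError("expression table has no genes")
    all_missing = table.missing.all(axis=1)
    if all_missing.any():
        bad = [table.gene_ids[i] for i in np.nonzero(all_missing)[0][:5]]
        raise ValueError(f"genes with all tips missing: {bad}")
    x_log = np.where(table.missing, 0.0, np.log(table.values + grid.e_min))
    tip_idx = tree.tip_index()
    logscale, root_partial, partials, child_msgs = _pruning_pass(
        x_log, table.missing, tree, kernels, grid, tip_idx, table.species,
        keep_partials=keep_partials,
    )
    # integrate the root partial against the prior (delta-inclusive: the
    # prior weights are bin masses, so no extra delta factor appears here)
    marg = prior.weights @ root_partial
    if np.any(marg <= 0):
        bad = table.gene_ids[int(np.argmax(marg <= 0))]
        raise ValueError(f"zero marginal likelihood for gene {bad!r}")
    log_liks = np.log(marg) + logscale
    return log_liks, root_partial, partials, child_msgs


def gene_log_likelihood(
    row_values: np.ndarray,
    row_missing: np.ndarray,
    species: list,
    gene_id: str,
    tree: PhyloTree,
    rates: RateModel,
    grid: Grid,
    prior: RootPrior,
    kernel_bank: KernelBank | None = None,
    sample: str = DEFAULT_SAMPLE,
) -> GeneLikelihood:
    """Pruning log-likelihood of a single gene row (see module docstring)."""
    table = ExpressionTable(
        gene_ids=[gene_id],
        samples=[sample],
        descriptions=[""],
        species=list(species),
        values=np.asarray(row_values, float)[None, :],
        missing=np.asarray(row_missing, bool)[None, :],
    )
    bank = kernel_bank if kernel_bank is not None else KernelBank(tree, grid)
    kernels = bank.branch_kernels(rates, sample)
    log_liks, root_partial, _, _ = _table_log_liks(table, tree, kernels, grid, prior)
    dens = DiscretizedDensity(grid, np.maximum(root_partial[:, 0], 0.0))
    return GeneLikelihood(
        gene_id=gene_id, sample=sample, log_lik=float(log_liks[0]), root_density=dens
    )


def total_log_likelihood(
    table: ExpressionTable,
    tree: PhyloTree,
    rates: RateModel,
    grid: Grid,
    prior: RootPrior,
    kernel_bank: KernelBank | None = None,
) -> float:
    """Sum of per-gene log-likelihoods over the whole table.

    For sample-based models each sample group is evaluated with its own
    sigma^2; branch-based and single-rate models share one kernel set.
    """
    rates.validate_for_tree(tree)
    bank = kernel_bank if kernel_bank is not None else KernelBank(tree, grid)
    total = 0.0
    if rates.kind == "sample":
        for name, sub in table.by_sample().items():
            kernels = bank.branch_kernels(rates, name)
            log_liks, _, _, _ = _table_log_liks(sub, tree, kernels, grid, prior)
            total += float(log_liks.sum())
    else:
        kernels = bank.branch_kernels(rates)
        log_liks, _, _, _ = _table_log_liks(table, tree, kernels, grid, prior)
        total = float(log_liks.sum())
    return total
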