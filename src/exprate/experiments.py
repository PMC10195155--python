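"""Simulation-study protocols: rate accuracy, LRT calibration, pooled-rate bias.

Each function runs one of the package's standard validation experiments on
the default 5-tip study tree and returns its summary statistic.  They are
deliberately deterministic given a seed, so the same study can be replayed
at any scale.
"""

from __future__ import annotations

import numpy as np

from .grid_kernel import build_grid
from .inference import calibrate_false_positive_rate, fit
from .likelihood import RateModel, evaluate_root_prior
from .phylo_io import ExpressionTable, PhyloTree
from .simulate import SimConfig, default_study_tree, simulate

__all__ = [
    "adjacent_branch_groups",
    "dispersed_branch_groups",
    "lrt_calibration_two_sample",
    "lrt_calibration_branch",
    "rate_accuracy",
    "mixed_rate_bias",
    "missing_data_accuracy",
    "concat_tables",
]


def adjacent_branch_groups(tree: PhyloTree) -> dict:
    """Two-rate grouping with the rate classes adjacent: the clade spanned by
    the first two tips (pendant branches plus stem) against the rest."""
    a, b = tree.tips[:2]
    stem = int(tree.parent[a])
    group = {a, b} | ({stem} if stem != tree.root else set())
    return {br: (0 if br in group else 1) for br in tree.branches}


def dispersed_branch_groups(tree: PhyloTree) -> dict:
    """Two-rate grouping with the classes interleaved across the tree
    (alternating branches in id order)."""
    return {br: (i % 2) for i, br in enumerate(tree.branches)}


def lrt_calibration_two_sample(
    n_datasets: int = 200,
    n_genes: int = 200,
    sigma2: float = 1.0,
    grid_n: int = 64,
    seed: int = 0,
    tree: PhyloTree | None = None,
):
    """Type-I error of the df=1 LRT for a two-sample model on single-rate
    data (genes split into two equal samples)."""
    if tree is None:
        tree = default_study_tree()
    half = n_genes // 2
    config = SimConfig(
        tree=tree,
        rates=RateModel.per_sample(["s1", "s2"], values=[sigma2, sigma2]),
        n_genes={"s1": half, "s2": n_genes - half},
        seed=0,
    )
    full = RateModel.per_sample(["s1", "s2"])
    return calibrate_false_positive_rate(
        config, full, n_datasets=n_datasets, seed=seed, grid_n=grid_n
    )


def lrt_calibration_branch(
    grouping: str,
    n_datasets: int = 200,
    n_genes: int = 200,
    sigma2: float = 1.0,
    grid_n: int = 64,
    seed: int = 0,
    tree: PhyloTree | None = None,
):
    """Type-I error of the df=1 LRT for a two-rate branch model
    (``grouping`` = 'adjacent' or 'dispersed') on single-rate data."""
    if tree is None:
        tree = default_study_tree()
    groups = (
        adjacent_branch_groups(tree)
        if grouping == "adjacent"
        else dispersed_branch_groups(tree)
    )
    config = SimConfig(
        tree=tree, rates=RateModel.single(sigma2), n_genes=n_genes, seed=0
    )
    full = RateModel.per_branch(groups)
    return calibrate_false_positive_rate(
        config, full, n_datasets=n_datasets, seed=seed, grid_n=grid_n
    )


def rate_accuracy(
    sigma2_values=(0.25, 1.0, 4.0),
    n_replicates: int = 20,
    n_genes: int = 1000,
    grid_n: int = 200,
    seed: int = 0,
    tree: PhyloTree | None = None,
) -> dict:
    """Relative error of the single shared-rate estimate per true rate.

    Returns {sigma2: array of |sigma2_hat - sigma2| / sigma2 over replicates}.
    """
    if tree is None:
        tree = default_study_tree()
    rng = np.random.default_rng(seed)
    out = {}
    for s2 in sigma2_values:
        errs = np.empty(n_replicates)
        for r in range(n_replicates):
            config = SimConfig(
                tree=tree,
                rates=RateModel.single(float(s2)),
                n_genes=n_genes,
                seed=int(rng.integers(2**31 - 1)),
            )
            table, _ = simulate(config)
            grid = build_grid(table, n=grid_n)
            prior = evaluate_root_prior(grid)
            res = fit(table, tree, RateModel.single(), grid, prior)
            errs[r] = abs(res.rates.values[0] - s2) / s2
        out[float(s2)] = errs
    return out


def concat_tables(tables, prefix_ids: bool = True) -> ExpressionTable:
    """Stack tables sharing the same species into one (gene ids made unique)."""
    first = tables[0]
    gene_ids, samples, descs, vals, miss = [], [], [], [], []
    for k, t in enumerate(tables):
        if t.species != first.species:
            raise ValueError("tables must share the same species columns")
        ids = [f"set{k + 1}.{g}" for g in t.gene_ids] if prefix_ids else list(t.gene_ids)
        gene_ids += ids
        samples += list(t.samples)
        descs += list(t.descriptions)
        vals.append(t.values)
        miss.append(t.missing)
    return ExpressionTable(
        gene_ids=gene_ids,
        samples=samples,
        descriptions=descs,
        species=list(first.species),
        values=np.vstack(vals),
        missing=np.vstack(miss),
    )


def mixed_rate_bias(
    sigma2_values=(0.5, 3.0, 9.0),
    n_genes_each: int = 300,
    n_replicates: int = 5,
    grid_n: int = 200,
    seed: int = 0,
    tree: PhyloTree | None = None,
) -> np.ndarray:
    """Single shared-rate estimates on data pooled from several true rates.

    Returns the per-replicate sigma2_hat; fitting one rate to heterogeneous
    data is expected to land below the arithmetic mean of the true rates.
    """
    if tree is None:
        tree = default_study_tree()
    rng = np.random.default_rng(seed)
    ests = np.empty(n_replicates)
    for r in range(n_replicates):
        tables = []
        for s2 in sigma2_values:
            config = SimConfig(
                tree=tree,
                rates=RateModel.single(float(s2)),
                n_genes=n_genes_each,
                seed=int(rng.integers(2**31 - 1)),
            )
            tables.append(simulate(config).table)
        pooled = concat_tables(tables)
        grid = build_grid(pooled, n=grid_n)
        prior = evaluate_root_prior(grid)
        res = fit(pooled, tree, RateModel.single(), grid, prior)
        ests[r] = float(res.rates.values[0])
    return ests


def missing_data_accuracy(
    missing_fraction: float = 0.75,
    n_genes: int = 1000,
    sigma2: float = 1.0,
    grid_n: int = 200,
    seed: int = 0,
    tree: PhyloTree | None = None,
) -> float:
    """Single shared-rate estimate on one dataset with cells masked at random."""
    if tree is None:
        tree = default_study_tree()
    config = SimConfig(
        tree=tree,
        rates=RateModel.single(sigma2),
        n_genes=n_genes,
        missing_fraction=missing_fraction,
        seed=seed,
    )
    table, _ = simulate(config)
    informative = np.nonzero(~table.missing.all(axis=1))[0]
    table = table.subset(informative)  # all-missing rows carry no signal
    grid = build_grid(table, n=grid_n)
    prior = evaluate_root_prior(grid)
    res = fit(table, tree, RateModel.single(), grid, prior)
    return float(res.rates.values[0])
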