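"""Forward simulation of expression evolution under bounded Brownian motion.

Each gene's root expression is drawn from the gamma root prior (linear
scale), log-transformed, and evolved down the tree: along a branch of length
t with rate sigma^2 the increment is Normal(0, sigma^2 t), and a draw
falling below the boundary x_min is reflected once (x -> 2 x_min - x).  With
a single reflecting boundary that single reflection is the exact transition
law (method of images), so no time-stepping is needed.  There is no upper
bound, matching the model; the inference grid's finite upper edge is a
numerical device and expands to cover whatever the simulator produces.

Tips are reported on the linear scale E = exp(x) - e_min and an optional
i.i.d. Bernoulli missing mask is applied per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .likelihood import DEFAULT_PRIOR_SCALE, DEFAULT_PRIOR_SHAPE, RateModel
from .phylo_io import DEFAULT_SAMPLE, ExpressionTable, PhyloTree, parse_newick

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate",
    "simulate_study",
    "default_study_tree",
]

#: 5-tip ultrametric study tree (depth 3) used throughout the simulation
#: experiments; all tips are equidistant from the root.
DEFAULT_STUDY_TREE = "((A:1,B:1):2,((C:1,D:1):1,E:2):1);"


def default_study_tree() -> PhyloTree:
    return parse_newick(DEFAULT_STUDY_TREE)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    ``n_genes`` is either an int (all genes in the default sample) or a
    mapping sample-name -> count.  ``rates`` must carry true sigma^2 values;
    sample-kind rate models pair with the sample structure of ``n_genes``.
    """

    tree: PhyloTree
    rates: RateModel
    n_genes: int | dict = 1000
    prior_shape: float = DEFAULT_PRIOR_SHAPE
    prior_scale: float = DEFAULT_PRIOR_SCALE
    e_min: float = 1.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rates.values is None:
            raise ValueError("simulation requires true sigma2 values")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.e_min <= 0:
            raise ValueError("e_min must be positive")
        counts = self.gene_counts()
        if any(c < 1 for c in counts.values()):
            raise ValueError("each sample needs at least one gene")

    def gene_counts(self) -> dict:
        if isinstance(self.n_genes, dict):
            return dict(self.n_genes)
        return {DEFAULT_SAMPLE: int(self.n_genes)}


class SimResult(NamedTuple):
    table: ExpressionTable
    states: pd.DataFrame
    """True log-expression states, one row per (gene, sample), one column
    per node id."""


def _simulate_sample(
    tree: PhyloTree,
    rates: RateModel,
    sample: str,
    n_genes: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_genes, n_nodes) matrix of true log-expression states."""
    x_min = np.log(config.e_min)
    x = np.empty((n_genes, tree.n_nodes))
    root_e = rng.gamma(shape=config.prior_shape, scale=config.prior_scale, size=n_genes)
    x[:, tree.root] = np.log(root_e + config.e_min)
    for v in tree.preorder():
        if v == tree.root:
            continue
        s2 = rates.sigma2(v, sample)
        sd = np.sqrt(s2 * tree.lengths[v])
        raw = x[:, tree.parent[v]] + rng.normal(0.0, 1.0, size=n_genes) * sd
        x[:, v] = np.where(raw < x_min, 2.0 * x_min - raw, raw)
    return x


def simulate(config: SimConfig) -> SimResult:
    """Simulate an expression table (plus true node states) under ``config``."""
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    tips = tree.tips
    species = [tree.labels[t] for t in tips]

    gene_ids: list[str] = []
    samples: list[str] = []
    blocks: list[np.ndarray] = []
    for sample, count in config.gene_counts().items():
        x = _simulate_sample(tree, config.rates, sample, count, config, rng)
        blocks.append(x)
        gene_ids.extend(f"g{i + 1}" for i in range(count))
        samples.extend([sample] * count)
    states = np.vstack(blocks)

    tip_x = states[:, tips]
    values = np.exp(tip_x) - config.e_min
    np.maximum(values, 0.0, out=values)  # exact-boundary round-off
    missing = np.zeros_like(values, dtype=bool)
    if config.missing_fraction > 0:
        # faithful i.i.d. per-cell mask; genes may lose every tip, and such
        # rows are dropped by the analysis (they carry no information)
        missing = rng.random(values.shape) < config.missing_fraction
    shown = np.where(missing, np.nan, values)

    table = ExpressionTable(
        gene_ids=gene_ids,
        samples=samples,
        descriptions=[""] * len(gene_ids),
        species=species,
        values=shown,
        missing=missing,
    )
    states_df = pd.DataFrame(
        states, columns=[str(v) for v in range(tree.n_nodes)]
    )
    states_df.insert(0, "gene", gene_ids)
    states_df.insert(1, "sample", samples)
    return SimResult(table=table, states=states_df)


def simulate_study(
    sigma2_values,
    n_genes_values,
    n_replicates: int,
    seed: int,
    tree: PhyloTree | None = None,
    missing_fraction: float = 0.0,
) -> dict:
    """Grid of seeded simulations: sigma^2 x dataset size x replicate.

    Returns {(sigma2, n_genes, replicate): SimResult}; the same seed always
    reproduces the same collection bit-for-bit.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if tree is None:
        tree = default_study_tree()
    rng = np.random.default_rng(seed)
    out = {}
    for s2 in sigma2_values:
        for g in n_genes_values:
            for r in range(n_replicates):
                config = SimConfig(
                    tree=tree,
                    rates=RateModel.single(float(s2)),
                    n_genes=int(g),
                    missing_fraction=missing_fraction,
                    seed=int(rng.integers(2**31 - 1)),
                )
                out[(float(s2), int(g), r)] = simulate(config)
    return out
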