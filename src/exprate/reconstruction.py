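"""Ancestral-state posteriors, credible intervals and per-branch change calls.

Marginal posteriors at every node come from two-pass belief propagation on
the discretized grid: the upward pass is the pruning recursion, the downward
pass starts from the root prior, and the node marginal is the normalized
elementwise product of the two.  Point estimates are posterior means on the
log grid (also reported as linear expression).  The default 95% credible
interval is the shortest contiguous run of bins holding at least 95% of the
posterior mass (highest-density-like); an equal-tail variant is available.

A branch change is *credible* when the parent's and child's credible
intervals do not overlap; change directions come from the sign of the
point-estimate difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_kernel import DiscretizedDensity, Grid, build_grid
from .likelihood import (
    KernelBank,
    RateModel,
    RootPrior,
    _table_log_liks,
    evaluate_root_prior,
)
from .phylo_io import DEFAULT_SAMPLE, ExpressionTable, PhyloTree

__all__ = [
    "NodePosterior",
    "BranchChange",
    "ReconstructionSet",
    "reconstruct",
    "node_posteriors",
    "call_changes",
    "change_summary",
    "credible_interval",
]

CI_MASS = 0.95
#: point-estimate differences below this (log units) count as "no change"
CHANGE_TIE_TOL = 1e-9


@dataclass
class NodePosterior:
    node: int
    posterior: DiscretizedDensity
    point_x: float
    point_e: float
    ci_lo: float
    ci_hi: float


@dataclass
class BranchChange:
    gene_id: str
    sample: str
    branch: int
    delta_x: float
    delta_e: float
    direction: str  # "increase" | "decrease" | "none"
    credible: bool


@dataclass
class ReconstructionSet:
    """Posterior summaries for every gene x node.

    Arrays are (n_genes, n_nodes): ``point`` (posterior mean, log scale),
    ``ci_lo``/``ci_hi`` (95% credible bounds, log scale).  ``posteriors``
    maps node id -> (n_bins, n_genes) posterior mass matrix.
    """

    tree: PhyloTree
    grid: Grid
    rates: RateModel
    gene_ids: list
    samples: list
    point: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    posteriors: dict
    log_lik: float | None = None


def credible_interval(
    weights: np.ndarray,
    centers: np.ndarray,
    mass: float = CI_MASS,
    method: str = "hpd",
    point: float | None = None,
) -> tuple[float, float]:
    """Bounds (bin centers) of a credible interval for a discrete posterior.

    ``method="hpd"``: shortest contiguous run of bins with total mass >=
    ``mass`` (ties broken toward the run containing ``point``, then the
    leftmost).  ``method="equal-tail"``: central interval cutting mass/2
    from each tail.
    """
    w = np.asarray(weights, float)
    total = w.sum()
    if total <= 0:
        raise ValueError("posterior has no mass")
    w = w / total
    n = w.size
    if method == "equal-tail":
        c = np.cumsum(w)
        tail = (1.0 - mass) / 2.0
        lo = int(np.searchsorted(c, tail, side="left"))
        hi = int(np.searchsorted(c, 1.0 - tail, side="left"))
        return float(centers[lo]), float(centers[min(hi, n - 1)])
    if method != "hpd":
        raise ValueError("method must be 'hpd' or 'equal-tail'")
    c = np.concatenate(([0.0], np.cumsum(w)))
    target = mass - 1e-12  # tolerate round-off on exact-mass windows
    # two-pointer scan for the shortest window with mass >= target
    best_len = n + 1
    candidates: list[tuple[int, int]] = []
    lo = 0
    for hi in range(n):
        while c[hi + 1] - c[lo + 1] >= target:  # window can shrink from the left
            lo += 1
        # window [lo, hi] is the smallest left edge for this hi with >= mass
        if c[hi + 1] - c[lo] >= target:
            length = hi - lo + 1
            if length < best_len:
                best_len = length
                candidates = [(lo, hi)]
            elif length == best_len:
                candidates.append((lo, hi))
    if not candidates:
        return float(centers[0]), float(centers[-1])
    if point is not None and len(candidates) > 1:
        inside = [
            (a, b) for a, b in candidates if centers[a] <= point <= centers[b]
        ]
        if inside:
            candidates = inside
    a, b = candidates[0]
    return float(centers[a]), float(centers[b])


def reconstruct(
    table: ExpressionTable,
    tree: PhyloTree,
    rates: RateModel,
    grid: Grid | None = None,
    prior: RootPrior | None = None,
    kernel_bank: KernelBank | None = None,
    ci_mass: float = CI_MASS,
    ci_method: str = "hpd",
) -> ReconstructionSet:
    """Marginal ancestral-state posteriors for every gene at every node."""
    if rates.values is None:
        raise ValueError("reconstruction requires fitted (or fixed) sigma2 values")
    if grid is None:
        grid = build_grid(table)
    if prior is None:
        prior = evaluate_root_prior(grid)
    bank = kernel_bank if kernel_bank is not None else KernelBank(tree, grid)
    rates.validate_for_tree(tree)

    n_nodes = tree.n_nodes
    point = np.empty((table.n_genes, n_nodes))
    ci_lo = np.empty_like(point)
    ci_hi = np.empty_like(point)
    posteriors: dict[int, np.ndarray] = {}
    total_ll = 0.0

    order = np.empty(table.n_genes, dtype=int)
    pos = 0
    for sample, sub in table.by_sample().items():
        rows = [i for i, s in enumerate(table.samples) if s == sample]
        kernels = bank.branch_kernels(rates, sample)
        res = _reconstruct_sample(sub, tree, kernels, grid, prior, ci_mass, ci_method)
        sub_point, sub_lo, sub_hi, sub_post, sub_ll = res
        idx = np.asarray(rows)
        point[idx] = sub_point
        ci_lo[idx] = sub_lo
        ci_hi[idx] = sub_hi
        for v, mat in sub_post.items():
            if v not in posteriors:
                posteriors[v] = np.empty((grid.n, table.n_genes))
            posteriors[v][:, idx] = mat
        total_ll += sub_ll
        order[pos : pos + len(rows)] = idx
        pos += len(rows)

    return ReconstructionSet(
        tree=tree,
        grid=grid,
        rates=rates,
        gene_ids=list(table.gene_ids),
        samples=list(table.samples),
        point=point,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        posteriors=posteriors,
        log_lik=total_ll,
    )


def _reconstruct_sample(table, tree, kernels, grid, prior, ci_mass, ci_method):
    log_liks, root_partial, partials, child_msgs = _table_log_liks(
        table, tree, kernels, grid, prior, keep_partials=True
    )
    n_genes = table.n_genes
    # downward messages; root's downward message is the prior itself
    downward: dict[int, np.ndarray] = {
        tree.root: np.repeat(prior.weights[:, None], n_genes, axis=1)
    }
    for v in tree.preorder():
        if not tree.children[v]:
            continue
        kids = tree.children[v]
        for c in kids:
            other = downward[v].copy()
            for s in kids:
                if s != c:
                    other *= child_msgs[s]
            msg = kernels[c] @ other  # kernels are symmetric: T^T = T
            peak = msg.max(axis=0)
            peak[peak <= 0] = 1.0
            downward[c] = msg / peak

    x_log = np.where(table.missing, 0.0, np.log(table.values + grid.e_min))
    tip_idx = tree.tip_index()
    col_of_tip = {tip_idx[s]: j for j, s in enumerate(table.species)}

    point = np.empty((n_genes, tree.n_nodes))
    ci_lo = np.empty_like(point)
    ci_hi = np.empty_like(point)
    posteriors: dict[int, np.ndarray] = {}
    centers = grid.centers

    for v in range(tree.n_nodes):
        post = partials[v] * downward[v]
        tot = post.sum(axis=0)
        bad = tot <= 0
        if bad.any():
            raise ValueError("degenerate posterior (no overlapping support)")
        post = post / tot
        posteriors[v] = post
        point[:, v] = centers @ post
        for g in range(n_genes):
            lo, hi = credible_interval(
                post[:, g], centers, mass=ci_mass, method=ci_method,
                point=point[g, v],
            )
            ci_lo[g, v] = lo
            ci_hi[g, v] = hi
        is_tip = not tree.children[v]
        if is_tip:
            j = col_of_tip[v]
            obs = ~table.missing[:, j]
            # observed tips: the point estimate is the measurement itself
            point[obs, v] = x_log[obs, j]
            ci_lo[obs, v] = np.minimum(ci_lo[obs, v], x_log[obs, j])
            ci_hi[obs, v] = np.maximum(ci_hi[obs, v], x_log[obs, j])

    return point, ci_lo, ci_hi, posteriors, float(log_liks.sum())


def node_posteriors(
    row_values: np.ndarray,
    row_missing: np.ndarray,
    species: list,
    tree: PhyloTree,
    rates: RateModel,
    grid: Grid,
    prior: RootPrior,
    gene_id: str = "gene",
    sample: str = DEFAULT_SAMPLE,
    ci_method: str = "hpd",
) -> list[NodePosterior]:
    """Single-gene convenience wrapper around :func:`reconstruct`."""
    table = ExpressionTable(
        gene_ids=[gene_id],
        samples=[sample],
        descriptions=[""],
        species=list(species),
        values=np.asarray(row_values, float)[None, :],
        missing=np.asarray(row_missing, bool)[None, :],
    )
    if rates.kind == "sample" and sample not in (rates.sample_assignment or {}):
        raise ValueError(f"sample {sample!r} has no rate assignment")
    recon = reconstruct(table, tree, rates, grid, prior, ci_method=ci_method)
    e_min = grid.e_min
    out = []
    for v in range(tree.n_nodes):
        dens = DiscretizedDensity(grid, recon.posteriors[v][:, 0].copy())
        x = float(recon.point[0, v])
        out.append(
            NodePosterior(
                node=v,
                posterior=dens,
                point_x=x,
                point_e=max(math.exp(x) - e_min, 0.0),
                ci_lo=float(recon.ci_lo[0, v]),
                ci_hi=float(recon.ci_hi[0, v]),
            )
        )
    return out


def call_changes(recon: ReconstructionSet) -> pd.DataFrame:
    """Per-gene, per-branch expression changes with credibility calls.

    Returns a DataFrame with one row per (gene, branch): the change in the
    point estimate (log and linear scale), its direction, and whether the
    parent and child credible intervals are disjoint.
    """
    tree = recon.tree
    e_min = recon.grid.e_min
    rows = []
    for b in tree.branches:
        p = tree.parent[b]
        d_x = recon.point[:, b] - recon.point[:, p]
        cred_inc = recon.ci_hi[:, p] < recon.ci_lo[:, b]
        cred_dec = recon.ci_hi[:, b] < recon.ci_lo[:, p]
        direction = np.where(
            np.abs(d_x) < CHANGE_TIE_TOL,
            "none",
            np.where(d_x > 0, "increase", "decrease"),
        )
        credible = (cred_inc & (direction == "increase")) | (
            cred_dec & (direction == "decrease")
        )
        d_e = (np.exp(recon.point[:, b]) - e_min) - (np.exp(recon.point[:, p]) - e_min)
        for i in range(len(recon.gene_ids)):
            rows.append(
                {
                    "gene": recon.gene_ids[i],
                    "sample": recon.samples[i],
                    "branch": b,
                    "parent": int(p),
                    "branch_label": tree.labels[b] or f"<{b}>",
                    "delta_log": float(d_x[i]),
                    "delta_linear": float(d_e[i]),
                    "direction": str(direction[i]),
                    "credible": bool(credible[i]),
                }
            )
    return pd.DataFrame(rows)


def change_summary(changes: pd.DataFrame, tree: PhyloTree) -> pd.DataFrame:
    """Per-branch tallies over genes: increases/decreases and credible ones."""
    rows = []
    for b in tree.branches:
        sub = changes[changes["branch"] == b]
        inc = sub["direction"] == "increase"
        dec = sub["direction"] == "decrease"
        rows.append(
            {
                "branch": b,
                "branch_label": tree.labels[b] or f"<{b}>",
                "n_genes": len(sub),
                "increases": int(inc.sum()),
                "decreases": int(dec.sum()),
                "no_change": int((sub["direction"] == "none").sum()),
                "credible_increases": int((inc & sub["credible"]).sum()),
                "credible_decreases": int((dec & sub["credible"]).sum()),
            }
        )
    return pd.DataFrame(rows)
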