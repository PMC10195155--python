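"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning/belief-propagation code
paths: likelihoods and marginals are computed by exhaustive enumeration
over discretized ancestral states, and transition densities by the
closed-form free/reflected normal solution.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from exprate.grid_kernel import Grid, tip_delta


def reflected_normal_bin_masses(
    grid: Grid, x0: float, variance: float
) -> np.ndarray:
    """Exact bounded-Brownian transition law binned onto the grid.

    Density = normal(x0, variance) plus its mirror image about x_min
    (method of images for a single reflecting boundary); each bin receives
    the integral of that density over its interval.
    """
    sd = np.sqrt(variance)
    # the discrete Neumann operator's reflecting wall sits half a bin below
    # the first bin center (eigenvectors cos(k pi (j+1/2)/N)), so the
    # continuous analogue lives on [wall, inf) with wall = x_min - delta/2
    # and every bin, including the first, is a full-width interval
    wall = grid.x_min - grid.delta / 2.0
    edges = np.concatenate(
        (
            [wall],
            (grid.centers[:-1] + grid.centers[1:]) / 2.0,
            [np.inf],
        )
    )
    direct = stats.norm.cdf(edges, loc=x0, scale=sd)
    mirror = stats.norm.cdf(edges, loc=2 * wall - x0, scale=sd)
    return np.diff(direct) + np.diff(mirror)


def enumerate_three_tip(
    tree, grid: Grid, kernels: dict, prior_weights: np.ndarray, tip_values: dict,
):
    """Brute-force joint sum for a 3-tip tree ((A,B)I, C) with root R.

    ``tip_values`` maps tip node id -> observed log value or None (missing).
    Returns (log_lik, marginals) where marginals maps every node id to its
    normalized posterior over grid states; the likelihood uses the same
    density convention as the package (observed tip deltas carry 1/delta).
    """
    root = tree.root
    internal = [v for v in tree.internal_nodes if v != root][0]
    ab = list(tree.children[internal])
    c = [v for v in tree.children[root] if v != internal][0]

    def tip_msg(v):
        x = tip_values[v]
        if x is None:
            return np.ones(grid.n)
        return tip_delta(grid, x) / grid.delta

    msgs = {v: tip_msg(v) for v in (*ab, c)}
    n = grid.n
    marg = {v: np.zeros(n) for v in (root, internal, *ab, c)}
    total = 0.0
    for r in range(n):
        like_c_vec = kernels[c][:, r] * msgs[c]
        like_c = like_c_vec.sum()
        for i in range(n):
            like_ab = 1.0
            parts = []
            for t in ab:
                vec = kernels[t][:, i] * msgs[t]
                parts.append(vec)
                like_ab *= vec.sum()
            w = prior_weights[r] * kernels[internal][i, r] * like_ab * like_c
            total += w
            marg[root][r] += w
            marg[internal][i] += w
            # tip marginals: distribute w over tip states proportionally
            for t, vec in zip(ab, parts):
                s = vec.sum()
                if s > 0:
                    marg[t] += (prior_weights[r] * kernels[internal][i, r] * like_c
                                * (like_ab / s)) * vec
        if like_c > 0:
            # tip C marginal accumulates over internal states
            inner = sum(
                kernels[internal][i, r]
                * np.prod([(kernels[t][:, i] * msgs[t]).sum() for t in ab])
                for i in range(n)
            )
            marg[c] += prior_weights[r] * inner * like_c_vec
    for v in marg:
        s = marg[v].sum()
        if s > 0:
            marg[v] = marg[v] / s
    return np.log(total), marg
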