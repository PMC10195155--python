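"""Discretization of the log-expression axis and the bounded-diffusion kernel.

Log expression X = ln(E + e_min) evolves by Brownian motion with a reflecting
boundary at x_min = ln(e_min).  On a uniform grid of N bins the diffusion
generator becomes the tridiagonal Neumann Laplacian M (diagonal -2 with -1 in
the two corner entries, off-diagonals 1), whose column sums vanish so
probability is conserved.  The finite-time transition operator is

    T(c) = exp(c M),   c = sigma^2 * dt / (2 delta^2),

evaluated through a single eigendecomposition of M that is reused for every
(sigma^2, dt) pair.  The grid's upper edge is a numerical device only (the
model itself has no upper bound), so grids are built with headroom above the
largest observed value.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.linalg import eigh_tridiagonal

__all__ = [
    "Grid",
    "DiffusionOperator",
    "DiscretizedDensity",
    "build_grid",
    "grid_from_values",
    "build_diffusion_operator",
    "transition_operator",
    "tip_delta",
    "propagate",
]

DEFAULT_N = 200
DEFAULT_E_MIN = 1.0
#: negative matrix-exponential entries beyond this are a numerical bug
NEGATIVITY_TOL = -1e-12


@dataclass(frozen=True)
class Grid:
    """Uniform grid of ``n`` bin centers spanning [x_min, x_max] in log
    expression; bin width delta = (x_max - x_min)/(n - 1)."""

    x_min: float
    x_max: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"grid needs at least 3 bins, got {self.n}")
        if not self.x_max > self.x_min:
            raise ValueError("x_max must exceed x_min")

    @property
    def delta(self) -> float:
        return (self.x_max - self.x_min) / (self.n - 1)

    @cached_property
    def centers(self) -> np.ndarray:
        c = np.linspace(self.x_min, self.x_max, self.n)
        c.flags.writeable = False
        return c

    @property
    def e_min(self) -> float:
        return float(np.exp(self.x_min))


@dataclass(frozen=True)
class DiffusionOperator:
    """Neumann Laplacian ``M`` with its precomputed eigendecomposition.

    Eigenvalues are ``-4 sin^2(k pi / (2N))`` for ``k = 0..N-1``; the zero
    eigenvalue's constant eigenvector makes the uniform distribution
    stationary.
    """

    n: int
    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class DiscretizedDensity:
    """Non-negative probability mass per grid bin."""

    grid: Grid
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.grid.n,):
            raise ValueError("density length does not match grid")
        if np.any(self.weights < 0):
            raise ValueError("density weights must be non-negative")

    def normalized(self) -> "DiscretizedDensity":
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero density")
        return DiscretizedDensity(self.grid, self.weights / total)

    def mean(self) -> float:
        w = self.weights / self.weights.sum()
        return float(w @ self.grid.centers)

    def variance(self) -> float:
        w = self.weights / self.weights.sum()
        m = w @ self.grid.centers
        return float(w @ (self.grid.centers - m) ** 2)


def grid_from_values(
    values: np.ndarray,
    e_min: float = DEFAULT_E_MIN,
    n: int = DEFAULT_N,
    headroom: float | None = None,
) -> Grid:
    """Build a grid covering log-transformed values ``ln(E + e_min)``.

    ``x_max`` is the largest transformed value plus headroom; by default the
    headroom is 20% of the data's log range but at least one natural-log
    unit, keeping the (unmodeled) numerical upper edge away from the data.
    """
    if e_min <= 0:
        raise ValueError("e_min must be positive")
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no finite expression values to build a grid from")
    if finite.min() < 0:
        raise ValueError("expression values must be non-negative")
    x_min = float(np.log(e_min))
    x_data = float(np.log(finite.max() + e_min))
    if headroom is None:
        headroom = max(0.2 * (x_data - x_min), 1.0)
    if headroom < 0:
        raise ValueError("headroom must be non-negative")
    x_max = x_data + headroom
    if not x_max > x_min:
        x_max = x_min + 1.0
    return Grid(x_min=x_min, x_max=x_max, n=n)


def build_grid(
    table,
    e_min: float = DEFAULT_E_MIN,
    n: int = DEFAULT_N,
    headroom: float | None = None,
) -> Grid:
    """Grid for an :class:`~exprate.phylo_io.ExpressionTable` (see
    :func:`grid_from_values`)."""
    observed = table.values[~table.missing]
    return grid_from_values(observed, e_min=e_min, n=n, headroom=headroom)


def build_diffusion_operator(n: int) -> DiffusionOperator:
    """Construct M and diagonalize it (done once per grid size)."""
    if n < 3:
        raise ValueError("diffusion operator needs n >= 3")
    diag = np.full(n, -2.0)
    diag[0] = diag[-1] = -1.0
    off = np.ones(n - 1)
    w, u = eigh_tridiagonal(diag, off)
    m = np.diag(diag) + np.diag(off, 1) + np.diag(off, -1)
    return DiffusionOperator(n=n, matrix=m, eigenvalues=w, eigenvectors=u)


def transition_matrix_from_c(op: DiffusionOperator, c: float) -> np.ndarray:
    """exp(c M) via the eigendecomposition; columns renormalized to sum 1."""
    if c < 0:
        raise ValueError("diffusion amount c must be non-negative")
    t = (op.eigenvectors * np.exp(c * op.eigenvalues)) @ op.eigenvectors.T
    np.maximum(t, 0.0, out=t)  # round-off negatives (>= NEGATIVITY_TOL) -> 0
    t /= t.sum(axis=0, keepdims=True)
    return t


def transition_operator(
    op: DiffusionOperator, grid: Grid, sigma2: float, dt: float
) -> np.ndarray:
    """Column-stochastic transition matrix for rate ``sigma2`` over time ``dt``."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if dt < 0:
        raise ValueError("elapsed time must be non-negative")
    if op.n != grid.n:
        raise ValueError("operator and grid sizes disagree")
    c = sigma2 * dt / (2.0 * grid.delta**2)
    return transition_matrix_from_c(op, c)


def tip_delta(grid: Grid, x: float) -> np.ndarray:
    """Unit point mass at log-expression ``x``, linearly interpolated over the
    two bracketing bins.  Values outside the grid are clamped to the edge."""
    pos = (x - grid.x_min) / grid.delta
    pos = min(max(pos, 0.0), grid.n - 1.0)
    lo = int(np.floor(pos))
    frac = pos - lo
    w = np.zeros(grid.n)
    if lo == grid.n - 1:
        w[lo] = 1.0
    else:
        w[lo] = 1.0 - frac
        w[lo + 1] = frac
    return w


def tip_deltas(grid: Grid, x: np.ndarray) -> np.ndarray:
    """Vectorized :func:`tip_delta`: returns an (n, len(x)) matrix of unit
    masses, one column per value."""
    x = np.asarray(x, dtype=float)
    pos = np.clip((x - grid.x_min) / grid.delta, 0.0, grid.n - 1.0)
    lo = np.floor(pos).astype(int)
    np.minimum(lo, grid.n - 2, out=lo)
    frac = pos - lo
    out = np.zeros((grid.n, x.size))
    cols = np.arange(x.size)
    out[lo, cols] = 1.0 - frac
    out[lo + 1, cols] += frac
    return out


def propagate(density: DiscretizedDensity, transition: np.ndarray) -> DiscretizedDensity:
    """Apply a transition operator to a density (mass is conserved)."""
    if transition.shape != (density.grid.n, density.grid.n):
        raise ValueError("transition matrix does not match grid size")
    w = transition @ density.weights
    np.maximum(w, 0.0, out=w)
    return DiscretizedDensity(density.grid, w)
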