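# Methods

## Model

`exprate` models the evolution of gene expression on a rooted, time-calibrated
(ultrametric) species tree. Measured expression is linear and non-negative
(TPM-like); internally every value is log-transformed,

    X_ij = ln(E_ij + e_min),        e_min > 0 (default 1),

so that evolutionary variance scales with expression level, and X evolves
along each branch as Brownian motion with rate σ² (variance per unit branch
time, in squared natural-log units). A reflecting boundary at
x_min = ln(e_min) keeps the walk from drifting to −∞: expression can approach
but never reach zero. There is no upper bound in the model; the upper edge of
the numerical grid (below) is a computational device only.

Genes are independent given the tree and rates. The per-gene likelihood is
computed by Felsenstein's pruning algorithm for continuous characters:
observed tips contribute point masses at their measured X values, partials
are pushed through the branch transition densities and multiplied at internal
nodes, and the root partial is integrated against a root prior ρ(x_R). The
total log-likelihood is the sum over genes, and rates may be shared by all
genes (single-rate), vary by sample group (tissue/condition/genome subset,
one σ² per group), or vary across branch groups (1 to 2n−2 parameters for n
tips, any grouping).

### Root prior

ρ is a gamma distribution over *linear* expression with shape k = 0.375 and
scale θ = 1600 (mean kθ = 600), mirroring empirical across-gene expression
distributions. Discretizing it onto the log grid requires a choice: treat the
gamma as a density in E and change variables to x (Jacobian e^x), or evaluate
it pointwise without the Jacobian. The package defaults to the linear-scale
convention, implemented exactly as CDF differences over each bin's E-interval
— this matches the simulator, which draws root E from the same gamma, and
handles the integrable singularity at E = 0 (k < 1) without special-casing.
The pointwise alternative is available via `prior_scale="log"`.

### Discretized diffusion

The log-expression axis is discretized into N equal bins of width
δ = (x_max − x_min)/(N − 1); the default N = 200 (N = 500 as a high-resolution
mode, with little accuracy gain in our experiments). The bounded diffusion
with zero-flux boundary becomes a linear system dP/dt = σ²/(2δ²) · M P with M
the tridiagonal Neumann Laplacian: diagonal −2 except −1 at the two corners,
off-diagonals 1. Columns of M sum to zero, so probability is conserved
exactly. The finite-time transition operator exp(σ²Δt/(2δ²) · M) is evaluated
by diagonalizing M once per grid size (eigenvalues −4 sin²(kπ/2N)) and is
cached per (branch length, σ²) pair, so optimizer sweeps only pay one O(N²)
reconstruction per new rate per distinct branch length.

Numerical conventions:

- x_max is the largest observed ln(E + e_min) plus headroom — 20% of the
  data's log range, at least one natural-log unit — keeping the artificial
  upper reflecting edge away from the data. One global grid is shared by all
  genes and samples so the eigendecomposition is reused everywhere.
- Observed tip values are discretized as unit masses linearly interpolated
  over the two bracketing bins (nearest-bin assignment would quantize
  likelihoods). Missing tips ("-", "?", "N") contribute an all-ones message —
  likelihood 1 for every ancestral state — not a normalized density, which
  would wrongly penalize missingness.
- Log-likelihoods use the density convention (tip deltas carry 1/δ, the root
  Riemann sum carries δ through mass-weighted prior bins), so values are
  comparable across grid resolutions.
- Matrix-exponential entries driven slightly negative by round-off (≳ −1e−12)
  are clipped to zero and columns renormalized.
- Per-node partials are rescaled by their maximum with the log accumulated,
  preventing underflow across thousands of genes.
- Note the discrete operator's reflecting wall sits half a bin below the
  first bin center (its eigenvectors are cos(kπ(j+½)/N)); the continuous
  analogue used as a test oracle mirrors about x_min − δ/2.

## Estimation

σ² parameters are fitted by Nelder–Mead in log σ² coordinates (positivity by
construction), warm-started from a method-of-moments guess: the mean across
genes of the across-tip variance of X, divided by tree depth, with the
initial simplex spread by a factor of 4 per coordinate. Convergence uses
relative simplex and function-spread tolerances of 1e−6 with a default cap of
300 iterations (raisable when complex models are still improving at the
limit). Sample-based models separate over sample groups, so each group is
fitted by an independent one-dimensional search; branch-based models are a
joint search, warm-started at the nested single-rate optimum when used in a
likelihood-ratio test so the statistic is non-negative by construction.

Nested models are compared by the likelihood-ratio test:
2(lnL_full − lnL_nested) ~ χ²(Δ#params) under the null. Statistics within
−1e−3 of zero are clamped (optimizer jitter); anything more negative raises,
flagging a failed search rather than hiding it.

## Ancestral reconstruction

Marginal posteriors at every node come from two-pass belief propagation on
the grid: upward partials from pruning, downward messages seeded with the
root prior, node marginal ∝ upward × downward. Point estimates are posterior
means on the log grid (reported on both scales; the mean is stable under
discretization, unlike the mode). The 95% credible interval is the shortest
contiguous run of bins holding ≥ 95% of the mass (HPD-like; deterministic,
with ties broken toward the run containing the point estimate) — an
equal-tail variant is available since either reading of "summing
probabilities until 95% is included" is defensible. A branch change is
*credible* when parent and child intervals are disjoint; directions come from
point-estimate differences, with |Δ| < 1e−9 log units treated as no change.
Because intervals widen toward the root, deep branches yield fewer credible
calls at equal true change — a property, not a bug.

## Simulator

The simulator draws each gene's root E from the gamma prior, log-transforms,
and walks down the tree: per branch the increment is Normal(0, σ²t), and a
value landing below x_min is reflected once (x → 2x_min − x). With a single
reflecting boundary the reflected normal is the *exact* transition law
(method of images), so no Euler time-stepping is involved. Tips are reported
as E = exp(x) − e_min; missing data is an i.i.d. Bernoulli mask per cell
(genes that lose every tip are uninformative and dropped by the analysis
routines). The simulator has no upper bound; the inference grid expands to
cover whatever it produces.

What the simulator does *not* emulate: measurement error, replicate-level
variation, correlated missingness, among-gene rate heterogeneity within a
sample (each gene gets exactly its group's σ²), and gene-tree discordance.
Passing recovery tests on simulated data therefore demonstrates correctness
of the estimator under the model, not robustness to these real-data
complications.

### Study conditions

Validation experiments run on a 5-tip ultrametric tree of depth 3,
`((A:1,B:1):2,((C:1,D:1):1,E:2):1);` — the
closest realizable shape to a balanced tree with unit-length branching (a
5-tip ultrametric tree cannot have literally all branches equal). Standard
problem sizes, chosen to keep full replications tractable on one CPU:

- LRT calibration: 200 null datasets × 200 genes, 64-bin grid, for the
  two-sample model and for adjacent/dispersed two-rate branch groupings;
  the acceptance band is the exact binomial 95% interval around 0.05.
- Rate accuracy: σ² ∈ {0.25, 1, 4}, 20 replicates × 1,000 genes, 200-bin
  grid; median relative error per condition is the statistic.
- Pooled-rate bias: 5 replicates of {0.5, 3, 9} × 300 genes fitted with one
  shared rate; the mean estimate falls below the arithmetic mean 4.17 — the
  classic downward bias of single-rate likelihood models under rate
  heterogeneity.
- Missing data: one 1,000-gene dataset masked at 75%.

## Known limitations

- Ornstein–Uhlenbeck and other constrained models are out of scope, as are
  among-gene gamma rate classes, tip measurement-error models, and gene-tree
  discordance corrections.
- The discretization biases σ̂² slightly downward at coarse grids (≲1% at
  N = 200 on the study tree); tip interpolation adds a tiny upward variance
  (~δ²/6 per observed tip).
- Single-gene fits are intrinsically high-variance (order-of-magnitude
  scatter); the method's value is pooling genes.
- Branch-rate groupings must cover every branch; the root has no branch and
  carries no rate.
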