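# exprate

Maximum-likelihood estimation of genome-wide rates of gene expression
evolution on a phylogeny, under bounded Brownian motion of log expression.

## The problem

Comparative RNA-seq gives expression levels (e.g. TPM) for thousands of genes
across species related by a time-calibrated tree. `exprate` asks: *how fast
does expression evolve?* It models log expression X = ln(E + e_min) as
Brownian motion with rate σ² per unit time along each branch, with a
reflecting boundary at x_min = ln(e_min) so expression can approach but never
reach zero (and no upper bound). For each gene the likelihood

    L_i(σ²) = ∫ L_i(σ² | E_i, T, x_R) ρ(x_R) dx_R

is computed by the pruning algorithm on a discretized log-expression grid;
the transition density along a branch is exp(σ²Δt/(2δ²)·M), the matrix
exponential of the tridiagonal Neumann Laplacian M, evaluated through a
single eigendecomposition. The root prior ρ is gamma(k = 0.375, θ = 1600)
over linear expression. The genome-wide likelihood is Π_i L_i, maximized
over σ² by Nelder–Mead.

Beyond a single shared rate, σ² can differ between sample groups (tissues,
conditions, chromosomes — via a `SAMPLETYPE` column) or between branch groups
(1 to 2n−2 parameters), with nested models compared by χ² likelihood-ratio
tests. The package also reconstructs ancestral expression at every internal
node with 95% credible intervals, flags *credible* per-branch changes
(non-overlapping parent/child intervals), and ships an exact simulator
(method-of-images reflected sampling) for power and calibration studies.

Who it is for: researchers in comparative transcriptomics and phylogenetic
comparative methods who want genome-wide rate estimates, rate-shift tests,
and ancestral expression states from a species tree plus an expression
matrix.

## Worked example

```python
import exprate as xr

tree = xr.default_study_tree()                     # 5-tip ultrametric tree
config = xr.SimConfig(tree=tree, rates=xr.RateModel.single(1.0),
                      n_genes=1000, seed=42)
table, truth = xr.simulate(config)

grid = xr.build_grid(table)                        # 200-bin log grid
prior = xr.evaluate_root_prior(grid)               # gamma(0.375, 1600)
result = xr.fit(table, tree, xr.RateModel.single(), grid, prior)
print(result.rates.values[0], result.neg_log_lik)
```

prints (seed 42):

```
1.0457...  9608.40...
```

— the rate estimate pooled over 1,000 genes (true value 1.0; typical error a
few percent at this size) and the fitted model's −lnL. The
`examples/` directory has narrative scripts for each capability: single-rate
fitting, sample-model comparison with the LRT (`model_comparison.py` prints
per-sample rates and the χ² statistic), ancestral reconstruction with
credible change tallies, and the simulate→write→read→refit round trip.

A thin CLI wraps the same library:

```sh
exprate simulate --tree tree.nwk --sigma2 1.0 --n-genes 1000 --seed 1 --out sim
exprate fit --tree tree.nwk --infile sim_expression.tsv --out run
exprate compare --tree tree.nwk --infile sim_expression.tsv \
    --rates branches --assign "(A,B):1,rest:2"
```

`fit` writes four files: per-gene ancestral states with credible bounds
(TSV), per-branch change tallies (TSV), NEXUS trees annotated
`[&state=..,lo=..,hi=..]`, and a model summary (σ², −lnL).

Input formats: a rooted ultrametric Newick tree with branch lengths, and a
tab-delimited table whose header holds species names plus optional
`GENE`/`DESC`/`SAMPLETYPE` columns; missing cells are `-`, `?` or `N`.

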