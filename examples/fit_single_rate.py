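"""Estimate a genome-wide rate of expression evolution from simulated data.

Simulates 1,000 genes evolving on a 5-tip time tree with a true rate of
sigma^2 = 1 (variance of log expression per unit branch time), then
recovers the rate by maximum likelihood.  The printed estimate should land
within a few percent of the truth; -lnL is the fitted model's negative
log-likelihood.
"""

import exprate as xr

tree = xr.default_study_tree()
config = xr.SimConfig(tree=tree, rates=xr.RateModel.single(1.0), n_genes=1000, seed=42)
table, _ = xr.simulate(config)

grid = xr.build_grid(table)  # 200-bin log-expression grid with headroom
prior = xr.evaluate_root_prior(grid)  # gamma(k=0.375, theta=1600) root prior
result = xr.fit(table, tree, xr.RateModel.single(), grid, prior)

print(f"true sigma^2 = 1.0")
print(f"estimated sigma^2 = {result.rates.values[0]:.4f}")
print(f"-lnL = {result.neg_log_lik:.2f} after {result.n_evals} evaluations")
print("The estimate pools information across all genes; single-dataset")
print("estimates at this size typically fall within a few percent of truth.")
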