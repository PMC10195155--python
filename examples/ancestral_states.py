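"""Reconstruct ancestral expression states with credible intervals.

Simulates a small dataset, reconstructs the posterior distribution of log
expression at every internal node for the first gene, and tallies credible
expression changes per branch across all genes (a change is credible when
the parent's and child's 95% credible intervals do not overlap).
"""

import numpy as np

import exprate as xr

tree = xr.default_study_tree()
config = xr.SimConfig(tree=tree, rates=xr.RateModel.single(1.0), n_genes=200, seed=11)
table, truth = xr.simulate(config)

grid = xr.build_grid(table)
prior = xr.evaluate_root_prior(grid)
fit = xr.fit(table, tree, xr.RateModel.single(), grid, prior)
recon = xr.reconstruct(table, tree, fit.rates, grid, prior)

print("gene g1, ancestral states (linear expression, 95% CI):")
for v in tree.internal_nodes:
    point = np.exp(recon.point[0, v]) - 1
    lo = np.exp(recon.ci_lo[0, v]) - 1
    hi = np.exp(recon.ci_hi[0, v]) - 1
    true_e = np.exp(truth.iloc[0][str(v)]) - 1
    print(f"  node {v}: {point:9.2f}  [{lo:9.2f}, {hi:9.2f}]  (truth {true_e:9.2f})")

summary = xr.change_summary(xr.call_changes(recon), tree)
print("\nper-branch credible changes over all genes (+increases/-decreases):")
for _, row in summary.iterrows():
    print(f"  branch {row.branch} ({row.branch_label}): "
          f"+{row.credible_increases}/-{row.credible_decreases}")
print("\nDeeper branches show fewer credible calls: credible intervals")
print("widen toward the root, so only large shifts remain distinguishable.")
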