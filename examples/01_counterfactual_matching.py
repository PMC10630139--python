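"""Counterfactual matching on a simulated perturbation experiment.

Simulates a small dataset with 3 cell states and a 3-cluster treatment
response, separates confounder from treatment-associated variation, matches
cells across conditions with entropic OT, and checks how well the per-cell
treatment effects recover the true response clusters.
"""

import numpy as np

from cfot import SimulationConfig, counterfactual_match, simulate_dataset
from cfot.evaluate import ari_ite

sim = simulate_dataset(SimulationConfig(n_cells=1500, n_confounder_genes=400,
                                        n_response_genes=200, n_states=3, seed=0))
res = counterfactual_match(sim.dataset, rank=20, threshold=0.05,
                           smoothness_per_dim=1e-5, seed=0,
                           ite_direction="counterfactual_for_treated")

decomp = res.decomposition
print(f"ICA components: {decomp.rank}  "
      f"(confounder: {decomp.confounder_idx.size}, "
      f"treatment-associated: {decomp.treatment_idx.size})")
print("top Chatterjee coefficients vs treatment:",
      np.round(np.sort(decomp.coefficients)[::-1][:5], 3))
# components whose coefficient exceeds the cutoff carry treatment signal and
# are excluded from the matching geometry

print(f"matching plan: {res.plan.shape[0]} control x {res.plan.shape[1]} treated, "
      f"marginal error {res.plan.marginal_error():.2e}, "
      f"converged={res.plan.converged}")

truth = sim.true_response_cluster[res.ite.cell_indices]
ari = ari_ite(res.ite, truth)
print(f"mean |ITE| {np.abs(res.ite.values).mean():.3f} "
      f"(log-normalized expression units)")
print(f"ARI between ITE Leiden clusters and the true response clusters: {ari:.3f}")
# an ARI near 1 means the inferred per-cell effects cleanly recover the
# simulated response heterogeneity
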