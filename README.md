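# cfot — counterfactual matching for perturbation scRNA-seq

`cfot` estimates **individual treatment effects (ITE)** from single-cell
perturbation experiments by matching each cell with its counterfactual in
the other condition. Perturbation responses in scRNA-seq are confounded by
cell-intrinsic variation — cell type, cell cycle, depth — that exists
independently of the treatment and also shapes the response. `cfot`
separates that confounding variation from treatment-associated variation,
matches control and treated cells **in confounder space only**, and reads
per-cell, per-gene effects off the resulting soft pairing. It is written
for computational biologists analyzing treatment-vs-control (or
combinatorial-treatment) scRNA-seq from Python.

## The method

Given a cells × genes matrix with binary treatment labels `z`:

1. **Rank initialization.** The signal rank `r` is either prespecified
   (robust for `r ∈ [20, 50]`) or estimated by *biwhitening*: rescale rows
   and columns so heteroskedastic count noise has unit variance, and count
   singular values above the Marchenko–Pastur edge `(1 + √(n/m))²`.
2. **Factorization.** The log-normalized matrix is PCA-embedded and factored
   with FastICA into `r` independent sources `S` (unmixing `B`).
3. **Confounder separation.** Each component is tested for functional
   dependence on the treatment with the Chatterjee cross rank coefficient

   ξₙ(Sᵢ, z) = 1 − n·Σ|r_{k+1} − r_k| / (2·Σ lₖ(n − lₖ)),

   the tie-aware form (z is binary). Components with ξ below a threshold
   `d` are confounders `S^c`; the rest carry treatment signal and are
   excluded from matching.
4. **Entropic optimal transport.** With pairwise Euclidean distances `D`
   between control and treated rows of `S^c`, the Gibbs kernel
   `A = exp(−D∘D/s)` (smoothness `s` = `smoothness_per_dim` × dim `S^c`) is
   scaled to prescribed marginals by Sinkhorn–Knopp, giving a coupling `M`
   that conserves mass and avoids the boundary artifacts of nearest-neighbor
   matching. Marginals are uniform, or balanced within known confounder
   labels (`weights_from_labels`).
5. **ITE.** Each control cell's counterfactual treated profile is its
   plan-row-weighted average of treated expression; `ITE = counterfactual −
   observed` (the treated-referenced transpose is available). Downstream:
   Leiden clustering of response programs, synergy
   `Ψ = D_{A+B} − (D_A + D_B)` for combinatorial treatments, coarse-grained
   attribution of responses to control clusters, the per-gene interaction
   regression `X = αz + βc + γcz + const` scored by ‖γ-fit‖₂/‖residual‖₂,
   and Wilcoxon signed-rank DE selection.

When treatment changes cell-state abundances, confounder/treatment
independence breaks; the **weighted variant** first aligns treated cells to
their k nearest control neighbors, balances conditions within Leiden
clusters of the aligned embedding, fits ICA on the balanced subset, and
applies the unmixing back to all cells.

A gamma-Poisson **simulator** (confounder block with 2–5 cell states and 2
gene programs; response block drawn from state-conditional cluster
distributions; differential-abundance subsampling; count thinning) plus
**metrics** (batch-mixing ASW and PCR of the matching embedding, ARI of ITE
clusters against truth, ITE-attribution PCR) make every claim testable
offline.

## Worked example

```python
from cfot import SimulationConfig, counterfactual_match, simulate_dataset
from cfot.evaluate import ari_ite

sim = simulate_dataset(SimulationConfig(n_cells=1500, n_confounder_genes=400,
                                        n_response_genes=200, n_states=3, seed=0))
res = counterfactual_match(sim.dataset, rank=20, threshold=0.05,
                           smoothness_per_dim=1e-5, seed=0,
                           ite_direction="counterfactual_for_treated")
```

Running `python examples/01_counterfactual_matching.py` prints:

```
ICA components: 20  (confounder: 16, treatment-associated: 4)
top Chatterjee coefficients vs treatment: [0.66  0.149 0.113 0.051 0.032]
matching plan: 750 control x 750 treated, marginal error 6.92e-03, converged=True
mean |ITE| 1.063 (log-normalized expression units)
ARI between ITE Leiden clusters and the true response clusters: 0.969
```

Four of twenty components correlate with the treatment event (the leading
one at ξ = 0.66) and are excluded from matching; the transport plan meets
its marginals to the 1e-2 tolerance; and clustering the per-cell effects
recovers the simulated response clusters almost perfectly (ARI 0.97, where
1 is exact agreement and 0 is chance). The other scripts in `examples/`
walk through differential abundance, synergy scoring, attribution, and the
benchmark driver; a thin CLI (`cfot simulate|run|synergy|attribute|benchmark`)
mirrors the same workflows on h5ad/MTX/CSV files.

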