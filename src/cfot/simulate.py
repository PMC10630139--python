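"""Gamma-Poisson synthetic benchmark generator with ground-truth labels.

The generator emulates a perturbation scRNA-seq experiment: a confounder
block of genes structured by discrete cell states plus two shared continuous
gene-regulation programs, and a response block that is at baseline in control
cells while each treated cell draws a response cluster from a discrete
distribution conditional on its cell state.  Differential abundance and
count-depth downsampling are applied as separate, composable corruptions.
Every quantity needed for evaluation (state, response cluster, block
membership) is returned as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from cfot.data import ExpressionDataset

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "apply_differential_abundance",
    "downsample_counts",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic benchmark.

    Defaults follow the benchmark protocol: 5,000 cells, a 1,000-gene
    confounder block with 2-5 cell states and 2 gene-regulation programs,
    and a 500-gene response block whose cluster assignment is drawn from a
    state-conditional discrete distribution.
    """

    n_cells: int = 5000
    n_confounder_genes: int = 1000
    n_response_genes: int = 500
    n_states: int = 4
    n_programs: int = 2
    n_response_clusters: int = 3
    response_distributions: np.ndarray | None = None  # n_states x n_response_clusters
    state_specific_response: bool = True
    treated_fraction: float = 0.5
    da_ratio: float = 1.0
    downsample_fraction: float = 1.0
    # noise / effect-size parameters of the gamma-Poisson model
    base_shape: float = 2.0
    base_scale: float = 1.0
    de_prob: float = 0.1
    de_sigma: float = 1.0
    program_prob: float = 0.15
    program_sigma: float = 0.5
    response_de_prob: float = 0.2
    response_sigma: float = 1.0
    dispersion: float = 0.1
    libsize_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_states <= 5:
            raise ValueError("n_states must lie in [2, 5]")
        if not 0.0 <= self.da_ratio <= 1.0:
            raise ValueError("da_ratio must lie in [0, 1]")
        if not 0.0 < self.downsample_fraction <= 1.0:
            raise ValueError("downsample_fraction must lie in (0, 1]")
        if self.response_distributions is not None:
            P = np.asarray(self.response_distributions, dtype=float)
            if P.shape != (self.n_states, self.n_response_clusters):
                raise ValueError("response_distributions must be n_states x n_response_clusters")
            if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0):
                raise ValueError("each state's response distribution must sum to 1")
            self.response_distributions = P


@dataclass
class SimulatedDataset:
    """Synthetic counts with full ground truth."""

    dataset: ExpressionDataset
    true_state: np.ndarray
    true_response_cluster: np.ndarray  # -1 for control cells
    block_index: np.ndarray  # per gene: "confounder" | "response"
    response_distributions: np.ndarray
    config: SimulationConfig

    @property
    def confounder_genes(self) -> np.ndarray:
        return np.flatnonzero(self.block_index == "confounder")

    @property
    def response_genes(self) -> np.ndarray:
        return np.flatnonzero(self.block_index == "response")


def _gamma_poisson(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    noisy = mean * rng.gamma(shape=1.0 / dispersion, scale=dispersion, size=mean.shape)
    return rng.poisson(noisy)


def simulate_dataset(config: SimulationConfig | None = None, **kwargs) -> SimulatedDataset:
    """Draw one synthetic dataset; bitwise reproducible from ``config.seed``."""
    if config is None:
        config = SimulationConfig(**kwargs)
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    states = rng.integers(0, cfg.n_states, size=cfg.n_cells)
    n_treated = int(round(cfg.treated_fraction * cfg.n_cells))
    treatment = np.zeros(cfg.n_cells, dtype=int)
    treatment[rng.choice(cfg.n_cells, size=n_treated, replace=False)] = 1
    libsize = rng.lognormal(mean=0.0, sigma=cfg.libsize_sigma, size=cfg.n_cells)

    # confounder block: state-specific DE plus shared continuous programs
    g_c = cfg.n_confounder_genes
    base_c = rng.gamma(shape=cfg.base_shape, scale=cfg.base_scale, size=g_c)
    state_lfc = np.zeros((cfg.n_states, g_c))
    for s in range(cfg.n_states):
        de = rng.random(g_c) < cfg.de_prob
        state_lfc[s, de] = rng.normal(0.0, cfg.de_sigma, size=de.sum())
    loadings = np.zeros((cfg.n_programs, g_c))
    for k in range(cfg.n_programs):
        on = rng.random(g_c) < cfg.program_prob
        loadings[k, on] = rng.normal(0.0, cfg.program_sigma, size=on.sum())
    activity = rng.random((cfg.n_cells, cfg.n_programs))
    log_mean = state_lfc[states] + activity @ loadings
    mean_c = base_c[None, :] * np.exp(log_mean) * libsize[:, None]
    counts_c = _gamma_poisson(rng, mean_c, cfg.dispersion)

    # response block: baseline in control, cluster signature in treated
    g_r = cfg.n_response_genes
    base_r = rng.gamma(shape=cfg.base_shape, scale=cfg.base_scale, size=g_r)
    sig = np.zeros((cfg.n_response_clusters, g_r))
    for k in range(cfg.n_response_clusters):
        on = rng.random(g_r) < cfg.response_de_prob
        sig[k, on] = rng.normal(0.0, cfg.response_sigma, size=on.sum())
    P = cfg.response_distributions
    if P is None:
        if cfg.state_specific_response:
            P = rng.dirichlet(np.ones(cfg.n_response_clusters), size=cfg.n_states)
        else:
            row = rng.dirichlet(np.ones(cfg.n_response_clusters))
            P = np.tile(row, (cfg.n_states, 1))
    response_cluster = np.full(cfg.n_cells, -1, dtype=int)
    for i in np.flatnonzero(treatment == 1):
        response_cluster[i] = rng.choice(cfg.n_response_clusters, p=P[states[i]])
    log_mean_r = np.where(treatment[:, None] == 1,
                          sig[np.clip(response_cluster, 0, None)], 0.0)
    mean_r = base_r[None, :] * np.exp(log_mean_r) * libsize[:, None]
    counts_r = _gamma_poisson(rng, mean_r, cfg.dispersion)

    counts = np.hstack([counts_c, counts_r]).astype(float)
    gene_ids = [f"conf_{j}" for j in range(g_c)] + [f"resp_{j}" for j in range(g_r)]
    block = np.array(["confounder"] * g_c + ["response"] * g_r)
    dataset = ExpressionDataset(values=counts, treatment=treatment, gene_ids=gene_ids,
                                cell_labels=states.astype(str), is_counts=True)
    return SimulatedDataset(dataset=dataset, true_state=states,
                            true_response_cluster=response_cluster,
                            block_index=block, response_distributions=np.asarray(P),
                            config=cfg)


def apply_differential_abundance(sim: SimulatedDataset, da_ratio: float,
                                 seed: int = 0) -> SimulatedDataset:
    """Subsample treated cells from half of the cell states.

    ``ceil(n_states / 2)`` states are chosen at random; within each, exactly
    ``round(da_ratio * n)`` of the treated cells are retained.  ``da_ratio=1``
    returns the dataset unchanged; ``da_ratio=0`` removes the chosen states
    from the treated condition entirely (missing cell types).
    """
    if not 0.0 <= da_ratio <= 1.0:
        raise ValueError("da_ratio must lie in [0, 1]")
    if da_ratio == 1.0:
        return sim
    cfg = sim.config
    rng = np.random.default_rng(seed)
    affected = rng.choice(cfg.n_states, size=math.ceil(cfg.n_states / 2), replace=False)
    z = sim.dataset.treatment
    drop = np.zeros(z.shape[0], dtype=bool)
    for s in affected:
        idx = np.flatnonzero((z == 1) & (sim.true_state == s))
        n_keep = int(round(da_ratio * idx.size))
        dropped = rng.choice(idx, size=idx.size - n_keep, replace=False)
        drop[dropped] = True
    keep = ~drop
    ds = sim.dataset
    new_ds = ExpressionDataset(values=ds.values[keep], treatment=z[keep],
                               gene_ids=list(ds.gene_ids),
                               cell_labels=None if ds.cell_labels is None else ds.cell_labels[keep],
                               batch=None if ds.batch is None else ds.batch[keep],
                               is_counts=ds.is_counts)
    return SimulatedDataset(dataset=new_ds, true_state=sim.true_state[keep],
                            true_response_cluster=sim.true_response_cluster[keep],
                            block_index=sim.block_index,
                            response_distributions=sim.response_distributions,
                            config=replace(cfg, da_ratio=float(da_ratio)))


def downsample_counts(counts: np.ndarray, fraction: float, seed: int = 0) -> np.ndarray:
    """Hypergeometric thinning of the pooled count total.

    Exactly ``round(fraction * total)`` count units are retained, drawn
    without replacement from the pooled units, so gene/cell structure is
    preserved in expectation (for Poisson counts this is Poisson thinning up
    to the fixed-total constraint).
    """
    counts = np.asarray(counts)
    if fraction > 1.0 or fraction <= 0.0:
        raise ValueError("fraction must lie in (0, 1]")
    if not np.allclose(counts, np.round(counts)) or counts.min() < 0:
        raise ValueError("counts must be nonnegative integers")
    if fraction == 1.0:
        return counts.copy()
    flat = np.round(counts).astype(np.int64).ravel()
    total = int(flat.sum())
    target = int(round(fraction * total))
    rng = np.random.default_rng(seed)
    thinned = rng.multivariate_hypergeometric(flat, target, method="marginals")
    return thinned.reshape(counts.shape).astype(counts.dtype)
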