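"""End-to-end counterfactual matching pipelines.

``counterfactual_match`` implements the core procedure: PCA -> ICA ->
Chatterjee-coefficient partition -> entropic OT on the confounder sources ->
individual treatment effects (ITE).  ``counterfactual_match_weighted`` is the
differential-abundance-robust variant: treated cells are first aligned to
their k nearest control neighbors, Leiden clusters of the aligned embedding
are balanced by subsampling, ICA is fitted on the balanced subset and (by
default) applied back to the full data before matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from sklearn.neighbors import NearestNeighbors

from cfot._clustering import leiden_cluster
from cfot.data import ExpressionDataset, PCEmbedding, log_normalize, pc_embed
from cfot.decompose import ICADecomposition, ica_decompose, partition_components
from cfot.match import MatchingPlan, Weights, ot_match

__all__ = [
    "ITEMatrix",
    "WPreprocessState",
    "CausalMatchResult",
    "WeightedMatchResult",
    "compute_ite",
    "counterfactual_match",
    "counterfactual_match_weighted",
    "weights_from_labels",
    "knn_align",
    "balanced_subsample",
]


@dataclass
class ITEMatrix:
    """Per-cell, per-gene individual treatment effect.

    Rows index the reference population: control cells for direction
    ``counterfactual_for_control`` (each control cell is paired with its
    inferred counterfactual treated expression), treated cells for the
    transposed direction.  The sign convention is treated-minus-control in
    both directions.
    """

    values: np.ndarray
    direction: str = "counterfactual_for_control"
    space: str = "expression"  # "expression" | "pc"
    log_transformed: bool = True
    cell_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("ITE values must be finite")
        if self.direction not in ("counterfactual_for_control", "counterfactual_for_treated"):
            raise ValueError(f"unknown direction '{self.direction}'")


@dataclass
class WPreprocessState:
    """Bookkeeping for the weighted variant's alignment and balancing step."""

    aligned_embedding: np.ndarray
    leiden_labels: np.ndarray
    kept_indices: np.ndarray
    k: int
    resolution: float
    seed: int


class CausalMatchResult(NamedTuple):
    decomposition: ICADecomposition
    plan: MatchingPlan
    ite: ITEMatrix
    embedding: PCEmbedding


class WeightedMatchResult(NamedTuple):
    decomposition: ICADecomposition
    plan: MatchingPlan
    ite: ITEMatrix
    state: WPreprocessState
    embedding: PCEmbedding


def compute_ite(expr_control: np.ndarray, expr_treated: np.ndarray,
                plan: MatchingPlan | np.ndarray,
                direction: str = "counterfactual_for_control",
                space: str = "expression", log_transformed: bool = True) -> ITEMatrix:
    """Treatment effects from a matching plan and the two expression blocks.

    For each control cell i the counterfactual treated profile is the
    plan-row-weighted average of treated expression,
    ``cf_i = (M_i / sum_j M_ij) @ X_treated``, and ``ITE_i = cf_i - X_control_i``.
    The transposed direction column-normalizes the plan instead and reports
    ``X_treated_j - cf_j`` per treated cell.  ITE is invariant to rescaling
    any plan row (resp. column) by a positive constant.
    """
    M = plan.plan if isinstance(plan, MatchingPlan) else np.asarray(plan, dtype=float)
    X0 = np.atleast_2d(np.asarray(expr_control, dtype=float))
    X1 = np.atleast_2d(np.asarray(expr_treated, dtype=float))
    if M.shape != (X0.shape[0], X1.shape[0]):
        raise ValueError("plan shape must be (n_control, n_treated)")
    if direction == "counterfactual_for_control":
        norm = M.sum(axis=1)
        if np.any(norm <= 0):
            raise ValueError("plan has a zero row; cannot normalize counterfactuals")
        cf = (M / norm[:, None]) @ X1
        values = cf - X0
    elif direction == "counterfactual_for_treated":
        norm = M.sum(axis=0)
        if np.any(norm <= 0):
            raise ValueError("plan has a zero column; cannot normalize counterfactuals")
        cf = (M / norm[None, :]).T @ X0
        values = X1 - cf
    else:
        raise ValueError(f"unknown direction '{direction}'")
    return ITEMatrix(values=values, direction=direction, space=space,
                     log_transformed=log_transformed)


def weights_from_labels(labels: np.ndarray, treatment: np.ndarray) -> Weights:
    """Marginal weights that balance known confounder labels across conditions.

    Within each label cells are weighted uniformly; each label's total mass
    is its pooled frequency on both sides, so OT transports mass within
    labels rather than across them.
    """
    labels = np.asarray(labels)
    z = np.asarray(treatment).astype(int)
    n = labels.shape[0]
    if z.shape[0] != n:
        raise ValueError("labels and treatment must have equal length")
    w0 = np.zeros(np.sum(z == 0))
    w1 = np.zeros(np.sum(z == 1))
    lab0 = labels[z == 0]
    lab1 = labels[z == 1]
    for lab in np.unique(labels):
        n0 = int(np.sum(lab0 == lab))
        n1 = int(np.sum(lab1 == lab))
        if n0 == 0 or n1 == 0:
            raise ValueError(f"label '{lab}' missing from one condition")
        pooled = (n0 + n1) / n
        w0[lab0 == lab] = pooled / n0
        w1[lab1 == lab] = pooled / n1
    return Weights(w0=w0, w1=w1)


def knn_align(X0: np.ndarray, X1: np.ndarray, k: int) -> np.ndarray:
    """Replace each treated embedding by the mean of its k nearest control cells."""
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X0.shape[0]:
        raise ValueError("k exceeds the number of control cells")
    nn = NearestNeighbors(n_neighbors=k).fit(X0)
    _, idx = nn.kneighbors(X1)
    return X0[idx].mean(axis=1)


def balanced_subsample(aligned: np.ndarray, treatment: np.ndarray,
                       resolution: float = 1.0, seed: int = 0,
                       k: int = 0, n_neighbors: int = 15) -> WPreprocessState:
    """Leiden-cluster the aligned embedding and balance conditions per cluster.

    Within every cluster the condition with more cells is subsampled without
    replacement to the other condition's count; clusters containing only one
    condition are dropped entirely.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    aligned = np.asarray(aligned, dtype=float)
    z = np.asarray(treatment).astype(int)
    labels = leiden_cluster(aligned, resolution=resolution, seed=seed,
                            n_neighbors=n_neighbors)
    rng = np.random.default_rng(seed)
    kept: list[np.ndarray] = []
    for lab in np.unique(labels):
        in_cluster = np.flatnonzero(labels == lab)
        idx0 = in_cluster[z[in_cluster] == 0]
        idx1 = in_cluster[z[in_cluster] == 1]
        if idx0.size == 0 or idx1.size == 0:
            continue  # subsampled to zero: condition absent
        target = min(idx0.size, idx1.size)
        big, small = (idx0, idx1) if idx0.size >= idx1.size else (idx1, idx0)
        kept.append(small)
        kept.append(rng.choice(big, size=target, replace=False))
    if not kept:
        raise ValueError("conditions do not overlap in any cluster")
    kept_indices = np.sort(np.concatenate(kept))
    return WPreprocessState(aligned_embedding=aligned, leiden_labels=labels,
                            kept_indices=kept_indices, k=k,
                            resolution=float(resolution), seed=int(seed))


def _prepare(dataset: ExpressionDataset, rank: int, seed: int):
    data = log_normalize(dataset)
    rank = int(min(rank, min(data.values.shape) - 1))
    pc = pc_embed(data.values, n_comps=rank, seed=seed)
    return data, pc, pc.coords.shape[1]


def counterfactual_match(dataset: ExpressionDataset, rank: int = 30,
                         threshold: float = 0.5, smoothness_per_dim: float = 1e-4,
                         weights: Weights | None = None, seed: int = 0,
                         tol: float = 1e-2, max_iter: int = 5000,
                         ite_space: str = "expression",
                         ite_direction: str = "counterfactual_for_control") -> CausalMatchResult:
    """Run the full confounder-matched treatment-effect pipeline.

    Counts are library-size normalized and log1p transformed, embedded with
    centered PCA, factored with FastICA, and each component's Chatterjee
    coefficient against the treatment vector decides whether it is a
    confounder (coefficient below ``threshold``).  Entropic OT is solved on
    the confounder sources only — equivalent to transporting on the full ICA
    embedding with the treatment-associated factors zeroed — and the coupling
    yields per-cell counterfactuals and the ITE matrix.
    """
    data, pc, rank = _prepare(dataset, rank, seed)
    decomp = ica_decompose(pc, rank=rank, seed=seed)
    decomp = partition_components(decomp, data.treatment, threshold=threshold, seed=seed)
    Sc = decomp.confounder_sources
    z = data.treatment
    plan = ot_match(Sc[z == 0], Sc[z == 1], weights=weights,
                    smoothness_per_dim=smoothness_per_dim, tol=tol, max_iter=max_iter)
    if not plan.converged:
        warnings.warn("Sinkhorn did not reach tolerance; ITE computed from the last iterate")
    expr = pc.coords if ite_space == "pc" else data.values
    ite = compute_ite(expr[z == 0], expr[z == 1], plan, direction=ite_direction,
                      space=ite_space)
    ref = dataset.control_idx if ite_direction == "counterfactual_for_control" else dataset.treated_idx
    ite.cell_indices = ref
    return CausalMatchResult(decomposition=decomp, plan=plan, ite=ite, embedding=pc)


def counterfactual_match_weighted(dataset: ExpressionDataset, rank: int = 30,
                                  threshold: float = 0.5,
                                  smoothness_per_dim: float = 1e-4, k: int = 20,
                                  resolution: float = 1.0, seed: int = 0,
                                  tol: float = 1e-2, max_iter: int = 5000,
                                  apply_to_full: bool = True,
                                  ite_space: str = "expression",
                                  ite_direction: str = "counterfactual_for_control") -> WeightedMatchResult:
    """Differential-abundance-robust variant of :func:`counterfactual_match`.

    Treated cells are aligned to the average of their ``k`` nearest control
    neighbors in PC space, the aligned set is Leiden-clustered at
    ``resolution`` and each cluster is subsampled so both conditions are
    equally represented.  ICA (and the confounder partition) is fitted on the
    balanced subset, restoring the confounder-treatment independence the
    factorization assumes.  With ``apply_to_full`` the fitted unmixing is
    applied to the full embedding so OT and the ITE cover every cell;
    otherwise they cover the balanced subset only.
    """
    data, pc, rank = _prepare(dataset, rank, seed)
    z = data.treatment
    ctrl = np.flatnonzero(z == 0)
    trt = np.flatnonzero(z == 1)
    X0 = pc.coords[ctrl]
    X1a = knn_align(X0, pc.coords[trt], k=min(k, ctrl.size))
    aligned = np.vstack([X0, X1a])
    z_concat = np.concatenate([np.zeros(ctrl.size, int), np.ones(trt.size, int)])
    state = balanced_subsample(aligned, z_concat, resolution=resolution,
                               seed=seed, k=k)
    concat_to_orig = np.concatenate([ctrl, trt])
    kept_orig = concat_to_orig[state.kept_indices]
    sub_rank = int(min(rank, kept_orig.size - 1))
    decomp = ica_decompose(pc.coords[kept_orig], rank=sub_rank, seed=seed)
    decomp = partition_components(decomp, z[kept_orig], threshold=threshold, seed=seed)
    if apply_to_full:
        # the unmixing fitted on the balanced subset, applied to every cell;
        # coefficients remain those estimated on the subset
        S = decomp.transform(pc.coords)
        decomp.sources = S
        use_ctrl, use_trt = ctrl, trt
        Sc = S[:, decomp.confounder_idx]
        S0, S1 = Sc[ctrl], Sc[trt]
        expr_src = pc.coords if ite_space == "pc" else data.values
        expr0, expr1 = expr_src[ctrl], expr_src[trt]
    else:
        Sc = decomp.confounder_sources
        kept_z = z[kept_orig]
        use_ctrl = kept_orig[kept_z == 0]
        use_trt = kept_orig[kept_z == 1]
        S0, S1 = Sc[kept_z == 0], Sc[kept_z == 1]
        expr_src = pc.coords if ite_space == "pc" else data.values
        expr0, expr1 = expr_src[use_ctrl], expr_src[use_trt]
    plan = ot_match(S0, S1, smoothness_per_dim=smoothness_per_dim,
                    tol=tol, max_iter=max_iter)
    if not plan.converged:
        warnings.warn("Sinkhorn did not reach tolerance; ITE computed from the last iterate")
    ite = compute_ite(expr0, expr1, plan, direction=ite_direction, space=ite_space)
    ite.cell_indices = use_ctrl if ite_direction == "counterfactual_for_control" else use_trt
    return WeightedMatchResult(decomposition=decomp, plan=plan, ite=ite,
                               state=state, embedding=pc)
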