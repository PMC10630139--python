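"""Downstream analyses of ITE matrices: synergy, attribution, DE selection.

Synergy compares the combined-treatment ITE against the sum of the single
treatments on a shared control population; attribution relates responses to
the underlying confounder states through a coarse-grained matching matrix and
a per-gene interaction regression; DE selection produces ranked gene lists
ready for external enrichment tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cfot.match import MatchingPlan
from cfot.pipeline import ITEMatrix

__all__ = [
    "SynergyMatrix",
    "AttributionFit",
    "CoarseMatching",
    "synergy_matrix",
    "gene_synergy_score",
    "cell_synergy_score",
    "coarse_grain_matching",
    "attribution_regression",
    "attribution_ratios",
    "select_de_genes",
]


@dataclass
class SynergyMatrix:
    """Cell x gene deviation of the combined treatment from additivity.

    ``mode`` records the scale of the inputs: "multiplicative" when ITEs were
    computed on log1p data (the additive null on the log scale tests for
    multiplicative interaction of expression), "additive" for library-size
    normalized inputs only.
    """

    psi: np.ndarray
    mode: str = "multiplicative"


@dataclass
class AttributionFit:
    """Coefficients of the per-gene interaction model X = a*z + b*c + g*c*z + const.

    ``ratio`` is the l2-norm ratio between the fitted confounder-specific
    effect (the interaction term) and the residual; large values indicate a
    confounder-dependent treatment response.  ``ratio_infinite`` flags exact
    interpolation (residual below machine level).
    """

    alpha: float
    beta: np.ndarray
    gamma: np.ndarray
    intercept: float
    ratio: float
    ratio_infinite: bool = False


@dataclass
class CoarseMatching:
    """Plan mass aggregated over (response cluster, control cluster) blocks.

    ``matrix`` is row-normalized (each response cluster's distribution over
    control clusters); ``column_view`` normalizes columns instead (each
    control cluster's distribution over response modes).  ``mass`` keeps the
    unnormalized block totals, which sum to the total plan mass.
    """

    matrix: np.ndarray
    column_view: np.ndarray
    mass: np.ndarray
    response_labels: np.ndarray
    control_labels: np.ndarray


def _as_ite(x) -> ITEMatrix:
    if isinstance(x, ITEMatrix):
        return x
    return ITEMatrix(values=np.asarray(x, dtype=float))


def synergy_matrix(ite_A: ITEMatrix, ite_B: ITEMatrix, ite_AB: ITEMatrix) -> SynergyMatrix:
    """Synergy Psi = D_AB - (D_A + D_B) over a shared control population.

    All three ITEs must be referenced to the same control cells (direction
    ``counterfactual_for_control`` with identical row indexing) so the
    elementwise difference is meaningful.
    """
    ites = [_as_ite(m) for m in (ite_A, ite_B, ite_AB)]
    shapes = {m.values.shape for m in ites}
    if len(shapes) != 1:
        raise ValueError(f"ITE shapes differ: {sorted(shapes)}")
    for m in ites:
        if m.direction != "counterfactual_for_control":
            raise ValueError("synergy requires counterfactual_for_control ITEs")
    refs = [m.cell_indices for m in ites if m.cell_indices is not None]
    if refs and any(not np.array_equal(refs[0], r) for r in refs[1:]):
        raise ValueError("ITEs reference different control populations")
    psi = ites[2].values - ites[0].values - ites[1].values
    mode = "multiplicative" if all(m.log_transformed for m in ites) else "additive"
    return SynergyMatrix(psi=psi, mode=mode)


def gene_synergy_score(psi: SynergyMatrix | np.ndarray) -> np.ndarray:
    """|mean over cells| of each synergy column; sign cancellation is intended."""
    P = psi.psi if isinstance(psi, SynergyMatrix) else np.asarray(psi, dtype=float)
    if P.shape[0] < 1:
        raise ValueError("need at least one cell")
    return np.abs(P.mean(axis=0))


def cell_synergy_score(psi: SynergyMatrix | np.ndarray,
                       gene_threshold: float = 0.15) -> np.ndarray:
    """Per-cell Euclidean norm of the synergy rows over strongly synergistic genes.

    Genes are selected by ``gene_synergy_score >= gene_threshold``; errors if
    none passes, reporting the maximum score observed.
    """
    P = psi.psi if isinstance(psi, SynergyMatrix) else np.asarray(psi, dtype=float)
    scores = gene_synergy_score(P)
    sel = scores >= gene_threshold
    if not sel.any():
        raise ValueError(
            f"no gene passes synergy threshold {gene_threshold} "
            f"(max score {scores.max():.4g})")
    return np.linalg.norm(P[:, sel], axis=1)


def coarse_grain_matching(plan: MatchingPlan | np.ndarray, response_labels: np.ndarray,
                          control_labels: np.ndarray) -> CoarseMatching:
    """Aggregate plan mass into response-cluster x control-cluster blocks.

    ``response_labels`` label the treated axis (typically Leiden clusters of
    the ITE matrix), ``control_labels`` the control axis (cell subtypes).
    Rows of ``matrix`` attribute each response mode to control clusters;
    ``column_view`` reads the other way.  Response clusters receiving zero
    mass are dropped with a warning.
    """
    M = plan.plan if isinstance(plan, MatchingPlan) else np.asarray(plan, dtype=float)
    response_labels = np.asarray(response_labels)
    control_labels = np.asarray(control_labels)
    if response_labels.shape[0] != M.shape[1]:
        raise ValueError("response labels must match the treated axis of the plan")
    if control_labels.shape[0] != M.shape[0]:
        raise ValueError("control labels must match the control axis of the plan")
    r_levels = np.unique(response_labels)
    c_levels = np.unique(control_labels)
    mass = np.zeros((r_levels.size, c_levels.size))
    for a, rl in enumerate(r_levels):
        cols = response_labels == rl
        for b, cl in enumerate(c_levels):
            mass[a, b] = M[np.ix_(control_labels == cl, cols)].sum()
    row_tot = mass.sum(axis=1)
    keep = row_tot > 0
    if not keep.all():
        dropped = r_levels[~keep]
        warnings.warn(f"response clusters with zero plan mass dropped: {list(dropped)}")
    mass = mass[keep]
    r_levels = r_levels[keep]
    matrix = mass / mass.sum(axis=1, keepdims=True)
    col_tot = mass.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore"):
        column_view = np.where(col_tot > 0, mass / col_tot, 0.0)
    return CoarseMatching(matrix=matrix, column_view=column_view, mass=mass,
                          response_labels=r_levels, control_labels=c_levels)


def _design(treatment: np.ndarray, confounder: np.ndarray) -> np.ndarray:
    z = np.asarray(treatment, dtype=float).ravel()
    C = np.asarray(confounder, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != z.shape[0]:
        raise ValueError("confounder design and treatment length mismatch")
    return np.column_stack([z, C, C * z[:, None], np.ones_like(z)]), C


def attribution_regression(expr_g: np.ndarray, treatment: np.ndarray,
                           confounder: np.ndarray) -> AttributionFit:
    """OLS fit of one gene to X = alpha*z + beta.c + gamma.(c*z) + const.

    The interaction term gamma.(c*z) is the confounder-specific treatment
    effect; its strength is summarized by the l2-norm ratio of the fitted
    interaction values to the residual, which stays meaningful when the
    noise itself carries latent-factor structure and classical standard
    errors do not apply.
    """
    y = np.asarray(expr_g, dtype=float).ravel()
    D, C = _design(treatment, confounder)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient design (collinear confounder/interaction columns)")
    coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    p = C.shape[1]
    alpha = float(coef[0])
    beta = coef[1:1 + p]
    gamma = coef[1 + p:1 + 2 * p]
    intercept = float(coef[-1])
    z = np.asarray(treatment, dtype=float).ravel()
    gamma_fit = (C * z[:, None]) @ gamma
    resid = y - D @ coef
    resid_norm = float(np.linalg.norm(resid))
    if resid_norm < 1e-10:
        return AttributionFit(alpha=alpha, beta=beta, gamma=gamma, intercept=intercept,
                              ratio=np.inf, ratio_infinite=True)
    ratio = float(np.linalg.norm(gamma_fit) / resid_norm)
    return AttributionFit(alpha=alpha, beta=beta, gamma=gamma, intercept=intercept,
                          ratio=ratio)


def attribution_ratios(values: np.ndarray, treatment: np.ndarray,
                       confounder: np.ndarray) -> np.ndarray:
    """Vectorized interaction-to-residual ratio for every gene column."""
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    D, C = _design(treatment, confounder)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient design (collinear confounder/interaction columns)")
    coef, _, _, _ = np.linalg.lstsq(D, Y, rcond=None)
    p = C.shape[1]
    z = np.asarray(treatment, dtype=float).ravel()
    gamma_fit = (C * z[:, None]) @ coef[1 + p:1 + 2 * p]
    resid = Y - D @ coef
    rn = np.linalg.norm(resid, axis=0)
    gn = np.linalg.norm(gamma_fit, axis=0)
    with np.errstate(divide="ignore"):
        return np.where(rn < 1e-10, np.inf, gn / np.maximum(rn, 1e-300))


def select_de_genes(ite: ITEMatrix | np.ndarray, p_threshold: float = 1e-5,
                    delta_threshold: float = 0.5,
                    gene_ids: list[str] | None = None) -> pd.DataFrame:
    """Matched differential-expression gene table from an ITE matrix.

    Each gene's ITE values are tested against zero with a two-sided Wilcoxon
    signed-rank test; a gene passes when ``p < p_threshold`` and the absolute
    mean ITE exceeds ``delta_threshold``.  Genes whose ITE is identically
    zero have no defined p-value and fail.  The table is sorted by p-value
    then effect size, ready for external enrichment tools.
    """
    V = ite.values if isinstance(ite, ITEMatrix) else np.asarray(ite, dtype=float)
    n_cells, n_genes = V.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if n_cells < 6:
        # exact two-sided signed-rank p is floored at 2/2^n > 1e-5 below n=6,
        # so no gene can pass the default p threshold
        warnings.warn("fewer than 6 cells: signed-rank p floor exceeds typical thresholds")
    if gene_ids is None:
        gene_ids = [f"gene_{j}" for j in range(n_genes)]
    pvals = np.ones(n_genes)
    for j in range(n_genes):
        col = V[:, j]
        if np.all(col == 0):
            pvals[j] = np.nan
            continue
        method = "exact" if n_cells <= 25 else "approx"
        pvals[j] = stats.wilcoxon(col, alternative="two-sided", method=method).pvalue
    effect = V.mean(axis=0)
    median = np.median(V, axis=0)
    passed = (pvals < p_threshold) & (np.abs(effect) > delta_threshold)
    passed &= ~np.isnan(pvals)
    table = pd.DataFrame({
        "gene": gene_ids,
        "effect": effect,
        "median_effect": median,
        "p": pvals,
        "pass": passed,
    })
    return table.sort_values(["p", "effect"], ascending=[True, False],
                             key=lambda s: np.abs(s) if s.name == "effect" else s,
                             na_position="last").reset_index(drop=True)
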