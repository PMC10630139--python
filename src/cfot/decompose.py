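"""Signal-rank estimation, ICA factorization and confounder/treatment partitioning.

The factorization step assumes that confounding sources (cell state, cycle,
depth) and the treatment event are statistically independent, and that the
observed embedding is a linear mixture of independent sources.  Under those
assumptions the treatment-associated sources can be singled out by testing
each independent component for functional dependence on the binary treatment
vector with the Chatterjee cross rank coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from cfot.data import PCEmbedding

__all__ = [
    "RankEstimate",
    "ICADecomposition",
    "estimate_rank",
    "biwhiten",
    "ica_decompose",
    "xicor",
    "partition_components",
]


@dataclass
class RankEstimate:
    """Estimated signal rank of a count matrix."""

    rank: int
    method: str  # "biwhitening" | "prespecified"
    mp_edge: float | None = None

    def __post_init__(self) -> None:
        if self.rank < 0:
            raise ValueError("rank must be nonnegative")


@dataclass
class ICADecomposition:
    """ICA sources with the per-component treatment-dependence coefficients.

    ``confounder_idx`` collects components whose Chatterjee coefficient with
    the treatment vector falls below ``threshold``; the complement is
    ``treatment_idx``.  ``mean`` is the column mean removed before unmixing,
    so ``sources = (X - mean) @ unmixing.T`` for new data ``X``.
    """

    sources: np.ndarray
    unmixing: np.ndarray
    mean: np.ndarray | None = None
    coefficients: np.ndarray | None = None
    confounder_idx: np.ndarray | None = None
    treatment_idx: np.ndarray | None = None
    threshold: float | None = None

    @property
    def rank(self) -> int:
        return self.sources.shape[1]

    @property
    def confounder_sources(self) -> np.ndarray:
        if self.confounder_idx is None:
            raise ValueError("components not partitioned yet")
        return self.sources[:, self.confounder_idx]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the fitted unmixing to a new embedding."""
        X = np.asarray(X, dtype=float)
        if self.mean is not None:
            X = X - self.mean
        return X @ self.unmixing.T


def biwhiten(counts: np.ndarray, n_iter: int = 30) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row/column rescaling so heteroskedastic count noise has unit variance.

    Uses the counts themselves as the Poisson variance proxy and runs a fixed
    number of Sinkhorn-type scaling sweeps so that every row and column of the
    scaled variance matrix has mean one.  Returns ``(Y, u, v)`` where
    ``Y = diag(sqrt(u)) @ counts @ diag(sqrt(v))``.  All-zero rows/columns are
    left untouched (their scale is irrelevant to the spectrum).
    """
    X = np.asarray(counts, dtype=float)
    if X.min() < 0:
        raise ValueError("counts must be nonnegative")
    if X.sum() == 0:
        raise ValueError("degenerate input: all-zero count matrix")
    m, n = X.shape
    V = X.copy()  # Poisson variance estimate: var = mean ~ observed count
    u = np.ones(m)
    v = np.ones(n)
    for _ in range(n_iter):
        rs = V @ v
        u = np.divide(n, rs, out=np.zeros_like(rs), where=rs > 0)
        cs = u @ V
        v = np.divide(m, cs, out=np.zeros_like(cs), where=cs > 0)
    Y = np.sqrt(u)[:, None] * X * np.sqrt(v)[None, :]
    return Y, u, v


def estimate_rank(counts: np.ndarray, method: str = "biwhitening",
                  prespecified: int | None = None, n_iter: int = 30) -> RankEstimate:
    """Estimate the number of signal components in a count matrix.

    The biwhitening path rescales rows and columns so the noise spectrum
    follows the Marchenko-Pastur law, then counts singular values of the
    column-centered scaled matrix exceeding the MP upper edge
    ``(1 + sqrt(n/m))^2`` (in eigenvalue units of the scaled covariance, unit
    noise variance).  Centering removes the baseline-expression offset, which
    is also removed by the centered PCA used downstream.  A rank of 0 means no
    signal exceeds the noise edge and the caller should fall back to a
    prespecified rank.
    """
    counts = np.asarray(counts)
    if method == "prespecified":
        if prespecified is None:
            raise ValueError("prespecified rank required for method='prespecified'")
        if prespecified < 1:
            raise ValueError("prespecified rank must be >= 1")
        rank = int(min(prespecified, min(counts.shape)))
        return RankEstimate(rank=rank, method="prespecified")
    if method != "biwhitening":
        raise ValueError(f"unknown rank method '{method}'")
    Y, _, _ = biwhiten(counts, n_iter=n_iter)
    m, n = Y.shape
    Yc = Y - Y.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(Yc, compute_uv=False)
    edge = (1.0 + np.sqrt(n / m)) ** 2  # MP upper edge, sigma^2 = 1
    rank = int(np.sum(sv ** 2 / m > edge))
    rank = min(rank, min(m, n))
    return RankEstimate(rank=rank, method="biwhitening", mp_edge=edge)


def ica_decompose(embedding: PCEmbedding | np.ndarray, rank: int, seed: int = 0,
                  max_iter: int = 1000, n_retries: int = 3) -> ICADecomposition:
    """FastICA factorization of a PC embedding (arbitrary-variance whitening).

    Deterministic given ``seed``.  On non-convergence the fit is retried with
    up to ``n_retries`` incremented seeds; if none converges the last iterate
    is returned with a warning.
    """
    X = embedding.coords if isinstance(embedding, PCEmbedding) else np.asarray(embedding, float)
    if X.ndim == 1:
        X = X[:, None]
    if rank > X.shape[1]:
        raise ValueError(f"rank {rank} exceeds embedding width {X.shape[1]}")
    last = None
    for attempt in range(n_retries):
        ica = FastICA(n_components=rank, whiten="arbitrary-variance",
                      random_state=seed + attempt, max_iter=max_iter)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            S = ica.fit_transform(X)
        last = (S, ica)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            break
    else:
        warnings.warn("FastICA did not converge after retries; returning last iterate")
    S, ica = last
    return ICADecomposition(sources=S, unmixing=ica.components_, mean=ica.mean_)


def xicor(x: np.ndarray, y: np.ndarray, seed: int = 0) -> float:
    """Chatterjee's cross rank coefficient xi_n(x, y).

    Measures whether ``y`` is a (noisy) function of ``x``; approaches 1 for a
    strictly monotone (or any measurable) functional relation and 0 under
    independence.  Ties in ``x`` are broken uniformly at random with ``seed``
    (a single draw).  The tie-aware form

        xi = 1 - n * sum_i |r_{i+1} - r_i| / (2 * sum_i l_i (n - l_i))

    with ``r_i = #{j : y_j <= y_(i)}`` and ``l_i = #{j : y_j >= y_(i)}`` (the
    y-ranks along the x-sorted order) is used throughout; it reduces to the
    familiar ``1 - 3 sum|dr| / (n^2 - 1)`` when y has no ties, and it is
    required here because y is typically the binary treatment vector.
    Returns 0 with a warning when y is constant (undefined denominator).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if n != y.shape[0]:
        raise ValueError("x and y must have equal length")
    if n < 2:
        raise ValueError("need at least two observations")
    rng = np.random.default_rng(seed)
    order = np.lexsort((rng.random(n), x))
    yo = y[order]
    ys = np.sort(y)
    r = np.searchsorted(ys, yo, side="right")
    l = n - np.searchsorted(ys, yo, side="left")
    denom = 2.0 * np.sum(l * (n - l))
    if denom == 0:
        warnings.warn("constant y: xi coefficient undefined, returning 0")
        return 0.0
    return float(1.0 - n * np.abs(np.diff(r)).sum() / denom)


def partition_components(decomp: ICADecomposition, treatment: np.ndarray,
                         threshold: float = 0.5, seed: int = 0) -> ICADecomposition:
    """Split ICA components into confounder vs treatment-associated sets.

    Component ``i`` is a confounder iff ``xicor(S[:, i], treatment) <
    threshold``.  Mutates and returns ``decomp`` with coefficients and index
    sets filled.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    treatment = np.asarray(treatment)
    S = decomp.sources
    coeffs = np.array([xicor(S[:, i], treatment, seed=seed + i)
                       for i in range(S.shape[1])])
    conf = np.flatnonzero(coeffs < threshold)
    if conf.size == 0:
        raise ValueError("no confounder signal; lower threshold or raise rank")
    decomp.coefficients = coeffs
    decomp.confounder_idx = conf
    decomp.treatment_idx = np.flatnonzero(coeffs >= threshold)
    decomp.threshold = float(threshold)
    return decomp
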