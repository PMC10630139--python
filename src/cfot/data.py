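"""In-memory containers for expression data and PC embeddings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class ExpressionDataset:
    """A cells x genes expression matrix with a binary treatment label per cell.

    Parameters
    ----------
    values
        Dense cells x genes matrix; raw counts if ``is_counts`` else
        library-size-normalized log1p expression.
    treatment
        Binary vector (0 = control, 1 = treated), one entry per cell.
    gene_ids
        Gene identifiers, one per column.
    cell_labels
        Optional per-cell categorical confounder labels (e.g. cell type).
    batch
        Optional per-cell batch labels.
    is_counts
        Whether ``values`` holds raw counts (True) or log-normalized data.
    """

    values: np.ndarray
    treatment: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_labels: np.ndarray | None = None
    batch: np.ndarray | None = None
    is_counts: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.treatment = np.asarray(self.treatment).astype(int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes matrix")
        if self.treatment.shape != (self.values.shape[0],):
            raise ValueError("treatment length must equal number of cells")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")
        levels = set(np.unique(self.treatment))
        if not levels <= {0, 1}:
            raise ValueError("treatment must be binary {0,1}")
        if levels != {0, 1}:
            raise ValueError("both treatment groups must be non-empty")
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(self.values.shape[1])]
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError("gene_ids length must equal number of genes")
        for name in ("cell_labels", "batch"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (self.n_cells,):
                    raise ValueError(f"{name} length must equal number of cells")
                setattr(self, name, arr)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def control_idx(self) -> np.ndarray:
        return np.flatnonzero(self.treatment == 0)

    @property
    def treated_idx(self) -> np.ndarray:
        return np.flatnonzero(self.treatment == 1)

    def to_anndata(self):
        """Convert to :class:`anndata.AnnData` (obs carries labels)."""
        import anndata as ad
        import pandas as pd

        obs = pd.DataFrame(index=[f"cell_{i}" for i in range(self.n_cells)])
        obs["treatment"] = self.treatment
        if self.cell_labels is not None:
            obs["cell_label"] = pd.Categorical(self.cell_labels)
        if self.batch is not None:
            obs["batch"] = pd.Categorical(self.batch)
        adata = ad.AnnData(X=self.values.copy(), obs=obs)
        adata.var_names = list(self.gene_ids)
        adata.uns["is_counts"] = bool(self.is_counts)
        return adata

    @classmethod
    def from_anndata(cls, adata, treatment_key: str, control_label,
                     treated_label=None) -> "ExpressionDataset":
        """Build from an AnnData, mapping one obs column to the binary treatment.

        ``control_label`` names the reference level; with more than two levels
        ``treated_label`` must disambiguate which level is the treated one.
        """
        import scipy.sparse as sp

        if treatment_key not in adata.obs:
            raise KeyError(f"obs column '{treatment_key}' not found")
        col = np.asarray(adata.obs[treatment_key]).astype(str)
        levels = sorted(set(col))
        control_label = str(control_label)
        if control_label not in levels:
            raise ValueError(f"control label '{control_label}' not among levels {levels}")
        others = [v for v in levels if v != control_label]
        if treated_label is None:
            if len(others) != 1:
                raise ValueError(
                    f"treatment column has levels {levels}; pass treated_label "
                    "to select the treated condition")
            treated_label = others[0]
        treated_label = str(treated_label)
        keep = (col == control_label) | (col == treated_label)
        X = adata.X[keep]
        if sp.issparse(X):
            X = X.toarray()
        X = np.asarray(X, dtype=float)
        z = (col[keep] == treated_label).astype(int)
        is_counts = bool(adata.uns.get("is_counts", np.allclose(X, np.round(X)) and X.min() >= 0))
        labels = None
        if "cell_label" in adata.obs:
            labels = np.asarray(adata.obs["cell_label"])[keep]
        batch = np.asarray(adata.obs["batch"])[keep] if "batch" in adata.obs else None
        return cls(values=X, treatment=z, gene_ids=list(adata.var_names),
                   cell_labels=labels, batch=batch, is_counts=is_counts)


@dataclass
class PCEmbedding:
    """Principal-component embedding of the (centered) expression matrix."""

    coords: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.coords.shape[1] != self.explained_variance.shape[0]:
            raise ValueError("explained_variance length must equal embedding width")
        if np.any(np.diff(self.explained_variance) > 1e-8):
            raise ValueError("explained_variance must be non-increasing")


def log_normalize(dataset: ExpressionDataset, target_sum: float = 1e4) -> ExpressionDataset:
    """Library-size normalize to ``target_sum`` counts per cell and log1p.

    Returns a new dataset flagged ``is_counts=False``; a no-op (copy) when the
    input is already log-normalized.
    """
    if not dataset.is_counts:
        return dataset
    X = dataset.values
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    X = np.log1p(X / totals * target_sum)
    return ExpressionDataset(values=X, treatment=dataset.treatment,
                             gene_ids=list(dataset.gene_ids),
                             cell_labels=dataset.cell_labels, batch=dataset.batch,
                             is_counts=False)


def pc_embed(values: np.ndarray, n_comps: int, seed: int = 0) -> PCEmbedding:
    """Centered PCA embedding of a cells x genes matrix."""
    values = np.asarray(values, dtype=float)
    n_comps = int(min(n_comps, min(values.shape) - 1))
    if n_comps < 1:
        raise ValueError("need at least one principal component")
    pca = PCA(n_components=n_comps, random_state=seed)
    coords = pca.fit_transform(values)
    return PCEmbedding(coords=coords, explained_variance=pca.explained_variance_)
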