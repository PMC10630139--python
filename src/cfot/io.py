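"""Reading/writing expression data and pipeline results; run configuration.

Supported input formats: h5ad, a MatrixMarket directory (matrix.mtx +
barcodes.tsv + features.tsv), and CSV.  Results are written as a single h5ad
holding the confounder embedding, ITE, component coefficients and the sparse
matching plan, with a sidecar JSON run log of all resolved parameters.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from cfot.data import ExpressionDataset, log_normalize

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression_mtx",
    "write_results",
    "read_results",
    "write_simulation",
    "highly_variable_genes",
]


@dataclass
class RunConfig:
    """Resolved pipeline parameters; serialized into every output."""

    rank: int = 30
    rank_method: str = "prespecified"
    xicor_threshold: float = 0.5
    smoothness_per_dim: float = 1e-4
    tol: float = 1e-2
    max_iter: int = 5000
    k: int = 20
    resolution: float = 1.0
    seed: int = 0
    variant: str = "default"  # "default" | "w"
    input_path: str = ""
    treatment_key: str = "treatment"
    control_label: str = "0"
    treated_label: str | None = None
    weights_key: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _infer_format(path: str) -> str:
    if os.path.isdir(path):
        return "mtx_dir"
    if path.endswith(".h5ad"):
        return "h5ad"
    if path.endswith(".csv") or path.endswith(".csv.gz"):
        return "csv"
    raise ValueError(f"cannot infer format of '{path}'")


def read_expression(path: str, fmt: str | None = None,
                    treatment_key: str = "treatment", control_label="0",
                    treated_label=None, genes_as_rows: bool = False,
                    normalize: bool = False) -> ExpressionDataset:
    """Load a cells x genes dataset with its binary treatment labels.

    The treatment column must contain the control label plus exactly one
    other level, unless ``treated_label`` disambiguates.  ``normalize``
    applies library-size normalization and log1p (recorded on the dataset).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "h5ad":
        import anndata as ad
        dataset = ExpressionDataset.from_anndata(ad.read_h5ad(path), treatment_key,
                                                 control_label, treated_label)
    elif fmt == "mtx_dir":
        dataset = _read_mtx_dir(path, treatment_key, control_label, treated_label)
    elif fmt == "csv":
        dataset = _read_csv(path, treatment_key, control_label, treated_label,
                            genes_as_rows)
    else:
        raise ValueError(f"unknown format '{fmt}'")
    if normalize:
        dataset = log_normalize(dataset)
    return dataset


def _canon_label(v) -> str:
    """Canonicalize numeric-looking labels so '1', '1.0' and 1 all agree."""
    s = str(v)
    try:
        f = float(s)
        if f == int(f):
            return str(int(f))
    except ValueError:
        pass
    return s


def _binary_treatment(col: np.ndarray, control_label, treated_label):
    col = np.array([_canon_label(v) for v in col])
    control_label = _canon_label(control_label)
    if treated_label is not None:
        treated_label = _canon_label(treated_label)
    levels = sorted(set(col))
    if control_label not in levels:
        raise ValueError(f"control label '{control_label}' not among levels {levels}")
    others = [v for v in levels if v != control_label]
    if treated_label is None:
        if len(others) != 1:
            raise ValueError(f"treatment column has levels {levels}; pass treated_label")
        treated_label = others[0]
    keep = (col == control_label) | (col == str(treated_label))
    return keep, (col == str(treated_label)).astype(int)


def _read_mtx_dir(path: str, treatment_key, control_label, treated_label) -> ExpressionDataset:
    mtx = os.path.join(path, "matrix.mtx")
    barcodes = os.path.join(path, "barcodes.tsv")
    features = os.path.join(path, "features.tsv")
    for f in (mtx, barcodes, features):
        if not os.path.exists(f):
            raise FileNotFoundError(f)
    # genes x cells on disk (10x convention); transpose to cells x genes
    X = np.asarray(sp.coo_matrix(scipy.io.mmread(mtx)).todense()).T
    obs = pd.read_csv(barcodes, sep="\t")
    genes = pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
    if treatment_key not in obs.columns:
        raise KeyError(f"column '{treatment_key}' not found in barcodes.tsv")
    keep, z = _binary_treatment(obs[treatment_key].to_numpy(), control_label, treated_label)
    labels = obs["cell_label"].to_numpy()[keep] if "cell_label" in obs.columns else None
    return ExpressionDataset(values=X[keep], treatment=z[keep], gene_ids=genes,
                             cell_labels=labels)


def _read_csv(path: str, treatment_key, control_label, treated_label,
              genes_as_rows: bool) -> ExpressionDataset:
    df = pd.read_csv(path, index_col=0)
    if genes_as_rows:
        df = df.T
    if treatment_key not in df.columns:
        raise KeyError(f"column '{treatment_key}' not found in CSV")
    tcol = df[treatment_key].to_numpy()
    label_col = df["cell_label"].to_numpy() if "cell_label" in df.columns else None
    expr = df.drop(columns=[c for c in (treatment_key, "cell_label") if c in df.columns])
    keep, z = _binary_treatment(tcol, control_label, treated_label)
    labels = label_col[keep] if label_col is not None else None
    return ExpressionDataset(values=expr.to_numpy(float)[keep], treatment=z[keep],
                             gene_ids=list(expr.columns), cell_labels=labels)


def write_expression_mtx(dataset: ExpressionDataset, path: str) -> None:
    """Write a MatrixMarket directory (genes x cells) with labeled barcodes."""
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"),
                     sp.coo_matrix(dataset.values.T))
    obs = pd.DataFrame({"barcode": [f"cell_{i}" for i in range(dataset.n_cells)],
                        "treatment": dataset.treatment})
    if dataset.cell_labels is not None:
        obs["cell_label"] = dataset.cell_labels
    obs.to_csv(os.path.join(path, "barcodes.tsv"), sep="\t", index=False)
    pd.Series(dataset.gene_ids).to_csv(os.path.join(path, "features.tsv"),
                                       sep="\t", index=False, header=False)


def write_results(result, path: str, config: RunConfig | None = None,
                  treatment: np.ndarray | None = None) -> None:
    """Persist a pipeline result as h5ad plus a sidecar JSON run log.

    Stores the confounder embedding and full ICA sources (obsm), the ITE
    matrix with its reference cell indices, the matching plan as explicit
    (control_index, treated_index, mass) triplets, and the per-component
    coefficients.
    """
    import anndata as ad

    decomp, plan, ite = result.decomposition, result.plan, result.ite
    n = decomp.sources.shape[0]
    obs = pd.DataFrame(index=[f"cell_{i}" for i in range(n)])
    if treatment is not None:
        obs["treatment"] = np.asarray(treatment).astype(int)
    adata = ad.AnnData(X=np.zeros((n, 0)), obs=obs)
    adata.obsm["X_ica"] = decomp.sources
    adata.obsm["X_confounder"] = decomp.confounder_sources
    coo = sp.coo_matrix(plan.plan)
    adata.uns["plan"] = {"control_index": coo.row.astype(np.int64),
                         "treated_index": coo.col.astype(np.int64),
                         "mass": coo.data,
                         "shape": np.array(plan.shape, dtype=np.int64),
                         "converged": bool(plan.converged),
                         "iterations": int(plan.iterations)}
    adata.uns["ite"] = ite.values
    adata.uns["ite_direction"] = ite.direction
    adata.uns["ite_space"] = ite.space
    if ite.cell_indices is not None:
        adata.uns["ite_cell_indices"] = np.asarray(ite.cell_indices, dtype=np.int64)
    if decomp.coefficients is not None:
        adata.uns["coefficients"] = decomp.coefficients
    adata.uns["confounder_idx"] = np.asarray(decomp.confounder_idx, dtype=np.int64)
    cfg = (config or RunConfig()).to_dict()
    adata.uns["run_config"] = json.dumps(cfg)
    adata.write_h5ad(path)
    with open(path + ".json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)


def read_results(path: str) -> dict:
    """Load a results h5ad back into plain arrays and pipeline objects."""
    import anndata as ad

    from cfot.match import MatchingPlan
    from cfot.pipeline import ITEMatrix

    adata = ad.read_h5ad(path)
    p = adata.uns["plan"]
    shape = tuple(int(x) for x in p["shape"])
    plan_mat = sp.coo_matrix((p["mass"], (p["control_index"], p["treated_index"])),
                             shape=shape).toarray()
    plan = MatchingPlan(plan=plan_mat,
                        row_marginal=plan_mat.sum(axis=1),
                        col_marginal=plan_mat.sum(axis=0),
                        converged=bool(p["converged"]), iterations=int(p["iterations"]))
    ite = ITEMatrix(values=np.asarray(adata.uns["ite"]),
                    direction=str(adata.uns["ite_direction"]),
                    space=str(adata.uns["ite_space"]))
    if "ite_cell_indices" in adata.uns:
        ite.cell_indices = np.asarray(adata.uns["ite_cell_indices"])
    out = {"plan": plan, "ite": ite,
           "sources": np.asarray(adata.obsm["X_ica"]),
           "confounder_idx": np.asarray(adata.uns["confounder_idx"]),
           "run_config": json.loads(adata.uns["run_config"])}
    if "coefficients" in adata.uns:
        out["coefficients"] = np.asarray(adata.uns["coefficients"])
    if "treatment" in adata.obs:
        out["treatment"] = adata.obs["treatment"].to_numpy()
    return out


def write_simulation(sim, path: str) -> None:
    """Write a simulated dataset as h5ad with truth columns in obs."""
    adata = sim.dataset.to_anndata()
    adata.obs["truth_state"] = sim.true_state
    adata.obs["truth_response"] = sim.true_response_cluster
    adata.var["block"] = sim.block_index
    adata.uns["response_distributions"] = sim.response_distributions
    adata.write_h5ad(path)


def highly_variable_genes(dataset: ExpressionDataset, min_mean: float = 0.0125,
                          max_mean: float = 3.0, min_disp: float = 0.5) -> np.ndarray:
    """Boolean mask of highly variable genes by mean/dispersion thresholds."""
    import scanpy as sc

    data = log_normalize(dataset)
    adata = data.to_anndata()
    sc.pp.highly_variable_genes(adata, min_mean=min_mean, max_mean=max_mean,
                                min_disp=min_disp)
    return adata.var["highly_variable"].to_numpy()
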