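"""Shared data model and I/O for paired (expression, velocity) single-cell data.

The toolkit operates on a cell-by-gene matrix of normalized spliced counts
together with a same-shape matrix of RNA velocities (d normalized-count / dt,
estimated upstream, e.g. by scVelo) and a per-cell type label.  Three on-disk
representations are supported: AnnData ``.h5ad``, loom, and a plain-text MTX
directory.  In memory everything is dense: the downstream math (vector-field
learning, ODE integration) is dense, and desk-scale datasets fit comfortably.

Matrices are cells-in-rows, genes-in-columns everywhere.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import anndata as ad
import h5py
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "Dataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "select_velocity_genes",
]

DEFAULT_VELOCITY_LAYER = "velocity"
DEFAULT_LABEL_KEY = "cell_type"


class DatasetError(ValueError):
    """Raised when a dataset fails validation or a layer/column is missing."""


@dataclass
class Dataset:
    """Aligned expression / velocity matrices with per-cell labels.

    Parameters
    ----------
    expression
        ``(n_cells, n_genes)`` non-negative normalized counts.
    velocity
        ``(n_cells, n_genes)`` RNA velocities; any sign.
    gene_names
        Unique gene identifiers, length ``n_genes``.
    cell_labels
        Cell-type label per cell (strings; mapped to integer codes only
        inside classifiers).
    obs_meta
        Optional per-cell table (e.g. latent time, ground-truth annotations).
    """

    expression: np.ndarray
    velocity: np.ndarray
    gene_names: list[str]
    cell_labels: list[str]
    obs_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_labels = [str(c) for c in self.cell_labels]
        if self.expression.ndim != 2:
            raise DatasetError("expression must be a 2-D cells × genes matrix")
        if self.expression.shape != self.velocity.shape:
            raise DatasetError(
                f"expression {self.expression.shape} and velocity "
                f"{self.velocity.shape} must have identical shape"
            )
        n_cells, n_genes = self.expression.shape
        if len(self.gene_names) != n_genes:
            raise DatasetError(
                f"{len(self.gene_names)} gene names for {n_genes} genes"
            )
        if len(self.cell_labels) != n_cells:
            raise DatasetError(
                f"{len(self.cell_labels)} labels for {n_cells} cells"
            )
        if len(set(self.gene_names)) != n_genes:
            raise DatasetError("gene names must be unique")
        if not np.isfinite(self.expression).all():
            raise DatasetError("expression contains NaN or infinite values")
        if not np.isfinite(self.velocity).all():
            raise DatasetError("velocity contains NaN or infinite values")
        if (self.expression < 0).any():
            raise DatasetError("expression must be non-negative")
        if self.obs_meta is not None and len(self.obs_meta) != n_cells:
            raise DatasetError("obs_meta row count must equal n_cells")

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def label_set(self) -> list[str]:
        return sorted(set(self.cell_labels))

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise DatasetError(f"unknown gene {gene!r}") from None

    def subset_cells(self, index: np.ndarray) -> "Dataset":
        """Rows restricted to ``index`` (boolean mask or integer positions)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        meta = None
        if self.obs_meta is not None:
            meta = self.obs_meta.iloc[index].reset_index(drop=True)
        return Dataset(
            expression=self.expression[index],
            velocity=self.velocity[index],
            gene_names=list(self.gene_names),
            cell_labels=[self.cell_labels[i] for i in index],
            obs_meta=meta,
        )

    def cells_with_label(self, label: str) -> np.ndarray:
        return np.array([lab == label for lab in self.cell_labels])

    def to_anndata(self) -> ad.AnnData:
        obs = pd.DataFrame(
            {DEFAULT_LABEL_KEY: pd.Categorical(self.cell_labels)},
            index=[f"cell_{i}" for i in range(self.n_cells)],
        )
        if self.obs_meta is not None:
            for col in self.obs_meta.columns:
                obs[col] = np.asarray(self.obs_meta[col])
        adata = ad.AnnData(
            X=self.expression.copy(),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
            layers={DEFAULT_VELOCITY_LAYER: self.velocity.copy()},
        )
        return adata


def _densify(x) -> np.ndarray:
    if sparse.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


def _from_anndata(
    adata: ad.AnnData, velocity_layer: str, label_key: str
) -> Dataset:
    if velocity_layer not in adata.layers:
        raise DatasetError(
            f"no velocity layer {velocity_layer!r}; available layers: "
            f"{sorted(adata.layers.keys())}"
        )
    if label_key not in adata.obs:
        raise DatasetError(
            f"no label column {label_key!r}; available obs columns: "
            f"{sorted(adata.obs.columns)}"
        )
    meta_cols = [c for c in adata.obs.columns if c != label_key]
    meta = adata.obs[meta_cols].reset_index(drop=True) if meta_cols else None
    return Dataset(
        expression=_densify(adata.X),
        velocity=_densify(adata.layers[velocity_layer]),
        gene_names=list(adata.var_names),
        cell_labels=[str(v) for v in adata.obs[label_key]],
        obs_meta=meta,
    )


# ---------------------------------------------------------------------------
# loom (minimal h5py-based reader/writer; rows are genes, columns are cells)
# ---------------------------------------------------------------------------

def _read_loom(path: str, velocity_layer: str, label_key: str) -> Dataset:
    with h5py.File(path, "r") as f:
        layer_path = f"layers/{velocity_layer}"
        if layer_path not in f:
            available = sorted(f["layers"].keys()) if "layers" in f else []
            raise DatasetError(
                f"no velocity layer {velocity_layer!r} in {path}; "
                f"available layers: {available}"
            )
        expression = np.asarray(f["matrix"], dtype=float).T
        velocity = np.asarray(f[layer_path], dtype=float).T
        genes = [g.decode() if isinstance(g, bytes) else str(g)
                 for g in f["row_attrs/Gene"][:]]
        if f"col_attrs/{label_key}" not in f:
            available = sorted(f["col_attrs"].keys())
            raise DatasetError(
                f"no label column {label_key!r}; available col_attrs: {available}"
            )
        labels = [v.decode() if isinstance(v, bytes) else str(v)
                  for v in f[f"col_attrs/{label_key}"][:]]
    return Dataset(expression, velocity, genes, labels)


def _write_loom(ds: Dataset, path: str, velocity_layer: str,
                label_key: str) -> None:
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        # track_times=False keeps the bytes reproducible run-to-run
        f.create_dataset("matrix", data=ds.expression.T, track_times=False)
        f.create_dataset(f"layers/{velocity_layer}", data=ds.velocity.T,
                         track_times=False)
        f.create_dataset("row_attrs/Gene",
                         data=np.array(ds.gene_names, dtype=str_dt),
                         track_times=False)
        f.create_dataset("col_attrs/CellID",
                         data=np.array([f"cell_{i}" for i in range(ds.n_cells)],
                                       dtype=str_dt),
                         track_times=False)
        f.create_dataset(f"col_attrs/{label_key}",
                         data=np.array(ds.cell_labels, dtype=str_dt),
                         track_times=False)


# ---------------------------------------------------------------------------
# MTX directory (matrix.mtx, velocity.mtx, genes.csv, labels.csv)
# ---------------------------------------------------------------------------

def _read_mtx_dir(path: str, label_key: str) -> Dataset:
    mat_p = os.path.join(path, "matrix.mtx")
    vel_p = os.path.join(path, "velocity.mtx")
    if not os.path.exists(vel_p):
        present = sorted(os.listdir(path))
        raise DatasetError(
            f"no velocity.mtx in {path}; directory contains: {present}"
        )
    expression = _densify(mmread(mat_p))
    velocity = _densify(mmread(vel_p))
    genes = pd.read_csv(os.path.join(path, "genes.csv"))["gene"].tolist()
    labels_df = pd.read_csv(os.path.join(path, "labels.csv"))
    labels = labels_df[label_key].astype(str).tolist()
    return Dataset(expression, velocity, genes, labels)


def _write_mtx_dir(ds: Dataset, path: str, label_key: str) -> None:
    os.makedirs(path, exist_ok=True)
    mmwrite(os.path.join(path, "matrix.mtx"), sparse.csr_matrix(ds.expression))
    mmwrite(os.path.join(path, "velocity.mtx"), sparse.csr_matrix(ds.velocity))
    pd.DataFrame({"gene": ds.gene_names}).to_csv(
        os.path.join(path, "genes.csv"), index=False
    )
    pd.DataFrame({label_key: ds.cell_labels}).to_csv(
        os.path.join(path, "labels.csv"), index=False
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_dataset(
    path: str,
    format: str | None = None,
    velocity_layer: str = DEFAULT_VELOCITY_LAYER,
    label_key: str = DEFAULT_LABEL_KEY,
) -> Dataset:
    """Read a validated :class:`Dataset` from h5ad, loom, or an MTX directory.

    ``format`` is inferred from the path when omitted (``.h5ad`` / ``.loom``
    suffix, otherwise a directory is treated as ``mtx_dir``).
    """
    if format is None:
        if str(path).endswith(".h5ad"):
            format = "h5ad"
        elif str(path).endswith(".loom"):
            format = "loom"
        elif os.path.isdir(path):
            format = "mtx_dir"
        else:
            raise DatasetError(f"cannot infer format of {path!r}")
    if format == "h5ad":
        return _from_anndata(ad.read_h5ad(path), velocity_layer, label_key)
    if format == "loom":
        return _read_loom(path, velocity_layer, label_key)
    if format == "mtx_dir":
        return _read_mtx_dir(path, label_key)
    raise DatasetError(f"unknown format {format!r}")


def write_dataset(
    ds: Dataset,
    path: str,
    format: str | None = None,
    velocity_layer: str = DEFAULT_VELOCITY_LAYER,
    label_key: str = DEFAULT_LABEL_KEY,
) -> None:
    """Write ``ds`` so that :func:`read_dataset` round-trips it losslessly
    (up to on-disk dtype)."""
    if format is None:
        if str(path).endswith(".h5ad"):
            format = "h5ad"
        elif str(path).endswith(".loom"):
            format = "loom"
        else:
            format = "mtx_dir"
    if format == "h5ad":
        adata = ds.to_anndata()
        adata.layers[velocity_layer] = adata.layers.pop(DEFAULT_VELOCITY_LAYER)
        if label_key != DEFAULT_LABEL_KEY:
            adata.obs[label_key] = adata.obs.pop(DEFAULT_LABEL_KEY)
        adata.write_h5ad(path)
    elif format == "loom":
        _write_loom(ds, path, velocity_layer, label_key)
    elif format == "mtx_dir":
        _write_mtx_dir(ds, path, label_key)
    else:
        raise DatasetError(f"unknown format {format!r}")


def select_velocity_genes(ds: Dataset, gene_mask) -> Dataset:
    """Restrict both layers to the masked genes (the "velocity genes"
    carrying valid upstream velocity estimates, used as the feature space)."""
    gene_mask = np.asarray(gene_mask, dtype=bool)
    if gene_mask.shape != (ds.n_genes,):
        raise DatasetError(
            f"mask length {gene_mask.size} does not match n_genes {ds.n_genes}"
        )
    kept = int(gene_mask.sum())
    if kept < 2:
        raise DatasetError(f"mask retains {kept} genes; at least 2 required")
    idx = np.flatnonzero(gene_mask)
    return Dataset(
        expression=ds.expression[:, idx],
        velocity=ds.velocity[:, idx],
        gene_names=[ds.gene_names[i] for i in idx],
        cell_labels=list(ds.cell_labels),
        obs_meta=None if ds.obs_meta is None else ds.obs_meta.copy(),
    )
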