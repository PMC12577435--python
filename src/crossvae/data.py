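"""Expression data container, IO and preprocessing.

The canonical object is :class:`ExpressionDataset`: a cells x genes matrix
with per-cell covariates. Two covariates are mandatory and drive batch
correction: ``system`` (a coarse stratum with substantial divergence, e.g.
species or cell-vs-nuclei) and ``sample`` (a donor/run nested inside one
system). ``cell_type`` and ``condition`` are optional annotations used by
evaluation only.

Preprocessing follows the common single-cell recipe: per-system gene
detection filter, median-target total-count normalisation with log1p, and
per-system highly-variable-gene selection intersected across systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp


class ProcessingState(str, Enum):
    """Tracks what has been done to the matrix; guards double-processing."""

    RAW_COUNTS = "raw_counts"
    NORMALIZED_LOG = "normalized_log"


@dataclass
class CovariateEncoding:
    """One-hot encoding map: a system block followed by a sample block."""

    system_categories: list[str]
    sample_categories: list[str]

    @property
    def width(self) -> int:
        return len(self.system_categories) + len(self.sample_categories)

    @property
    def n_systems(self) -> int:
        return len(self.system_categories)

    def system_index(self, system: str) -> int:
        return self.system_categories.index(system)

    def encode(self, system: np.ndarray, sample: np.ndarray) -> np.ndarray:
        sys_idx = pd.Categorical(system, categories=self.system_categories).codes
        smp_idx = pd.Categorical(sample, categories=self.sample_categories).codes
        if (sys_idx < 0).any() or (smp_idx < 0).any():
            raise ValueError("covariate level not present in the encoding")
        n = len(system)
        out = np.zeros((n, self.width))
        out[np.arange(n), sys_idx] = 1.0
        out[np.arange(n), self.n_systems + smp_idx] = 1.0
        return out


@dataclass
class ExpressionDataset:
    """Cells x genes expression with aligned per-cell covariates."""

    matrix: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    system: np.ndarray
    sample: np.ndarray
    cell_type: np.ndarray | None = None
    condition: np.ndarray | None = None
    state: ProcessingState = ProcessingState.RAW_COUNTS
    obs_extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        n, g = self.matrix.shape
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} matrix columns")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        for name in ("system", "sample", "cell_type", "condition"):
            vals = getattr(self, name)
            if vals is None:
                continue
            vals = np.asarray(vals)
            object.__setattr__(self, name, vals)
            if len(vals) != n:
                raise ValueError(f"covariate '{name}' has length {len(vals)}, expected {n}")
        dense_sample = self.matrix[: min(n, 50)]
        arr = np.asarray(dense_sample.todense() if sp.issparse(dense_sample) else dense_sample)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite entries")
        # each sample must belong to exactly one system
        mapping = pd.DataFrame({"system": self.system, "sample": self.sample})
        per_sample = mapping.groupby("sample", observed=True)["system"].nunique()
        bad = per_sample[per_sample > 1]
        if len(bad):
            raise ValueError(f"samples mapped to multiple systems: {list(bad.index)}")
        if self.state == ProcessingState.RAW_COUNTS:
            mn = self.matrix.min() if not sp.issparse(self.matrix) else self.matrix.min()
            if mn < 0:
                raise ValueError("raw counts must be non-negative")

    # -- basic introspection ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def systems(self) -> list[str]:
        return sorted(pd.unique(self.system).tolist())

    @property
    def samples(self) -> list[str]:
        return sorted(pd.unique(self.sample).tolist())

    def dense(self) -> np.ndarray:
        m = self.matrix
        return np.asarray(m.todense()) if sp.issparse(m) else np.asarray(m, dtype=float)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            matrix=self.matrix[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            system=self.system[idx],
            sample=self.sample[idx],
            cell_type=None if self.cell_type is None else self.cell_type[idx],
            condition=None if self.condition is None else self.condition[idx],
            obs_extra=None if self.obs_extra is None else self.obs_extra.iloc[idx],
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in genes])
        return replace(self, matrix=self.matrix[:, idx], gene_ids=list(genes))

    # -- AnnData bridge --------------------------------------------------------
    def to_anndata(self) -> ad.AnnData:
        obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        obs["system"] = pd.Categorical(self.system)
        obs["sample"] = pd.Categorical(self.sample)
        if self.cell_type is not None:
            obs["cell_type"] = pd.Categorical(self.cell_type)
        if self.condition is not None:
            obs["condition"] = pd.Categorical(self.condition)
        if self.obs_extra is not None:
            for col in self.obs_extra.columns:
                obs[col] = np.asarray(self.obs_extra[col])
        adata = ad.AnnData(
            X=self.matrix.copy() if not sp.issparse(self.matrix) else self.matrix.copy(),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        adata.uns["processing_state"] = self.state.value
        return adata

    @classmethod
    def from_anndata(
        cls,
        adata: ad.AnnData,
        system_key: str = "system",
        sample_key: str = "sample",
        cell_type_key: str | None = "cell_type",
        condition_key: str | None = "condition",
    ) -> "ExpressionDataset":
        for key, label in ((system_key, "system"), (sample_key, "sample")):
            if key not in adata.obs:
                raise KeyError(
                    f"required per-cell column '{key}' ({label}) not found; "
                    f"available: {list(adata.obs.columns)}"
                )

        def _opt(key):
            return np.asarray(adata.obs[key].astype(str)) if key and key in adata.obs else None

        X = adata.X
        matrix = X.tocsr().copy() if sp.issparse(X) else np.asarray(X, dtype=float)
        vals = matrix.data if sp.issparse(matrix) else matrix
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression matrix contains non-finite entries")
        state = ProcessingState(
            adata.uns.get(
                "processing_state",
                ProcessingState.RAW_COUNTS.value
                if _looks_like_counts(vals)
                else ProcessingState.NORMALIZED_LOG.value,
            )
        )
        return cls(
            matrix=matrix,
            gene_ids=adata.var_names.tolist(),
            cell_ids=adata.obs_names.tolist(),
            system=np.asarray(adata.obs[system_key].astype(str)),
            sample=np.asarray(adata.obs[sample_key].astype(str)),
            cell_type=_opt(cell_type_key),
            condition=_opt(condition_key),
            state=state,
        )


def _looks_like_counts(values: np.ndarray) -> bool:
    return bool(np.allclose(values, np.round(values)) and np.min(values) >= 0)


# -- IO ------------------------------------------------------------------------


def load_dataset(
    path: str | Path,
    fmt: str | None = None,
    system_key: str = "system",
    sample_key: str = "sample",
    cell_type_key: str | None = "cell_type",
    condition_key: str | None = "condition",
) -> ExpressionDataset:
    """Load an H5AD file or an MTX directory into an :class:`ExpressionDataset`.

    An MTX directory holds ``matrix.mtx`` (cells x genes), ``genes.csv``
    (one id per line, header ``gene_id``) and ``cells.csv`` (per-cell
    metadata incl. the covariate columns).
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx_dir" if path.is_dir() else "h5ad"
    keys = dict(
        system_key=system_key,
        sample_key=sample_key,
        cell_type_key=cell_type_key,
        condition_key=condition_key,
    )
    if fmt == "h5ad":
        return ExpressionDataset.from_anndata(ad.read_h5ad(path), **keys)
    if fmt == "mtx_dir":
        from scipy.io import mmread

        matrix = mmread(path / "matrix.mtx").tocsr()
        genes = pd.read_csv(path / "genes.csv")["gene_id"].astype(str).tolist()
        cells = pd.read_csv(path / "cells.csv")
        for key, label in ((system_key, "system"), (sample_key, "sample")):
            if key not in cells.columns:
                raise KeyError(
                    f"required per-cell column '{key}' ({label}) not found in cells.csv; "
                    f"available: {list(cells.columns)}"
                )
        vals = matrix.data
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression matrix contains non-finite entries")

        def _opt(key):
            return np.asarray(cells[key].astype(str)) if key and key in cells.columns else None

        cell_ids = (
            cells["cell_id"].astype(str).tolist()
            if "cell_id" in cells.columns
            else [f"cell{i}" for i in range(matrix.shape[0])]
        )
        state = (
            ProcessingState.RAW_COUNTS
            if _looks_like_counts(vals)
            else ProcessingState.NORMALIZED_LOG
        )
        return ExpressionDataset(
            matrix=matrix,
            gene_ids=genes,
            cell_ids=cell_ids,
            system=np.asarray(cells[system_key].astype(str)),
            sample=np.asarray(cells[sample_key].astype(str)),
            cell_type=_opt(cell_type_key),
            condition=_opt(condition_key),
            state=state,
        )
    raise ValueError(f"unknown format {fmt!r}; use 'h5ad' or 'mtx_dir'")


def save_dataset(ds: ExpressionDataset, path: str | Path) -> None:
    ds.to_anndata().write_h5ad(Path(path))


# -- preprocessing ---------------------------------------------------------------


def filter_genes_min_cells(
    ds: ExpressionDataset, min_cells: int = 20, per: str = "system"
) -> ExpressionDataset:
    """Keep genes detected (count > 0) in more than ``min_cells`` cells in
    every system; the final gene set is the intersection across systems."""
    if ds.state != ProcessingState.RAW_COUNTS:
        raise ValueError("gene filtering expects raw counts")
    if per != "system":
        raise ValueError("only per-system filtering is supported")
    keep = np.ones(ds.n_genes, dtype=bool)
    for system in ds.systems:
        sub = ds.matrix[ds.system == system]
        detected = np.asarray((sub > 0).sum(axis=0)).ravel()
        keep &= detected > min_cells
    if not keep.any():
        raise ValueError(
            f"no gene is detected in more than {min_cells} cells in every system"
        )
    return ds.subset_genes([g for g, k in zip(ds.gene_ids, keep) if k])


def normalize_log(ds: ExpressionDataset) -> ExpressionDataset:
    """Median-target total-count normalisation followed by log1p.

    Every cell is scaled so its total equals the median pre-normalisation
    cell total (the scanpy ``normalize_total`` default), then log1p is
    applied and the processing state advances to ``normalized_log``.
    """
    if ds.state != ProcessingState.RAW_COUNTS:
        raise ValueError("normalize_log expects raw counts")
    totals = np.asarray(ds.matrix.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        ids = [ds.cell_ids[i] for i in zero[:10]]
        raise ValueError(f"cells with zero total counts cannot be normalised: {ids}")
    adata = ad.AnnData(X=ds.matrix.astype(np.float64, copy=True))
    sc.pp.normalize_total(adata, target_sum=None)
    sc.pp.log1p(adata)
    return replace(ds, matrix=adata.X, state=ProcessingState.NORMALIZED_LOG)


def select_hvgs_intersection(
    ds: ExpressionDataset, n_per_system: int, n_bins: int = 20
) -> list[str]:
    """Per-system Seurat-flavour (mean-binned normalised dispersion) HVG
    ranking; return the intersection of the per-system top-``n_per_system``
    sets in original gene order.

    ``n_bins`` is the number of mean-expression bins for dispersion
    normalisation; small gene panels need coarser bins.
    """
    if ds.state != ProcessingState.NORMALIZED_LOG:
        raise ValueError("HVG selection expects normalized-log data")
    if n_per_system > ds.n_genes:
        raise ValueError("n_per_system exceeds the number of genes")
    keep = np.ones(ds.n_genes, dtype=bool)
    for system in ds.systems:
        sub = ds.matrix[ds.system == system]
        adata = ad.AnnData(X=sub.astype(np.float64, copy=True))
        adata.var_names = ds.gene_ids
        sc.pp.highly_variable_genes(
            adata, flavor="seurat", n_top_genes=n_per_system, n_bins=n_bins
        )
        keep &= np.asarray(adata.var["highly_variable"])
    if not keep.any():
        raise ValueError(
            "no gene is highly variable in every system; increase n_per_system"
        )
    return [g for g, k in zip(ds.gene_ids, keep) if k]


def encode_covariates(ds: ExpressionDataset) -> tuple[CovariateEncoding, np.ndarray]:
    """One-hot encode (system, sample) per cell: one 1 in each block."""
    enc = CovariateEncoding(
        system_categories=ds.systems, sample_categories=ds.samples
    )
    return enc, enc.encode(ds.system, ds.sample)


def preprocess(
    ds: ExpressionDataset, min_cells: int = 20, n_hvgs: int | None = None
) -> ExpressionDataset:
    """Standard recipe: gene filter -> normalise/log -> optional HVG subset."""
    ds = filter_genes_min_cells(ds, min_cells=min_cells)
    ds = normalize_log(ds)
    if n_hvgs is not None:
        ds = ds.subset_genes(select_hvgs_intersection(ds, n_hvgs))
    return ds
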