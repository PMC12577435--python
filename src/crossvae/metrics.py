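"""Integration-evaluation and batch-strength statistics.

Batch correction is scored with the graph integration local inverse
Simpson's index (iLISI): per cell, the inverse Simpson index of the batch
composition of its k-nearest-neighbour neighbourhood, normalised to [0, 1].
Cell-type preservation uses NMI between ground truth and high-resolution
Leiden clusters majority-relabelled to cell types (NMI-fixed), plus a
per-type Jaccard index. Within-cell-type preservation uses Moran's I of
variable genes on per-(cell type, sample) neighbour graphs, reported as a
post/pre-integration ratio. A weighted overall score (0.6 biology, 0.4
batch) drives hyperparameter selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.metrics import normalized_mutual_info_score, silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .data import ExpressionDataset

__all__ = [
    "EmbeddingView",
    "MetricReport",
    "knn_graph",
    "ilisi",
    "leiden_majority_relabel",
    "majority_relabel",
    "nmi_fixed",
    "jaccard_per_type",
    "asw_batch",
    "morans_i",
    "morans_i_ratio",
    "scale_and_overall",
    "select_best_setting",
    "batch_strength_unintegrated",
    "condition_mixing",
    "gene_group_heterogeneity",
    "evaluate_embedding",
]


@dataclass
class EmbeddingView:
    """Cells x d embedding aligned with covariates."""

    embedding: np.ndarray
    system: np.ndarray
    sample: np.ndarray | None = None
    cell_type: np.ndarray | None = None
    condition: np.ndarray | None = None
    subsample_seed: int | None = None

    @classmethod
    def from_dataset(cls, ds: ExpressionDataset, embedding: np.ndarray) -> "EmbeddingView":
        return cls(
            embedding=np.asarray(embedding, float),
            system=ds.system,
            sample=ds.sample,
            cell_type=ds.cell_type,
            condition=ds.condition,
        )

    def subsample(self, max_cells: int = 100_000, seed: int = 0) -> "EmbeddingView":
        n = len(self.embedding)
        if n <= max_cells:
            return self
        idx = np.sort(np.random.default_rng(seed).choice(n, max_cells, replace=False))

        def _sub(a):
            return None if a is None else np.asarray(a)[idx]

        return EmbeddingView(
            embedding=self.embedding[idx],
            system=self.system[idx],
            sample=_sub(self.sample),
            cell_type=_sub(self.cell_type),
            condition=_sub(self.condition),
            subsample_seed=seed,
        )


@dataclass
class MetricReport:
    ilisi: float
    nmi_fixed: float
    jaccard_per_type: dict[str, float]
    asw_batch: float | None = None
    morans_i_ratio: float | None = None
    scaled: dict[str, float] = field(default_factory=dict)
    overall: float | None = None

    def to_dict(self) -> dict:
        return {
            "ilisi": self.ilisi,
            "nmi_fixed": self.nmi_fixed,
            "jaccard_per_type": self.jaccard_per_type,
            "asw_batch": self.asw_batch,
            "morans_i_ratio": self.morans_i_ratio,
            "scaled": self.scaled,
            "overall": self.overall,
        }


# -- graphs --------------------------------------------------------------------


def knn_graph(embedding: np.ndarray, k: int, row_normalize: bool = True) -> sp.csr_matrix:
    """k-nearest-neighbour weight matrix (self excluded, uniform weights)."""
    embedding = np.asarray(embedding, float)
    n = len(embedding)
    k = min(k, n - 1)
    if k < 1:
        raise ValueError("need at least 2 cells for a neighbour graph")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    vals = np.full(n * k, 1.0 / k if row_normalize else 1.0)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


# -- iLISI ---------------------------------------------------------------------


def ilisi(
    embedding: np.ndarray | None,
    labels: np.ndarray,
    k_neighbors: int = 90,
    graph: sp.spmatrix | None = None,
) -> float:
    """Normalised inverse Simpson index of `labels` over kNN neighbourhoods.

    Per cell: p_c = graph-weighted frequency of each label among its
    neighbours; ISI = 1 / sum_c p_c^2; normalised as (ISI - 1) /
    (n_labels - 1) and averaged over cells. 0 = no mixing, 1 = perfect
    mixing.
    """
    labels = np.asarray(labels)
    cats, codes = np.unique(labels, return_inverse=True)
    if len(cats) < 2:
        raise ValueError("iLISI needs at least two label categories")
    if graph is None:
        if embedding is None:
            raise ValueError("provide an embedding or a precomputed graph")
        graph = knn_graph(embedding, k_neighbors)
    graph = sp.csr_matrix(graph)
    row_sums = np.asarray(graph.sum(axis=1)).ravel()
    onehot = sp.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), len(cats)),
    )
    probs = np.asarray((graph @ onehot).todense())
    probs = probs / np.maximum(row_sums, 1e-12)[:, None]
    isi = 1.0 / np.maximum((probs**2).sum(axis=1), 1e-12)
    return float(((isi - 1.0) / (len(cats) - 1.0)).mean())


# -- cluster-based cell-type preservation ----------------------------------------


def leiden_majority_relabel(
    embedding: np.ndarray,
    truth: np.ndarray,
    resolution: float = 2.0,
    seed: int = 0,
    n_neighbors: int = 15,
) -> np.ndarray:
    """Leiden clusters on the embedding kNN graph, each renamed to its modal
    ground-truth label (ties -> lowest-sorted label)."""
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(X=np.asarray(embedding, float))
    n_neighbors = min(n_neighbors, len(embedding) - 1)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, use_rep="X")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                     flavor="leidenalg")
    clusters = np.asarray(adata.obs["leiden"])
    return majority_relabel(clusters, truth)


def majority_relabel(clusters: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Rename each cluster to its most common ground-truth label; modal ties
    resolve to the lowest-sorted label."""
    clusters = np.asarray(clusters)
    truth = np.asarray(truth)
    derived = np.empty(len(truth), dtype=object)
    for cl in np.unique(clusters):
        mask = clusters == cl
        vals, counts = np.unique(truth[mask], return_counts=True)
        derived[mask] = sorted(vals[counts == counts.max()])[0]
    return derived.astype(str)


def nmi_fixed(derived: np.ndarray, truth: np.ndarray) -> float:
    """Arithmetic-mean-normalised mutual information between labelings."""
    return float(
        normalized_mutual_info_score(
            np.asarray(truth), np.asarray(derived), average_method="arithmetic"
        )
    )


def jaccard_per_type(derived: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    derived = np.asarray(derived).astype(str)
    truth = np.asarray(truth).astype(str)
    out = {}
    for t in np.unique(truth):
        a, b = derived == t, truth == t
        union = (a | b).sum()
        out[t] = float((a & b).sum() / union) if union else 0.0
    return out


# -- silhouette-based batch strength ---------------------------------------------


def asw_batch(
    embedding: np.ndarray, batch: np.ndarray, cell_type: np.ndarray
) -> float:
    """Signed silhouette of batch labels within each cell type, averaged per
    type then across types. Higher = stronger batch separation. Types with a
    single batch are skipped with a warning."""
    embedding = np.asarray(embedding, float)
    batch = np.asarray(batch)
    cell_type = np.asarray(cell_type)
    per_type = []
    for t in np.unique(cell_type):
        mask = cell_type == t
        b = batch[mask]
        if len(np.unique(b)) < 2 or mask.sum() <= len(np.unique(b)):
            warnings.warn(f"cell type {t!r} skipped in ASW: fewer than two batches")
            continue
        per_type.append(float(silhouette_samples(embedding[mask], b).mean()))
    if not per_type:
        raise ValueError("no cell type has at least two batches")
    return float(np.mean(per_type))


# -- Moran's I -------------------------------------------------------------------


def morans_i(values: np.ndarray, graph: sp.spmatrix) -> float:
    """Moran's I of per-cell values on a weighted graph.

    I = (n / sum_ij w_ij) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    Constant input returns NaN with a warning.
    """
    x = np.asarray(values, float).ravel()
    w = sp.csr_matrix(graph)
    n = len(x)
    xc = x - x.mean()
    denom = float((xc**2).sum())
    if denom == 0.0:
        warnings.warn("Moran's I undefined for a constant vector; returning NaN")
        return float("nan")
    num = float(xc @ (w @ xc))
    return (n / w.sum()) * num / denom


def _morans_i_many(values: np.ndarray, graph: sp.csr_matrix) -> np.ndarray:
    """Moran's I per column of a cells x genes matrix (vectorised)."""
    x = np.asarray(values, float)
    xc = x - x.mean(axis=0, keepdims=True)
    denom = (xc**2).sum(axis=0)
    num = (xc * (graph @ xc)).sum(axis=0)
    n = x.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (n / graph.sum()) * num / denom
    out[denom == 0] = np.nan
    return out


@dataclass
class MoransIReport:
    per_group: pd.DataFrame  # columns: cell_type, sample, gene, mi_pre, mi_post
    ratio: float


def _group_gene_selection(
    x_group: np.ndarray, expr_frac: float, n_pcs: int, k: int,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Per-group pre-integration graph and the boolean kept-gene mask."""
    detected = (x_group > 0).mean(axis=0)
    keep = detected >= expr_frac
    xs = x_group[:, keep]
    xs = (xs - xs.mean(axis=0)) / (xs.std(axis=0) + 1e-8)
    n_comp = min(n_pcs, xs.shape[0] - 1, xs.shape[1])
    pcs = PCA(n_components=n_comp, random_state=0).fit_transform(xs)
    return knn_graph(pcs, k), keep


def morans_i_ratio(
    ds: ExpressionDataset,
    post_embedding: np.ndarray,
    pre_embedding: np.ndarray | None = None,
    min_cells: int = 500,
    expr_frac: float = 0.10,
    n_pcs: int = 15,
    k_neighbors: int = 15,
    keep_genes: tuple[int, int] = (12, 150),
    i_cutoff: float = 0.1,
    doublet_marker: str = "+",
) -> MoransIReport:
    """Post/pre-integration ratio of per-group gene autocorrelation.

    Groups are (cell type, sample) pairs with at least ``min_cells`` cells,
    doublet types (name containing ``doublet_marker``) excluded. Per group:
    drop genes expressed in fewer than ``expr_frac`` of the group's cells,
    build a neighbour graph (from per-group PCA of the expression by
    default, or from ``pre_embedding`` if given), compute Moran's I per
    gene, keep genes above ``i_cutoff`` with the kept count clamped into
    ``keep_genes``, recompute Moran's I on the post-integration embedding's
    per-group graph over the same genes, and average the per-gene ratios
    over genes, then samples, then cell types.
    """
    if ds.cell_type is None:
        raise ValueError("Moran's I ratio needs cell type annotations")
    x = ds.dense()
    post_embedding = np.asarray(post_embedding, float)
    rows = []
    for ct in np.unique(ds.cell_type):
        if doublet_marker and doublet_marker in ct:
            continue
        for smp in np.unique(ds.sample[ds.cell_type == ct]):
            mask = (ds.cell_type == ct) & (ds.sample == smp)
            if mask.sum() < min_cells:
                continue
            xg = x[mask]
            if pre_embedding is None:
                pre_graph, keep = _group_gene_selection(xg, expr_frac, n_pcs, k_neighbors)
            else:
                keep = (xg > 0).mean(axis=0) >= expr_frac
                pre_graph = knn_graph(np.asarray(pre_embedding)[mask], k_neighbors)
            gene_idx = np.flatnonzero(keep)
            mi_pre = _morans_i_many(xg[:, gene_idx], pre_graph)
            order = np.argsort(mi_pre)[::-1]
            n_above = int((mi_pre > i_cutoff).sum())
            n_keep = int(np.clip(n_above, keep_genes[0], keep_genes[1]))
            n_keep = min(n_keep, len(gene_idx))
            sel = order[:n_keep]
            post_graph = knn_graph(post_embedding[mask], k_neighbors)
            mi_post = _morans_i_many(xg[:, gene_idx[sel]], post_graph)
            for j, g in enumerate(sel):
                rows.append(
                    {
                        "cell_type": ct,
                        "sample": smp,
                        "gene": ds.gene_ids[gene_idx[g]],
                        "mi_pre": mi_pre[g],
                        "mi_post": mi_post[j],
                    }
                )
    if not rows:
        raise ValueError(
            f"no (cell type, sample) group has at least {min_cells} cells"
        )
    df = pd.DataFrame(rows)
    df["ratio"] = df["mi_post"] / df["mi_pre"]
    ratio = float(
        df.groupby(["cell_type", "sample"], observed=True)["ratio"]
        .mean()
        .groupby("cell_type", observed=True)
        .mean()
        .mean()
    )
    return MoransIReport(per_group=df, ratio=ratio)


# -- scaling / selection ----------------------------------------------------------


def scale_and_overall(
    runs: pd.DataFrame,
    bio_metrics: tuple[str, ...] = ("morans_i_ratio", "nmi_fixed"),
    batch_metric: str = "ilisi",
    bio_weight: float = 0.6,
) -> pd.DataFrame:
    """Min-max scale each metric across runs and add the overall score.

    overall = bio_weight * mean(scaled bio metrics) +
              (1 - bio_weight) * scaled batch metric.
    With a single run (or all-equal values) a metric scales to 0.
    """
    out = runs.copy()
    for col in (*bio_metrics, batch_metric):
        vals = out[col].astype(float)
        span = vals.max() - vals.min()
        out[f"{col}_scaled"] = 0.0 if span == 0 else (vals - vals.min()) / span
    out["bio_score"] = out[[f"{m}_scaled" for m in bio_metrics]].mean(axis=1)
    out["overall"] = (
        bio_weight * out["bio_score"] + (1 - bio_weight) * out[f"{batch_metric}_scaled"]
    )
    return out


def select_best_setting(
    runs: pd.DataFrame, setting_cols: list[str], overall_col: str = "overall"
) -> tuple[dict, pd.Series]:
    """Best hyperparameter setting by seed-averaged overall score, plus the
    representative run (the run whose overall is the median within the best
    setting; ties -> first in table order)."""
    grouped = runs.groupby(setting_cols, dropna=False, sort=False)[overall_col].mean()
    best_key = grouped.idxmax()
    if not isinstance(best_key, tuple):
        best_key = (best_key,)
    setting = dict(zip(setting_cols, best_key))
    mask = np.ones(len(runs), dtype=bool)
    for col, val in setting.items():
        mask &= (runs[col] == val).to_numpy()
    sub = runs[mask]
    med = sub[overall_col].median()
    rep_idx = (sub[overall_col] - med).abs().idxmin()
    return setting, runs.loc[rep_idx]


# -- pre-integration batch strength -----------------------------------------------


def batch_strength_unintegrated(
    ds: ExpressionDataset,
    n_pcs: int = 15,
    min_cells: int = 50,
    min_samples_per_system: int = 3,
) -> pd.DataFrame:
    """Within- vs between-system distances of (cell type, sample) centroids.

    Gene-scaled expression -> PCA -> per-group mean embeddings -> pairwise
    Euclidean distances split by whether the two samples share a system ->
    one-sided Mann-Whitney U per cell type (between > within).
    """
    if ds.cell_type is None:
        raise ValueError("batch-strength analysis needs cell type annotations")
    x = ds.dense()
    xs = (x - x.mean(axis=0)) / (x.std(axis=0) + 1e-8)
    pcs = PCA(n_components=min(n_pcs, x.shape[1], x.shape[0] - 1), random_state=0).fit_transform(xs)
    rows = []
    for ct in np.unique(ds.cell_type):
        groups = []
        for smp in np.unique(ds.sample[ds.cell_type == ct]):
            mask = (ds.cell_type == ct) & (ds.sample == smp)
            if mask.sum() < min_cells:
                continue
            groups.append((smp, ds.system[mask][0], pcs[mask].mean(axis=0)))
        systems = pd.Series([g[1] for g in groups])
        if (systems.value_counts() < min_samples_per_system).any() or systems.nunique() < 2:
            continue
        within, between = [], []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                d = float(np.linalg.norm(groups[i][2] - groups[j][2]))
                (within if groups[i][1] == groups[j][1] else between).append(d)
        stat, p = mannwhitneyu(between, within, alternative="greater")
        rows.append(
            {
                "cell_type": ct,
                "n_within": len(within),
                "n_between": len(between),
                "mean_within": float(np.mean(within)),
                "mean_between": float(np.mean(between)),
                "mannwhitney_u": float(stat),
                "p_value": float(p),
            }
        )
    if not rows:
        raise ValueError("no cell type qualifies for the batch-strength analysis")
    return pd.DataFrame(rows)


# -- condition mixing --------------------------------------------------------------


def condition_mixing(
    embedding: np.ndarray,
    system: np.ndarray,
    similar_mask: np.ndarray,
    dissimilar_mask: np.ndarray,
    k_neighbors: int = 90,
) -> tuple[float, float]:
    """iLISI of the system label on two cell subsets: a biologically similar
    pair of groups (should mix) and a dissimilar pair (should not)."""
    out = []
    for mask in (similar_mask, dissimilar_mask):
        mask = np.asarray(mask, bool)
        if mask.sum() < 3:
            raise ValueError("each group pair needs at least 3 cells")
        out.append(ilisi(np.asarray(embedding)[mask], np.asarray(system)[mask], k_neighbors))
    return out[0], out[1]


# -- gene-group heterogeneity ------------------------------------------------------


def gene_group_heterogeneity(
    ds: ExpressionDataset,
    embedding: np.ndarray,
    gene_sets: dict[str, list[str]],
    mask: np.ndarray | None = None,
    k_neighbors: int = 15,
    seed: int = 0,
) -> dict[str, float]:
    """Moran's I of per-cell gene-set scores on the embedding's kNN graph.

    Scores use scanpy ``score_genes`` (set mean minus binned control mean),
    optionally restricted to one (sample, cell type) group via ``mask``.
    """
    import scanpy as sc

    adata = ds.to_anndata()
    if mask is not None:
        mask = np.asarray(mask, bool)
        adata = adata[mask].copy()
        embedding = np.asarray(embedding)[mask]
    graph = knn_graph(np.asarray(embedding, float), k_neighbors)
    out = {}
    for name, genes in gene_sets.items():
        missing = [g for g in genes if g not in adata.var_names]
        if missing:
            raise ValueError(f"gene set {name!r} has genes absent from the data: {missing[:5]}")
        sc.tl.score_genes(adata, gene_list=genes, score_name="_score", random_state=seed)
        out[name] = morans_i(np.asarray(adata.obs["_score"]), graph)
    return out


# -- one-call evaluation ------------------------------------------------------------


def evaluate_embedding(
    ds: ExpressionDataset,
    embedding: np.ndarray,
    k_ilisi: int = 90,
    leiden_resolution: float = 2.0,
    seed: int = 0,
    morans_kwargs: dict | None = None,
    max_cells: int = 100_000,
) -> MetricReport:
    """iLISI (system), NMI-fixed, per-type Jaccard and Moran's I ratio for
    one embedding of ``ds`` (subsampled to ``max_cells`` for the graph
    metrics)."""
    view = EmbeddingView.from_dataset(ds, embedding).subsample(max_cells, seed)
    score_ilisi = ilisi(view.embedding, view.system, k_ilisi)
    if view.cell_type is None:
        raise ValueError("evaluation needs cell type annotations")
    derived = leiden_majority_relabel(
        view.embedding, view.cell_type, resolution=leiden_resolution, seed=seed
    )
    report = MetricReport(
        ilisi=score_ilisi,
        nmi_fixed=nmi_fixed(derived, view.cell_type),
        jaccard_per_type=jaccard_per_type(derived, view.cell_type),
    )
    if morans_kwargs is not None:
        report.morans_i_ratio = morans_i_ratio(ds, embedding, **morans_kwargs).ratio
    return report
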