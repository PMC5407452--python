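"""Sample-level QC and structure for log2 expression matrices.

Quantile normalisation, ComBat-style batch adjustment (exact location/scale
equalisation or empirical-Bayes shrinkage), correlation-based outlier
flagging, PCA embedding and Ward hierarchical clustering of samples.

Matrices are pandas DataFrames with genes in rows and samples in columns,
log2 scale throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

__all__ = [
    "validate_matrix",
    "quantile_normalize",
    "adjust_batch",
    "detect_outliers",
    "PCAResult",
    "pca_embed",
    "ClusterResult",
    "cluster_samples",
]


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate an expression matrix: finite values, unique gene ids
    (case-insensitive) and unique sample ids."""
    if not np.all(np.isfinite(matrix.to_numpy(dtype=float))):
        raise ValueError("expression matrix contains non-finite values")
    upper = matrix.index.astype(str).str.upper()
    if upper.duplicated().any():
        dup = upper[upper.duplicated()].unique()
        raise ValueError(f"duplicate gene ids (case-insensitive): {list(dup)[:5]}")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    return matrix


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common quantile distribution.

    The reference distribution is the across-sample mean of the sorted
    columns; each column's values are replaced by the reference value at
    their rank, with ties receiving the average of the tied reference
    values. Idempotent, and the identity for matrices whose columns are
    already identical distributions.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalisation needs >=2 samples")
    validate_matrix(matrix)
    x = matrix.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = pd.Series(x[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return pd.DataFrame(out, index=matrix.index.copy(),
                        columns=matrix.columns.copy())


def _batch_groups(matrix: pd.DataFrame, batches) -> dict[str, np.ndarray]:
    b = np.asarray(batches, dtype=object)
    if b.size != matrix.shape[1]:
        raise ValueError(
            f"got {b.size} batch labels for {matrix.shape[1]} samples")
    groups = {label: np.flatnonzero(b == label) for label in pd.unique(b)}
    if len(groups) < 2:
        raise ValueError("batch adjustment needs >=2 batches")
    for label, idx in groups.items():
        if idx.size < 2:
            raise ValueError(f"batch {label!r} has {idx.size} samples; need >=2")
    return groups


def adjust_batch(matrix: pd.DataFrame, batches, mode: str = "meanvar") -> pd.DataFrame:
    """Remove additive/multiplicative batch effects per gene.

    ``mode='meanvar'`` standardises each batch per gene and rescales to the
    gene's pooled mean and pooled within-batch variance, which removes pure
    location (and scale) batch effects exactly. ``mode='eb'`` shrinks the
    per-gene batch location and log-scale estimates across genes toward
    their batch-wise means with inverse-variance weights before
    subtracting, trading exactness for stability at small batch sizes.
    """
    if mode not in ("meanvar", "eb"):
        raise ValueError(f"unknown mode {mode!r}")
    validate_matrix(matrix)
    groups = _batch_groups(matrix, batches)
    x = matrix.to_numpy(dtype=float)
    n_genes, _ = x.shape

    means = {b: x[:, idx].mean(axis=1) for b, idx in groups.items()}
    variances = {b: x[:, idx].var(axis=1, ddof=1) for b, idx in groups.items()}
    sizes = {b: idx.size for b, idx in groups.items()}
    n_total = sum(sizes.values())
    grand_mean = sum(means[b] * sizes[b] for b in groups) / n_total
    dof = sum(sizes[b] - 1 for b in groups)
    pooled_var = sum(variances[b] * (sizes[b] - 1) for b in groups) / dof

    out = x.copy()
    if mode == "meanvar":
        pooled_sd = np.sqrt(pooled_var)
        for b, idx in groups.items():
            sd_b = np.sqrt(variances[b])
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (x[:, idx] - means[b][:, None]) / sd_b[:, None]
            z[~np.isfinite(z)] = 0.0
            out[:, idx] = grand_mean[:, None] + z * pooled_sd[:, None]
    else:
        for b, idx in groups.items():
            gamma_hat = means[b] - grand_mean          # per-gene location shift
            gamma_bar = float(gamma_hat.mean())
            # inverse-variance weight between the gene's own estimate and the
            # batch-wide mean shift; sampling variance of gamma_hat ~ var/n,
            # subtracted from the raw spread to estimate the true offset spread
            samp_var = variances[b] / sizes[b]
            tau2 = max(float(gamma_hat.var(ddof=1)) - float(samp_var.mean()), 0.0)
            w = tau2 / (tau2 + samp_var) if tau2 > 0 else np.zeros(n_genes)
            gamma_star = w * gamma_hat + (1.0 - w) * gamma_bar

            with np.errstate(divide="ignore"):
                log_delta = np.log(np.where(variances[b] > 0, variances[b], np.nan))
            lbar = np.nanmean(log_delta)
            shrink = sizes[b] / (sizes[b] + 2.0)
            delta_star = np.exp(shrink * np.nan_to_num(log_delta, nan=lbar)
                                + (1 - shrink) * lbar)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (x[:, idx] - grand_mean[:, None] - gamma_star[:, None]) \
                    / np.sqrt(delta_star)[:, None]
            z[~np.isfinite(z)] = 0.0
            out[:, idx] = grand_mean[:, None] + z * np.sqrt(pooled_var)[:, None]
    return pd.DataFrame(out, index=matrix.index.copy(),
                        columns=matrix.columns.copy())


def detect_outliers(matrix: pd.DataFrame, meta: pd.DataFrame,
                    k: float = 3.0) -> list[str]:
    """Flag samples poorly correlated with their own tissue group.

    For each tissue with >=4 samples, every sample's median Pearson
    correlation to the other samples of that tissue is computed; samples
    below Q1 - k*IQR of the tissue's median-correlation distribution are
    flagged. Tissues with <4 samples are skipped with a warning.
    """
    validate_matrix(matrix)
    flagged: list[str] = []
    for tissue, sub in meta.groupby("tissue", sort=True):
        ids = [s for s in sub["sample_id"] if s in matrix.columns]
        if len(ids) < 4:
            warnings.warn(
                f"tissue {tissue!r} has {len(ids)} samples; outlier check skipped",
                RuntimeWarning)
            continue
        corr = np.corrcoef(matrix[ids].to_numpy(dtype=float).T)
        med = np.array([np.median(np.delete(corr[i], i))
                        for i in range(len(ids))])
        q1, q3 = np.percentile(med, [25, 75])
        cut = q1 - k * (q3 - q1)
        flagged.extend(s for s, m in zip(ids, med) if m < cut)
    return flagged


@dataclass
class PCAResult:
    """Per-sample scores on k principal components and the variance
    fraction each component explains."""

    scores: pd.DataFrame  # samples x components, columns PC1..PCk
    variance_ratio: np.ndarray


def pca_embed(matrix: pd.DataFrame, k: int = 2) -> PCAResult:
    """Project samples onto the top-k principal axes after per-gene centring."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(matrix.shape):
        raise ValueError(f"k={k} exceeds min(genes, samples)={min(matrix.shape)}")
    validate_matrix(matrix)
    x = matrix.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns.copy(),
                            columns=[f"PC{i + 1}" for i in range(k)]),
        variance_ratio=pca.explained_variance_ratio_.copy(),
    )


@dataclass
class ClusterResult:
    """Ward linkage over samples, with the sample order used."""

    linkage: np.ndarray
    sample_ids: list[str]
    n_top_genes: int

    def cut(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return self.sample_ids[node.id]
            return (f"({rec(node.left)}:{node.dist - node.left.dist:.6g},"
                    f"{rec(node.right)}:{node.dist - node.right.dist:.6g})")

        return rec(tree) + ";"


def cluster_samples(matrix: pd.DataFrame, n_top_genes: int = 500) -> ClusterResult:
    """Ward hierarchical clustering of samples.

    Euclidean distances over the ``n_top_genes`` most-variable genes
    (ties in variance broken by gene id). Samples are processed in sorted
    id order so the tree is invariant to the input column order.
    """
    if matrix.shape[1] < 3:
        raise ValueError("clustering needs >=3 samples")
    if n_top_genes < 2:
        raise ValueError("n_top_genes must be >= 2")
    validate_matrix(matrix)
    ordered = matrix.reindex(columns=sorted(matrix.columns))
    var = ordered.var(axis=1)
    rank = pd.DataFrame({"variance": var.to_numpy(),
                         "gene_id": var.index.astype(str)})
    rank = rank.sort_values(["variance", "gene_id"], ascending=[False, True])
    keep = var.index[rank.index[:n_top_genes]]
    sub = ordered.loc[keep]
    z = hierarchy.linkage(sub.to_numpy(dtype=float).T, method="ward")
    return ClusterResult(linkage=z, sample_ids=list(ordered.columns),
                         n_top_genes=min(n_top_genes, matrix.shape[0]))
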