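"""Leave-one-gene-out silhouette importance of genes for a fixed clustering.

The silhouette coefficient of a clustered sample is s_i = (b_i - a_i) /
max(a_i, b_i), where a_i is the mean Euclidean distance to the sample's own
cluster (excluding itself) and b_i the smallest mean distance to any other
cluster; singletons contribute 0. The mean over samples measures clustering
quality. A gene's importance is the *drop* in mean silhouette when the gene
is removed from the expression matrix (cluster labels held fixed): genes
whose removal degrades the separation most are the ones that determined the
clustering. Genes in the top third of this ranking feed the enrichment
analysis.

Removing gene g only subtracts its per-pair squared differences from the
squared Euclidean distances, so the leave-one-out sweep reuses one full
distance computation instead of recomputing n_genes distance matrices.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def _pairwise_sq_dists(x: np.ndarray) -> np.ndarray:
    """Full matrix of squared Euclidean distances between rows of x."""
    sq = np.einsum("ij,ij->i", x, x)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def silhouette_samples_from_dist(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette values from a full distance matrix.

    Singleton clusters contribute s_i = 0; a sample with a_i = b_i = 0
    (all distances zero) also scores 0.
    """
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = d.shape[0]
    onehot = np.zeros((n, len(uniq)))
    onehot[np.arange(n), inv] = 1.0
    sums = d @ onehot  # sums[i, c] = sum of distances from i to cluster c
    sizes = onehot.sum(axis=0)
    own_size = sizes[inv]
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sums[np.arange(n), inv] / (own_size - 1.0)
    other = sums / sizes[None, :]
    other[np.arange(n), inv] = np.inf
    b = other.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / denom, 0.0)
    s[own_size == 1] = 0.0  # singleton convention
    return s


def mean_silhouette(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette of a samples-by-genes matrix under Euclidean distance."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be 2-D (samples x genes)")
    d = np.sqrt(_pairwise_sq_dists(x))
    return float(silhouette_samples_from_dist(d, labels).mean())


def incremental_loo_distances(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full squared distances and per-gene squared-difference adjustments.

    Returns ``(d2_full, adjustments)`` with ``adjustments[g][i, j] =
    (x[i, g] - x[j, g])**2`` so that the leave-gene-g-out squared distance is
    ``d2_full - adjustments[g]`` exactly. Materializes an (n_genes, n, n)
    tensor — intended for verification and small inputs; the importance
    sweep below computes the same quantities gene-by-gene without storing
    the tensor.
    """
    x = np.asarray(x, dtype=float)
    d2 = _pairwise_sq_dists(x)
    diffs = x.T[:, :, None] - x.T[:, None, :]  # genes x n x n
    return d2, diffs**2


def loo_silhouette_importance(
    x: np.ndarray,
    labels: np.ndarray,
    gene_ids: list[str],
    s_full: float | None = None,
    top_fraction: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Rank genes by silhouette drop when left out; flag the top third.

    ``x`` is the patients-by-genes matrix the clustering was computed on
    (already standardized if the clustering was); ``labels`` are held fixed
    during the sweep. Returns an ImportanceTable with columns ``s_without``
    (mean silhouette with the gene removed), ``delta`` (s_full - s_without;
    large positive = removing the gene hurts the separation = important),
    ``rank`` (1 = most important; ties broken by gene id) and ``top_third``
    (exactly ceil(n_genes * top_fraction) genes flagged).
    """
    x = np.asarray(x, dtype=float)
    n, g = x.shape
    if g != len(gene_ids):
        raise ValueError("gene_ids length does not match matrix width")
    if g < 3:
        raise ValueError("top third undefined for fewer than 3 genes")
    d2_full = _pairwise_sq_dists(x)
    if s_full is None:
        s_full = float(silhouette_samples_from_dist(np.sqrt(d2_full), labels).mean())
    s_without = np.empty(g)
    for j in range(g):
        diff = x[:, j][:, None] - x[:, j][None, :]
        d2 = np.maximum(d2_full - diff * diff, 0.0)
        s_without[j] = silhouette_samples_from_dist(np.sqrt(d2), labels).mean()
    delta = s_full - s_without
    table = pd.DataFrame(
        {"s_without": s_without, "delta": delta},
        index=pd.Index(gene_ids, name="gene"),
    )
    # two-key ordering: delta descending, gene id ascending
    order = (
        table.reset_index()
        .sort_values(["delta", "gene"], ascending=[False, True], kind="mergesort")["gene"]
        .tolist()
    )
    rank = pd.Series(np.arange(1, g + 1), index=order, name="rank")
    table["rank"] = rank
    n_top = math.ceil(g * top_fraction)
    table["top_third"] = table["rank"] <= n_top
    return table


def recluster_loo_silhouette_importance(
    x: np.ndarray,
    gene_ids: list[str],
    k: int,
    seed: int = 0,
    n_init: int = 10,
    top_fraction: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Alternative sweep that re-runs k-means for every left-out gene.

    Far more expensive than the fixed-label procedure and stochastic through
    the k-means restarts; provided for sensitivity analysis.
    """
    from sklearn.cluster import KMeans

    x = np.asarray(x, dtype=float)
    n, g = x.shape
    if g < 3:
        raise ValueError("top third undefined for fewer than 3 genes")
    full_labels = KMeans(k, n_init=n_init, random_state=seed).fit_predict(x)
    s_full = mean_silhouette(x, full_labels)
    s_without = np.empty(g)
    for j in range(g):
        xr = np.delete(x, j, axis=1)
        lab = KMeans(k, n_init=n_init, random_state=seed).fit_predict(xr)
        s_without[j] = mean_silhouette(xr, lab)
    table = pd.DataFrame(
        {"s_without": s_without, "delta": s_full - s_without},
        index=pd.Index(gene_ids, name="gene"),
    )
    order = (
        table.reset_index()
        .sort_values(["delta", "gene"], ascending=[False, True], kind="mergesort")["gene"]
        .tolist()
    )
    table["rank"] = pd.Series(np.arange(1, g + 1), index=order)
    table["top_third"] = table["rank"] <= math.ceil(g * top_fraction)
    return table
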