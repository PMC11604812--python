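"""k-means subtyping of patient samples in DE-gene space.

Patients are clustered with Lloyd's k-means (best of ``n_init``
restarts) on the DE-selected genes, optionally z-scored per gene across
patients so no single high-variance gene dominates the Euclidean metric.
The cluster count is chosen by a deterministic surrogate of the visual
elbow method: the k maximizing the second difference of the
within-cluster sum-of-squares curve. Cluster index 0 ("Cluster I") is
always the cluster whose centroid lies farther from the control
centroid, i.e. the molecularly distinct subtype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


@dataclass
class ClusterResult:
    """Patient cluster labels plus the diagnostics of the fit."""

    labels: pd.Series  # cluster index per patient; 0 == "Cluster I"
    k: int
    inertia: float
    mean_silhouette: float
    seed: int
    inertia_curve: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None

    @property
    def cluster_sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (x - mu) / sd, mu, sd

def _patient_matrix(
    m: pd.DataFrame, patient_ids: list[str], genes: list[str], standardize: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Patients-by-genes array in canonical (sorted-sample) order."""
    order = sorted(patient_ids)
    x = m.loc[genes, order].to_numpy(float).T
    if standardize:
        x, mu, sd = _standardize(x)
    else:
        mu = np.zeros(x.shape[1])
        sd = np.ones(x.shape[1])
    return x, mu, sd, order


def kmeans_cluster(
    m: pd.DataFrame,
    patient_ids: list[str],
    control_ids: list[str],
    genes: list[str],
    k: int = 2,
    seed: int = 0,
    n_init: int = 50,
    standardize: bool = True,
) -> ClusterResult:
    """Cluster patients in the space of ``genes``; label the control-distal cluster I.

    The best-of-``n_init`` Lloyd solution is deterministic given ``seed``;
    sample order is canonicalized (sorted ids) before fitting so permuting
    the input permutes the labels identically. Controls are projected into
    the same (optionally standardized) space only to orient the labels:
    cluster 0 is the cluster whose centroid is farther from the control
    centroid.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(patient_ids):
        raise ValueError(f"k={k} exceeds number of patients ({len(patient_ids)})")
    if not genes:
        raise ValueError("empty gene list")
    x, mu, sd, order = _patient_matrix(m, patient_ids, genes, standardize)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(x)

    ctrl = (m.loc[genes, sorted(control_ids)].to_numpy(float).T - mu) / sd
    ctrl_centroid = ctrl.mean(axis=0)
    dist = np.linalg.norm(km.cluster_centers_ - ctrl_centroid, axis=1)
    # relabel: 0 = farthest from controls ("Cluster I"), then by distance
    new_of_old = np.empty(k, dtype=int)
    new_of_old[np.argsort(-dist, kind="stable")] = np.arange(k)
    labels = pd.Series(new_of_old[raw], index=pd.Index(order, name="sample_id"), name="cluster")

    from .importance import mean_silhouette  # local import to avoid cycle

    sil = mean_silhouette(x, labels.to_numpy()) if k < len(patient_ids) else 0.0
    return ClusterResult(
        labels=labels.loc[sorted(patient_ids)],
        k=k,
        inertia=float(km.inertia_),
        mean_silhouette=float(sil),
        seed=seed,
    )


def elbow_select_k(
    m: pd.DataFrame,
    patient_ids: list[str],
    genes: list[str],
    k_max: int = 6,
    seed: int = 0,
    n_init: int = 50,
    standardize: bool = True,
) -> tuple[int, dict[int, float]]:
    """Choose k by the maximum-curvature elbow of the inertia curve.

    Computes within-cluster sum of squares for k = 1..k_max and returns
    ``chosen_k = argmax_{2 <= k <= k_max-1}`` of the second difference
    ``inertia(k-1) - 2*inertia(k) + inertia(k+1)``, ties broken toward the
    smallest k. If fewer patients than ``k_max`` are available, k_max is
    reduced with a warning.
    """
    if k_max < 3:
        raise ValueError("k_max must be >= 3 for the elbow to be defined")
    if len(patient_ids) < k_max:
        warnings.warn(
            f"k_max={k_max} reduced to {len(patient_ids)} (number of patients)",
            stacklevel=2,
        )
        k_max = len(patient_ids)
        if k_max < 3:
            raise ValueError("need at least 3 patients for elbow selection")
    x, _, _, _ = _patient_matrix(m, patient_ids, genes, standardize)
    curve: dict[int, float] = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
        km.fit(x)
        curve[k] = float(km.inertia_)
    best_k, best_curv = None, -np.inf
    for k in range(2, k_max):
        curv = curve[k - 1] - 2.0 * curve[k] + curve[k + 1]
        if curv > best_curv + 1e-12:  # strict improvement -> ties go to smallest k
            best_k, best_curv = k, curv
    assert best_k is not None
    return best_k, curve


def pca_project(
    m: pd.DataFrame, gene_subset: list[str], n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Project all samples onto the top principal components of a gene subset.

    The samples-by-genes matrix is column-centered; component signs are
    fixed by making the largest-magnitude entry of each loading vector
    positive. Returns (coordinates, loadings, explained_variance_ratio).
    """
    if not gene_subset:
        raise ValueError("gene_subset is empty")
    missing = set(gene_subset) - set(m.index)
    if missing:
        raise KeyError(f"genes absent from matrix: {sorted(missing)[:10]}")
    x = m.loc[gene_subset].to_numpy(float).T  # samples x genes
    if n_components > min(x.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, genes)={min(x.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    loadings = pca.components_  # components x genes
    for i in range(n_components):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            coords[:, i] = -coords[:, i]
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=m.columns.rename("sample_id"), columns=comp_names),
        pd.DataFrame(loadings.T, index=pd.Index(gene_subset, name="gene"), columns=comp_names),
        pca.explained_variance_ratio_,
    )
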