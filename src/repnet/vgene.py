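"""V-gene usage profiling: usage matrices, PCA, k-means, marker selection.

Usage is the percent of a sample's clones assigned to each germline V gene
(clone-weighted, not read-weighted, so clonal expansion does not inflate a
gene). Samples with too few clones for a stable percentage (fewer than 100
by default) are excluded. The discovery stages mirror a standard workflow:
PCA on the usage matrix, k-means in PC1-PC2 to delineate sample clusters,
an elastic-net classifier to name the genes separating them, and
complete-linkage hierarchical clustering for heatmap ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .network import CloneSet


def usage_matrix(
    clone_sets: Mapping[str, CloneSet],
    min_clones: int = 100,
) -> pd.DataFrame:
    """Percent-of-clones V-gene usage matrix (samples x genes).

    Rows are restricted to samples with at least ``min_clones`` clones; each
    retained row sums to 100. Columns are every V gene observed among the
    retained samples, sorted.
    """
    eligible = {
        sid: cs for sid, cs in clone_sets.items() if cs.n_clones >= min_clones
    }
    genes = sorted({c.v_gene for cs in eligible.values() for c in cs.clones})
    data = np.zeros((len(eligible), len(genes)))
    gene_ix = {g: i for i, g in enumerate(genes)}
    sample_ids = sorted(eligible)
    for r, sid in enumerate(sample_ids):
        cs = eligible[sid]
        for clone in cs.clones:
            data[r, gene_ix[clone.v_gene]] += 1
        data[r] *= 100.0 / cs.n_clones
    return pd.DataFrame(data, index=sample_ids, columns=genes)


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x PCs
    loadings: pd.DataFrame        # genes x PCs
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def pca_embed(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Column-centered PCA via SVD (no variance scaling: columns share the
    percent scale, and unit-variance scaling would inflate rare genes).

    Sign convention: each loading vector's largest-magnitude element is made
    positive, so the embedding is deterministic.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, S.size)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U * S
    n = X.shape[0]
    ev = S**2 / (n - 1)
    total_var = np.sum(X**2) / (n - 1)
    ratio = ev / total_var if total_var > 0 else np.zeros_like(ev)
    pcs = [f"PC{i+1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=matrix.columns, columns=pcs),
        explained_variance=ev,
        explained_variance_ratio=ratio,
    )


def kmeans_partition(
    scores: pd.DataFrame | np.ndarray, k: int = 2, seed: int = 0
) -> np.ndarray:
    """k-means labels in the PC space, largest cluster relabelled 0.

    Uses 10 restarts and keeps the lowest-inertia solution; label identity
    is resolved by decreasing cluster size, with size ties broken by
    centroid coordinates, so the labelling depends only on the fitted
    partition and not on initialisation order.
    """
    X = scores.to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of points ({X.shape[0]})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    order = sorted(
        range(k), key=lambda lab: (-sizes[lab], tuple(km.cluster_centers_[lab]))
    )
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[lab] for lab in raw])


@dataclass
class MarkerSelection:
    genes: list[str]
    l1_ratio: float
    C: float
    coefficients: pd.Series


def elastic_net_markers(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    l1_ratios: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    folds: int = 5,
    seed: int = 0,
    Cs: int = 10,
) -> MarkerSelection:
    """Elastic-net logistic regression markers for a binary sample cluster.

    The mixing parameter is scanned over ``l1_ratios`` and, jointly with the
    regularization strength path, chosen by minimizing the mean
    cross-validated binomial deviance over ``folds`` stratified folds.
    Predictors are standardized internally; the selected genes (nonzero
    coefficients at the chosen point) are reported by original name.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if matrix.shape[0] < folds:
        raise ValueError("need at least as many samples as CV folds")
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns stay constant (zero) -> never selected
    Xs = (X - mu) / sd
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        solver="saga",
        l1_ratios=list(l1_ratios),
        scoring="neg_log_loss",
        max_iter=10000,
        random_state=seed,
        tol=1e-4,
        use_legacy_attributes=False,
    )
    model.fit(Xs, y)
    coefs = pd.Series(model.coef_[0], index=matrix.columns)
    selected = [g for g, c in coefs.items() if c != 0.0]
    return MarkerSelection(
        genes=selected,
        l1_ratio=float(np.ravel(model.l1_ratio_)[0]),
        C=float(np.ravel(model.C_)[0]),
        coefficients=coefs,
    )


@dataclass
class ClusterOrder:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def hierarchical_order(matrix: pd.DataFrame) -> ClusterOrder:
    """Complete-linkage Euclidean clustering of rows and columns.

    Returns leaf orders and the merge trees; scipy's index-based
    tie-breaking makes the result deterministic and invariant to row
    permutation (up to the identical tree topology).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    X = matrix.to_numpy(dtype=float)
    row_Z = linkage(X, method="complete", metric="euclidean")
    col_Z = linkage(X.T, method="complete", metric="euclidean")
    return ClusterOrder(
        row_order=[matrix.index[i] for i in leaves_list(row_Z)],
        col_order=[matrix.columns[i] for i in leaves_list(col_Z)],
        row_linkage=row_Z,
        col_linkage=col_Z,
    )
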