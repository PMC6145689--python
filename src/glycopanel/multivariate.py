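"""Sample-level multivariate analysis: PCA with outlier-channel detection,
Euclidean hierarchical clustering for heat-map ordering, and PLS-DA
cross-validated ROC curves for panel evaluation.

PCA is computed by singular value decomposition of the feature-centered
sample x feature table (features with any missing value are dropped first).
An outlier channel is one whose distance from the sample centroid in the
PC1-PC2 plane exceeds ``k_mad`` times the median distance of all samples --
the rule used to drop one aberrant control channel before differential
statistics, mirroring how a deviant TMT channel is excluded from a cohort.

The ROC evaluation fits a 2-component PLS-DA (partial least squares with a
0/1 class response) under leave-one-out cross-validation and computes AUC
from the held-out sample scores by the Mann-Whitney rank formula with ties
counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "PcaResult",
    "RocResult",
    "pca",
    "detect_outlier_samples",
    "hierarchical_cluster",
    "rank_features",
    "auc_mann_whitney",
    "plsda_loo_scores",
    "plsda_roc",
]


@dataclass
class PcaResult:
    """Scores (samples x components), loadings (features x components) and
    explained-variance fractions, nonincreasing across components."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


@dataclass
class RocResult:
    panel_size: int
    auc: float
    scores: pd.Series  # held-out predicted score per sample
    features: list[str]


def pca(matrix: pd.DataFrame, n_components: int | None = None, scale: bool = False) -> PcaResult:
    """SVD-based PCA of a sample x feature table.

    Features (columns) are mean-centered; with ``scale=True`` also scaled to
    unit variance.  Columns with missing values are dropped (complete-feature
    restriction).  Rows are samples.
    """
    x = matrix.dropna(axis=1)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 complete features")
    centered = x - x.mean(axis=0)
    if scale:
        sd = centered.std(axis=0, ddof=1)
        centered = centered.loc[:, sd > 0] / sd[sd > 0]
    u, s, vt = np.linalg.svd(centered.to_numpy(float), full_matrices=False)
    if not np.any(s > 0):
        raise ValueError("rank-0 input")
    k = n_components or min(len(s), x.shape[0] - 1)
    k = min(k, len(s))
    var = s**2 / (x.shape[0] - 1)
    evr = var / var.sum()
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=x.index, columns=comp_names)
    loadings = pd.DataFrame(vt[:k].T, index=centered.columns, columns=comp_names)
    return PcaResult(scores=scores, loadings=loadings, explained_variance_ratio=evr[:k])


def detect_outlier_samples(result: PcaResult, k_mad: float = 3.0) -> list[str]:
    """Samples whose PC1-PC2 distance from the centroid exceeds ``k_mad``
    times the median distance of all samples."""
    if result.scores.shape[0] < 4:
        raise ValueError("need >= 4 samples for outlier detection")
    plane = result.scores.iloc[:, : min(2, result.scores.shape[1])]
    centroid = plane.mean(axis=0)
    dist = np.sqrt(((plane - centroid) ** 2).sum(axis=1))
    cutoff = k_mad * dist.median()
    return list(dist.index[dist > cutoff])


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "average",
    n_clusters: int = 2,
) -> tuple[np.ndarray, list, np.ndarray]:
    """Agglomerative clustering of the rows of ``matrix``.

    Returns (linkage matrix, dendrogram leaf order as row labels, flat
    cluster labels from cutting at ``n_clusters``).
    """
    x = matrix.dropna(axis=1).to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    z = hierarchy.linkage(pdist(x, metric=metric), method=linkage)
    leaves = hierarchy.leaves_list(z)
    flat = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return z, [matrix.index[i] for i in leaves], flat


def rank_features(diff: pd.DataFrame, by: str = "t") -> list[str]:
    """Feature keys ordered by decreasing |moderated t| (default ranking)."""
    return list(diff[by].abs().sort_values(ascending=False, kind="mergesort").index)


def auc_mann_whitney(scores, labels, positive) -> float:
    """AUC from scores via the rank-sum formula, ties counted 1/2.

    Equals the probability that a random positive outscores a random
    negative; invariant under strictly monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes to compute AUC")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def plsda_loo_scores(x: pd.DataFrame, y: np.ndarray, n_components: int = 2) -> pd.Series:
    """Leave-one-out cross-validated PLS-DA scores per sample.

    For each held-out sample the 2-component PLS regression on the 0/1 class
    response is refit on the remainder and the held-out predicted response is
    recorded as the sample's discriminant score.
    """
    n = x.shape[0]
    scores = np.empty(n)
    xv = x.to_numpy(float)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        k = min(n_components, xv.shape[1], mask.sum() - 1)
        model = PLSRegression(n_components=k, scale=True)
        model.fit(xv[mask], y[mask].astype(float))
        scores[i] = float(model.predict(xv[i : i + 1]).ravel()[0])
    return pd.Series(scores, index=x.index)


def plsda_roc(
    matrix: pd.DataFrame,
    labels: dict[str, str] | pd.Series,
    panel_sizes: list[int],
    ranking: list[str],
    positive: str = "case",
    n_components: int = 2,
) -> list[RocResult]:
    """Cross-validated PLS-DA ROC over nested panels of top-ranked features.

    ``matrix`` is sample x feature; ``ranking`` orders the candidate features
    (typically by decreasing |moderated t|).  For each panel size the top
    features are used, a leave-one-out PLS-DA is run, and AUC is computed
    from the held-out scores.
    """
    labels = pd.Series(labels).reindex(matrix.index)
    classes = labels.value_counts()
    if len(classes) != 2 or (classes < 2).any():
        raise ValueError("need two classes with >= 2 samples each")
    y = (labels == positive).to_numpy()
    results = []
    for size in panel_sizes:
        if size > len(ranking):
            raise ValueError(f"panel size {size} exceeds {len(ranking)} ranked features")
        feats = ranking[:size]
        scores = plsda_loo_scores(matrix[feats], y, n_components=n_components)
        auc = auc_mann_whitney(scores.to_numpy(), labels.to_numpy(), positive)
        results.append(RocResult(panel_size=size, auc=auc, scores=scores, features=feats))
    return results
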