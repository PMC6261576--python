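"""Unsupervised three-group stratification: k-means and Ward clustering.

Patients are clustered on the standardized 17-item symptom matrix (VAS
and covariates are excluded by default), the three clusters are relabeled
mild/moderate/severe by ascending mean severity score, and repeatability
is quantified by re-clustering with one random patient held out per run
and measuring pairwise label agreement on the shared patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .errors import ConfigurationError, ValidationError


@dataclass
class StandardizedMatrix:
    """Column-wise z-scored data with the means/SDs used, for inversion."""

    values: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    variables: tuple[str, ...]


@dataclass
class ClusteringResult:
    """Labels plus method-specific fit detail.

    ``labels`` take values 0/1/2; after :func:`order_clusters_by_severity`
    they follow the mild < moderate < severe convention.  k-means stores
    the centers and total within-cluster sum of squares (inertia); Ward
    stores the merge tree with per-merge semipartial R^2 and the
    cumulative R^2 of the k-cluster solution.
    """

    labels: np.ndarray
    method: str
    k: int
    inertia: float | None = None
    centers: np.ndarray | None = None
    merge_tree: np.ndarray | None = None  # linkage rows: id1, id2, height, size
    merge_r2_decrements: np.ndarray | None = None
    r2: float | None = None
    seed: int | None = None

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def standardize(matrix, variables=None) -> StandardizedMatrix:
    """Column-wise z-scores with the sample (n-1) standard deviation."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("need an n x p matrix with n >= 2")
    if np.isnan(X).any():
        raise ValidationError("matrix contains missing values; filter complete cases first")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if variables is None:
        variables = tuple(f"x{j}" for j in range(X.shape[1]))
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValidationError(f"zero-variance column {variables[zero[0]]!r}")
    return StandardizedMatrix((X - means) / sds, means, sds, tuple(variables))


def _as_values(matrix) -> np.ndarray:
    return matrix.values if isinstance(matrix, StandardizedMatrix) else np.asarray(matrix, float)


def kmeans_cluster(matrix, k: int = 3, seed: int = 0, n_init: int = 10) -> ClusteringResult:
    """Lloyd k-means from ``n_init`` seeded starts, keeping the best inertia."""
    X = _as_values(matrix)
    if k > X.shape[0]:
        raise ConfigurationError(f"k={k} exceeds n={X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd", max_iter=300)
    labels = km.fit_predict(X)
    return ClusteringResult(
        labels=labels.astype(int),
        method="kmeans",
        k=k,
        inertia=float(km.inertia_),
        centers=km.cluster_centers_,
        seed=seed,
    )


def ward_cluster(matrix, k: int = 3) -> ClusteringResult:
    """Agglomerative clustering under Ward's minimum-variance criterion.

    Cutting the Ward tree at ``k`` clusters yields the labels.  Each
    merge's semipartial R^2 (the fraction of total variance absorbed into
    within-cluster scatter by that merge, ``h^2/2 / TSS`` for Ward merge
    height ``h``) is recorded, and the cumulative R^2 of the k-cluster
    solution (between-cluster over total sum of squares) is reported.
    """
    X = _as_values(matrix)
    n = X.shape[0]
    if n < 2:
        raise ConfigurationError("need at least 2 observations")
    if k > n:
        raise ConfigurationError(f"k={k} exceeds n={n}")
    Z = hierarchy.linkage(X, method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    delta_ess = Z[:, 2] ** 2 / 2.0  # Ward height h: merge cost = h^2/2
    r2_decrements = delta_ess / tss if tss > 0 else np.zeros(n - 1)
    # merges performed down to k clusters are the first n-k rows
    within = float(delta_ess[: n - k].sum())
    r2 = 1.0 - within / tss if tss > 0 else 1.0
    return ClusteringResult(
        labels=labels.astype(int),
        method="ahc",
        k=int(k),
        inertia=within,
        merge_tree=Z,
        merge_r2_decrements=r2_decrements,
        r2=r2,
    )


def order_clusters_by_severity(result: ClusteringResult, reference_scores) -> ClusteringResult:
    """Relabel clusters 0/1/2 by ascending mean reference score.

    Ties on the mean are broken by cluster size descending (the larger
    cluster takes the lower severity), then by original cluster index.
    """
    scores = np.asarray(reference_scores, dtype=float)
    labels = result.labels
    if scores.shape[0] != labels.shape[0]:
        raise ConfigurationError("reference_scores must align with labels")
    ids = np.unique(labels)
    if len(ids) != result.k:
        raise ConfigurationError(
            f"expected {result.k} non-empty clusters, found {len(ids)}"
        )
    keys = []
    for c in ids:
        mask = labels == c
        keys.append((scores[mask].mean(), -int(mask.sum()), int(c)))
    order = [c for _, c in sorted(zip(keys, ids))]
    remap = {old: new for new, old in enumerate(order)}
    new_labels = np.array([remap[c] for c in labels], dtype=int)
    centers = result.centers[order] if result.centers is not None else None
    return ClusteringResult(
        labels=new_labels,
        method=result.method,
        k=result.k,
        inertia=result.inertia,
        centers=centers,
        merge_tree=result.merge_tree,
        merge_r2_decrements=result.merge_r2_decrements,
        r2=result.r2,
        seed=result.seed,
    )


def cluster_cohort(matrix, method: str, k: int = 3, seed: int = 0, reference_scores=None):
    """Cluster and severity-order in one call. ``method`` is kmeans|ahc."""
    if method == "kmeans":
        result = kmeans_cluster(matrix, k=k, seed=seed)
    elif method == "ahc":
        result = ward_cluster(matrix, k=k)
    else:
        raise ConfigurationError(f"unknown clustering method {method!r}")
    if reference_scores is None:
        reference_scores = _as_values(matrix).sum(axis=1)
    return order_clusters_by_severity(result, reference_scores)


def pairwise_agreement(label_runs: list[np.ndarray], kept_indices: list[np.ndarray]) -> float:
    """Mean fraction of identically-labeled patients over all run pairs.

    ``label_runs[r]`` holds severity-ordered labels for the patients whose
    original indices are ``kept_indices[r]``; agreement for a pair is
    computed on the intersection of the two kept sets.
    """
    m = len(label_runs)
    if m < 2:
        raise ConfigurationError("need at least 2 runs")
    fracs = []
    for a in range(m):
        pos_a = {idx: j for j, idx in enumerate(kept_indices[a])}
        for b in range(a + 1, m):
            shared = [idx for idx in kept_indices[b] if idx in pos_a]
            if not shared:
                raise ConfigurationError("runs share no patients")
            pos_b = {idx: j for j, idx in enumerate(kept_indices[b])}
            la = label_runs[a][[pos_a[i] for i in shared]]
            lb = label_runs[b][[pos_b[i] for i in shared]]
            fracs.append(float((la == lb).mean()))
    return float(np.mean(fracs))


def repeatability(
    matrix, method: str, n_runs: int = 10, seed: int = 0, reference_scores=None
) -> float:
    """Hold-one-patient-out re-clustering stability, as a percentage.

    Each of ``n_runs`` runs drops one randomly chosen patient (k-means
    additionally gets a fresh seed per run), clusters the rest, orders the
    clusters by severity, and the mean pairwise label agreement over
    shared patients is returned on the 0-100 scale.
    """
    if n_runs < 2:
        raise ConfigurationError("n_runs must be >= 2")
    X = _as_values(matrix)
    n = X.shape[0]
    if reference_scores is None:
        reference_scores = X.sum(axis=1)
    reference_scores = np.asarray(reference_scores, dtype=float)
    rng = np.random.default_rng(seed)
    runs, kept_sets = [], []
    for r in range(n_runs):
        drop = int(rng.integers(n))
        keep = np.delete(np.arange(n), drop)
        result = cluster_cohort(
            X[keep],
            method,
            seed=int(rng.integers(2**31 - 1)),
            reference_scores=reference_scores[keep],
        )
        runs.append(result.labels)
        kept_sets.append(keep)
    return 100.0 * pairwise_agreement(runs, kept_sets)
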