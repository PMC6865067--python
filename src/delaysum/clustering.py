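"""Functional clustering of glutamate-release kinetics.

Temporal features of modulating-flash responses are extracted with a sparse
PCA (cardinality-constrained truncated power iteration, one component at a
time with deflation), a Gaussian mixture model is fitted over a range of
cluster counts with restarts, and the mixture order is selected by the
Bayesian information criterion BIC = -2 ln L + k ln n. Cluster similarity is
summarised by hierarchical linkage, either on five kinetic features or on
1 - Pearson correlation of mean traces (the blocker-condition analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from sklearn.mixture import GaussianMixture

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "Dendrogram",
    "spca_features",
    "fit_gmm_bic",
    "hierarchical_similarity",
    "correlation_linkage",
    "hungarian_match",
    "SIMILARITY_FEATURES",
]

#: the five per-cluster features used for kinetic similarity analysis
SIMILARITY_FEATURES = (
    "peak_latency",
    "response_decay",
    "frequency_sensitivity",
    "contrast_sensitivity",
    "stimulus_correlation",
)


@dataclass
class FeatureMatrix:
    """Sparse-PCA scores (rows = ROIs) with loadings and explained variance."""

    scores: np.ndarray
    loading_matrix: np.ndarray  # (n_features, n_components)
    explained_variance: np.ndarray
    sparsity: int | None

    @property
    def n_components(self) -> int:
        return self.loading_matrix.shape[1]


def spca_features(
    response_matrix: np.ndarray,
    n_components: int = 20,
    sparsity: int | None = 10,
    seed: int = 0,
    n_iter: int = 200,
    tol: float = 1e-8,
) -> FeatureMatrix:
    """Cardinality-constrained sparse PCA by truncated power iteration.

    Each loading vector is restricted to at most ``sparsity`` non-zero
    entries (``None`` removes the constraint, recovering ordinary PCA up to
    sign); components are extracted one at a time with deflation.
    Deterministic given ``seed``.
    """
    X = np.asarray(response_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("response matrix must be 2-D (ROIs x time points)")
    n, d = X.shape
    if n_components >= min(n, d):
        raise ValueError("n_components must be < min(n_rois, n_timepoints)")
    Xc = X - X.mean(axis=0)
    total_var = float((Xc**2).sum())
    R = Xc.copy()
    rng = np.random.default_rng(seed)
    loadings = np.zeros((d, n_components))
    expl = np.zeros(n_components)
    for c in range(n_components):
        v = rng.normal(size=d)
        v /= np.linalg.norm(v)
        for _ in range(n_iter):
            w = R.T @ (R @ v)
            if sparsity is not None and sparsity < d:
                keep = np.argsort(np.abs(w))[-sparsity:]
                mask = np.zeros(d, dtype=bool)
                mask[keep] = True
                w = np.where(mask, w, 0.0)
            nrm = np.linalg.norm(w)
            if nrm == 0:
                break
            w /= nrm
            if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
                v = w
                break
            v = w
        loadings[:, c] = v
        s = R @ v
        expl[c] = float(s @ s)
        R = R - np.outer(s, v)
    scores = Xc @ loadings
    return FeatureMatrix(
        scores=scores,
        loading_matrix=loadings,
        explained_variance=expl / total_var if total_var > 0 else expl,
        sparsity=sparsity,
    )


@dataclass
class ClusterModel:
    """A fitted Gaussian mixture with its BIC model-selection curve."""

    K: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    labels: np.ndarray
    bic_by_k: dict[int, float]
    log_likelihood: float
    n_params: int
    n_samples: int
    covariance_type: str = "diag"
    meta: dict = field(default_factory=dict)


def bic_score(log_likelihood: float, n_params: int, n_samples: int) -> float:
    """BIC = -2 ln L + k ln n (L already on the log scale)."""
    return -2.0 * log_likelihood + n_params * np.log(n_samples)


def fit_gmm_bic(
    features: np.ndarray | FeatureMatrix,
    k_range=range(2, 13),
    n_restarts: int = 10,
    seed: int = 0,
    covariance_type: str = "diag",
) -> ClusterModel:
    """EM fit of Gaussian mixtures over ``k_range``; best-of-restarts per K,
    chosen K minimises the BIC. The full BIC curve is returned."""
    X = features.scores if isinstance(features, FeatureMatrix) else np.asarray(features)
    n = X.shape[0]
    bic_by_k: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for K in k_range:
        try:
            gm = GaussianMixture(
                n_components=K,
                covariance_type=covariance_type,
                n_init=n_restarts,
                random_state=seed,
                reg_covar=1e-6,
                max_iter=200,
            ).fit(X)
        except ValueError:
            bic_by_k[K] = np.inf
            continue
        ll = float(gm.score(X) * n)
        bic_by_k[K] = bic_score(ll, gm._n_parameters(), n)
        fits[K] = gm
    if not fits:
        raise RuntimeError("every mixture order failed to fit")
    best_k = min(fits, key=lambda K: bic_by_k[K])
    gm = fits[best_k]
    ll = float(gm.score(X) * n)
    return ClusterModel(
        K=best_k,
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        labels=gm.predict(X),
        bic_by_k=bic_by_k,
        log_likelihood=ll,
        n_params=int(gm._n_parameters()),
        n_samples=n,
        covariance_type=covariance_type,
        meta={"n_restarts": n_restarts, "seed": seed},
    )


@dataclass
class Dendrogram:
    """A hierarchical-linkage tree over named clusters."""

    linkage: np.ndarray
    labels: list[str]
    method: str
    metric: str

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic_distance(self, a: str, b: str) -> float:
        d = hierarchy.cophenet(self.linkage)
        i, j = self.labels.index(a), self.labels.index(b)
        n = len(self.labels)
        if i > j:
            i, j = j, i
        # condensed index
        idx = n * i - i * (i + 1) // 2 + (j - i - 1)
        return float(d[idx])

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


def hierarchical_similarity(
    cluster_feature_table,
    method: str = "ward",
) -> Dendrogram:
    """Linkage over clusters on the five z-scored kinetic features.

    ``cluster_feature_table`` is a DataFrame (rows = clusters, columns = the
    five features) or an equivalent (labels, matrix) pair.
    """
    try:
        import pandas as pd

        if isinstance(cluster_feature_table, pd.DataFrame):
            labels = [str(i) for i in cluster_feature_table.index]
            M = cluster_feature_table.to_numpy(dtype=float)
        else:
            raise TypeError
    except TypeError:
        labels, M = cluster_feature_table
        labels = [str(x) for x in labels]
        M = np.asarray(M, dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 clusters")
    sd = M.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = hierarchy.linkage((M - M.mean(axis=0)) / sd, method=method)
    return Dendrogram(Z, labels, method, "euclidean-zscored")


def correlation_linkage(
    mean_traces_by_cluster: dict[str, np.ndarray],
    method: str = "average",
) -> Dendrogram:
    """Linkage on 1 - Pearson correlation between cluster mean traces."""
    labels = list(mean_traces_by_cluster)
    traces = [np.asarray(mean_traces_by_cluster[k], dtype=float) for k in labels]
    n = len(traces)
    if n < 2:
        raise ValueError("need at least 2 clusters")
    lens = {t.size for t in traces}
    if len(lens) != 1:
        raise ValueError("traces must share a common time base")
    for k, t in zip(labels, traces):
        if np.std(t) == 0:
            raise ValueError(f"constant trace for cluster {k!r}: correlation undefined")
    Z = np.stack(traces)
    Zc = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, keepdims=True)
    corr = (Zc @ Zc.T) / Z.shape[1]
    dist = 1.0 - corr
    cond = dist[np.triu_indices(n, k=1)]
    cond = np.clip(cond, 0.0, None)
    link = hierarchy.linkage(cond, method=method)
    return Dendrogram(link, labels, method, "1-pearson")


def hungarian_match(labels: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Relabel ``labels`` to best match ``truth`` (maximum-overlap assignment).

    Returns the permuted label array; cluster identities beyond the truth's
    range are left unmatched.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    lu, tu = np.unique(labels), np.unique(truth)
    cost = np.zeros((lu.size, tu.size))
    for i, a in enumerate(lu):
        for j, b in enumerate(tu):
            cost[i, j] = -np.sum((labels == a) & (truth == b))
    ri, ci = linear_sum_assignment(cost)
    mapping = {lu[i]: tu[j] for i, j in zip(ri, ci)}
    fallback = iter([x for x in range(labels.max() + tu.size + 2)
                     if x not in mapping.values()])
    return np.array([mapping.get(x, -1) if x in mapping else next(fallback)
                     for x in labels])
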