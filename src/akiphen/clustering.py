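"""Phenotype clustering in attribution space.

The AKI-restricted Shapley matrix is embedded into two dimensions with UMAP
(Euclidean metric, min_dist 0.1, 15 neighbors) and clustered with DBSCAN
(eps 1 in embedding units, min_pts 5).  Cluster separability is validated by
one-vs-rest linear SVMs tuned by repeated cross-validation on an 80% split and scored
on bootstrap resamples of the held-out 20%.  Clusters are profiled by their mean
attributions, and each cluster's defining risk factor is the feature whose
cluster-mean attribution deviates most from the overall mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NOISE = -1


@dataclass
class EmbeddingConfig:
    metric: str = "euclidean"
    min_dist: float = 0.1
    n_neighbors: int = 15
    n_components: int = 2
    seed: int = 0

    def validate(self):
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.min_dist <= 0:
            raise ValueError("min_dist must be positive")


@dataclass
class ClusterConfig:
    eps: float = 1.0
    min_pts: int = 5

    def validate(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


def embed(matrix, config: EmbeddingConfig | None = None) -> np.ndarray:
    """2-D UMAP embedding of the attribution matrix (deterministic given seed)."""
    config = config or EmbeddingConfig()
    config.validate()
    X = matrix.to_numpy(dtype=float) if hasattr(matrix, "to_numpy") else np.asarray(matrix, float)
    if len(X) < config.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {config.n_neighbors + 1} rows, got {len(X)}")
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=config.n_components, metric=config.metric,
            min_dist=config.min_dist, n_neighbors=config.n_neighbors,
            random_state=config.seed,
        )
        return np.asarray(reducer.fit_transform(X), dtype=float)


def dbscan(points, config: ClusterConfig | None = None) -> np.ndarray:
    """DBSCAN with deterministic semantics.

    A point is core iff at least ``min_pts`` points (itself included) lie within
    ``eps``; clusters are the connected components of core points under
    eps-reachability, numbered by the lowest point index they contain; border points
    join the cluster of the lowest-index core point within ``eps``; everything else is
    labelled ``NOISE`` (-1).
    """
    config = config or ClusterConfig()
    config.validate()
    P = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(P)):
        raise ValueError("points must be finite")
    n = len(P)
    d2 = np.sum((P[:, None, :] - P[None, :, :]) ** 2, axis=-1)
    within = d2 <= config.eps**2
    core = within.sum(axis=1) >= config.min_pts

    labels = np.full(n, NOISE, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        # BFS over core points reachable from i
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(within[j]):
                if core[k] and labels[k] == NOISE:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    # border points: attach to the lowest-index core neighbor's cluster
    for i in range(n):
        if labels[i] != NOISE or core[i]:
            continue
        neighbors = np.flatnonzero(within[i] & core)
        if len(neighbors):
            labels[i] = labels[neighbors[0]]
    return labels


@dataclass
class SvmValidationReport:
    per_cluster: dict      # cluster -> dict(cost, auc_mean, auc_sd, auc_boot)
    split: float
    cv_scheme: tuple
    n_boot: int


def svm_validate(points, labels, split: float = 0.8, cv=(3, 10), n_boot: int = 2000,
                 seed: int = 0, cost_grid=None) -> SvmValidationReport:
    """One-vs-rest linear-SVM separability check per cluster.

    The embedding is split 80:20 (stratified); the SVM cost parameter is tuned on the
    training split by repeated CV (3 repeats x 10 folds) maximizing AUC over a
    log-spaced grid; the tuned model is scored on ``n_boot`` bootstrap resamples of
    the held-out split.  Noise points are excluded.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
    from sklearn.svm import SVC

    P = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    keep = labels != NOISE
    P, labels = P[keep], labels[keep]
    clusters = sorted(np.unique(labels).tolist())
    if len(clusters) < 2:
        raise ValueError("need >= 2 non-noise clusters")
    if cost_grid is None:
        cost_grid = np.logspace(-2, 3, 6)

    def make_svm(cost):
        # bounded iterations keep the solver from stalling on non-separable
        # label assignments at large cost values
        return SVC(kernel="linear", C=cost, max_iter=200_000)

    idx_train, idx_test = train_test_split(
        np.arange(len(labels)), train_size=split, stratify=labels, random_state=seed)
    report = {}
    rng = np.random.default_rng(seed)
    for c in clusters:
        y = (labels == c).astype(int)
        y_tr, y_te = y[idx_train], y[idx_test]
        if y_tr.sum() in (0, len(y_tr)) or y_te.sum() in (0, len(y_te)):
            raise ValueError(f"cluster {c} absent from a split after stratification")
        X_tr, X_te = P[idx_train], P[idx_test]
        n_splits = min(cv[1], max(2, int(min(y_tr.sum(), len(y_tr) - y_tr.sum()))))
        kf = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=cv[0],
                                     random_state=seed)
        best_cost, best_auc = cost_grid[0], -np.inf
        for cost in cost_grid:
            aucs = []
            for tr, te in kf.split(X_tr, y_tr):
                if len(np.unique(y_tr[tr])) < 2 or len(np.unique(y_tr[te])) < 2:
                    continue
                m = make_svm(cost).fit(X_tr[tr], y_tr[tr])
                aucs.append(roc_auc_score(y_tr[te], m.decision_function(X_tr[te])))
            mean = np.mean(aucs) if aucs else -np.inf
            if mean > best_auc:
                best_auc, best_cost = mean, cost
        final = make_svm(best_cost).fit(X_tr, y_tr)
        scores = final.decision_function(X_te)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            while True:
                take = rng.integers(0, len(y_te), len(y_te))
                if 0 < y_te[take].sum() < len(take):
                    break
            boot[b] = roc_auc_score(y_te[take], scores[take])
        report[c] = {
            "cost": float(best_cost),
            "auc_mean": float(boot.mean()),
            "auc_sd": float(boot.std(ddof=0)),
            "auc_boot": boot,
        }
    return SvmValidationReport(per_cluster=report, split=split, cv_scheme=tuple(cv),
                               n_boot=n_boot)


@dataclass
class ClusterProfile:
    mean_phi: pd.DataFrame           # clusters x features
    mean_abs_phi: pd.DataFrame
    defining_factor: dict            # cluster -> feature
    ranked_factors: dict             # cluster -> features by |deviation from overall mean|
    discriminativeness: pd.Series    # per feature: across-cluster variance of mean phi


def cluster_profiles(shap_values: pd.DataFrame, labels) -> ClusterProfile:
    """Per-cluster attribution summaries and each cluster's defining risk factor."""
    labels = np.asarray(labels)
    clusters = sorted(c for c in np.unique(labels) if c != NOISE)
    if not clusters:
        raise ValueError("no non-noise clusters")
    for c in clusters:
        if (labels == c).sum() == 0:
            raise ValueError(f"empty cluster {c}")
    overall = shap_values.mean()
    mean_phi = pd.DataFrame(
        {c: shap_values[labels == c].mean() for c in clusters}).T
    mean_abs = pd.DataFrame(
        {c: shap_values[labels == c].abs().mean() for c in clusters}).T
    defining, ranked = {}, {}
    single = len(clusters) == 1
    for c in clusters:
        dev = (mean_phi.loc[c].abs() if single
               else (mean_phi.loc[c] - overall).abs())
        order = dev.sort_values(ascending=False, kind="stable").index.tolist()
        ranked[c] = order
        defining[c] = order[0]
    disc = mean_phi.var(axis=0, ddof=0)
    return ClusterProfile(mean_phi=mean_phi, mean_abs_phi=mean_abs,
                          defining_factor=defining, ranked_factors=ranked,
                          discriminativeness=disc)
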