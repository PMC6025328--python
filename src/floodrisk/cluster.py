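"""Fuzzy c-means clustering of ilr coordinates and cluster profiling.

Fuzzy c-means (FCM) assigns each site a graded membership to every
cluster instead of a hard label, minimizing

    J_m = sum_i sum_k  u_ik^m * ||z_i - v_k||^2,   sum_k u_ik = 1,

by alternating the closed-form membership and prototype updates. The
fuzzifier ``m > 1`` controls how soft the partition is (memberships tend
to 1/c as ``m`` grows). Clustering runs on ilr coordinates, where
Euclidean geometry matches the Aitchison geometry of the contribution
compositions, and is invariant to the particular orthonormal basis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import silhouette_score

from . import coda

__all__ = [
    "FuzzyCMeans",
    "fcm",
    "partition_coefficient",
    "choose_cluster_count",
    "cluster_profiles",
]


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means with k-means++ seeding and size-ordered labels.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : ndarray (c, d) prototypes
    membership_ : ndarray (n, c), rows sum to 1
    labels_ : ndarray (n,), argmax memberships
    objective_trace_ : list of per-iteration values of J_m (non-increasing)
    n_iter_ : int
    """

    def __init__(self, n_clusters=3, m=2.0, tol=1e-6, max_iter=300, random_state=0):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _memberships(self, Z, centers):
        d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        exact = d2 <= 1e-30
        expo = 1.0 / (self.m - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo)
            U = inv / inv.sum(axis=1, keepdims=True)
        hits = exact.any(axis=1)
        if hits.any():
            # a point sitting on a prototype gets an indicator membership
            U[hits] = exact[hits] / exact[hits].sum(axis=1, keepdims=True)
        return U, d2

    def fit(self, Z, y=None):
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        n, d = Z.shape
        c = int(self.n_clusters)
        if not 2 <= c < n:
            raise ValueError("need 2 <= n_clusters < n_samples")
        if self.m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        centers, _ = kmeans_plusplus(Z, c, random_state=self.random_state)
        trace = []
        for it in range(self.max_iter):
            U, d2 = self._memberships(Z, centers)
            Um = U**self.m
            new_centers = (Um.T @ Z) / Um.sum(axis=0)[:, None]
            trace.append(float((Um * d2).sum()))
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < self.tol:
                break
        U, d2 = self._memberships(Z, centers)
        trace.append(float((U**self.m * d2).sum()))

        # canonical order: descending (hard) cluster size, ties by first index
        hard = U.argmax(axis=1)
        sizes = np.bincount(hard, minlength=c)
        order = np.argsort(-sizes, kind="stable")
        self.cluster_centers_ = centers[order]
        self.membership_ = U[:, order]
        self.labels_ = self.membership_.argmax(axis=1)
        self.objective_trace_ = trace
        self.n_iter_ = it + 1
        self.n_features_in_ = d
        return self

    def predict(self, Z):
        return self.predict_proba(Z).argmax(axis=1)

    def predict_proba(self, Z):
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        U, _ = self._memberships(Z, self.cluster_centers_)
        return U


def fcm(Z, c: int, m: float = 2.0, tol: float = 1e-6, max_iter: int = 300,
        seed: int = 0) -> FuzzyCMeans:
    """Fit :class:`FuzzyCMeans` on an ilr coordinate matrix."""
    return FuzzyCMeans(n_clusters=c, m=m, tol=tol, max_iter=max_iter,
                       random_state=seed).fit(Z)


def partition_coefficient(U) -> float:
    """Bezdek's fuzzy partition coefficient, (1/n)·ΣΣ u²; 1 = crisp."""
    U = np.asarray(U, dtype=float)
    return float((U**2).sum() / U.shape[0])


def choose_cluster_count(Z, c_range, m: float = 2.0, seed: int = 0) -> pd.DataFrame:
    """Score candidate cluster counts; the caller decides.

    Reports the fuzzy partition coefficient and the average silhouette of
    the hard labels for each candidate ``c``, flagging the best count per
    criterion. The two criteria are reported side by side and may
    disagree; no automatic choice is made.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    rows = []
    for c in sorted(set(int(c) for c in c_range)):
        if not 2 <= c < Z.shape[0]:
            raise ValueError(f"cluster count {c} out of range")
        model = fcm(Z, c, m=m, seed=seed)
        sil = (
            silhouette_score(Z, model.labels_)
            if len(np.unique(model.labels_)) > 1
            else np.nan
        )
        rows.append(
            {
                "c": c,
                "partition_coefficient": partition_coefficient(model.membership_),
                "silhouette": sil,
            }
        )
    table = pd.DataFrame(rows).set_index("c")
    table["best_partition_coefficient"] = (
        table.index == table["partition_coefficient"].idxmax()
    )
    table["best_silhouette"] = (
        table.index == table["silhouette"].idxmax()
        if table["silhouette"].notna().any()
        else False
    )
    return table


def cluster_profiles(
    X_centered, U, labels=None, hard: bool = False, enrich_threshold=None
) -> pd.DataFrame:
    """Per-cluster compositional profile on centred data.

    Each cluster's profile is the closed geometric mean of its member
    compositions — membership-weighted by default, or over hard members
    only. On centred data the neutral value is 1/D, so parts above
    ``1/D`` are flagged as enriched in that cluster relative to the
    overall centre.
    """
    X = np.atleast_2d(np.asarray(X_centered, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    n, D = X.shape
    if U.shape[0] != n:
        raise ValueError("membership rows must match compositions")
    c = U.shape[1]
    if labels is None:
        labels = [f"part_{i}" for i in range(D)]
    if enrich_threshold is None:
        enrich_threshold = 1.0 / D
    logx = np.log(X)
    if hard:
        hard_lab = U.argmax(axis=1)
        W = np.eye(c)[hard_lab]
    else:
        W = U
    weights = W.sum(axis=0)
    if np.any(weights <= 0):
        raise ValueError("empty cluster")
    profiles = coda.closure(np.exp((W.T @ logx) / weights[:, None]))
    # strict exceedance with a float guard so a flat profile is not flagged
    enrich_cut = enrich_threshold + 1e-12
    frames = []
    for k in range(c):
        frames.append(
            pd.DataFrame(
                {
                    "cluster": k,
                    "part": list(labels),
                    "relative_weight": profiles[k],
                    "enriched": profiles[k] > enrich_cut,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
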