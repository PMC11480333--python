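"""Fuzzy c-means clustering of temporal phosphorylation profiles.

Fuzzy c-means (Bezdek's alternating minimization) assigns each standardized
stage profile a soft membership in each of ``c`` clusters, minimizing

    J(U, C) = sum_i sum_j u_ij^m ||x_i - c_j||^2,   sum_j u_ij = 1,

with the fuzzifier ``m > 1`` controlling softness (m -> 1 approaches hard
k-means).  The alternating updates are the classical closed forms: centers
are membership-weighted means, memberships are inverse-distance ratios

    u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)).

A profile coincident with a center receives membership 1 there.  Each half
step cannot increase J, so the objective path is non-increasing; the loop
stops when the largest membership change drops below ``tol``.

:class:`FuzzyCMeans` follows the scikit-learn estimator protocol (``fit`` /
``predict``, ``get_params``/``set_params``, trailing-underscore fitted
attributes) and so composes with sklearn model selection.  Memberships are
initialized from a seeded flat Dirichlet; because a single random start can
collapse two centers onto one group, ``n_init`` restarts are run and the
solution with the lowest objective is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_array, check_random_state

__all__ = ["FuzzyCMeans", "ClusterModel", "fuzzy_cmeans"]

_ZERO_DIST = 1e-300  # guard before taking the negative power of squared distances


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering with soft memberships.

    Parameters
    ----------
    n_clusters : int, default 5
        Number of clusters ``c``.
    m : float, default 2.0
        Fuzzifier; must be > 1.
    tol : float, default 1e-6
        Convergence threshold on the max absolute membership change.
    max_iter : int, default 1000
        Iteration cap per restart.
    n_init : int, default 10
        Number of seeded random restarts; the best objective wins.
    random_state : int, RandomState or None
        Seed for the Dirichlet membership initializations.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    membership_ : ndarray of shape (n_samples, n_clusters)
        Rows sum to 1.
    labels_ : ndarray of shape (n_samples,)
        Hard assignment (argmax membership, ties to the lowest index).
    objective_ : float
        Final value of J for the best restart.
    objective_path_ : list of float
        Per-iteration J of the best restart (non-increasing).
    n_iter_ : int
    """

    def __init__(self, n_clusters=5, m=2.0, tol=1e-6, max_iter=1000, n_init=10, random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not self.m > 1:
            raise ValueError("fuzzifier m must be > 1")
        n_distinct = np.unique(X, axis=0).shape[0]
        if n_distinct < self.n_clusters:
            raise ValueError(
                f"need at least n_clusters={self.n_clusters} distinct profiles, got {n_distinct}"
            )
        rng = check_random_state(self.random_state)
        best = None
        for _ in range(max(1, int(self.n_init))):
            result = self._single_run(X, rng)
            if best is None or result["objective"] < best["objective"]:
                best = result
        self.cluster_centers_ = best["centers"]
        self.membership_ = best["membership"]
        self.labels_ = best["membership"].argmax(axis=1)
        self.objective_ = best["objective"]
        self.objective_path_ = best["path"]
        self.n_iter_ = best["n_iter"]
        self.n_features_in_ = X.shape[1]
        return self

    def _single_run(self, X, rng):
        n = X.shape[0]
        u = rng.dirichlet(np.ones(self.n_clusters), size=n)
        path: list[float] = []
        centers = self._update_centers(X, u)
        for iteration in range(1, self.max_iter + 1):
            u_new = self._memberships(X, centers)
            d2 = cdist(X, centers, metric="sqeuclidean")
            path.append(float(np.sum(u_new**self.m * d2)))
            delta = float(np.abs(u_new - u).max())
            u = u_new
            centers = self._update_centers(X, u)
            if delta < self.tol:
                break
        return {
            "centers": centers,
            "membership": u,
            "objective": path[-1],
            "path": path,
            "n_iter": iteration,
        }

    def _update_centers(self, X, u):
        w = u**self.m
        return (w.T @ X) / w.sum(axis=0)[:, None]

    def _memberships(self, X, centers):
        d2 = cdist(X, centers, metric="sqeuclidean")
        zero_rows = d2.min(axis=1) <= 0.0
        d2 = np.maximum(d2, _ZERO_DIST)
        inv = d2 ** (-1.0 / (self.m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        if zero_rows.any():
            # profile coincides with a center: full membership there
            for i in np.flatnonzero(zero_rows):
                j = int(np.argmin(d2[i]))
                u[i] = 0.0
                u[i, j] = 1.0
        return u

    def predict(self, X):
        X = check_array(X, dtype=np.float64)
        return self._memberships(X, self.cluster_centers_).argmax(axis=1)

    def predict_membership(self, X):
        X = check_array(X, dtype=np.float64)
        return self._memberships(X, self.cluster_centers_)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass(frozen=True)
class ClusterModel:
    """Fitted clustering of regulated-site profiles (tabular view).

    ``centers``: cluster x stage DataFrame; ``memberships``: site x cluster
    DataFrame whose rows sum to 1; ``hard_assignment``: site -> cluster label
    (argmax membership, ties to the lowest cluster index).
    """

    c: int
    m: float
    centers: pd.DataFrame
    memberships: pd.DataFrame
    hard_assignment: pd.Series
    objective: float
    objective_path: tuple[float, ...]
    iterations: int
    seed: int | None

    def __post_init__(self) -> None:
        sums = self.memberships.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1 within 1e-9")


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int = 5,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_init: int = 10,
    seed: int | None = None,
) -> ClusterModel:
    """Cluster a site x stage profile table; thin wrapper over :class:`FuzzyCMeans`."""
    est = FuzzyCMeans(
        n_clusters=c, m=m, tol=tol, max_iter=max_iter, n_init=n_init, random_state=seed
    ).fit(profiles.to_numpy(dtype=float))
    cluster_labels = [f"C{j + 1}" for j in range(c)]
    return ClusterModel(
        c=c,
        m=m,
        centers=pd.DataFrame(est.cluster_centers_, index=cluster_labels, columns=profiles.columns),
        memberships=pd.DataFrame(est.membership_, index=profiles.index, columns=cluster_labels),
        hard_assignment=pd.Series(
            [cluster_labels[j] for j in est.labels_], index=profiles.index, name="cluster"
        ),
        objective=est.objective_,
        objective_path=tuple(est.objective_path_),
        iterations=est.n_iter_,
        seed=seed,
    )
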