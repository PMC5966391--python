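"""Fuzzy c-means clustering of expression trajectories.

Features are clustered on their standardized per-stage profiles (replicate
means of log2(CPM+1) across the ordered differentiation stages, row
z-scored), so that clusters capture the *shape* of the dynamic response —
monotone up, late up, late down, early down, transient up — rather than its
level. :class:`FuzzyCMeans` is an sklearn-style estimator; the module-level
functions are thin wrappers matching the rest of the pipeline.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "ProfileMatrix",
    "FuzzyModel",
    "FuzzyCMeans",
    "stage_means",
    "standardize_profiles",
    "fuzzy_cmeans",
    "select_cluster_number",
    "assign_clusters",
]

ProfileMatrix = pd.DataFrame  # features x stages, row mean 0 / sd 1


@dataclass
class FuzzyModel:
    """Fitted fuzzy partition: centroids, soft memberships, objective trace."""

    c: int
    m: float
    centroids: pd.DataFrame  # c x stages
    membership: pd.DataFrame  # features x c, rows sum to 1
    objective_trace: list[float]


def stage_means(
    log_matrix: pd.DataFrame, design: pd.DataFrame, stages: list[str] | None = None
) -> pd.DataFrame:
    """Per-population replicate means of a (log-scale) expression matrix."""
    pops = design.loc[log_matrix.columns, "population"]
    means = log_matrix.T.groupby(pops).mean().T
    if stages is not None:
        means = means.loc[:, stages]
    return means


def standardize_profiles(stage_means: pd.DataFrame) -> ProfileMatrix:
    """Row z-score (sample s.d., ddof 1); constant rows dropped with warning."""
    if stage_means.shape[1] < 2:
        raise ValueError("need at least 2 stages to standardize")
    sd = stage_means.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant profiles")
    kept = stage_means.loc[~const]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[~const], axis=0)


def _row_hashes(X: np.ndarray) -> np.ndarray:
    """Stable content hash per row, for order-independent initialization."""
    out = np.empty(len(X), dtype=np.uint64)
    for i, row in enumerate(X):
        h = hashlib.blake2b(np.ascontiguousarray(row, dtype=np.float64).tobytes(),
                            digest_size=8).digest()
        out[i] = int.from_bytes(h, "little")
    return out


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means with Euclidean distance and fuzzifier ``m``.

    Parameters
    ----------
    n_clusters : number of clusters ``c``.
    m : fuzzifier (> 1); memberships harden as ``m -> 1``.
    tol : convergence threshold on the max membership change.
    max_iter : iteration cap.
    n_init : number of seeded restarts; the run with the lowest final
        objective is kept.
    random_state : seed for centroid initialization (a random choice of
        distinct data rows, drawn in content-hash order so that permuting
        the input rows permutes the fitted memberships identically).

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : (c, n_stages) centroid array.
    membership_ : (n_samples, c) membership matrix, rows summing to 1.
    objective_trace_ : per-iteration objective values (non-increasing).
    n_iter_ : iterations run.
    """

    def __init__(
        self,
        n_clusters: int = 5,
        m: float = 2.0,
        tol: float = 1e-6,
        max_iter: int = 500,
        n_init: int = 10,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
        u = np.empty((len(X), len(centers)))
        zero = d <= 0
        coincident = zero.any(axis=1)
        if coincident.any():
            u[coincident] = 0.0
            # membership 1 at the (first) coincident centroid
            first = np.argmax(zero[coincident], axis=1)
            u[np.flatnonzero(coincident), first] = 1.0
        reg = ~coincident
        if reg.any():
            power = 2.0 / (self.m - 1.0)
            ratio = (d[reg][:, :, None] / d[reg][:, None, :]) ** power
            u[reg] = 1.0 / ratio.sum(axis=2)
        return u

    def _objective(self, X, centers, u) -> float:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return float((u**self.m * d2).sum())

    def _init_centers(self, X: np.ndarray, seed: int | None) -> np.ndarray:
        order = np.argsort(_row_hashes(X), kind="stable")
        Xs = X[order]
        # prefer distinct row values so no two centroids coincide at start
        _, first_idx = np.unique(_row_hashes(Xs), return_index=True)
        pool = np.sort(first_idx)
        rng = np.random.default_rng(seed)
        if len(pool) >= self.n_clusters:
            pick = rng.choice(len(pool), size=self.n_clusters, replace=False)
            return Xs[pool[np.sort(pick)]].copy()
        pick = rng.choice(len(Xs), size=self.n_clusters, replace=False)
        return Xs[np.sort(pick)].copy()

    def _fit_single(self, X: np.ndarray, seed: int | None):
        centers = self._init_centers(X, seed)
        u = self._memberships(X, centers)
        trace = [self._objective(X, centers, u)]
        for it in range(1, self.max_iter + 1):
            w = u**self.m
            centers = (w.T @ X) / w.sum(axis=0)[:, None]
            u_new = self._memberships(X, centers)
            trace.append(self._objective(X, centers, u_new))
            delta = np.abs(u_new - u).max()
            u = u_new
            if delta < self.tol:
                break
        return centers, u, trace, it

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (profiles x stages)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > len(X):
            raise ValueError("more clusters than profiles")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        seed_rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(self.n_init, 1)):
            sub = int(seed_rng.integers(0, 2**31 - 1))
            result = self._fit_single(X, sub)
            if best is None or result[2][-1] < best[2][-1]:
                best = result
        self.cluster_centers_, self.membership_ = best[0], best[1]
        self.objective_trace_ = best[2]
        self.n_iter_ = best[3]
        return self

    def predict_membership(self, X) -> np.ndarray:
        return self._memberships(np.asarray(X, dtype=float), self.cluster_centers_)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_membership(X), axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def fuzzy_cmeans(
    profiles: ProfileMatrix,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    restarts: int = 10,
) -> FuzzyModel:
    """Fit fuzzy c-means to standardized profiles; see :class:`FuzzyCMeans`."""
    est = FuzzyCMeans(
        n_clusters=c, m=m, tol=tol, max_iter=max_iter, n_init=restarts,
        random_state=seed,
    ).fit(profiles.to_numpy(float))
    cols = [f"cluster{k + 1}" for k in range(c)]
    return FuzzyModel(
        c=c,
        m=m,
        centroids=pd.DataFrame(
            est.cluster_centers_, index=cols, columns=profiles.columns
        ),
        membership=pd.DataFrame(est.membership_, index=profiles.index, columns=cols),
        objective_trace=est.objective_trace_,
    )


def select_cluster_number(
    profiles: ProfileMatrix,
    c_range=range(2, 11),
    m: float = 2.0,
    seed: int = 0,
    restarts: int = 10,
    min_centroid_distance: float = 0.5,
) -> tuple[int, pd.DataFrame]:
    """Choose c as the largest value whose best-of-restarts model keeps all
    centroids at least ``min_centroid_distance`` apart (standardized units).

    Returns ``(chosen_c, diagnostics)``; diagnostics holds, per candidate c,
    the best final objective and the minimum pairwise centroid distance.
    """
    c_range = list(c_range)
    if not c_range:
        raise ValueError("empty cluster-number range")
    rng = np.random.default_rng(seed)
    rows = []
    for c in c_range:
        best = fuzzy_cmeans(
            profiles, c, m=m, seed=int(rng.integers(0, 2**31 - 1)),
            restarts=restarts,
        )
        C = best.centroids.to_numpy()
        if c < 2:
            mind = np.inf
        else:
            d = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=2)
            mind = float(d[np.triu_indices(c, k=1)].min())
        rows.append({"c": c, "objective": best.objective_trace[-1],
                     "min_centroid_distance": mind})
    table = pd.DataFrame(rows).set_index("c")
    ok = table.index[table["min_centroid_distance"] > min_centroid_distance]
    chosen = int(ok.max()) if len(ok) else int(table.index.min())
    return chosen, table


def assign_clusters(model: FuzzyModel, min_membership: float = 0.5) -> pd.Series:
    """Hard assignment: argmax membership if >= ``min_membership``, else
    ``"unassigned"``; ties go to the lowest cluster index."""
    u = model.membership.to_numpy()
    idx = np.argmax(u, axis=1)  # first max = lowest index on ties
    top = u[np.arange(len(u)), idx]
    labels = np.where(top >= min_membership, idx + 1, 0)
    out = pd.Series(
        [f"cluster{k}" if k else "unassigned" for k in labels],
        index=model.membership.index,
        name="cluster",
    )
    return out
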