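"""Recurrent connectome states and their dissociability.

Frames pooled over subjects are clustered with K-means into timescale-
specific group-level states.  How distinct the states are is quantified by
the *dissociability*: the Pearson correlation between the off-diagonal
entries of the frame-proximity matrix (pairwise Pearson similarity between
frames) and the ideal binary within-cluster indicator.  The empirical
dissociability is z-scored against surrogate datasets whose edge
timecourses are temporally phase-permuted per subject — a null that keeps
the static connectome but destroys the dynamic state structure.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .signals import EdgeFrameSeries
from .surrogates import temporal_phase_permute_edges

__all__ = [
    "pool_frames",
    "ConnectomeStates",
    "kmeans_states",
    "proximity_matrix",
    "dissociability",
    "dissociability_zscore",
]


def pool_frames(series_list: Sequence[EdgeFrameSeries]) -> tuple[np.ndarray, np.ndarray]:
    """Row-stack frames of several subjects; returns (frames, subject_index)."""
    if not series_list:
        raise ValueError("no series given")
    n_edges = {s.n_edges for s in series_list}
    if len(n_edges) != 1:
        raise ValueError("edge sets differ across subjects")
    frames = np.vstack([s.frames for s in series_list])
    subj = np.concatenate([np.full(s.n_frames, i) for i, s in enumerate(series_list)])
    return frames, subj


def proximity_matrix(frames: np.ndarray, labels: Optional[np.ndarray] = None) -> np.ndarray:
    """Pairwise Pearson similarity between frames, optionally label-sorted.

    With ``labels`` given, rows and columns are reordered by cluster label
    (stable within label), exposing the block structure of dissociable
    states.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if np.any(frames.std(axis=1) == 0):
        raise ValueError("zero-variance frame(s); cannot correlate")
    P = np.corrcoef(frames)
    if labels is not None:
        order = np.argsort(np.asarray(labels), kind="stable")
        P = P[np.ix_(order, order)]
    return P


def dissociability(proximity: np.ndarray, labels: np.ndarray) -> float:
    """Correlation of off-diagonal proximity with the within-cluster indicator.

    1 means perfectly block-structured proximity (complete dissociation);
    values near 0 mean the clustering does not organize frame similarity.
    Order of frames in ``proximity`` must match ``labels``.
    """
    P = np.asarray(proximity, dtype=float)
    labels = np.asarray(labels)
    n = labels.size
    if P.shape != (n, n):
        raise ValueError("proximity and labels sizes are inconsistent")
    if np.unique(labels).size < 2:
        warnings.warn("single cluster: dissociability undefined")
        return float("nan")
    off = ~np.eye(n, dtype=bool)
    indicator = labels[:, None] == labels[None, :]
    return float(np.corrcoef(P[off], indicator[off].astype(float))[0, 1])


class ConnectomeStates(BaseEstimator, ClusterMixin):
    """K-means connectome states with proximity-based dissociability.

    Parameters
    ----------
    n_states : int, default 5
        Number of states K (the replication value 7 is also standard).
    n_init : int, default 20
        K-means restarts; the best-inertia solution is kept.
    metric : {"euclidean", "correlation"}, default "euclidean"
        "correlation" row-standardizes frames before clustering, making
        Euclidean distance monotone in correlation distance.
    random_state : int, optional

    Attributes
    ----------
    cluster_centers_ : (K, E) centroids in the input edge space
    labels_ : per-frame state index in [0, K)
    proximity_ : (n, n) frame-similarity matrix (input order)
    dissociability_ : float
    """

    def __init__(self, n_states: int = 5, n_init: int = 20,
                 metric: str = "euclidean", random_state: Optional[int] = None):
        self.n_states = n_states
        self.n_init = n_init
        self.metric = metric
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected (n_frames, n_edges)")
        if self.n_states > X.shape[0]:
            raise ValueError("more states than frames")
        if self.metric == "correlation":
            sd = X.std(axis=1, keepdims=True)
            Xc = (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
        elif self.metric == "euclidean":
            Xc = X
        else:
            raise ValueError(f"unknown metric {self.metric!r}")
        km = KMeans(n_clusters=self.n_states, n_init=self.n_init,
                    random_state=self.random_state).fit(Xc)
        self.labels_ = km.labels_
        self.cluster_centers_ = np.vstack([
            X[self.labels_ == k].mean(axis=0) for k in range(self.n_states)
        ])
        self.inertia_ = km.inertia_
        if X.shape[0] >= 2 and not np.any(X.std(axis=1) == 0):
            self.proximity_ = proximity_matrix(X)
            self.dissociability_ = (dissociability(self.proximity_, self.labels_)
                                    if self.n_states > 1 else float("nan"))
        return self


def kmeans_states(frames: np.ndarray, n_states: int, seed: Optional[int] = None,
                  n_init: int = 20, metric: str = "euclidean") -> ConnectomeStates:
    """Cluster pooled frames into ``n_states`` recurrent connectome states."""
    frames = np.asarray(frames, dtype=float)
    if n_states > 1 and frames.shape[0] < 10 * n_states:
        warnings.warn(f"only {frames.shape[0]} frames for K={n_states}; "
                      "states may be unstable")
    return ConnectomeStates(n_states=n_states, n_init=n_init, metric=metric,
                            random_state=seed).fit(frames)


def dissociability_zscore(series_list: Sequence[EdgeFrameSeries], n_states: int,
                          n_surrogates: int = 50, seed: Optional[int] = None,
                          n_init: int = 20) -> tuple[float, float, np.ndarray]:
    """Real dissociability z-scored against temporally phase-permuted surrogates.

    Surrogates are built per subject (each edge timecourse phase-permuted,
    static FC preserved), re-pooled and re-clustered with fresh K-means seeds
    so the null includes clustering variability.

    Returns ``(z, real_dissociability, surrogate_values)``.
    """
    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogates")
    ss = np.random.SeedSequence(seed)
    km_seed, surr_seed = ss.spawn(2)
    frames, _ = pool_frames(series_list)
    real = kmeans_states(frames, n_states,
                         seed=np.random.default_rng(km_seed).integers(2**31),
                         n_init=n_init).dissociability_
    rng = np.random.default_rng(surr_seed)
    null = np.empty(n_surrogates)
    for s in range(n_surrogates):
        surr = [temporal_phase_permute_edges(x, rng) for x in series_list]
        sframes, _ = pool_frames(surr)
        null[s] = kmeans_states(sframes, n_states,
                                seed=int(rng.integers(2**31)),
                                n_init=n_init).dissociability_
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate: zero surrogate dissociability variance")
    return float((real - null.mean()) / sd), float(real), null
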