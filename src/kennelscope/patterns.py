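"""Unsupervised discovery of recurring behaviour patterns.

A recording is cut into fixed-length windows; each window is a temporal
sequence of symbols — either ground-plane coordinates (trajectory analysis)
or skeleton-graph descriptors (action analysis).  Pairs of windows are
compared with Needleman-Wunsch global alignment under a match/mismatch/gap
scheme (+2 for a perfect match, -1 for a full mismatch, 0 for a gap); the
zero gap score lets two renditions of the same behaviour at different
speeds align well.  The pairwise alignment scores feed a K-medoids
partition whose medoids are the most representative windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .skeleton import SkeletonGraph, build_skeleton_graph, \
    leading_eigenvectors

GAP = None  # gap sentinel for symbol_score


# ---------------------------------------------------------------------------
# symbol similarities

def traj_symbol_similarity(p, q, scale: float = 1.0) -> float:
    """Negative-exponential similarity of two ground positions.

    ``c_b = exp(-||p - q|| / scale)``; equals 1 for coincident points and
    decays with the Euclidean distance (metres).  ``scale`` defaults to 1 m,
    which separates within-pen movement patterns well.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("coordinates must be finite")
    return float(np.exp(-np.linalg.norm(p - q) / scale))


def action_symbol_similarity(ga: SkeletonGraph, gb: SkeletonGraph,
                             k: int = 3) -> float:
    """Spectral similarity of two skeleton graphs.

    Projects the leading ``k`` Laplacian eigenvectors of one graph onto the
    other's: with orthonormal bases Ba, Bb and M = Ba^T Bb, the similarity
    is sqrt(det(M^T M)) = |det M| — 1 when the spectral subspaces coincide,
    0 when they are orthogonal.
    """
    if tuple(ga.vertices) != tuple(gb.vertices):
        raise ValueError("graphs must share the same vertex labelling")
    ba = leading_eigenvectors(ga.L, k)
    bb = leading_eigenvectors(gb.L, k)
    m = ba.T @ bb
    cb = float(np.abs(np.linalg.det(m)))
    return float(np.clip(cb, 0.0, 1.0))


def symbol_score(c_b=GAP) -> float:
    """Alignment score of one symbol pair (or a symbol against a gap).

    Piecewise scheme: 2*c_b when c_b >= 0.5, 2*(c_b - 0.5) when c_b < 0.5,
    and 0 when either symbol is a gap — i.e. +2 for a perfect match, -1 for
    a complete mismatch, 0 for gaps.
    """
    if c_b is GAP:
        return 0.0
    c_b = float(c_b)
    if not 0.0 <= c_b <= 1.0:
        raise ValueError(f"similarity {c_b} outside [0, 1]")
    if c_b >= 0.5:
        return 2.0 * c_b
    return 2.0 * (c_b - 0.5)


GAP_SCORE = symbol_score(GAP)


# ---------------------------------------------------------------------------
# sequence windows

@dataclass
class SequenceWindow:
    """A fixed-length temporal window of behaviour symbols.

    ``symbols`` is either an (n, 2) array of ground coordinates or a list
    of SkeletonGraph descriptors, depending on the analysis feature.
    """

    id: int
    start_s: float
    end_s: float
    symbols: object
    source: str = ""
    feature: str = "trajectory"   # trajectory | action

    def __len__(self):
        return len(self.symbols)


def _similarity_matrix_of_pair(wa: SequenceWindow, wb: SequenceWindow,
                               scale: float = 1.0, k: int = 3) -> np.ndarray:
    if wa.feature != wb.feature:
        raise ValueError("cannot align windows of different feature types")
    if wa.feature == "trajectory":
        a = np.asarray(wa.symbols, dtype=float)
        b = np.asarray(wb.symbols, dtype=float)
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        return np.exp(-d / scale)
    sims = np.empty((len(wa), len(wb)))
    ea = [leading_eigenvectors(g.L, k) for g in wa.symbols]
    eb = [leading_eigenvectors(g.L, k) for g in wb.symbols]
    for i, ba in enumerate(ea):
        for j, bb in enumerate(eb):
            m = ba.T @ bb
            sims[i, j] = np.clip(abs(np.linalg.det(m)), 0.0, 1.0)
    return sims


@dataclass
class AlignmentResult:
    """Outcome of one global alignment: score, DP table and matched pairs."""

    score: float
    table: np.ndarray            # (n+1, m+1) cumulative score table
    pairs: list                  # (i, j) matches; gaps carry None on one side


def nw_align(wa: SequenceWindow, wb: SequenceWindow, scale: float = 1.0,
             k: int = 3) -> AlignmentResult:
    """Needleman-Wunsch global alignment of two windows.

    Fills the cumulative score table (gap score 0 along the first row and
    column), takes the three-way maximum per cell, and returns the
    bottom-right optimal score plus one traceback path (tie order:
    diagonal > up > left).
    """
    if len(wa) == 0 or len(wb) == 0:
        return AlignmentResult(score=0.0,
                               table=np.zeros((len(wa) + 1, len(wb) + 1)),
                               pairs=[])
    sims = _similarity_matrix_of_pair(wa, wb, scale=scale, k=k)
    omega = np.where(sims >= 0.5, 2.0 * sims, 2.0 * (sims - 0.5))
    n, m = omega.shape
    V = np.zeros((n + 1, m + 1))
    V[1:, 0] = np.cumsum(np.full(n, GAP_SCORE))
    V[0, 1:] = np.cumsum(np.full(m, GAP_SCORE))
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 diag, 2 up, 3 left
    for i in range(1, n + 1):
        diag = V[i - 1, :-1] + omega[i - 1]
        up = V[i - 1, 1:] + GAP_SCORE
        for j in range(1, m + 1):
            left = V[i, j - 1] + GAP_SCORE
            best = diag[j - 1]
            mv = 1
            if up[j - 1] > best:
                best, mv = up[j - 1], 2
            if left > best:
                best, mv = left, 3
            V[i, j] = best
            move[i, j] = mv
    pairs = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and move[i, j] == 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and (j == 0 or move[i, j] == 2):
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    return AlignmentResult(score=float(V[n, m]), table=V, pairs=pairs)


def pairwise_similarity_matrix(windows, scale: float = 1.0,
                               k: int = 3) -> np.ndarray:
    """Symmetric matrix of pairwise alignment scores over windows."""
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    n = len(windows)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = nw_align(windows[i], windows[j], scale=scale, k=k).score
            sim[i, j] = sim[j, i] = s
    return sim


# ---------------------------------------------------------------------------
# clustering

def similarity_to_distance(sim: np.ndarray) -> np.ndarray:
    """Monotone-decreasing transform of alignment scores to distances."""
    sim = np.asarray(sim, dtype=float)
    return sim.max() - sim


class KMedoids(BaseEstimator, ClusterMixin):
    """PAM-style K-medoids over a precomputed distance matrix.

    Medoids are initialised as ``n_clusters`` distinct items drawn by a
    seeded RNG, then improved by greedy swaps until no swap lowers the sum
    of within-cluster distances to the medoid.

    Attributes: ``labels_``, ``medoid_indices_``, ``inertia_`` and
    ``objective_trace_`` (non-increasing across swap iterations).
    """

    def __init__(self, n_clusters: int = 4, max_iter: int = 100,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        D = np.asarray(X, dtype=float)
        n = len(D)
        if D.shape != (n, n):
            raise ValueError("X must be a square distance matrix")
        if not 1 <= self.n_clusters <= n:
            raise ValueError(f"n_clusters must be in [1, {n}]")
        rng = np.random.default_rng(self.random_state)
        medoids = list(rng.choice(n, size=self.n_clusters, replace=False))

        def objective(meds):
            return float(D[:, meds].min(axis=1).sum())

        trace = [objective(medoids)]
        for _ in range(self.max_iter):
            best_delta, best_swap = 0.0, None
            current = trace[-1]
            in_medoids = set(medoids)
            for mi, m in enumerate(medoids):
                for cand in range(n):
                    if cand in in_medoids:
                        continue
                    trial = medoids.copy()
                    trial[mi] = cand
                    delta = objective(trial) - current
                    if delta < best_delta - 1e-12:
                        best_delta, best_swap = delta, (mi, cand)
            if best_swap is None:
                break
            medoids[best_swap[0]] = best_swap[1]
            trace.append(current + best_delta)
        self.medoid_indices_ = np.array(sorted(medoids))
        self.labels_ = np.argmin(D[:, self.medoid_indices_], axis=1)
        # a medoid always belongs to its own cluster
        for ci, m in enumerate(self.medoid_indices_):
            self.labels_[m] = ci
        self.inertia_ = objective(list(self.medoid_indices_))
        self.objective_trace_ = trace
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ClusterResult:
    """K-medoids partition of sequence windows with medoid-distance ordering."""

    assignment: np.ndarray        # window -> cluster id
    medoids: np.ndarray           # one window index per cluster
    distances: np.ndarray         # distance of each window to its medoid
    similarity: np.ndarray        # the underlying alignment score matrix
    windows: list = field(default=None)

    def ordering(self, cluster: int) -> np.ndarray:
        """Window indices of one cluster, closest to the medoid first.

        The medoid itself leads the list even when other members tie its
        (zero-ish) distance, e.g. for duplicated windows.
        """
        members = np.nonzero(self.assignment == cluster)[0]
        medoid = self.medoids[cluster]
        keys = np.stack([self.distances[members],
                         (members != medoid).astype(float)])
        return members[np.lexsort(keys)]

    def manifest(self) -> pd.DataFrame:
        rows = []
        for c in range(len(self.medoids)):
            for w in self.ordering(c):
                win = self.windows[w] if self.windows else None
                rows.append({"window_id": int(w),
                             "start_s": win.start_s if win else np.nan,
                             "end_s": win.end_s if win else np.nan,
                             "cluster": int(c),
                             "distance_to_medoid": float(self.distances[w]),
                             "is_medoid": bool(w == self.medoids[c])})
        return pd.DataFrame(rows, columns=["window_id", "start_s", "end_s",
                                           "cluster", "distance_to_medoid",
                                           "is_medoid"])


def kmedoids_cluster(similarity: np.ndarray, n_clusters: int, seed: int = 0,
                     windows=None) -> ClusterResult:
    """Partition windows from their alignment-score matrix."""
    D = similarity_to_distance(similarity)
    km = KMedoids(n_clusters=n_clusters, random_state=seed).fit(D)
    dist = D[np.arange(len(D)), km.medoid_indices_[km.labels_]]
    return ClusterResult(assignment=km.labels_,
                         medoids=km.medoid_indices_,
                         distances=dist, similarity=np.asarray(similarity),
                         windows=windows)


def cluster_windows(windows, n_clusters: int, seed: int = 0,
                    scale: float = 1.0, k: int = 3) -> ClusterResult:
    """End-to-end: alignment similarity matrix + K-medoids partition."""
    sim = pairwise_similarity_matrix(windows, scale=scale, k=k)
    return kmedoids_cluster(sim, n_clusters, seed=seed, windows=windows)


# ---------------------------------------------------------------------------
# windowing

def partition_video(annotations: pd.DataFrame, window_s: float = 5.0,
                    feature: str = "trajectory", skeletons=None,
                    fps: float = None, source: str = "") -> list:
    """Cut a recording into contiguous non-overlapping windows.

    ``annotations`` needs columns time_s, x_m, y_m (the per-frame ground
    positions).  For ``feature='action'`` a parallel list of per-frame
    Skeletons (or SkeletonGraphs) supplies the symbols — action analysis
    describes the skeleton's movement only, deliberately ignoring where in
    the pen it happens.  A trailing remainder shorter than half a window is
    dropped, but a clip shorter than one window still yields one window.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if feature not in ("trajectory", "action"):
        raise ValueError(f"unknown feature {feature!r}")
    times = np.asarray(annotations["time_s"], dtype=float)
    n = len(times)
    if n == 0:
        return []
    if fps is None:
        fps = 1.0 / np.median(np.diff(times)) if n > 1 else 1.0
    per = max(int(round(window_s * fps)), 1)
    n_full = n // per
    rem = n - n_full * per
    starts = [i * per for i in range(n_full)]
    sizes = [per] * n_full
    if rem >= 0.5 * per or n_full == 0:
        starts.append(n_full * per)
        sizes.append(rem)
    windows = []
    if feature == "action":
        if skeletons is None or len(skeletons) != n:
            raise ValueError("action windows need one skeleton per frame")
        graphs = [s if isinstance(s, SkeletonGraph)
                  else build_skeleton_graph(s) for s in skeletons]
    coords = np.stack([np.asarray(annotations["x_m"], dtype=float),
                       np.asarray(annotations["y_m"], dtype=float)], axis=-1)
    for wid, (s0, size) in enumerate(zip(starts, sizes)):
        sl = slice(s0, s0 + size)
        symbols = coords[sl] if feature == "trajectory" else graphs[sl]
        windows.append(SequenceWindow(id=wid, start_s=float(times[s0]),
                                      end_s=float(times[s0 + size - 1])
                                      + 1.0 / fps,
                                      symbols=symbols, source=source,
                                      feature=feature))
    return windows
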