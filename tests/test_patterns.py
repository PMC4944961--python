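"""Alignment scoring, NW tables, similarity matrices and K-medoids."""

import numpy as np
import pytest

from conftest import random_skeleton
from kennelscope import patterns as pat
from kennelscope import synthetic as syn
from kennelscope.skeleton import build_skeleton_graph


def traj_window(coords, wid=0):
    return pat.SequenceWindow(id=wid, start_s=0.0,
                              end_s=len(coords) / 10.0,
                              symbols=np.asarray(coords, dtype=float))


def action_window(graphs, wid=0):
    return pat.SequenceWindow(id=wid, start_s=0.0, end_s=len(graphs) / 10.0,
                              symbols=list(graphs), feature="action")


def brute_force_alignment_score(sims):
    """Enumerate every global alignment of the similarity matrix ``sims``.

    Independent recursive oracle (no DP table); exponential, so only for
    tiny sequences.
    """
    n, m = sims.shape
    omega = np.where(sims >= 0.5, 2.0 * sims, 2.0 * (sims - 0.5))

    def best(i, j):
        if i == n and j == m:
            return 0.0
        options = []
        if i < n and j < m:
            options.append(omega[i, j] + best(i + 1, j + 1))
        if i < n:
            options.append(0.0 + best(i + 1, j))
        if j < m:
            options.append(0.0 + best(i, j + 1))
        return max(options)

    return best(0, 0)


class TestTrajSimilarity:
    def test_identical_points(self):
        assert pat.traj_symbol_similarity((1.0, 2.0), (1.0, 2.0)) == 1.0

    def test_one_metre_apart(self):
        c = pat.traj_symbol_similarity((0.0, 0.0), (1.0, 0.0))
        assert c == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_monotone_decreasing_in_distance(self):
        dists = np.linspace(0, 3, 30)
        sims = [pat.traj_symbol_similarity((0, 0), (d, 0)) for d in dists]
        assert np.all(np.diff(sims) < 0)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            pat.traj_symbol_similarity((np.nan, 0), (0, 0))


class TestActionSimilarity:
    def test_identical_graph_scores_one(self, rng):
        g = build_skeleton_graph(random_skeleton(rng))
        assert pat.action_symbol_similarity(g, g) == pytest.approx(1.0,
                                                                   abs=1e-9)

    def test_symmetric(self, rng):
        ga = build_skeleton_graph(random_skeleton(rng))
        gb = build_skeleton_graph(random_skeleton(rng))
        ab = pat.action_symbol_similarity(ga, gb)
        ba = pat.action_symbol_similarity(gb, ga)
        assert ab == pytest.approx(ba, abs=1e-10)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            ga = build_skeleton_graph(random_skeleton(rng))
            gb = build_skeleton_graph(random_skeleton(rng))
            c = pat.action_symbol_similarity(ga, gb)
            assert 0.0 <= c <= 1.0

    def test_vertex_mismatch_raises(self, rng):
        ga = build_skeleton_graph(random_skeleton(rng))
        gb = pat.SkeletonGraph(vertices=("a", "b"),
                               W=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            pat.action_symbol_similarity(ga, gb)


class TestSymbolScore:
    @pytest.mark.parametrize("cb,expected", [
        (1.0, 2.0),       # perfect match
        (0.0, -1.0),      # complete mismatch
        (0.5, 1.0),       # branch boundary
        (0.75, 1.5),
        (0.25, -0.5),
    ])
    def test_piecewise_scheme(self, cb, expected):
        assert pat.symbol_score(cb) == pytest.approx(expected)

    def test_gap_scores_zero(self):
        assert pat.symbol_score(pat.GAP) == 0.0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            pat.symbol_score(1.2)


class TestNWAlign:
    def test_self_alignment_scores_two_per_symbol(self):
        w = traj_window(np.tile([1.0, 1.0], (7, 1)))
        r = pat.nw_align(w, w)
        assert r.score == pytest.approx(2.0 * 7)
        assert r.table[0, 0] == 0.0

    def test_empty_window_scores_zero(self):
        w = traj_window(np.empty((0, 2)))
        v = traj_window(np.zeros((4, 2)))
        assert pat.nw_align(w, v).score == 0.0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            na, nb = rng.integers(1, 7, size=2)
            a = traj_window(rng.uniform(0, 3, size=(na, 2)))
            b = traj_window(rng.uniform(0, 3, size=(nb, 2)))
            sims = pat._similarity_matrix_of_pair(a, b)
            assert pat.nw_align(a, b).score == pytest.approx(
                brute_force_alignment_score(sims), abs=1e-9)

    def test_table_cells_obey_recursion(self, rng):
        a = traj_window(rng.uniform(0, 3, size=(5, 2)))
        b = traj_window(rng.uniform(0, 3, size=(6, 2)))
        r = pat.nw_align(a, b)
        sims = pat._similarity_matrix_of_pair(a, b)
        omega = np.where(sims >= 0.5, 2 * sims, 2 * (sims - 0.5))
        V = r.table
        for i in range(1, 6):
            for j in range(1, 7):
                expect = max(V[i - 1, j - 1] + omega[i - 1, j - 1],
                             V[i - 1, j], V[i, j - 1])
                assert V[i, j] == pytest.approx(expect)

    def test_speed_change_is_weakly_penalised(self):
        """Same path at 1x vs 2x sampling outscores a different pattern."""
        t = np.linspace(0, 2 * np.pi, 40)
        circle = np.stack([1.5 + 0.8 * np.cos(t), 1.5 + 0.8 * np.sin(t)],
                          axis=-1)
        slow = traj_window(circle)
        fast = traj_window(circle[::2])          # same circle, double speed
        line = np.stack([np.linspace(0.3, 2.7, 20), np.full(20, 0.5)],
                        axis=-1)
        other = traj_window(line)
        s_speed = pat.nw_align(slow, fast).score
        s_other = pat.nw_align(slow, other).score
        assert s_speed > s_other

    def test_inserted_dwell_does_not_reduce_score(self, rng):
        coords = rng.uniform(0, 3, size=(8, 2))
        base = traj_window(coords)
        # insert one second of dwell in the middle
        dwell = np.tile(coords[4], (10, 1))
        padded = traj_window(np.concatenate([coords[:4], dwell, coords[4:]]))
        s_base = pat.nw_align(base, base).score
        s_padded = pat.nw_align(base, padded).score
        assert s_padded >= s_base - 1e-9

    def test_rigidly_rotated_skeleton_sequences_align_like_self(self, rng):
        """Rotation invariance of the whole action-similarity pipeline."""
        skels = [random_skeleton(rng) for _ in range(5)]
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        from kennelscope.skeleton import Skeleton
        rotated = [Skeleton(segments={k: v @ R.T
                                      for k, v in s.segments.items()},
                            posture=s.posture) for s in skels]
        wa = action_window([build_skeleton_graph(s) for s in skels])
        wb = action_window([build_skeleton_graph(s) for s in rotated])
        self_score = pat.nw_align(wa, wa).score
        cross_score = pat.nw_align(wa, wb).score
        assert cross_score == pytest.approx(self_score, abs=1e-6)
        assert cross_score == pytest.approx(2.0 * 5, abs=1e-6)


class TestSimilarityMatrix:
    def test_symmetric_and_sized(self, rng):
        ws = [traj_window(rng.uniform(0, 3, size=(6, 2)), wid=i)
              for i in range(4)]
        S = pat.pairwise_similarity_matrix(ws)
        assert S.shape == (4, 4)
        assert np.allclose(S, S.T, atol=1e-9)

    def test_two_windows_give_two_by_two(self, rng):
        ws = [traj_window(rng.uniform(0, 3, size=(5, 2)), wid=i)
              for i in range(2)]
        assert pat.pairwise_similarity_matrix(ws).shape == (2, 2)

    def test_self_alignment_attains_row_maximum(self, rng):
        ws = [traj_window(rng.uniform(0, 3, size=(6, 2)), wid=i)
              for i in range(5)]
        S = pat.pairwise_similarity_matrix(ws)
        assert np.all(np.diag(S) >= S.max(axis=1) - 1e-9)


class TestKMedoids:
    def test_each_window_its_own_medoid_when_k_equals_n(self, rng):
        ws = [traj_window(rng.uniform(0, 3, size=(5, 2)), wid=i)
              for i in range(5)]
        S = pat.pairwise_similarity_matrix(ws)
        res = pat.kmedoids_cluster(S, n_clusters=5, seed=0)
        assert sorted(res.medoids) == list(range(5))
        assert len(set(res.assignment)) == 5

    def test_objective_trace_non_increasing(self, rng):
        D = rng.uniform(0, 1, size=(12, 12))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        km = pat.KMedoids(n_clusters=3, random_state=1).fit(D)
        assert np.all(np.diff(km.objective_trace_) <= 1e-12)

    def test_medoid_belongs_to_own_cluster(self, rng):
        D = rng.uniform(0, 1, size=(10, 10))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        km = pat.KMedoids(n_clusters=3, random_state=0).fit(D)
        for c, m in enumerate(km.medoid_indices_):
            assert km.labels_[m] == c

    def test_invalid_cluster_count_raises(self):
        with pytest.raises(ValueError):
            pat.KMedoids(n_clusters=5).fit(np.zeros((3, 3)))

    def test_planted_patterns_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        coords, labels = syn.planted_pattern_windows(seed=3)
        ws = [traj_window(c, wid=i) for i, c in enumerate(coords)]
        res = pat.cluster_windows(ws, n_clusters=4, seed=3)
        assert adjusted_rand_score(labels, res.assignment) == 1.0

    def test_ordering_starts_at_medoid(self, rng):
        coords, _ = syn.planted_pattern_windows(seed=1)
        ws = [traj_window(c, wid=i) for i, c in enumerate(coords)]
        res = pat.cluster_windows(ws, n_clusters=4, seed=1)
        for c in range(4):
            order = res.ordering(c)
            assert order[0] == res.medoids[c]
        manifest = res.manifest()
        assert manifest["is_medoid"].sum() == 4


class TestPartitionVideo:
    def _annotations(self, n, fps=10.0):
        import pandas as pd
        t = np.arange(n) / fps
        return pd.DataFrame({"time_s": t, "x_m": np.linspace(0, 2, n),
                             "y_m": np.full(n, 1.0)})

    def test_fifty_seconds_gives_ten_windows(self):
        windows = pat.partition_video(self._annotations(500), window_s=5.0)
        assert len(windows) == 10
        assert all(len(w) == 50 for w in windows)

    def test_short_remainder_dropped(self):
        windows = pat.partition_video(self._annotations(520), window_s=5.0)
        assert len(windows) == 10

    def test_long_remainder_kept_truncated(self):
        windows = pat.partition_video(self._annotations(530), window_s=5.0)
        assert len(windows) == 11
        assert len(windows[-1]) == 30

    def test_window_longer_than_video_gives_one(self):
        windows = pat.partition_video(self._annotations(20), window_s=60.0)
        assert len(windows) == 1

    def test_action_feature_builds_graphs(self, rng):
        skels = [random_skeleton(rng) for _ in range(20)]
        windows = pat.partition_video(self._annotations(20), window_s=1.0,
                                      feature="action", skeletons=skels)
        assert len(windows) == 2
        assert windows[0].feature == "action"
        assert isinstance(windows[0].symbols[0], pat.SkeletonGraph)
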