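"""Structured SVM: feature map, candidates, training, inference, postures."""

import numpy as np
import pytest

from conftest import SMALL_GRID, annotate
from kennelscope import depth_scene as ds
from kennelscope import ssvm
from kennelscope import synthetic as syn
from kennelscope.skeleton import LEG_NAMES, MotionVector


class TestJointFeatureMap:
    def test_deterministic(self, stand_items):
        feats, gt = stand_items[0]
        phi1 = ssvm.joint_feature_map(feats, gt)
        phi2 = ssvm.joint_feature_map(feats, gt)
        assert np.array_equal(phi1, phi2)
        assert phi1.shape == (ssvm.FEATURE_DIM,)

    def test_empty_blob_zero_appearance_motion_passthrough(self, stand_items):
        motion = MotionVector(dx=0.03, dy=-0.02)
        feats = ssvm.BlobFeatures.empty(motion)
        _, gt = stand_items[0]
        phi = ssvm.joint_feature_map(feats, gt, motion)
        # appearance (ribbon occupancy) entries are all zero
        i = 0
        assert np.allclose(phi[i:i + ssvm.N_APPEAR], 0.0)
        i += ssvm.BLOCK_TORSO
        for _ in range(6):
            assert np.allclose(phi[i:i + ssvm.N_APPEAR], 0.0)
            i += ssvm.BLOCK_PART
        assert np.allclose(phi[-2:], [0.03, -0.02])

    def test_norm_bounded_over_random_pairs(self, stand_items, rng):
        """phi stays finite and bounded across many random candidates."""
        feats, _ = stand_items[0]
        cand = ssvm.generate_candidates(feats, "stand", **SMALL_GRID)
        blocks = ssvm.compute_feature_blocks(cand)
        T, nH, nT, nG = cand.shape
        bound = np.sqrt(ssvm.FEATURE_DIM) * 3 + 1
        for _ in range(1000):
            idx = (rng.integers(T), rng.integers(nH), rng.integers(nT),
                   rng.integers(nG))
            phi = blocks.phi(*idx)
            assert np.all(np.isfinite(phi))
            assert np.linalg.norm(phi) < bound


class TestScore:
    def test_zero_weights_score_zero(self, stand_items):
        feats, gt = stand_items[0]
        phi = ssvm.joint_feature_map(feats, gt)
        assert ssvm.score(np.zeros_like(phi), phi) == 0.0

    def test_self_weights_give_squared_norm(self, stand_items):
        feats, gt = stand_items[0]
        phi = ssvm.joint_feature_map(feats, gt)
        assert ssvm.score(phi, phi) == pytest.approx(phi @ phi)
        assert ssvm.score(phi, phi) >= 0

    def test_linearity_in_weights(self, stand_items, rng):
        feats, gt = stand_items[0]
        phi = ssvm.joint_feature_map(feats, gt)
        w1 = rng.normal(size=phi.shape)
        w2 = rng.normal(size=phi.shape)
        lhs = ssvm.score(2.0 * w1 + 3.0 * w2, phi)
        rhs = 2.0 * ssvm.score(w1, phi) + 3.0 * ssvm.score(w2, phi)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            ssvm.score(np.zeros(3), np.zeros(4))


class TestCandidates:
    def test_count_is_product_of_grid_sizes(self, stand_items):
        feats, _ = stand_items[0]
        cand = ssvm.generate_candidates(feats, "stand", **SMALL_GRID)
        g = SMALL_GRID
        assert len(cand) == (g["n_torso_angles"] * g["n_torso_lengths"]
                             * g["n_head_angles"] * g["n_tail_angles"]
                             * g["n_leg_configs"])

    def test_lie_class_has_zero_length_legs(self, stand_items):
        feats, _ = stand_items[0]
        cand = ssvm.generate_candidates(feats, "lie", **SMALL_GRID)
        assert np.allclose(cand.leg_segs[..., 0, :], cand.leg_segs[..., 1, :])
        skel = cand.skeleton(0, 0, 0, 0)
        for name in LEG_NAMES:
            assert skel.part_length(name) == 0.0

    def test_sit_class_omits_hind_legs_only(self, stand_items):
        feats, _ = stand_items[0]
        cand = ssvm.generate_candidates(feats, "sit", **SMALL_GRID)
        skel = cand.skeleton(0, 0, 0, 0)
        assert skel.part_length("leg_bl") == 0.0
        assert skel.part_length("leg_fl") > 0.0

    def test_torso_midpoint_anchored_at_barycentre(self, stand_items):
        feats, _ = stand_items[0]
        cand = ssvm.generate_candidates(feats, "stand", **SMALL_GRID)
        mids = cand.torso_segs.mean(axis=1)
        assert np.allclose(mids, feats.barycentre, atol=1e-9)

    def test_stand_legs_point_below_torso(self, stand_items):
        feats, _ = stand_items[0]
        cand = ssvm.generate_candidates(feats, "stand", **SMALL_GRID)
        # leg tips are below their attachments (upright-plane y down)
        tips = cand.leg_segs[..., 1, 1]
        roots = cand.leg_segs[..., 0, 1]
        active = cand.leg_segs[..., 1, :] != cand.leg_segs[..., 0, :]
        mask = active.any(axis=-1)
        assert np.all(tips[mask] < roots[mask])


class TestTraining:
    def test_single_pair_memorisation(self, stand_items):
        feats, gt = stand_items[0]
        model = ssvm.StructuredBodyPartSVM(posture_class="stand",
                                           n_epochs=60, random_state=0,
                                           **SMALL_GRID)
        model.fit([feats], [gt])
        cand = model.candidates(feats)
        gt_idx = cand.ravel(*ssvm.snap_to_grid(cand, gt))
        _, _, idx = model.infer(feats)
        assert idx == gt_idx

    def test_training_loss_decreases_on_average(self, tiny_model):
        losses = tiny_model.training_loss_
        assert np.mean(losses[-3:]) < losses[0]

    def test_separable_two_pose_set_reaches_zero_error(self, stand_items):
        items = stand_items[:2]
        model = ssvm.StructuredBodyPartSVM(posture_class="stand",
                                           n_epochs=60, random_state=1,
                                           **SMALL_GRID)
        model.fit([f for f, _ in items], [g for _, g in items])
        for feats, gt in items:
            cand = model.candidates(feats)
            gt_idx = cand.ravel(*ssvm.snap_to_grid(cand, gt))
            assert model.infer(feats)[2] == gt_idx

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError):
            ssvm.StructuredBodyPartSVM().fit([], [])

    def test_train_wrapper_accepts_pairs(self, stand_items):
        pairs = [ssvm.TrainingPair(x=f, y=g) for f, g in stand_items[:2]]
        model = ssvm.train(pairs, posture_class="stand", n_epochs=2,
                           **SMALL_GRID)
        assert hasattr(model, "w_")


class TestInference:
    def test_matches_brute_force_oracle(self, tiny_model, stand_items):
        """Factorised argmax equals explicit enumeration on every frame."""
        for feats, _ in stand_items[:4]:
            cand = tiny_model.candidates(feats)
            blocks = ssvm.compute_feature_blocks(cand)
            _, score, idx = tiny_model.infer(feats)
            oracle_idx, oracle_score = ssvm.brute_force_argmax(
                tiny_model.w_, cand, blocks)
            assert idx == oracle_idx
            assert score == pytest.approx(oracle_score, abs=1e-9)

    def test_untrained_model_raises(self, stand_items):
        feats, _ = stand_items[0]
        with pytest.raises(RuntimeError):
            ssvm.StructuredBodyPartSVM().infer(feats)


class TestWeightPersistence:
    def test_round_trip(self, tiny_model, stand_items, tmp_path):
        path = tmp_path / "weights.txt"
        ssvm.save_weights(tiny_model, path)
        loaded = ssvm.load_weights(path, **SMALL_GRID)
        assert np.allclose(loaded.w_, tiny_model.w_)
        feats, _ = stand_items[0]
        assert loaded.infer(feats)[2] == tiny_model.infer(feats)[2]


@pytest.fixture(scope="module")
def posture_clf():
    items, labels = [], []
    for j, post in enumerate(("stand", "sit", "lie")):
        data = syn.posture_frames(post, 12, seed=40 + j,
                                  proportion_spread=0.2)
        for f, g in annotate(data):
            items.append((f, g))
            labels.append(post)
    clf = ssvm.PostureClassifier(n_epochs=4, random_state=0, **SMALL_GRID)
    return clf.fit(items, labels)


class TestPostureClassifier:
    def test_classifies_held_out_standing_frame(self, posture_clf):
        data = syn.posture_frames("stand", 4, seed=321)
        hits = sum(posture_clf.classify(f)[0] == "stand"
                   for f, _ in annotate(data))
        assert hits >= 3

    def test_no_detection_yields_unknown(self, posture_clf):
        label, skel, scores = posture_clf.classify(None)
        assert label == "unknown"
        assert skel.is_empty

    def test_tie_break_order_prefers_stand(self, posture_clf, stand_items):
        feats, _ = stand_items[0]
        raw = np.zeros(9)
        cal = posture_clf._calibrated_scores(raw)
        forced = np.full(3, cal.max())
        assert ssvm.PostureClassifier.CLASSES[int(np.argmax(forced))] == \
            "stand"

    def test_untrained_raises(self, stand_items):
        with pytest.raises(RuntimeError):
            ssvm.PostureClassifier().classify(stand_items[0][0])


class TestDeriveLocomotion:
    def _traj(self, xy, fps=10.0):
        xy = np.asarray(xy, dtype=float)
        return ds.Trajectory(t=np.arange(len(xy)) / fps, x=xy[:, 0],
                             y=xy[:, 1], fps=fps)

    def test_stationary_dog_never_locomotes(self):
        traj = self._traj(np.tile([1.5, 1.5], (20, 1)))
        labels = np.array(["stand"] * 20, dtype=object)
        out = ssvm.derive_locomotion(labels, traj)
        assert np.all(out == "stand")

    def test_scripted_walk_relabels_all_standing_frames(self):
        xy = np.stack([np.linspace(0, 1.0, 21), np.full(21, 1.0)], axis=-1)
        traj = self._traj(xy)  # 0.5 m/s
        labels = np.array(["stand"] * 21, dtype=object)
        out = ssvm.derive_locomotion(labels, traj, speed_threshold=0.1)
        assert np.all(out == "locomotion")

    def test_sit_lie_never_relabelled(self):
        xy = np.stack([np.linspace(0, 1.0, 21), np.full(21, 1.0)], axis=-1)
        traj = self._traj(xy)
        labels = np.array(["sit", "lie"] * 10 + ["sit"], dtype=object)
        out = ssvm.derive_locomotion(labels, traj, speed_threshold=0.1)
        assert np.array_equal(out, labels)

    def test_infinite_threshold_is_identity(self):
        xy = np.stack([np.linspace(0, 2.0, 21), np.full(21, 1.0)], axis=-1)
        traj = self._traj(xy)
        labels = np.array(["stand"] * 21, dtype=object)
        out = ssvm.derive_locomotion(labels, traj, speed_threshold=np.inf)
        assert np.array_equal(out, labels)

    def test_length_mismatch_raises(self):
        traj = self._traj(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            ssvm.derive_locomotion(["stand"] * 4, traj)
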