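"""Segmentation, homography and trajectory projection."""

import numpy as np
import pytest

from kennelscope import depth_scene as ds
from kennelscope import synthetic as syn
from kennelscope.geometry import CameraIntrinsics, Plane


def test_empty_pen_yields_no_detection():
    scene, camera = syn.make_scene()
    intr = syn.DEFAULT_INTRINSICS
    depth = syn._plane_depth_for((3.0, 3.0), intr, camera) * 1000.0
    frame = ds.DepthFrame(depth=depth, timestamp=0.0, index=0)
    assert ds.segment_frame(frame, scene, intr) is None


def test_blob_matches_rendered_ground_truth(stand_dataset):
    for i in range(len(stand_dataset)):
        frame = stand_dataset.video.frames[i]
        gt_mask = stand_dataset.masks[i]
        blob = ds.segment_frame(frame, stand_dataset.scene,
                                stand_dataset.video.intrinsics)
        assert blob is not None
        inter = np.sum(blob.mask & gt_mask)
        union = np.sum(blob.mask | gt_mask)
        assert inter / union >= 0.95
        # pixel count close to the renderer's ground truth
        assert abs(blob.mask.sum() - gt_mask.sum()) <= 0.1 * gt_mask.sum()


def test_segmentation_is_idempotent(stand_dataset):
    frame = stand_dataset.video.frames[0]
    intr = stand_dataset.video.intrinsics
    b1 = ds.segment_frame(frame, stand_dataset.scene, intr)
    b2 = ds.segment_frame(frame, stand_dataset.scene, intr)
    assert np.array_equal(b1.mask, b2.mask)


def test_foreground_excludes_points_near_planes(stand_dataset):
    """Brute-force check of the plane-distance rule on every blob point."""
    threshold = 0.05
    frame = stand_dataset.video.frames[0]
    intr = stand_dataset.video.intrinsics
    # hysteresis disabled: every point must clear the full threshold
    blob = ds.segment_frame(frame, stand_dataset.scene, intr,
                            threshold=threshold, weak_fraction=1.0)
    for plane in stand_dataset.scene.planes:
        assert np.all(np.abs(plane.signed_distance(blob.points)) > threshold)
    # default hysteresis: points clear the weak threshold and the blob
    # keeps a strong core beyond the full threshold
    blob = ds.segment_frame(frame, stand_dataset.scene, intr,
                            threshold=threshold)
    strong = np.ones(len(blob.points), dtype=bool)
    for plane in stand_dataset.scene.planes:
        dist = np.abs(plane.signed_distance(blob.points))
        assert np.all(dist > 0.4 * threshold)
        strong &= dist > threshold
    assert strong.any()


def test_frame_dimension_mismatch_raises(stand_dataset):
    frame = ds.DepthFrame(depth=np.ones((10, 10)), timestamp=0.0, index=0)
    with pytest.raises(ds.ConfigurationError):
        ds.segment_frame(frame, stand_dataset.scene,
                         stand_dataset.video.intrinsics)


class TestBarycentre:
    def test_mean_of_two_points(self):
        blob = ds.Blob(mask=np.ones((1, 2), dtype=bool),
                       points=np.array([[0.0, 0, 1], [2.0, 0, 1]]),
                       barycentre=np.array([1.0, 0, 1]))
        assert np.allclose(ds.compute_barycentre(blob), [1, 0, 1])

    def test_single_point_identity(self):
        p = np.array([[0.3, -0.2, 2.5]])
        blob = ds.Blob(mask=np.ones((1, 1), dtype=bool), points=p,
                       barycentre=p[0])
        assert np.allclose(ds.compute_barycentre(blob), p[0])

    def test_empty_blob_raises(self):
        blob = ds.Blob(mask=np.zeros((2, 2), dtype=bool),
                       points=np.empty((0, 3)), barycentre=np.zeros(3))
        with pytest.raises(ValueError):
            ds.compute_barycentre(blob)


class TestHomography:
    def test_matches_analytic_projection_on_floor_grid(self, walk_dataset):
        scene = walk_dataset.scene
        video = walk_dataset.video
        hom = ds.fit_ground_homography(scene, video)
        gx, gy = np.meshgrid(np.linspace(0.2, 2.8, 5),
                             np.linspace(0.2, 2.8, 5))
        ground = np.stack([gx.ravel(), gy.ravel()], axis=-1)
        img = video.intrinsics.project(scene.floor_point(ground))
        err = np.linalg.norm(hom.apply(img) - ground, axis=1)
        assert np.max(err) < 0.01

    def test_overhead_camera_gives_scaling_map(self):
        # identity-pose camera looking straight down a unit-square pen
        intr = CameraIntrinsics(fx=100, fy=100, cx=50, cy=50,
                                width=100, height=100)
        corners_img = np.array([[0, 0], [100, 0], [0, 100], [100, 100]],
                               dtype=float)
        corners_gnd = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        hom = ds.GroundHomography.from_points(corners_img, corners_gnd)
        m = hom.matrix / hom.matrix[2, 2]
        assert np.allclose(m, [[0.01, 0, 0], [0, 0.01, 0], [0, 0, 1]],
                           atol=1e-9)

    def test_duplicate_correspondence_raises(self):
        img = np.array([[0, 0], [0, 0], [1, 0], [1, 1]], dtype=float)
        gnd = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        with pytest.raises(ds.CalibrationError):
            ds.GroundHomography.from_points(img, gnd)

    def test_composed_with_inverse_is_identity(self, walk_dataset):
        hom = ds.fit_ground_homography(walk_dataset.scene,
                                       walk_dataset.video)
        corners = np.array([[0, 0], [3, 0], [0, 3], [3, 3]], dtype=float)
        img = hom.inverse().apply(corners)
        assert np.allclose(hom.apply(img), corners, atol=1e-6)


class TestTrajectory:
    def _trajectory(self, dataset):
        intr = dataset.video.intrinsics
        hom = ds.fit_ground_homography(dataset.scene, dataset.video)
        bary = []
        for frame in dataset.video.frames:
            blob = ds.segment_frame(frame, dataset.scene, intr)
            bary.append(blob.barycentre)
        return ds.project_trajectory(bary, hom, dataset.video.fps,
                                     dataset.scene, intr)

    def test_stationary_dog_stays_within_two_cm(self):
        script = syn.posture_script("stand", 2.0, (1.5, 1.5), heading=0.3)
        data = syn.render_sequence(syn.QuadrupedModel(), script, seed=2)
        traj = self._trajectory(data)
        centre = traj.xy.mean(axis=0)
        assert np.max(np.linalg.norm(traj.xy - centre, axis=1)) < 0.02

    def test_straight_walk_covers_scripted_distance(self):
        script = syn.posture_script("stand", 4.0, (1.5, 1.5), heading=0.0,
                                    speed=0.5)
        data = syn.render_sequence(syn.QuadrupedModel(), script, seed=3)
        traj = self._trajectory(data)
        walked = np.linalg.norm(traj.xy[-1] - traj.xy[0])
        scripted = np.linalg.norm(data.positions[-1] - data.positions[0])
        assert abs(walked - scripted) < 0.02

    def test_empty_input_gives_empty_trajectory(self, walk_dataset):
        hom = ds.fit_ground_homography(walk_dataset.scene,
                                       walk_dataset.video)
        traj = ds.project_trajectory([], hom, 10.0, walk_dataset.scene,
                                     walk_dataset.video.intrinsics)
        assert len(traj) == 0

    def test_out_of_pen_samples_are_clamped_and_flagged(self, walk_dataset):
        scene = walk_dataset.scene
        intr = walk_dataset.video.intrinsics
        hom = ds.fit_ground_homography(scene, walk_dataset.video)
        outside = scene.floor_point(np.array([[-0.5, 1.0]]))[0]
        traj = ds.project_trajectory([outside], hom, 10.0, scene, intr)
        assert traj.clamped[0]
        assert 0.0 <= traj.x[0] <= 3.0


def test_scene_requires_exactly_one_floor():
    wall = Plane(normal=(1, 0, 0), offset=0.0, kind="wall")
    with pytest.raises(ValueError):
        ds.SceneModel(planes=[wall], pen_bounds=(3, 3),
                      floor_origin=np.zeros(3),
                      floor_axes=np.eye(3)[:2])
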