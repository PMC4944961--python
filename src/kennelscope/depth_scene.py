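"""Scene modelling, foreground segmentation and ground-plane trajectories.

A recording shows a single animal inside a rectangular pen observed by a
side-mounted depth sensor.  The pen geometry is described by a small set of
planes (one floor, several walls) given in the sensor frame, together with a
metric coordinate frame on the floor.  Foreground extraction removes every
pixel that lies close to one of those planes; what remains, the largest
connected component, is the animal "blob".  Its barycentre, re-projected
through a ground-plane homography, yields the bird's-eye trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import ProjectiveTransform

from .geometry import CameraIntrinsics, Plane


class ConfigurationError(ValueError):
    """Frame geometry inconsistent with the scene calibration."""


class CalibrationError(ValueError):
    """Degenerate plane / correspondence configuration."""


@dataclass(frozen=True)
class DepthFrame:
    """A single depth map.

    ``depth`` holds millimetres as a 2D float array; 0 marks invalid pixels.
    """

    depth: np.ndarray
    timestamp: float
    index: int

    def __post_init__(self):
        d = np.asarray(self.depth)
        if d.ndim != 2:
            raise ValueError("depth must be a 2D grid")
        if np.any(d < 0):
            raise ValueError("depth values must be non-negative")


@dataclass
class DepthVideo:
    """An in-memory depth-video: frames plus acquisition metadata."""

    frames: list
    fps: float
    intrinsics: CameraIntrinsics

    def __len__(self):
        return len(self.frames)


@dataclass
class SceneModel:
    """Pen geometry in the sensor frame.

    ``floor_origin`` / ``floor_axes`` define the metric pen coordinate frame
    on the floor plane: ground coordinates of a 3D point are its projections
    onto the two (orthonormal, in-plane) axes.  ``pen_bounds`` is the
    (width, depth) of the pen rectangle in metres, with the origin at the pen
    corner nearest the sensor's left edge.
    """

    planes: list
    pen_bounds: tuple
    floor_origin: np.ndarray
    floor_axes: np.ndarray  # (2, 3)

    def __post_init__(self):
        floors = [p for p in self.planes if p.kind == "floor"]
        if len(floors) != 1:
            raise ValueError("scene must contain exactly one floor plane")
        w, h = self.pen_bounds
        if not (w > 0 and h > 0):
            raise ValueError("pen_bounds must have positive area")
        self.floor_origin = np.asarray(self.floor_origin, dtype=float)
        self.floor_axes = np.asarray(self.floor_axes, dtype=float)

    @property
    def floor(self) -> Plane:
        return next(p for p in self.planes if p.kind == "floor")

    def ground_coords(self, points: np.ndarray) -> np.ndarray:
        """Project sensor-frame points (N, 3) to pen floor coordinates (N, 2)."""
        rel = np.asarray(points, dtype=float) - self.floor_origin
        return rel @ self.floor_axes.T

    def floor_point(self, ground_xy: np.ndarray) -> np.ndarray:
        """Lift pen floor coordinates (N, 2) back to sensor-frame 3D points."""
        g = np.atleast_2d(np.asarray(ground_xy, dtype=float))
        return self.floor_origin + g @ self.floor_axes


@dataclass(frozen=True)
class Blob:
    """Foreground animal region: pixel mask, 3D point cloud and barycentre."""

    mask: np.ndarray          # (H, W) bool
    points: np.ndarray        # (N, 3) metres, sensor frame
    barycentre: np.ndarray    # (3,)


@dataclass
class Trajectory:
    """Ground-plane barycentre track sampled at the video frame rate."""

    t: np.ndarray          # seconds, strictly increasing
    x: np.ndarray          # metres, pen frame
    y: np.ndarray
    fps: float
    clamped: np.ndarray = field(default=None)  # bool flags, out-of-pen samples

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.clamped is None:
            self.clamped = np.zeros(self.t.shape, dtype=bool)
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self):
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        return np.stack([self.x, self.y], axis=-1)


class GroundHomography:
    """3x3 projective map from image (col, row) to pen floor (x, y) metres."""

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (3, 3) or abs(np.linalg.det(matrix)) < 1e-12:
            raise CalibrationError("homography matrix must be invertible 3x3")
        self.matrix = matrix

    def apply(self, image_xy: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(image_xy, dtype=float))
        hom = np.hstack([pts, np.ones((len(pts), 1))]) @ self.matrix.T
        return hom[:, :2] / hom[:, 2:3]

    def inverse(self) -> "GroundHomography":
        return GroundHomography(np.linalg.inv(self.matrix))

    @classmethod
    def from_points(cls, image_xy: np.ndarray,
                    ground_xy: np.ndarray) -> "GroundHomography":
        image_xy = np.asarray(image_xy, dtype=float)
        ground_xy = np.asarray(ground_xy, dtype=float)
        if len(image_xy) < 4:
            raise CalibrationError("need at least 4 correspondences")
        if len(np.unique(np.round(image_xy, 9), axis=0)) < 4:
            raise CalibrationError("duplicate correspondences are degenerate")
        if hasattr(ProjectiveTransform, "from_estimate"):
            tf = ProjectiveTransform.from_estimate(image_xy, ground_xy)
            if not tf:
                raise CalibrationError("homography estimation failed")
        else:  # scikit-image < 0.26
            tf = ProjectiveTransform()
            if not tf.estimate(image_xy, ground_xy):
                raise CalibrationError("homography estimation failed")
        matrix = tf.params
        if not np.all(np.isfinite(matrix)) or abs(np.linalg.det(matrix)) < 1e-12:
            raise CalibrationError("degenerate correspondence configuration")
        return cls(matrix)


def back_project_frame(frame: DepthFrame,
                       intrinsics: CameraIntrinsics) -> tuple:
    """Return (valid mask, 3D points for valid pixels) for one frame."""
    depth_m = np.asarray(frame.depth, dtype=float) / 1000.0
    valid = depth_m > 0
    rows, cols = np.nonzero(valid)
    points = intrinsics.back_project(cols, rows, depth_m[valid])
    return valid, points


def segment_frame(frame: DepthFrame, scene: SceneModel,
                  intrinsics: CameraIntrinsics, threshold: float = 0.05,
                  min_pixels: int = 200, bounds_margin: float = 0.15,
                  weak_fraction: float = 0.4):
    """Isolate the animal blob from one depth frame.

    A pixel is foreground when its back-projected 3D point lies farther
    than ``threshold`` metres from every scene plane and inside the pen
    bounds (expanded by ``bounds_margin``).  Segmentation is hysteresis
    style: pixels clearing only the weaker threshold
    (``weak_fraction * threshold``) are kept when 8-connected to the strong
    component, which preserves the feet where the legs approach the floor.
    The largest component is returned; ``None`` signals no-detection.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    h, w = np.asarray(frame.depth).shape
    if (h, w) != (intrinsics.height, intrinsics.width):
        raise ConfigurationError(
            f"frame {w}x{h} inconsistent with calibration "
            f"{intrinsics.width}x{intrinsics.height}")

    valid, points = back_project_frame(frame, intrinsics)
    if len(points) == 0:
        return None
    strong = np.ones(len(points), dtype=bool)
    weak = np.ones(len(points), dtype=bool)
    for plane in scene.planes:
        dist = np.abs(plane.signed_distance(points))
        strong &= dist > threshold
        weak &= dist > weak_fraction * threshold
    gxy = scene.ground_coords(points)
    bw, bh = scene.pen_bounds
    in_pen = ((gxy[:, 0] > -bounds_margin) & (gxy[:, 0] < bw + bounds_margin)
              & (gxy[:, 1] > -bounds_margin) & (gxy[:, 1] < bh + bounds_margin))
    strong &= in_pen
    weak &= in_pen

    structure = np.ones((3, 3), dtype=int)
    rows, cols = np.nonzero(valid)
    fg_weak = np.zeros((h, w), dtype=bool)
    fg_weak[rows, cols] = weak
    fg_strong = np.zeros((h, w), dtype=bool)
    fg_strong[rows, cols] = strong
    labels, n = ndimage.label(fg_weak, structure=structure)
    if n == 0:
        return None
    # keep only weak components anchored by strong pixels; pick the largest
    strong_counts = ndimage.sum_labels(fg_strong, labels,
                                       index=np.arange(1, n + 1))
    sizes = ndimage.sum_labels(fg_weak, labels, index=np.arange(1, n + 1))
    sizes = np.where(strong_counts > 0, sizes, 0)
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_pixels:
        return None
    mask = labels == best
    depth_m = np.asarray(frame.depth, dtype=float) / 1000.0
    rows, cols = np.nonzero(mask)
    pts = intrinsics.back_project(cols, rows, depth_m[mask])
    return Blob(mask=mask, points=pts, barycentre=pts.mean(axis=0))


def compute_barycentre(blob: Blob) -> np.ndarray:
    """Centre of mass of the blob's 3D point cloud."""
    if blob is None or len(blob.points) == 0:
        raise ValueError("cannot compute barycentre of an empty blob")
    return np.asarray(blob.points, dtype=float).mean(axis=0)


def fit_ground_homography(scene: SceneModel, video: DepthVideo,
                          grid_n: int = 8,
                          corner_tol: float = 0.01) -> GroundHomography:
    """Estimate the image -> pen-floor homography from the scene calibration.

    A grid of floor points spanning the pen is projected into the image with
    the video's intrinsics and a projective map is fit to the
    correspondences.  The pen corners must reproject within ``corner_tol``
    metres.
    """
    bw, bh = scene.pen_bounds
    gx, gy = np.meshgrid(np.linspace(0, bw, grid_n), np.linspace(0, bh, grid_n))
    ground = np.stack([gx.ravel(), gy.ravel()], axis=-1)
    floor3d = scene.floor_point(ground)
    if np.any(floor3d[:, 2] <= 1e-6):
        raise CalibrationError("floor points behind the sensor")
    image = video.intrinsics.project(floor3d)
    hom = GroundHomography.from_points(image, ground)
    corners = np.array([[0, 0], [bw, 0], [0, bh], [bw, bh]], dtype=float)
    corner_img = video.intrinsics.project(scene.floor_point(corners))
    err = np.linalg.norm(hom.apply(corner_img) - corners, axis=1)
    if np.max(err) > corner_tol:
        raise CalibrationError(
            f"corner reprojection error {np.max(err):.4f} m exceeds tolerance")
    return hom


def project_trajectory(barycentres, hom: GroundHomography, fps: float,
                       scene: SceneModel, intrinsics: CameraIntrinsics,
                       timestamps=None, body_radius: float = 0.07) -> Trajectory:
    """Re-project 3D barycentres onto the pen floor via the homography.

    The barycentre of the *visible* surface points sits in front of the
    true body centre (only the near surface is seen), so each barycentre is
    first pushed ``body_radius`` metres away from the sensor along its
    viewing ray — the default is the hemisphere-averaged offset of a
    medium-sized animal's torso — then dropped along the floor normal onto the floor plane (removing
    body-height parallax), projected into the image and mapped through the
    homography.  Samples outside the pen are clamped to the bounds and
    flagged.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    barycentres = np.asarray(barycentres, dtype=float).reshape(-1, 3)
    n = len(barycentres)
    if timestamps is None:
        timestamps = np.arange(n) / fps
    if n == 0:
        return Trajectory(t=np.empty(0), x=np.empty(0), y=np.empty(0), fps=fps)
    rays = barycentres / np.linalg.norm(barycentres, axis=1, keepdims=True)
    barycentres = barycentres + body_radius * rays
    floor = scene.floor
    height = floor.signed_distance(barycentres)
    feet = barycentres - height[:, None] * floor.normal
    ground = hom.apply(intrinsics.project(feet))
    bw, bh = scene.pen_bounds
    clamped_x = np.clip(ground[:, 0], 0.0, bw)
    clamped_y = np.clip(ground[:, 1], 0.0, bh)
    flags = (clamped_x != ground[:, 0]) | (clamped_y != ground[:, 1])
    return Trajectory(t=np.asarray(timestamps, dtype=float), x=clamped_x,
                      y=clamped_y, fps=fps, clamped=flags)
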