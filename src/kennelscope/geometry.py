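"""Pinhole-camera geometry and plane primitives shared across the package.

The sensor ("camera") frame follows the usual computer-vision convention:
x to the right, y down, z forward along the optical axis, units in metres.
Depth maps store the z coordinate of the observed surface in millimetres,
with 0 marking an invalid (unmeasured) pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics of the depth sensor (pixel units)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project camera-frame 3D points (N, 3) to pixel (col, row) pairs."""
        points = np.asarray(points, dtype=float)
        z = points[..., 2]
        u = self.fx * points[..., 0] / z + self.cx
        v = self.fy * points[..., 1] / z + self.cy
        return np.stack([u, v], axis=-1)

    def back_project(self, cols: np.ndarray, rows: np.ndarray,
                     depth_m: np.ndarray) -> np.ndarray:
        """Lift pixels with metric depth to camera-frame 3D points (N, 3)."""
        x = (np.asarray(cols, dtype=float) - self.cx) * depth_m / self.fx
        y = (np.asarray(rows, dtype=float) - self.cy) * depth_m / self.fy
        return np.stack([x, y, np.asarray(depth_m, dtype=float)], axis=-1)

    def pixel_rays(self) -> np.ndarray:
        """Unnormalised ray directions (H, W, 3) with unit z component."""
        cols, rows = np.meshgrid(np.arange(self.width), np.arange(self.height))
        return np.stack([(cols - self.cx) / self.fx,
                         (rows - self.cy) / self.fy,
                         np.ones_like(cols, dtype=float)], axis=-1)

    def to_dict(self) -> dict:
        return {"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
                "width": self.width, "height": self.height}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(fx=float(d["fx"]), fy=float(d["fy"]), cx=float(d["cx"]),
                   cy=float(d["cy"]), width=int(d["width"]),
                   height=int(d["height"]))


@dataclass(frozen=True)
class CameraPose:
    """Rigid transform world -> camera: p_c = R @ (p_w - position).

    Rows of ``rotation`` are the camera's right / down / forward axes
    expressed in world coordinates.
    """

    rotation: np.ndarray  # (3, 3)
    position: np.ndarray  # (3,)

    def world_to_camera(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.position) @ self.rotation.T

    def camera_to_world(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation + self.position

    @staticmethod
    def look_at(position, target, up=(0.0, 0.0, 1.0)) -> "CameraPose":
        position = np.asarray(position, dtype=float)
        forward = np.asarray(target, dtype=float) - position
        forward = forward / np.linalg.norm(forward)
        up = np.asarray(up, dtype=float)
        right = np.cross(forward, up)
        nr = np.linalg.norm(right)
        if nr < 1e-12:
            raise ValueError("camera forward direction parallel to up vector")
        right = right / nr
        down = np.cross(forward, right)
        rotation = np.stack([right, down, forward], axis=0)
        return CameraPose(rotation=rotation, position=position)


@dataclass(frozen=True)
class Plane:
    """Plane in the sensor frame: points p with normal . p == offset (metres)."""

    normal: np.ndarray  # (3,), unit
    offset: float
    kind: str = "wall"  # floor | wall | fence

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm < 1e-12:
            raise ValueError("plane normal must be non-zero")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "offset", float(self.offset) / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.normal - self.offset


def transform_plane(normal_w, offset_w, pose: CameraPose, kind="wall") -> Plane:
    """Express a world-frame plane (n . p = d) in the camera frame."""
    normal_w = np.asarray(normal_w, dtype=float)
    n_c = pose.rotation @ normal_w
    d_c = float(offset_w) - float(normal_w @ pose.position)
    return Plane(normal=n_c, offset=d_c, kind=kind)
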