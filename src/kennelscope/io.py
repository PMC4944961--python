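"""File formats: depth-video container, scene files, skeleton CSV, weights.

The depth-video container is a directory of 16-bit little-endian grayscale
PNGs (one per frame, depth in millimetres, 0 = invalid) plus a ``meta.json``
sidecar with the frame rate and sensor intrinsics.  A minimal reader
protocol (:class:`FrameSource`) is defined so converters from other
acquisition containers can be plugged in later.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator, Protocol

import imageio.v3 as iio
import numpy as np
import yaml

from .geometry import CameraIntrinsics, Plane
from .depth_scene import DepthFrame, DepthVideo, SceneModel
from .skeleton import PART_NAMES, Skeleton


class FrameSource(Protocol):
    """Adapter interface for pluggable depth-video readers."""

    fps: float
    intrinsics: CameraIntrinsics

    def __iter__(self) -> Iterator[DepthFrame]: ...


def write_depth_video(path, video: DepthVideo) -> None:
    """Write a video as one 16-bit PNG per frame plus a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for frame in video.frames:
        depth = np.clip(np.round(np.asarray(frame.depth)), 0,
                        65535).astype("<u2")
        iio.imwrite(path / f"frame_{frame.index:06d}.png", depth)
    meta = {"fps": video.fps, "n_frames": len(video.frames),
            "intrinsics": video.intrinsics.to_dict()}
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def read_depth_video(path) -> DepthVideo:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    intrinsics = CameraIntrinsics.from_dict(meta["intrinsics"])
    fps = float(meta["fps"])
    frames = []
    for i, png in enumerate(sorted(path.glob("frame_*.png"))):
        depth = np.asarray(iio.imread(png)).astype(np.float32)
        frames.append(DepthFrame(depth=depth, timestamp=i / fps, index=i))
    if len(frames) != int(meta["n_frames"]):
        raise IOError(f"expected {meta['n_frames']} frames, "
                      f"found {len(frames)}")
    return DepthVideo(frames=frames, fps=fps, intrinsics=intrinsics)


class DirectoryFrameSource:
    """FrameSource over the on-disk container (lazy per-frame reads)."""

    def __init__(self, path):
        self.path = Path(path)
        meta = json.loads((self.path / "meta.json").read_text())
        self.fps = float(meta["fps"])
        self.intrinsics = CameraIntrinsics.from_dict(meta["intrinsics"])
        self._files = sorted(self.path.glob("frame_*.png"))

    def __iter__(self):
        for i, png in enumerate(self._files):
            depth = np.asarray(iio.imread(png)).astype(np.float32)
            yield DepthFrame(depth=depth, timestamp=i / self.fps, index=i)

    def __len__(self):
        return len(self._files)


# ---------------------------------------------------------------------------
# scene files

def write_scene(path, scene: SceneModel) -> None:
    """Human-editable YAML description of the pen geometry."""
    doc = {"pen_bounds": [float(v) for v in scene.pen_bounds],
           "floor_origin": [float(v) for v in scene.floor_origin],
           "floor_axes": [[float(v) for v in ax] for ax in scene.floor_axes],
           "planes": [{"normal": [float(v) for v in p.normal],
                       "offset": float(p.offset), "kind": p.kind}
                      for p in scene.planes]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_scene(path) -> SceneModel:
    doc = yaml.safe_load(Path(path).read_text())
    planes = [Plane(normal=np.array(p["normal"]), offset=p["offset"],
                    kind=p["kind"]) for p in doc["planes"]]
    return SceneModel(planes=planes,
                      pen_bounds=tuple(doc["pen_bounds"]),
                      floor_origin=np.array(doc["floor_origin"]),
                      floor_axes=np.array(doc["floor_axes"]))


def plane_from_points(p1, p2, p3, kind: str = "wall") -> Plane:
    """Plane through three user-picked 3D points (sensor frame)."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    normal = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(normal)
    if norm < 1e-9:
        raise ValueError("points are collinear")
    normal = normal / norm
    return Plane(normal=normal, offset=float(normal @ p1), kind=kind)


# ---------------------------------------------------------------------------
# skeleton CSV

def skeletons_to_csv(path, skeletons) -> None:
    """One row per frame: frame, posture, then 6 endpoint coordinates per
    part (x0, y0, z0, x1, y1, z1 in metres, sensor frame; omitted parts as
    zeros)."""
    import pandas as pd
    rows = []
    for i, skel in enumerate(skeletons):
        row = {"frame": i, "posture": skel.posture}
        for name in PART_NAMES:
            seg = skel.segments.get(name)
            vals = (np.zeros(6) if seg is None
                    else np.asarray(seg, dtype=float).ravel())
            for j, axis in enumerate(("x0", "y0", "z0", "x1", "y1", "z1")):
                row[f"{name}_{axis}"] = vals[j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def skeletons_from_csv(path) -> list:
    import pandas as pd
    df = pd.read_csv(path)
    skeletons = []
    for _, row in df.iterrows():
        segments = {}
        for name in PART_NAMES:
            vals = np.array([row[f"{name}_{axis}"]
                             for axis in ("x0", "y0", "z0",
                                          "x1", "y1", "z1")], dtype=float)
            seg = vals.reshape(2, 3)
            if np.any(seg != 0):
                segments[name] = seg
        skeletons.append(Skeleton(segments=segments,
                                  posture=str(row["posture"])))
    return skeletons
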