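"""Synthetic depth recordings of an articulated quadruped in a pen.

The generator replaces a physical depth sensor: a capsule-limbed quadruped
model is posed by a motion script inside a 3 x 3 m pen and z-buffered into
depth frames as seen by a side-mounted sensor 1.5 m above the floor, the
acquisition geometry of a kennel monitoring rig.  Every frame carries
ground-truth skeleton segments, posture label, position and foreground
mask, so the full pipeline (segmentation, skeleton fitting, ethogram,
clustering, validation) can be trained and audited offline.

Depth units are millimetres with additive Gaussian sensor noise; the
default frame rate is 10 fps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import CameraIntrinsics, CameraPose, transform_plane
from .depth_scene import DepthFrame, DepthVideo, SceneModel
from .skeleton import Skeleton, PART_NAMES


class ScriptError(ValueError):
    """A motion script leaves the pen bounds."""


@dataclass(frozen=True)
class QuadrupedModel:
    """Body proportions (metres) and capsule radii of the synthetic animal."""

    torso_length: float = 0.60
    shoulder_height: float = 0.42
    head_length: float = 0.25
    tail_length: float = 0.25
    torso_radius: float = 0.11
    head_radius: float = 0.07
    leg_radius: float = 0.045
    tail_radius: float = 0.03
    lateral_spread: float = 0.07
    sit_rear_height: float = 0.18
    lie_height: float = 0.16

    def __post_init__(self):
        for name in ("torso_length", "shoulder_height", "head_length",
                     "tail_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def randomised(self, rng: np.random.Generator,
                   spread: float = 0.3) -> "QuadrupedModel":
        """Perturb body proportions by up to +-``spread`` (multiplicative)."""
        def jitter(v):
            return float(v * (1.0 + rng.uniform(-spread, spread)))
        return replace(self,
                       torso_length=jitter(self.torso_length),
                       shoulder_height=jitter(self.shoulder_height),
                       head_length=jitter(self.head_length),
                       tail_length=jitter(self.tail_length))


@dataclass(frozen=True)
class ScriptStep:
    """One scripted behaviour bout: a posture moved along a path primitive.

    ``path`` is one of stay | line | circle | perimeter; ``params`` holds the
    primitive's geometry (all coordinates in pen metres).
    """

    duration_s: float
    posture: str
    path: str = "stay"
    params: dict = field(default_factory=dict)
    speed: float = 0.0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("step duration must be positive")


@dataclass
class MotionScript:
    steps: list

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.steps)

    def pose_at(self, t: float) -> tuple:
        """(x, y, heading, posture, arc_length) of the animal at time t."""
        for step in self.steps:
            if t <= step.duration_s or step is self.steps[-1]:
                return _eval_step(step, min(t, step.duration_s))
            t -= step.duration_s
        raise ValueError("empty script")


def _eval_step(step: ScriptStep, t: float) -> tuple:
    p = step.params
    if step.path == "stay":
        x, y = p["position"]
        heading = p.get("heading", 0.0)
        return x, y, heading, step.posture, 0.0
    if step.path == "line":
        (x0, y0), (x1, y1) = p["start"], p["end"]
        seg = math.hypot(x1 - x0, y1 - y0)
        dist = step.speed * t + p.get("phase", 0.0) * 2 * seg
        # bounce back and forth along the segment
        lap, rem = divmod(dist, seg) if seg > 0 else (0, 0.0)
        frac = rem / seg if seg > 0 else 0.0
        if int(lap) % 2 == 1:
            frac = 1.0 - frac
        x = x0 + frac * (x1 - x0)
        y = y0 + frac * (y1 - y0)
        heading = math.atan2(y1 - y0, x1 - x0)
        if int(lap) % 2 == 1:
            heading += math.pi
        return x, y, heading, step.posture, dist
    if step.path == "circle":
        cx, cy = p["centre"]
        r = p["radius"]
        phase = p.get("phase", 0.0)
        omega = step.speed / r
        ang = phase + omega * t
        x = cx + r * math.cos(ang)
        y = cy + r * math.sin(ang)
        heading = ang + math.pi / 2
        return x, y, heading, step.posture, step.speed * t
    if step.path == "perimeter":
        # rounded-rectangle circuit inset by ``margin`` from the pen walls
        w, h = p["pen"]
        m = p.get("margin", 0.45)
        corners = [(m, m), (w - m, m), (w - m, h - m), (m, h - m)]
        lengths = [w - 2 * m, h - 2 * m, w - 2 * m, h - 2 * m]
        total = sum(lengths)
        dist = (step.speed * t + p.get("phase", 0.0) * total) % total
        for i, seg_len in enumerate(lengths):
            if dist <= seg_len:
                x0, y0 = corners[i]
                x1, y1 = corners[(i + 1) % 4]
                frac = dist / seg_len
                heading = math.atan2(y1 - y0, x1 - x0)
                return (x0 + frac * (x1 - x0), y0 + frac * (y1 - y0),
                        heading, step.posture, step.speed * t)
            dist -= seg_len
        x0, y0 = corners[0]
        return x0, y0, 0.0, step.posture, step.speed * t
    raise ValueError(f"unknown path primitive {step.path!r}")


# ---------------------------------------------------------------------------
# posing

def pose_skeleton(model: QuadrupedModel, x: float, y: float, heading: float,
                  posture: str, gait_phase: float = 0.0,
                  lie_mix: float = None) -> dict:
    """World-frame (2, 3) endpoint arrays for the seven body parts.

    ``gait_phase`` swings the legs for locomotion; ``lie_mix`` in [0, 1]
    interpolates continuously from the canonical sit (0) to the canonical
    lie (1) pose, producing the ambiguous crouches seen in real animals.
    """
    f = np.array([math.cos(heading), math.sin(heading), 0.0])
    lat = np.array([-math.sin(heading), math.cos(heading), 0.0])
    up = np.array([0.0, 0.0, 1.0])
    base = np.array([x, y, 0.0])
    L = model.torso_length

    if lie_mix is not None:
        sit = pose_skeleton(model, x, y, heading, "sit")
        lie = pose_skeleton(model, x, y, heading, "lie")
        mix = {name: (1 - lie_mix) * sit[name] + lie_mix * lie[name]
               for name in PART_NAMES}
        return mix

    segs = {}
    if posture in ("stand", "locomotion"):
        h = model.shoulder_height
        rear = base - 0.5 * L * f + h * up
        front = base + 0.5 * L * f + h * up
        segs["torso"] = np.stack([rear, front])
        head_dir = math.cos(0.55) * f + math.sin(0.55) * up
        segs["head"] = np.stack([front, front + model.head_length * head_dir])
        tail_dir = -math.cos(0.4) * f + math.sin(0.4) * up
        segs["tail"] = np.stack([rear, rear + model.tail_length * tail_dir])
        swing = 0.28 * math.sin(gait_phase)
        for name, anchor, side, phase in (
                ("leg_fl", front, +1, swing), ("leg_fr", front, -1, -swing),
                ("leg_bl", rear, +1, -swing), ("leg_br", rear, -1, swing)):
            attach = anchor + side * model.lateral_spread * lat
            tip = attach + h * (math.sin(phase) * f - math.cos(phase) * up)
            tip[2] = max(tip[2], 0.01)
            segs[name] = np.stack([attach, tip])
        return segs

    if posture == "sit":
        h_r, h_f = model.sit_rear_height, model.shoulder_height + 0.03
        pitch = math.asin(min(1.0, (h_f - h_r) / L))
        span = L * math.cos(pitch)
        rear = base - 0.5 * span * f + h_r * up
        front = base + 0.5 * span * f + h_f * up
        segs["torso"] = np.stack([rear, front])
        head_dir = math.cos(0.9) * f + math.sin(0.9) * up
        segs["head"] = np.stack([front, front + model.head_length * head_dir])
        segs["tail"] = np.stack([rear, rear + model.tail_length *
                                 (-0.95 * f + 0.1 * up)])
        for name, side in (("leg_fl", +1), ("leg_fr", -1)):
            attach = front + side * model.lateral_spread * lat
            tip = attach - (h_f - 0.01) * up
            segs[name] = np.stack([attach, tip])
        for name, side in (("leg_bl", +1), ("leg_br", -1)):
            attach = rear + side * model.lateral_spread * lat
            segs[name] = np.stack([attach, attach])
        return segs

    if posture == "lie":
        h = model.lie_height
        rear = base - 0.5 * L * f + h * up
        front = base + 0.5 * L * f + h * up
        segs["torso"] = np.stack([rear, front])
        head_dir = math.cos(0.25) * f + math.sin(0.25) * up
        segs["head"] = np.stack([front, front + model.head_length * head_dir])
        segs["tail"] = np.stack([rear, rear - model.tail_length * f])
        for name, anchor, side in (("leg_fl", front, +1), ("leg_fr", front, -1),
                                   ("leg_bl", rear, +1), ("leg_br", rear, -1)):
            attach = anchor + side * model.lateral_spread * lat
            segs[name] = np.stack([attach, attach])
        return segs

    raise ValueError(f"cannot pose posture {posture!r}")


# ---------------------------------------------------------------------------
# scene / rendering

DEFAULT_INTRINSICS = CameraIntrinsics(fx=285.0, fy=285.0, cx=159.5, cy=119.5,
                                      width=320, height=240)


def make_camera(pen: tuple = (3.0, 3.0), standoff: float = 2.2,
                height: float = 1.5) -> CameraPose:
    """Sensor on a tripod ``height`` m up, ``standoff`` m in front of the pen."""
    w, h = pen
    return CameraPose.look_at(position=(w / 2, -standoff, height),
                              target=(w / 2, h / 2, 0.35))


def make_scene(pen: tuple = (3.0, 3.0),
               camera: CameraPose = None) -> tuple:
    """Build the sensor-frame SceneModel and the world-frame plane list.

    The pen has a floor and three solid walls; the front side (where the
    sensor stands) is open wire mesh and contributes no plane.
    """
    if camera is None:
        camera = make_camera(pen)
    w, h = pen
    world_planes = [((0.0, 0.0, 1.0), 0.0, "floor"),
                    ((1.0, 0.0, 0.0), 0.0, "wall"),
                    ((1.0, 0.0, 0.0), w, "wall"),
                    ((0.0, 1.0, 0.0), h, "wall")]
    planes = [transform_plane(n, d, camera, kind) for n, d, kind in world_planes]
    origin = camera.world_to_camera(np.zeros(3))
    axes = np.stack([camera.rotation @ np.array([1.0, 0.0, 0.0]),
                     camera.rotation @ np.array([0.0, 1.0, 0.0])])
    scene = SceneModel(planes=planes, pen_bounds=(w, h),
                       floor_origin=origin, floor_axes=axes)
    return scene, camera


def _render_planes(rays: np.ndarray, camera: CameraPose, pen: tuple,
                   wall_height: float = 2.0, apron: float = 0.5) -> np.ndarray:
    """Depth (metres, camera z) of the pen planes for every pixel ray."""
    h_img, w_img = rays.shape[:2]
    w, h = pen
    depth = np.full((h_img, w_img), np.inf)
    dirs_w = rays.reshape(-1, 3) @ camera.rotation  # rows are world dirs
    cam = camera.position

    def intersect(n, d, extent_check):
        n = np.asarray(n, dtype=float)
        denom = dirs_w @ n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (d - cam @ n) / denom
        pts = cam[None, :] + t[:, None] * dirs_w
        ok = (t > 0.05) & np.isfinite(t) & extent_check(pts)
        return np.where(ok, t, np.inf)

    floor_t = intersect((0, 0, 1), 0.0, lambda p: (
        (p[:, 0] > -apron) & (p[:, 0] < w + apron)
        & (p[:, 1] > -apron) & (p[:, 1] < h + apron)))
    back_t = intersect((0, 1, 0), h, lambda p: (
        (p[:, 0] > -apron) & (p[:, 0] < w + apron)
        & (p[:, 2] > -0.01) & (p[:, 2] < wall_height)))
    left_t = intersect((1, 0, 0), 0.0, lambda p: (
        (p[:, 1] > -apron) & (p[:, 1] < h + apron)
        & (p[:, 2] > -0.01) & (p[:, 2] < wall_height)))
    right_t = intersect((1, 0, 0), w, lambda p: (
        (p[:, 1] > -apron) & (p[:, 1] < h + apron)
        & (p[:, 2] > -0.01) & (p[:, 2] < wall_height)))
    t_all = np.minimum.reduce([floor_t, back_t, left_t, right_t])
    # camera z equals t because rays have unit z component
    depth = t_all.reshape(h_img, w_img)
    depth[~np.isfinite(depth)] = 0.0
    return depth


def _render_capsule(depth: np.ndarray, a: np.ndarray, b: np.ndarray,
                    radius: float, intr: CameraIntrinsics) -> None:
    """Z-buffer one capsule (segment a-b with radius) into ``depth`` (metres).

    Depth is the camera z of the approximate ray/capsule intersection;
    pixels keep the nearer of their current and new values.  Zero entries in
    ``depth`` are treated as empty (infinitely far).
    """
    if a[2] <= 0.1 or b[2] <= 0.1:
        return
    u = b - a
    seg_len = np.linalg.norm(u)
    # conservative image-space bounding box
    pts = np.stack([a, b])
    px = intr.project(pts)
    margin = radius * max(intr.fx, intr.fy) / min(a[2], b[2]) + 2
    c0 = max(int(np.floor(px[:, 0].min() - margin)), 0)
    c1 = min(int(np.ceil(px[:, 0].max() + margin)), intr.width - 1)
    r0 = max(int(np.floor(px[:, 1].min() - margin)), 0)
    r1 = min(int(np.ceil(px[:, 1].max() + margin)), intr.height - 1)
    if c1 < c0 or r1 < r0:
        return
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    d = np.stack([(cols - intr.cx) / intr.fx,
                  (rows - intr.cy) / intr.fy,
                  np.ones_like(cols, dtype=float)], axis=-1)
    norm = np.linalg.norm(d, axis=-1)
    e = d / norm[..., None]
    if seg_len < 1e-9:
        sigma = np.zeros_like(norm)
    else:
        B = e @ u
        C = float(u @ u)
        ae = e @ a
        au = float(a @ u)
        denom = C - B * B
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma = (ae * B - au) / denom
        sigma = np.where(np.abs(denom) < 1e-12, 0.0, sigma)
        sigma = np.clip(sigma, 0.0, 1.0)
    closest = a[None, None, :] + sigma[..., None] * u[None, None, :]
    t = np.einsum("ijk,ijk->ij", e, closest)
    diff = t[..., None] * e - closest
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    hit = (dist2 < radius * radius) & (t > 0.1)
    if not np.any(hit):
        return
    t_surf = t - np.sqrt(np.maximum(radius * radius - dist2, 0.0))
    z = t_surf * e[..., 2]
    sub = depth[r0:r1 + 1, c0:c1 + 1]
    empty = sub <= 0
    nearer = hit & (empty | (z < sub))
    sub[nearer] = z[nearer]


_PLANE_CACHE: dict = {}


def _plane_depth_for(pen: tuple, intrinsics: CameraIntrinsics,
                     camera: CameraPose) -> np.ndarray:
    """Memoised background (plane) depth render for the default camera."""
    key = (tuple(pen), intrinsics.to_dict().__str__(),
           camera.position.tobytes(), camera.rotation.tobytes())
    if key not in _PLANE_CACHE:
        _PLANE_CACHE[key] = _render_planes(intrinsics.pixel_rays(), camera,
                                           pen)
    return _PLANE_CACHE[key]


@dataclass
class AnnotatedDataset:
    """Rendered depth video plus per-frame ground truth."""

    video: DepthVideo
    scene: SceneModel
    camera: CameraPose
    skeletons: list          # camera-frame GT Skeleton per frame
    postures: list           # GT label per frame (before locomotion split)
    positions: np.ndarray    # (N, 2) pen coordinates
    masks: list              # (H, W) bool GT foreground per frame
    model: QuadrupedModel
    seed: int
    motions: list = None     # GT MotionVector per frame

    def __post_init__(self):
        if self.motions is None:
            from .skeleton import MotionVector
            n = len(self.video.frames)
            self.motions = [MotionVector()]
            for i in range(1, n):
                d = self.positions[i] - self.positions[i - 1]
                self.motions.append(MotionVector(dx=float(d[0]),
                                                 dy=float(d[1])))

    def __len__(self):
        return len(self.video.frames)


def render_sequence(model: QuadrupedModel, script: MotionScript,
                    pen: tuple = (3.0, 3.0), fps: float = 10.0,
                    noise_mm: float = 5.0, seed: int = 0,
                    intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS,
                    camera: CameraPose = None) -> AnnotatedDataset:
    """Render a motion script to an annotated depth video."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    scene, camera = make_scene(pen, camera)
    rng = np.random.default_rng(seed)
    plane_depth = _plane_depth_for(pen, intrinsics, camera)
    n_frames = int(round(script.duration_s * fps))
    body_margin = 0.5 * model.torso_length + model.head_length

    frames, skeletons, postures, masks = [], [], [], []
    positions = np.zeros((n_frames, 2))
    radii = {"torso": model.torso_radius, "head": model.head_radius,
             "tail": model.tail_radius}
    for i in range(n_frames):
        t = i / fps
        x, y, heading, posture, arc = script.pose_at(t)
        w, h = pen
        if not (-0.01 <= x <= w + 0.01 and -0.01 <= y <= h + 0.01):
            raise ScriptError(f"script leaves the pen at t={t:.2f}s "
                              f"({x:.2f}, {y:.2f})")
        if not (body_margin * 0.3 <= x <= w - body_margin * 0.3):
            x = float(np.clip(x, body_margin * 0.3, w - body_margin * 0.3))
        gait_phase = 2 * np.pi * arc / 0.5 if posture in ("stand",
                                                          "locomotion") else 0.0
        segs_w = pose_skeleton(model, x, y, heading, posture,
                               gait_phase=gait_phase)
        segs_c = {name: camera.world_to_camera(seg)
                  for name, seg in segs_w.items()}
        animal = np.zeros_like(plane_depth)
        for name, seg in segs_c.items():
            if np.linalg.norm(seg[1] - seg[0]) < 1e-9:
                continue
            _render_capsule(animal, seg[0], seg[1],
                            radii.get(name, model.leg_radius), intrinsics)
        mask = (animal > 0) & ((plane_depth <= 0) | (animal < plane_depth))
        depth_m = np.where(mask, animal, plane_depth)
        depth_mm = depth_m * 1000.0
        if noise_mm > 0:
            noise = rng.normal(0.0, noise_mm, size=depth_mm.shape)
            depth_mm = np.where(depth_mm > 0,
                                np.maximum(depth_mm + noise, 1.0), 0.0)
        gt_posture = "stand" if posture == "locomotion" else posture
        frames.append(DepthFrame(depth=depth_mm.astype(np.float32),
                                 timestamp=t, index=i))
        skeletons.append(Skeleton(segments=segs_c, posture=gt_posture))
        postures.append(gt_posture)
        positions[i] = (x, y)
        masks.append(mask)
    video = DepthVideo(frames=frames, fps=fps, intrinsics=intrinsics)
    return AnnotatedDataset(video=video, scene=scene, camera=camera,
                            skeletons=skeletons, postures=postures,
                            positions=positions, masks=masks, model=model,
                            seed=seed)


# ---------------------------------------------------------------------------
# scripted motion patterns (pen-level behaviours seen in kennelled dogs)

def perimeter_circuit(duration_s: float, pen=(3.0, 3.0), speed: float = 1.7,
                      phase: float = 0.0) -> MotionScript:
    """The animal circles along the pen perimeter (one lap per ~5 s)."""
    return MotionScript([ScriptStep(duration_s, "stand", "perimeter",
                                    {"pen": pen, "phase": phase},
                                    speed=speed)])


def half_pen_circle(duration_s: float, pen=(3.0, 3.0), speed: float = 0.7,
                    phase: float = 0.0) -> MotionScript:
    """Tight circling confined to the front half of the pen."""
    w, h = pen
    return MotionScript([ScriptStep(duration_s, "stand", "circle",
                                    {"centre": (w / 2, h / 4 + 0.25),
                                     "radius": 0.55, "phase": phase * 2 * np.pi},
                                    speed=speed)])


def side_pacing(duration_s: float, pen=(3.0, 3.0), speed: float = 0.8,
                phase: float = 0.0) -> MotionScript:
    """Back-and-forth pacing along one side of the pen."""
    w, h = pen
    return MotionScript([ScriptStep(duration_s, "stand", "line",
                                    {"start": (0.55, 0.55),
                                     "end": (w - 0.55, 0.55),
                                     "phase": phase},
                                    speed=speed)])


def corner_stand(duration_s: float, pen=(3.0, 3.0),
                 corner=None) -> MotionScript:
    """Stationary standing in one pen corner."""
    w, h = pen
    if corner is None:
        corner = (0.6, h - 0.6)
    return MotionScript([ScriptStep(duration_s, "stand", "stay",
                                    {"position": corner, "heading": -0.7})])


PATTERN_BUILDERS = {
    "perimeter": perimeter_circuit,
    "half_circle": half_pen_circle,
    "side_pacing": side_pacing,
    "corner_stand": corner_stand,
}
PATTERN_NAMES = tuple(PATTERN_BUILDERS)


def planted_pattern_windows(counts=(3, 2, 3, 2), window_s: float = 5.0,
                            fps: float = 10.0, jitter: float = 0.0,
                            seed: int = 0) -> tuple:
    """Trajectory windows drawn from the four scripted motion patterns.

    ``counts`` gives the number of windows per pattern in the order
    perimeter-circling, half-pen circling, side pacing, corner standing
    (default composition 3/2/3/2).  ``jitter`` adds isotropic Gaussian
    positional noise (metres).  Returns (list of (n, 2) coordinate arrays,
    list of pattern labels).
    """
    rng = np.random.default_rng(seed)
    n_sym = int(round(window_s * fps))
    windows, labels = [], []
    for name, count in zip(PATTERN_NAMES, counts):
        for _ in range(int(count)):
            phase = float(rng.uniform(0, 1))
            if name == "corner_stand":
                script = corner_stand(window_s)
            else:
                script = PATTERN_BUILDERS[name](window_s, phase=phase)
            coords = np.array([script.pose_at(i / fps)[:2]
                               for i in range(n_sym)])
            if jitter > 0:
                coords = coords + rng.normal(0.0, jitter, size=coords.shape)
            windows.append(coords)
            labels.append(name)
    return windows, labels


def posture_script(posture: str, duration_s: float, position,
                   heading: float = 0.0, speed: float = 0.0) -> MotionScript:
    """Single-bout script holding one posture (optionally walking a line)."""
    if speed > 0:
        x, y = position
        length = min(2.0, speed * duration_s)
        dx, dy = math.cos(heading), math.sin(heading)
        return MotionScript([ScriptStep(duration_s, posture, "line",
                                        {"start": (x - dx * length / 2,
                                                   y - dy * length / 2),
                                         "end": (x + dx * length / 2,
                                                 y + dy * length / 2)},
                                        speed=speed)])
    return MotionScript([ScriptStep(duration_s, posture, "stay",
                                    {"position": tuple(position),
                                     "heading": heading})])


def posture_frames(posture: str, n: int, seed: int = 0,
                   model: QuadrupedModel = None, pen=(3.0, 3.0),
                   fps: float = 10.0, noise_mm: float = 5.0,
                   intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS,
                   heading_range=(-np.pi, np.pi),
                   proportion_spread: float = 0.0) -> AnnotatedDataset:
    """Independent annotated frames of one posture at random poses.

    Positions and headings are drawn uniformly inside the pen (with a body
    margin); each frame is rendered as a one-frame stationary script and the
    results concatenated into a single dataset.  ``proportion_spread``
    randomises the animal's body proportions per frame (multiplicative,
    up to +-spread), emulating variation across individuals.
    """
    if model is None:
        model = QuadrupedModel()
    rng = np.random.default_rng(seed)
    w, h = pen
    margin = 0.8
    datasets = []
    for i in range(n):
        x = float(rng.uniform(margin, w - margin))
        y = float(rng.uniform(margin, h - margin))
        heading = float(rng.uniform(*heading_range))
        frame_model = (model.randomised(rng, proportion_spread)
                       if proportion_spread > 0 else model)
        script = posture_script(posture, 1.0 / fps, (x, y), heading)
        datasets.append(render_sequence(frame_model, script, pen=pen, fps=fps,
                                        noise_mm=noise_mm,
                                        seed=int(rng.integers(2 ** 31)),
                                        intrinsics=intrinsics))
    return _concat_datasets(datasets)


def ambiguous_posture_frames(n: int, seed: int = 0,
                             model: QuadrupedModel = None, pen=(3.0, 3.0),
                             fps: float = 10.0, noise_mm: float = 5.0,
                             intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS,
                             mix_range=(0.0, 1.0)) -> tuple:
    """Frames interpolating the sit and lie poses (the ambiguous crouch).

    The interpolation parameter is drawn uniformly from ``mix_range``; a
    frame is labelled by the nearest canonical template (sit below 0.5, lie
    at or above).  Returns (AnnotatedDataset, mix values array).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if model is None:
        model = QuadrupedModel()
    rng = np.random.default_rng(seed)
    scene, camera = make_scene(pen)
    plane_depth = _plane_depth_for(pen, intrinsics, camera)
    w, h = pen
    margin = 0.8
    radii = {"torso": model.torso_radius, "head": model.head_radius,
             "tail": model.tail_radius}
    frames, skeletons, postures, masks = [], [], [], []
    positions = np.zeros((n, 2))
    mixes = np.zeros(n)
    for i in range(n):
        x = float(rng.uniform(margin, w - margin))
        y = float(rng.uniform(margin, h - margin))
        heading = float(rng.uniform(-np.pi, np.pi))
        mix = float(rng.uniform(*mix_range))
        segs_w = pose_skeleton(model, x, y, heading, "sit", lie_mix=mix)
        segs_c = {name: camera.world_to_camera(seg)
                  for name, seg in segs_w.items()}
        animal = np.zeros_like(plane_depth)
        for name, seg in segs_c.items():
            if np.linalg.norm(seg[1] - seg[0]) < 1e-9:
                continue
            _render_capsule(animal, seg[0], seg[1],
                            radii.get(name, model.leg_radius), intrinsics)
        mask = (animal > 0) & ((plane_depth <= 0) | (animal < plane_depth))
        depth_mm = np.where(mask, animal, plane_depth) * 1000.0
        if noise_mm > 0:
            noise = rng.normal(0.0, noise_mm, size=depth_mm.shape)
            depth_mm = np.where(depth_mm > 0,
                                np.maximum(depth_mm + noise, 1.0), 0.0)
        label = "sit" if mix < 0.5 else "lie"
        frames.append(DepthFrame(depth=depth_mm.astype(np.float32),
                                 timestamp=i / fps, index=i))
        skeletons.append(Skeleton(segments=segs_c, posture=label))
        postures.append(label)
        positions[i] = (x, y)
        masks.append(mask)
        mixes[i] = mix
    video = DepthVideo(frames=frames, fps=fps, intrinsics=intrinsics)
    dataset = AnnotatedDataset(video=video, scene=scene, camera=camera,
                               skeletons=skeletons, postures=postures,
                               positions=positions, masks=masks, model=model,
                               seed=seed)
    return dataset, mixes


def walking_frames(n: int, seed: int = 0, model: QuadrupedModel = None,
                   pen=(3.0, 3.0), fps: float = 10.0, noise_mm: float = 5.0,
                   intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS,
                   speed_range=(0.25, 0.7),
                   proportion_spread: float = 0.0) -> AnnotatedDataset:
    """Independent frames of a walking animal with true motion vectors.

    Each sample renders a short straight-line walk at a random position,
    heading and speed and keeps the final frame, whose motion vector is the
    ground displacement from the previous frame.
    """
    if model is None:
        model = QuadrupedModel()
    rng = np.random.default_rng(seed)
    w, h = pen
    margin = 1.0
    datasets = []
    for i in range(n):
        x = float(rng.uniform(margin, w - margin))
        y = float(rng.uniform(margin, h - margin))
        heading = float(rng.uniform(-np.pi, np.pi))
        speed = float(rng.uniform(*speed_range))
        frame_model = (model.randomised(rng, proportion_spread)
                       if proportion_spread > 0 else model)
        script = posture_script("stand", 2.0 / fps, (x, y), heading,
                                speed=speed)
        ds = render_sequence(frame_model, script, pen=pen, fps=fps,
                             noise_mm=noise_mm,
                             seed=int(rng.integers(2 ** 31)),
                             intrinsics=intrinsics)
        last = len(ds) - 1
        datasets.append(AnnotatedDataset(
            video=DepthVideo(frames=[ds.video.frames[last]], fps=fps,
                             intrinsics=intrinsics),
            scene=ds.scene, camera=ds.camera,
            skeletons=[ds.skeletons[last]], postures=[ds.postures[last]],
            positions=ds.positions[last:last + 1],
            masks=[ds.masks[last]], model=frame_model, seed=seed,
            motions=[ds.motions[last]]))
    return _concat_datasets(datasets)


def _concat_datasets(datasets) -> AnnotatedDataset:
    first = datasets[0]
    frames, skeletons, postures, masks, motions = [], [], [], [], []
    positions = []
    for ds in datasets:
        for fr in ds.video.frames:
            frames.append(DepthFrame(depth=fr.depth,
                                     timestamp=len(frames) / first.video.fps,
                                     index=len(frames)))
        skeletons.extend(ds.skeletons)
        postures.extend(ds.postures)
        masks.extend(ds.masks)
        motions.extend(ds.motions)
        positions.append(ds.positions)
    video = DepthVideo(frames=frames, fps=first.video.fps,
                       intrinsics=first.video.intrinsics)
    return AnnotatedDataset(video=video, scene=first.scene,
                            camera=first.camera, skeletons=skeletons,
                            postures=postures,
                            positions=np.concatenate(positions),
                            masks=masks, model=first.model, seed=first.seed,
                            motions=motions)
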