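"""Structured max-margin body-part labelling and posture classification.

The body-part labeller is a structured SVM: a linear score
``F(x, y) = w . phi(x, y)`` over a discretised candidate space of skeletons
``y`` anchored on the animal blob ``x``.  Candidates are generated under
anatomical constraints — the torso passes through the blob barycentre, head
and tail attach at the torso ends, legs stay below the torso — with
posture-specific restrictions (a lying animal hides its legs, a sitting one
keeps the rear low and the front high).  The joint feature map samples blob
occupancy along each candidate segment; training uses online
passive-aggressive max-margin updates (a streaming approximation in the
LaRank family) with a margin scaled by the mean endpoint distance to the
ground-truth skeleton.

Because both the score and the loss decompose over body parts given the
torso, exact argmax inference factorises: for every torso candidate the
best head, tail and leg configurations are chosen independently.  This
equals brute-force enumeration over the full candidate grid (audited in the
test-suite) at a fraction of the cost.

Posture classification runs three per-posture structured models (stand,
sit, lie) and picks the best calibrated score; locomotion is split from
stand afterwards by thresholding barycentre speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .depth_scene import Blob, Trajectory
from .skeleton import (LEG_NAMES, PART_NAMES, MotionVector, Skeleton,
                       decode_solution, to_plane)

LEG_DOWN = -np.pi / 2  # straight-down direction in the upright image plane

PART_LENGTH_FRACS = {"head": 0.42, "tail": 0.42, "leg": 0.70}


def _wrap_angle(a):
    a = np.mod(np.asarray(a, dtype=float) + np.pi, 2 * np.pi) - np.pi
    return np.where(a <= -np.pi, np.pi, a)


@dataclass
class TrainingPair:
    """One supervised example: blob input, ground-truth skeleton, label."""

    x: object                 # Blob or BlobFeatures
    y: Skeleton
    motion: MotionVector = field(default_factory=MotionVector)
    posture_label: str = None


@dataclass
class BlobFeatures:
    """Per-frame appearance descriptor: an upright-plane occupancy grid.

    The blob's 3D points are projected onto the (right, up) plane and
    rasterised into an occupancy grid; candidate segments are scored by the
    occupancy sampled along their geometry.  ``extent`` is the diagonal of
    the blob's plane bounding box and anchors the torso length grid.
    """

    grid: np.ndarray          # (nx, ny) occupancy in [0, 1]
    origin: np.ndarray        # plane coords of grid cell (0, 0)
    cell: float
    barycentre: np.ndarray    # (2,) plane coords
    depth: float              # mean sensor z of the blob (m)
    extent: float             # bounding-box diagonal (m)
    motion: np.ndarray        # (2,) ground displacement per frame (m)
    floor_height: float = 0.0  # barycentre height above the floor plane (m)
    top_height: float = 0.0    # highest blob point above the floor (m)
    vertical_extent: float = 0.0
    horizontal_extent: float = 0.0
    bottom_height: float = 0.0  # 20th percentile of point heights (m)
    low_mass_frac: float = 0.0  # fraction of points within 0.12 m of floor

    @classmethod
    def from_blob(cls, blob: Blob, motion: MotionVector = None,
                  cell: float = 0.03, pad: float = 0.12,
                  floor=None) -> "BlobFeatures":
        if blob is None or len(blob.points) == 0:
            raise ValueError("cannot build features from an empty blob")
        if motion is None:
            motion = MotionVector()
        pts = to_plane(blob.points)
        lo = pts.min(axis=0) - pad
        hi = pts.max(axis=0) + pad
        nx = max(int(np.ceil((hi[0] - lo[0]) / cell)), 2)
        ny = max(int(np.ceil((hi[1] - lo[1]) / cell)), 2)
        idx = np.floor((pts - lo) / cell).astype(int)
        idx[:, 0] = np.clip(idx[:, 0], 0, nx - 1)
        idx[:, 1] = np.clip(idx[:, 1], 0, ny - 1)
        grid = np.zeros((nx, ny))
        grid[idx[:, 0], idx[:, 1]] = 1.0
        grid = ndimage.gaussian_filter(grid, sigma=0.8)
        m = grid.max()
        if m > 0:
            grid = grid / m
        extent = float(np.linalg.norm(hi - lo - 2 * pad))
        if floor is not None:
            heights = floor.signed_distance(blob.points)
            bary_height = float(floor.signed_distance(blob.barycentre[None])[0])
            top = float(np.max(heights))
            bottom = float(np.percentile(heights, 20))
            low_frac = float(np.mean(heights < 0.12))
        else:
            bary_height, top, bottom, low_frac = 0.0, 0.0, 0.0, 0.0
        span = hi - lo - 2 * pad
        return cls(grid=grid, origin=lo, cell=cell,
                   barycentre=to_plane(blob.barycentre[None])[0],
                   depth=float(np.mean(blob.points[:, 2])),
                   extent=extent, motion=motion.array,
                   floor_height=bary_height, top_height=top,
                   vertical_extent=float(span[1]),
                   horizontal_extent=float(span[0]),
                   bottom_height=bottom, low_mass_frac=low_frac)

    @classmethod
    def empty(cls, motion: MotionVector = None) -> "BlobFeatures":
        """All-background descriptor (no detection)."""
        if motion is None:
            motion = MotionVector()
        return cls(grid=np.zeros((2, 2)), origin=np.zeros(2), cell=0.03,
                   barycentre=np.zeros(2), depth=1.0, extent=0.5,
                   motion=motion.array)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Bilinear occupancy lookup at plane coordinates (..., 2)."""
        pts = np.asarray(points, dtype=float)
        shape = pts.shape[:-1]
        coords = (pts.reshape(-1, 2) - self.origin) / self.cell - 0.5
        out = ndimage.map_coordinates(self.grid, coords.T, order=1,
                                      mode="constant", cval=0.0)
        return out.reshape(shape)


# ---------------------------------------------------------------------------
# candidate generation

#: per-posture torso orientation arcs (radians in the upright plane) and
#: which legs are enumerated; "bodyparts" is the unconstrained labelling task
POSTURE_CONSTRAINTS = {
    "bodyparts": {"arcs": [(-np.pi, np.pi)], "legs": "all"},
    "stand": {"arcs": [(-np.pi, np.pi)], "legs": "all"},
    "sit": {"arcs": [(0.15, 1.2), (np.pi - 1.2, np.pi - 0.15)],
            "legs": "front"},
    "lie": {"arcs": [(-0.45, 0.45), (np.pi - 0.45, np.pi + 0.45)],
            "legs": "none"},
}


def _torso_angle_grid(posture_class: str, n: int) -> np.ndarray:
    spec = POSTURE_CONSTRAINTS[posture_class]
    arcs = spec["arcs"]
    if len(arcs) == 1 and arcs[0] == (-np.pi, np.pi):
        return _wrap_angle(np.linspace(-np.pi, np.pi, n, endpoint=False))
    per = max(n // len(arcs), 1)
    vals = [np.linspace(a, b, per) for a, b in arcs]
    return _wrap_angle(np.concatenate(vals))


@dataclass
class CandidateSet:
    """Factorised candidate skeletons for one blob.

    The full set is the cartesian product of torso, head, tail and leg
    grids; candidate ``i`` has index
    ``((t * n_head + h) * n_tail + ta) * n_leg + g`` with the torso index
    ``t`` running angle-major over the (angle, length) grid.
    """

    posture_class: str
    features: BlobFeatures
    torso_angles: np.ndarray     # (T,)
    torso_lengths: np.ndarray    # (T,)
    torso_segs: np.ndarray       # (T, 2, 2)
    head_angles: np.ndarray      # (T, nH) absolute
    head_segs: np.ndarray        # (T, nH, 2, 2)
    tail_angles: np.ndarray      # (T, nT)
    tail_segs: np.ndarray        # (T, nT, 2, 2)
    leg_alphas: np.ndarray       # (nG,) leg splay parameters
    leg_segs: np.ndarray         # (T, nG, 4, 2, 2), fl fr bl br
    leg_lengths: np.ndarray      # (T, nG, 4)

    @property
    def shape(self):
        return (len(self.torso_segs), self.head_segs.shape[1],
                self.tail_segs.shape[1], self.leg_segs.shape[1])

    def __len__(self):
        t, h, ta, g = self.shape
        return t * h * ta * g

    def unravel(self, index: int) -> tuple:
        _, h, ta, g = self.shape
        return np.unravel_index(index, (len(self.torso_segs), h, ta, g))

    def ravel(self, t, h, ta, g) -> int:
        _, nh, nt, ng = self.shape
        return int(((t * nh + h) * nt + ta) * ng + g)

    def solution_vector(self, t, h, ta, g) -> np.ndarray:
        """16-value solution vector of candidate (t, h, ta, g)."""
        vec = np.zeros(16)
        order = {name: i for i, name in enumerate(PART_NAMES)}
        ln = self.torso_lengths[t]
        vec[2 * order["torso"]] = self.torso_angles[t]
        vec[2 * order["torso"] + 1] = ln
        vec[2 * order["head"]] = self.head_angles[t, h]
        vec[2 * order["head"] + 1] = PART_LENGTH_FRACS["head"] * ln
        vec[2 * order["tail"]] = self.tail_angles[t, ta]
        vec[2 * order["tail"] + 1] = PART_LENGTH_FRACS["tail"] * ln
        for j, name in enumerate(LEG_NAMES):
            seg = self.leg_segs[t, g, j]
            d = seg[1] - seg[0]
            length = float(np.linalg.norm(d))
            vec[2 * order[name]] = (np.arctan2(d[1], d[0])
                                    if length > 1e-12 else 0.0)
            vec[2 * order[name] + 1] = length
        vec[14:16] = self.features.motion
        return vec

    def skeleton(self, t, h, ta, g, posture: str = None) -> Skeleton:
        vec = self.solution_vector(t, h, ta, g)
        posture = posture if posture in ("stand", "sit", "lie",
                                         "locomotion") else "unknown"
        skel, _ = decode_solution(vec, self.features.barycentre,
                                  self.features.depth, posture=posture)
        return skel


def generate_candidates(features: BlobFeatures, posture_class: str = "stand",
                        n_torso_angles: int = 24, n_torso_lengths: int = 5,
                        n_head_angles: int = 8, n_tail_angles: int = 8,
                        n_leg_configs: int = 6,
                        torso_length_range=(0.45, 0.85),
                        rel_angle_limit: float = np.pi / 3,
                        leg_alpha_limit: float = 0.4,
                        leg_offset_frac: float = 0.05) -> CandidateSet:
    """Enumerate constrained candidate skeletons for one blob.

    Torso candidates pass through the barycentre at discretised
    orientations and lengths spanning the blob extent; head and tail attach
    at the torso ends over discretised relative angles; legs point downward
    with a splay parameter and are enumerated only where the posture class
    allows them.
    """
    if posture_class not in POSTURE_CONSTRAINTS:
        raise ValueError(f"unknown posture class {posture_class!r}")
    angles = _torso_angle_grid(posture_class, n_torso_angles)
    lengths = np.linspace(*torso_length_range, n_torso_lengths) \
        * max(features.extent, 0.05)
    ang = np.repeat(angles, n_torso_lengths)
    ln = np.tile(lengths, len(angles))
    T = len(ang)
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    centre = features.barycentre
    rear = centre - 0.5 * ln[:, None] * dirs
    front = centre + 0.5 * ln[:, None] * dirs
    torso_segs = np.stack([rear, front], axis=1)

    rel = np.linspace(-rel_angle_limit, rel_angle_limit, n_head_angles)
    head_angles = _wrap_angle(ang[:, None] + rel[None, :])
    head_len = PART_LENGTH_FRACS["head"] * ln
    head_dirs = np.stack([np.cos(head_angles), np.sin(head_angles)], axis=-1)
    head_tips = front[:, None, :] + head_len[:, None, None] * head_dirs
    head_segs = np.stack([np.broadcast_to(front[:, None, :],
                                          head_tips.shape), head_tips], axis=2)

    rel_t = np.linspace(-rel_angle_limit, rel_angle_limit, n_tail_angles)
    tail_angles = _wrap_angle(ang[:, None] + np.pi + rel_t[None, :])
    tail_len = PART_LENGTH_FRACS["tail"] * ln
    tail_dirs = np.stack([np.cos(tail_angles), np.sin(tail_angles)], axis=-1)
    tail_tips = rear[:, None, :] + tail_len[:, None, None] * tail_dirs
    tail_segs = np.stack([np.broadcast_to(rear[:, None, :],
                                          tail_tips.shape), tail_tips], axis=2)

    legs_mode = POSTURE_CONSTRAINTS[posture_class]["legs"]
    if legs_mode == "none":
        alphas = np.zeros(1)
    else:
        alphas = np.linspace(-leg_alpha_limit, leg_alpha_limit, n_leg_configs)
    nG = len(alphas)
    off = leg_offset_frac * ln[:, None] * dirs
    anchors = np.stack([front - off, front - 2 * off,
                        rear + 2 * off, rear + off], axis=1)  # (T, 4, 2)
    leg_len = PART_LENGTH_FRACS["leg"] * ln
    leg_segs = np.zeros((T, nG, 4, 2, 2))
    leg_lengths = np.zeros((T, nG, 4))
    leg_segs[:, :, :, 0, :] = anchors[:, None, :, :]
    leg_segs[:, :, :, 1, :] = anchors[:, None, :, :]
    active = {"all": (0, 1, 2, 3), "front": (0, 1), "none": ()}[legs_mode]
    for j in active:
        sign = 1.0 if j < 2 else -1.0
        la = LEG_DOWN + sign * alphas  # (nG,)
        tip_dir = np.stack([np.cos(la), np.sin(la)], axis=-1)  # (nG, 2)
        tips = (anchors[:, None, j, :]
                + leg_len[:, None, None] * tip_dir[None, :, :])
        leg_segs[:, :, j, 1, :] = tips
        leg_lengths[:, :, j] = leg_len[:, None]
    return CandidateSet(posture_class=posture_class, features=features,
                        torso_angles=ang, torso_lengths=ln,
                        torso_segs=torso_segs, head_angles=head_angles,
                        head_segs=head_segs, tail_angles=tail_angles,
                        tail_segs=tail_segs, leg_alphas=alphas,
                        leg_segs=leg_segs, leg_lengths=leg_lengths)


# ---------------------------------------------------------------------------
# joint feature map

N_SAMPLES = 5            # occupancy samples along a segment
RIBBON_OFFSETS = (-0.06, 0.0, 0.06)   # parallel line offsets (m)
N_APPEAR = N_SAMPLES * len(RIBBON_OFFSETS)
BLOCK_TORSO = N_APPEAR + 2           # ribbon + length/extent + motion align
BLOCK_PART = N_APPEAR + 1            # ribbon + length/torso-length
FEATURE_DIM = BLOCK_TORSO + 6 * BLOCK_PART + 2


def _occupancy_samples(features: BlobFeatures, segs: np.ndarray) -> np.ndarray:
    """Ribbon occupancy along segments (..., 2, 2) -> (..., N_APPEAR).

    Samples N_SAMPLES points on the segment itself and on two parallel
    lines offset perpendicularly, making the descriptor sensitive to the
    local thickness of the blob (a raised head is thicker than a tail).
    """
    d = segs[..., 1, :] - segs[..., 0, :]
    lengths = np.linalg.norm(d, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = d / lengths[..., None]
    unit = np.where((lengths > 1e-9)[..., None], unit, 0.0)
    perp = np.stack([-unit[..., 1], unit[..., 0]], axis=-1)
    fracs = np.linspace(0.0, 1.0, N_SAMPLES)
    a = segs[..., 0, :][..., None, :]
    on_line = a + fracs[:, None] * d[..., None, :]        # (..., S, 2)
    rows = []
    for off in RIBBON_OFFSETS:
        rows.append(on_line + off * perp[..., None, :])
    pts = np.concatenate(rows, axis=-2)                   # (..., 3S, 2)
    samples = features.sample(pts)
    return np.where((lengths > 1e-9)[..., None], samples, 0.0)


def _motion_alignment(features: BlobFeatures,
                      torso_angles: np.ndarray) -> np.ndarray:
    """Alignment between torso direction and the motion vector.

    Zero when the animal is (nearly) still; this is what lets the model
    orient the torso so the head end leads during locomotion.
    """
    mag = np.linalg.norm(features.motion)
    if mag < 1e-6:
        return np.zeros_like(torso_angles)
    m_angle = np.arctan2(features.motion[1], features.motion[0])
    return np.cos(torso_angles - m_angle) * min(mag / 0.05, 1.0)


def _torso_block(features: BlobFeatures, cand: CandidateSet) -> np.ndarray:
    samples = _occupancy_samples(features, cand.torso_segs)
    length_feat = cand.torso_lengths / max(features.extent, 1e-6)
    align = _motion_alignment(features, cand.torso_angles)
    return np.concatenate([samples, length_feat[:, None], align[:, None]],
                          axis=-1)


def _part_block(features: BlobFeatures, segs: np.ndarray,
                torso_lengths: np.ndarray) -> np.ndarray:
    samples = _occupancy_samples(features, segs)
    lengths = np.linalg.norm(segs[..., 1, :] - segs[..., 0, :], axis=-1)
    ratio = lengths / np.maximum(torso_lengths.reshape(
        torso_lengths.shape + (1,) * (lengths.ndim - 1)), 1e-9)
    return np.concatenate([samples, ratio[..., None]], axis=-1)


@dataclass
class FeatureBlocks:
    """Cached per-factor feature blocks of one blob's candidate set."""

    torso: np.ndarray   # (T, BLOCK_TORSO)
    head: np.ndarray    # (T, nH, BLOCK_PART)
    tail: np.ndarray    # (T, nT, BLOCK_PART)
    legs: np.ndarray    # (T, nG, 4 * BLOCK_PART)
    motion: np.ndarray  # (2,)

    def phi(self, t, h, ta, g) -> np.ndarray:
        return np.concatenate([self.torso[t], self.head[t, h],
                               self.tail[t, ta], self.legs[t, g],
                               self.motion])


def compute_feature_blocks(cand: CandidateSet) -> FeatureBlocks:
    f = cand.features
    torso = _torso_block(f, cand)
    head = _part_block(f, cand.head_segs, cand.torso_lengths)
    tail = _part_block(f, cand.tail_segs, cand.torso_lengths)
    leg_samples = _occupancy_samples(f, cand.leg_segs)   # (T, nG, 4, S)
    ratio = cand.leg_lengths / np.maximum(
        cand.torso_lengths[:, None, None], 1e-9)          # (T, nG, 4)
    legs = np.concatenate([leg_samples, ratio[..., None]], axis=-1)
    legs = legs.reshape(legs.shape[0], legs.shape[1], -1)
    return FeatureBlocks(torso=torso, head=head, tail=tail, legs=legs,
                         motion=f.motion.copy())


def joint_feature_map(features: BlobFeatures, skeleton: Skeleton,
                      motion: MotionVector = None) -> np.ndarray:
    """phi(x, y) for an arbitrary skeleton (not necessarily on the grid).

    Concatenates, per body part, blob occupancy sampled along the segment
    plus a length ratio, a torso/motion alignment term, and the raw motion
    components; the layout matches the factorised candidate features.
    """
    if motion is None:
        motion = MotionVector(*features.motion)
    segs2d = {}
    for name in PART_NAMES:
        seg = skeleton.segments.get(name)
        if seg is None:
            anchor = to_plane(skeleton.segments["torso"])[1]
            segs2d[name] = np.stack([anchor, anchor])
        else:
            segs2d[name] = to_plane(seg)
    torso = segs2d["torso"]
    t_len = float(np.linalg.norm(torso[1] - torso[0]))
    t_angle = float(np.arctan2(*(torso[1] - torso[0])[::-1]))
    parts = []
    samples = _occupancy_samples(features, torso[None])[0]
    align = _motion_alignment(features, np.array([t_angle]))[0]
    parts.append(np.concatenate([samples,
                                 [t_len / max(features.extent, 1e-6), align]]))
    for name in ("head", "tail") + LEG_NAMES:
        seg = segs2d[name]
        samples = _occupancy_samples(features, seg[None])[0]
        length = float(np.linalg.norm(seg[1] - seg[0]))
        parts.append(np.concatenate([samples, [length / max(t_len, 1e-9)]]))
    parts.append(motion.array)
    return np.concatenate(parts)


def score(w: np.ndarray, phi: np.ndarray) -> float:
    """Compatibility score F(x, y) = w . phi(x, y)."""
    w = np.asarray(w, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if w.shape != phi.shape:
        raise ValueError(f"dimension mismatch: {w.shape} vs {phi.shape}")
    return float(w @ phi)


# ---------------------------------------------------------------------------
# loss

def _endpoint_distance_blocks(cand: CandidateSet,
                              gt: Skeleton) -> "LossBlocks":
    """Per-factor summed endpoint distances to the ground truth skeleton.

    The structured loss of a candidate is the mean endpoint distance over
    the seven parts, normalised by the ground-truth torso length; it
    decomposes additively over the torso / head / tail / legs factors.
    """
    gt2d = {name: to_plane(gt.segments[name]) if name in gt.segments
            else None for name in PART_NAMES}
    torso_gt = gt2d["torso"]
    norm = 14.0 * max(np.linalg.norm(torso_gt[1] - torso_gt[0]), 1e-9)

    def seg_cost(segs, gt_seg):
        if gt_seg is None:
            gt_seg = np.stack([torso_gt[1], torso_gt[1]])
        return (np.linalg.norm(segs[..., 0, :] - gt_seg[0], axis=-1)
                + np.linalg.norm(segs[..., 1, :] - gt_seg[1], axis=-1))

    torso = seg_cost(cand.torso_segs, gt2d["torso"])
    head = seg_cost(cand.head_segs, gt2d["head"])
    tail = seg_cost(cand.tail_segs, gt2d["tail"])
    legs = sum(seg_cost(cand.leg_segs[:, :, j], gt2d[name])
               for j, name in enumerate(LEG_NAMES))
    return LossBlocks(torso=torso / norm, head=head / norm,
                      tail=tail / norm, legs=legs / norm)


@dataclass
class LossBlocks:
    torso: np.ndarray  # (T,)
    head: np.ndarray   # (T, nH)
    tail: np.ndarray   # (T, nT)
    legs: np.ndarray   # (T, nG)

    def loss(self, t, h, ta, g) -> float:
        return float(self.torso[t] + self.head[t, h] + self.tail[t, ta]
                     + self.legs[t, g])


def _factorised_argmax(w: np.ndarray, blocks: FeatureBlocks,
                       loss_blocks: LossBlocks = None) -> tuple:
    """Exact (loss-augmented) argmax over the factorised candidate set.

    Returns (t, h, ta, g, total score incl. loss term).  Ties resolve to
    the lowest candidate index.
    """
    i0 = 0
    w_torso = w[i0:i0 + BLOCK_TORSO]; i0 += BLOCK_TORSO
    w_head = w[i0:i0 + BLOCK_PART]; i0 += BLOCK_PART
    w_tail = w[i0:i0 + BLOCK_PART]; i0 += BLOCK_PART
    w_legs = w[i0:i0 + 4 * BLOCK_PART]; i0 += 4 * BLOCK_PART
    w_motion = w[i0:i0 + 2]

    s_torso = blocks.torso @ w_torso
    s_head = blocks.head @ w_head
    s_tail = blocks.tail @ w_tail
    s_legs = blocks.legs @ w_legs
    if loss_blocks is not None:
        s_torso = s_torso + loss_blocks.torso
        s_head = s_head + loss_blocks.head
        s_tail = s_tail + loss_blocks.tail
        s_legs = s_legs + loss_blocks.legs
    best_h = np.argmax(s_head, axis=1)
    best_ta = np.argmax(s_tail, axis=1)
    best_g = np.argmax(s_legs, axis=1)
    totals = (s_torso + s_head[np.arange(len(s_head)), best_h]
              + s_tail[np.arange(len(s_tail)), best_ta]
              + s_legs[np.arange(len(s_legs)), best_g])
    t = int(np.argmax(totals))
    base = float(totals[t] + blocks.motion @ w_motion)
    return t, int(best_h[t]), int(best_ta[t]), int(best_g[t]), base


def snap_to_grid(cand: CandidateSet, gt: Skeleton) -> tuple:
    """Nearest candidate (by structured loss) to a ground-truth skeleton."""
    lb = _endpoint_distance_blocks(cand, gt)
    best_h = np.argmin(lb.head, axis=1)
    best_ta = np.argmin(lb.tail, axis=1)
    best_g = np.argmin(lb.legs, axis=1)
    totals = (lb.torso + lb.head[np.arange(len(lb.head)), best_h]
              + lb.tail[np.arange(len(lb.tail)), best_ta]
              + lb.legs[np.arange(len(lb.legs)), best_g])
    t = int(np.argmin(totals))
    return t, int(best_h[t]), int(best_ta[t]), int(best_g[t])


# ---------------------------------------------------------------------------
# estimators

class StructuredBodyPartSVM(BaseEstimator):
    """Structured SVM labelling the seven body parts of a depth blob.

    Parameters follow the candidate grid (numbers of discretised torso
    orientations/lengths, head/tail relative angles and leg configurations),
    the passive-aggressive aggressiveness ``C`` and the number of training
    epochs.  ``posture_class`` selects the anatomical constraint set.

    Attributes set by :meth:`fit`: ``w_`` (weight vector),
    ``training_loss_`` (mean structured hinge loss per epoch),
    ``n_feature_dim_``.
    """

    def __init__(self, posture_class: str = "bodyparts",
                 n_torso_angles: int = 24, n_torso_lengths: int = 5,
                 n_head_angles: int = 8, n_tail_angles: int = 8,
                 n_leg_configs: int = 6, C: float = 1.0, n_epochs: int = 5,
                 cell: float = 0.03, average: bool = True,
                 shuffle: bool = True, random_state: int = 0):
        self.posture_class = posture_class
        self.n_torso_angles = n_torso_angles
        self.n_torso_lengths = n_torso_lengths
        self.n_head_angles = n_head_angles
        self.n_tail_angles = n_tail_angles
        self.n_leg_configs = n_leg_configs
        self.C = C
        self.n_epochs = n_epochs
        self.cell = cell
        self.average = average
        self.shuffle = shuffle
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    def _features(self, x, motion=None) -> BlobFeatures:
        if isinstance(x, BlobFeatures):
            return x
        if isinstance(x, tuple):
            blob, motion = x
            return BlobFeatures.from_blob(blob, motion, cell=self.cell)
        return BlobFeatures.from_blob(x, motion, cell=self.cell)

    def candidates(self, features: BlobFeatures) -> CandidateSet:
        return generate_candidates(
            features, posture_class=self.posture_class,
            n_torso_angles=self.n_torso_angles,
            n_torso_lengths=self.n_torso_lengths,
            n_head_angles=self.n_head_angles,
            n_tail_angles=self.n_tail_angles,
            n_leg_configs=self.n_leg_configs)

    # -- training ---------------------------------------------------------
    def fit(self, X, y):
        """Train on blobs ``X`` with ground-truth skeletons ``y``.

        ``X`` is a sequence of BlobFeatures, Blob, or (Blob, MotionVector)
        tuples; ``y`` the matching GT skeletons (snapped to the candidate
        grid internally).
        """
        if len(X) == 0:
            raise ValueError("need at least one training pair")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.random_state)
        cache = []
        for x, gt in zip(X, y):
            feats = self._features(x)
            cand = self.candidates(feats)
            blocks = compute_feature_blocks(cand)
            gt_idx = snap_to_grid(cand, gt)
            gt_skel = cand.skeleton(*gt_idx)
            lb = _endpoint_distance_blocks(cand, gt_skel)
            phi_gt = blocks.phi(*gt_idx)
            cache.append((blocks, lb, gt_idx, phi_gt))
        w = np.zeros(FEATURE_DIM)
        w_sum = np.zeros(FEATURE_DIM)
        n_steps = 0
        self.training_loss_ = []
        for _ in range(self.n_epochs):
            order = (rng.permutation(len(cache)) if self.shuffle
                     else np.arange(len(cache)))
            epoch_loss = 0.0
            for i in order:
                blocks, lb, gt_idx, phi_gt = cache[i]
                t, h, ta, g, aug = _factorised_argmax(w, blocks, lb)
                pred_idx = (t, h, ta, g)
                hinge = aug - float(w @ phi_gt)
                epoch_loss += max(hinge, 0.0)
                if pred_idx != gt_idx and hinge > 0:
                    phi_pred = blocks.phi(*pred_idx)
                    diff = phi_gt - phi_pred
                    denom = float(diff @ diff)
                    if denom >= 1e-12:
                        tau = min(self.C, hinge / denom)
                        w = w + tau * diff
                w_sum += w
                n_steps += 1
            self.training_loss_.append(epoch_loss / len(cache))
        # averaged iterate: smoother and markedly more stable than the last
        self.w_ = w_sum / max(n_steps, 1) if self.average else w
        self.n_feature_dim_ = FEATURE_DIM
        self.n_trained_on_ = len(X)
        return self

    # -- inference --------------------------------------------------------
    def infer(self, features: BlobFeatures) -> tuple:
        """Best candidate for one blob: (Skeleton, score, candidate index)."""
        if not hasattr(self, "w_"):
            raise RuntimeError("model is not trained")
        cand = self.candidates(features)
        blocks = compute_feature_blocks(cand)
        t, h, ta, g, total = _factorised_argmax(self.w_, blocks)
        posture = (self.posture_class
                   if self.posture_class in ("stand", "sit", "lie")
                   else "unknown")
        return cand.skeleton(t, h, ta, g, posture), total, cand.ravel(t, h,
                                                                      ta, g)

    def predict(self, X):
        """Skeletons for a sequence of blobs (see :meth:`fit` for formats)."""
        return [self.infer(self._features(x))[0] for x in X]

    def decision_function(self, X):
        return np.array([self.infer(self._features(x))[1] for x in X])


def brute_force_argmax(w: np.ndarray, cand: CandidateSet,
                       blocks: FeatureBlocks = None) -> tuple:
    """Reference inference: score every candidate explicitly.

    Independent of the factorised path; used to audit inference exactness.
    Returns (global index, score).
    """
    if blocks is None:
        blocks = compute_feature_blocks(cand)
    T, nH, nT, nG = cand.shape
    best_idx, best_score = 0, -np.inf
    for t in range(T):
        for h in range(nH):
            for ta in range(nT):
                for g in range(nG):
                    phi = blocks.phi(t, h, ta, g)
                    s = float(w @ phi)
                    if s > best_score:
                        best_score = s
                        best_idx = cand.ravel(t, h, ta, g)
    return best_idx, best_score


def train(pairs, posture_class: str = "bodyparts",
          **hyperparams) -> StructuredBodyPartSVM:
    """Convenience wrapper: fit a structured model from TrainingPair records."""
    if not pairs:
        raise ValueError("need at least one training pair")
    model = StructuredBodyPartSVM(posture_class=posture_class, **hyperparams)
    X = [(p.x, p.motion) if isinstance(p.x, Blob) else p.x for p in pairs]
    y = [p.y for p in pairs]
    return model.fit(X, y)


class PostureClassifier(BaseEstimator):
    """Three per-posture structured models whose best score names the posture.

    One structured SVM is trained per posture (stand, sit, lie), each under
    its own anatomical constraint set.  Because the three models are trained
    independently their raw scores are not on a common scale; a calibration
    layer (an affine per-model score adjustment fit on the training data,
    or a multinomial logistic map over the three scores) makes the argmax
    comparable.  Ties resolve in the order stand > sit > lie.
    """

    CLASSES = ("stand", "sit", "lie")

    def __init__(self, calibration: str = "logistic",
                 n_torso_angles: int = 24, n_torso_lengths: int = 5,
                 n_head_angles: int = 8, n_tail_angles: int = 8,
                 n_leg_configs: int = 6, C: float = 1.0, n_epochs: int = 5,
                 cell: float = 0.03, random_state: int = 0,
                 score_offsets: dict = None):
        self.calibration = calibration
        self.n_torso_angles = n_torso_angles
        self.n_torso_lengths = n_torso_lengths
        self.n_head_angles = n_head_angles
        self.n_tail_angles = n_tail_angles
        self.n_leg_configs = n_leg_configs
        self.C = C
        self.n_epochs = n_epochs
        self.cell = cell
        self.random_state = random_state
        self.score_offsets = score_offsets

    def fit(self, X, y):
        """Train from (blob-or-features, GT skeleton) pairs and labels.

        ``X``: sequence of (Blob | BlobFeatures, Skeleton) or
        (Blob, MotionVector, Skeleton); ``y``: posture labels.
        """
        y = np.asarray(y)
        feats, gts = [], []
        for item in X:
            if len(item) == 3:
                blob, motion, gt = item
                feats.append(BlobFeatures.from_blob(blob, motion,
                                                    cell=self.cell))
            else:
                xi, gt = item
                feats.append(xi if isinstance(xi, BlobFeatures)
                             else BlobFeatures.from_blob(xi, cell=self.cell))
            gts.append(gt)
        self.models_ = {}
        for label in self.CLASSES:
            mask = y == label
            if not np.any(mask):
                raise ValueError(f"no training frames for posture {label!r}")
            model = StructuredBodyPartSVM(
                posture_class=label, n_torso_angles=self.n_torso_angles,
                n_torso_lengths=self.n_torso_lengths,
                n_head_angles=self.n_head_angles,
                n_tail_angles=self.n_tail_angles,
                n_leg_configs=self.n_leg_configs, C=self.C,
                n_epochs=self.n_epochs, cell=self.cell,
                random_state=self.random_state)
            model.fit([f for f, m in zip(feats, mask) if m],
                      [g for g, m in zip(gts, mask) if m])
            self.models_[label] = model
        raw = np.array([self._calibration_inputs(f) for f in feats])
        self.score_offsets_ = {c: 0.0 for c in self.CLASSES}
        if self.score_offsets is not None:
            self.score_offsets_.update(self.score_offsets)
            self.calibrator_ = None
        elif self.calibration == "logistic":
            self.calibration_mean_ = raw.mean(axis=0)
            self.calibration_scale_ = np.maximum(raw.std(axis=0), 1e-9)
            z = (raw - self.calibration_mean_) / self.calibration_scale_
            self.calibrator_ = LogisticRegression(
                max_iter=1000, random_state=self.random_state).fit(z, y)
        elif self.calibration == "offset":
            for j, c in enumerate(self.CLASSES):
                self.score_offsets_[c] = -float(raw[y == c, j].mean())
            self.calibrator_ = None
        elif self.calibration == "none":
            self.calibrator_ = None
        else:
            raise ValueError(f"unknown calibration {self.calibration!r}")
        return self

    def _calibration_inputs(self, feats: BlobFeatures) -> list:
        """Structured scores plus blob geometry covariates.

        The three per-posture scores are not on a common scale (each model
        is trained only within its own class), so the calibrator also sees
        floor-relative blob geometry — barycentre height, top height and
        the blob extents — which carry the posture signal that raw score
        differences cannot.
        """
        scores = [self.models_[c].infer(feats)[1] for c in self.CLASSES]
        return scores + [feats.floor_height, feats.top_height,
                         feats.vertical_extent, feats.horizontal_extent,
                         feats.bottom_height, feats.low_mass_frac]

    def _calibrated_scores(self, raw: np.ndarray) -> np.ndarray:
        if getattr(self, "calibrator_", None) is not None:
            z = (raw - self.calibration_mean_) / self.calibration_scale_
            dec = self.calibrator_.decision_function(z[None])[0]
            cols = {c: j for j, c in enumerate(self.calibrator_.classes_)}
            return np.array([dec[cols[c]] for c in self.CLASSES])
        return (raw[:3]
                + np.array([self.score_offsets_[c] for c in self.CLASSES]))

    def classify(self, blob, motion: MotionVector = None) -> tuple:
        """(posture, Skeleton, per-class score dict) for one frame.

        A ``None`` blob (no detection) yields ('unknown', empty skeleton).
        """
        if not hasattr(self, "models_"):
            raise RuntimeError("classifier is not trained")
        if blob is None:
            return "unknown", Skeleton(segments={}, posture="unknown"), {}
        feats = (blob if isinstance(blob, BlobFeatures)
                 else BlobFeatures.from_blob(blob, motion, cell=self.cell))
        results = {c: self.models_[c].infer(feats) for c in self.CLASSES}
        raw = np.array([results[c][1] for c in self.CLASSES]
                       + [feats.floor_height, feats.top_height,
                          feats.vertical_extent, feats.horizontal_extent,
                          feats.bottom_height, feats.low_mass_frac])
        cal = self._calibrated_scores(raw)
        best = self.CLASSES[int(np.argmax(cal))]
        skel = results[best][0]
        return best, skel, dict(zip(self.CLASSES, cal))

    def predict(self, X):
        """Posture labels for a sequence of blobs / (blob, motion) tuples."""
        labels = []
        for x in X:
            blob, motion = x if isinstance(x, tuple) else (x, None)
            labels.append(self.classify(blob, motion)[0])
        return np.array(labels)


def derive_locomotion(labels, trajectory: Trajectory,
                      speed_threshold: float = 0.1,
                      window_s: float = 0.5) -> np.ndarray:
    """Split locomotion from stand by barycentre speed.

    Frames labelled ``stand`` become ``locomotion`` when the mean speed over
    a centred window of ``window_s`` seconds exceeds ``speed_threshold``
    (m/s); sit and lie are never relabelled.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(trajectory):
        raise ValueError("labels and trajectory length mismatch")
    n = len(labels)
    if n < 2 or not np.isfinite(speed_threshold):
        return labels.copy()
    half = max(int(round(window_s * trajectory.fps / 2)), 1)
    xy = trajectory.xy
    out = labels.copy()
    for i in range(n):
        lo, hi = max(i - half, 0), min(i + half, n - 1)
        dt = trajectory.t[hi] - trajectory.t[lo]
        if dt <= 0:
            continue
        speed = np.linalg.norm(xy[hi] - xy[lo]) / dt
        if labels[i] == "stand" and speed > speed_threshold:
            out[i] = "locomotion"
    return out


# ---------------------------------------------------------------------------
# weight persistence

WEIGHTS_FORMAT_VERSION = 1


def save_weights(model: StructuredBodyPartSVM, path) -> None:
    """Persist trained weights as a versioned flat text file."""
    header = (f"kennelscope-weights v{WEIGHTS_FORMAT_VERSION} "
              f"class={model.posture_class} dim={model.n_feature_dim_} "
              f"trained_on={model.n_trained_on_}")
    np.savetxt(path, model.w_, header=header)


def load_weights(path, **params) -> StructuredBodyPartSVM:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    meta = dict(kv.split("=") for kv in header[2:])
    model = StructuredBodyPartSVM(posture_class=meta["class"], **params)
    model.w_ = np.loadtxt(path)
    model.n_feature_dim_ = int(meta["dim"])
    model.n_trained_on_ = int(meta["trained_on"])
    model.training_loss_ = []
    if model.w_.shape != (model.n_feature_dim_,):
        raise ValueError("weight file dimension mismatch")
    return model
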