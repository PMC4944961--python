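"""Seven-part skeleton representation and its spectral graph descriptor.

A skeleton is a set of seven labelled line segments (head, torso, tail and
four legs) in sensor-frame metres, tagged with a posture label.  Each
segment is stored endpoint-pair ``(attachment, tip)``: the attachment end is
the one joined to the torso (for the torso itself, the rear end comes
first).  Omitted parts (e.g. folded legs in a lying posture) use the
zero-length sentinel: both endpoints equal to the attachment point.

For pose comparison the skeleton is summarised by a junction graph whose
edge weights encode the angles between the body segments meeting along the
torso; the eigenvectors of its normalized Laplacian give a descriptor that
is invariant to rigid rotation and uniform scaling of the animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PART_NAMES = ("head", "torso", "tail", "leg_fl", "leg_fr", "leg_bl", "leg_br")
LEG_NAMES = ("leg_fl", "leg_fr", "leg_bl", "leg_br")
POSTURES = ("stand", "sit", "lie", "locomotion", "unknown")

#: junction order along the torso axis, rear to front is tail .. head
JUNCTION_ORDER = ("head", "leg_fl", "leg_fr", "leg_bl", "leg_br", "tail")


@dataclass
class Skeleton:
    """Labelled body-part segments plus a posture label.

    ``segments`` maps part name -> (2, 3) array of endpoints in metres
    (sensor frame), ordered (attachment, tip).
    """

    segments: dict
    posture: str = "unknown"

    def __post_init__(self):
        if self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")
        for name, seg in self.segments.items():
            if name not in PART_NAMES:
                raise ValueError(f"unknown part {name!r}")
            self.segments[name] = np.asarray(seg, dtype=float).reshape(2, 3)
        if self.segments and "torso" not in self.segments:
            raise ValueError("torso must be present when any part is present")

    def part_length(self, name: str) -> float:
        seg = self.segments[name]
        return float(np.linalg.norm(seg[1] - seg[0]))

    @property
    def is_empty(self) -> bool:
        return not self.segments


@dataclass(frozen=True)
class MotionVector:
    """Ground-plane barycentre displacement between consecutive frames (m)."""

    dx: float = 0.0
    dy: float = 0.0

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dx, self.dy))

    @property
    def array(self) -> np.ndarray:
        return np.array([self.dx, self.dy], dtype=float)


def to_plane(points: np.ndarray) -> np.ndarray:
    """Project sensor-frame points onto the upright image plane.

    Coordinates are (x right, up) in metres; the sensor y axis points down,
    hence the sign flip.  The depth coordinate is dropped.
    """
    pts = np.asarray(points, dtype=float)
    return np.stack([pts[..., 0], -pts[..., 1]], axis=-1)


def _segment_params(seg2d: np.ndarray) -> tuple:
    d = seg2d[1] - seg2d[0]
    length = float(np.linalg.norm(d))
    if length < 1e-12:
        return 0.0, 0.0
    angle = float(np.arctan2(d[1], d[0]))
    if angle <= -np.pi:
        angle = np.pi
    return angle, length


def encode_solution(skeleton: Skeleton, motion: MotionVector) -> np.ndarray:
    """Encode a skeleton + motion vector as the 16-value solution vector.

    Layout: for each of the seven parts in canonical order, the in-plane
    orientation angle (radians, (-pi, pi]) and projected length (metres);
    then the two motion components.  Omitted parts encode as (0, 0).
    """
    values = []
    for name in PART_NAMES:
        if name in skeleton.segments:
            angle, length = _segment_params(to_plane(skeleton.segments[name]))
        else:
            angle, length = 0.0, 0.0
        values.extend([angle, length])
    values.extend([motion.dx, motion.dy])
    return np.array(values, dtype=float)


def decode_solution(vector: np.ndarray, barycentre_plane: np.ndarray,
                    depth: float, posture: str = "unknown",
                    leg_offset_frac: float = 0.05) -> tuple:
    """Reconstruct a skeleton from a solution vector and its torso anchor.

    The torso is centred on ``barycentre_plane``; head and tail attach to
    its front and rear endpoints; legs attach near the torso ends, offset
    inward along the torso axis by ``leg_offset_frac`` of the torso length.
    All parts share the depth coordinate ``depth``.  Returns
    (Skeleton, MotionVector).
    """
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (16,):
        raise ValueError("solution vector must have 16 entries")
    params = {name: (vector[2 * i], vector[2 * i + 1])
              for i, name in enumerate(PART_NAMES)}
    t_angle, t_len = params["torso"]
    t_dir = np.array([np.cos(t_angle), np.sin(t_angle)])
    centre = np.asarray(barycentre_plane, dtype=float)
    rear = centre - 0.5 * t_len * t_dir
    front = centre + 0.5 * t_len * t_dir
    off = leg_offset_frac * t_len * t_dir
    anchors = {"head": front, "tail": rear,
               "leg_fl": front - off, "leg_fr": front - 2 * off,
               "leg_bl": rear + 2 * off, "leg_br": rear + off}
    segs2d = {"torso": np.stack([rear, front])}
    for name, anchor in anchors.items():
        angle, length = params[name]
        tip = anchor + length * np.array([np.cos(angle), np.sin(angle)])
        segs2d[name] = np.stack([anchor, tip])
    segments = {name: np.stack([[s[0, 0], -s[0, 1], depth],
                                [s[1, 0], -s[1, 1], depth]])
                for name, s in segs2d.items()}
    return (Skeleton(segments=segments, posture=posture),
            MotionVector(dx=vector[14], dy=vector[15]))


@dataclass
class SkeletonGraph:
    """Junction graph of a skeleton with angular edge weights.

    Vertices are the six torso junctions (head, four legs, tail).  Two
    junctions are connected when adjacent along the torso axis; the edge
    weight is exp(-dtheta) where dtheta is the unsigned angle between the
    non-torso segments incident at the two junctions.
    """

    vertices: tuple
    W: np.ndarray
    L: np.ndarray = field(default=None)

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if not np.allclose(W, W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        self.W = W
        if self.L is None:
            self.L = normalized_laplacian(W)


def normalized_laplacian(W: np.ndarray) -> np.ndarray:
    """L = I - D^(-1/2) W D^(-1/2) with D the degree (row-sum) matrix."""
    W = np.asarray(W, dtype=float)
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("every vertex needs positive degree")
    inv_sqrt = 1.0 / np.sqrt(deg)
    return np.eye(len(W)) - (inv_sqrt[:, None] * W) * inv_sqrt[None, :]


def _incident_direction(skeleton: Skeleton, part: str,
                        torso_dir: np.ndarray) -> np.ndarray:
    """Outward unit direction of the non-torso segment at a junction.

    Zero-length (omitted) parts fall back to the torso direction, which
    makes the descriptor total over all postures.
    """
    seg = skeleton.segments.get(part)
    if seg is None:
        return torso_dir
    d = seg[1] - seg[0]
    n = np.linalg.norm(d)
    if n < 1e-12:
        return torso_dir
    return d / n


def build_skeleton_graph(skeleton: Skeleton) -> SkeletonGraph:
    """Build the junction graph of one skeleton frame."""
    if "torso" not in skeleton.segments:
        raise ValueError("skeleton graph requires a torso")
    torso = skeleton.segments["torso"]
    t_dir = torso[1] - torso[0]
    n = np.linalg.norm(t_dir)
    if n < 1e-12:
        raise ValueError("torso has zero length")
    t_dir = t_dir / n
    dirs = [_incident_direction(skeleton, part, t_dir)
            for part in JUNCTION_ORDER]
    m = len(JUNCTION_ORDER)
    W = np.zeros((m, m))
    for i in range(m - 1):
        cosang = float(np.clip(np.dot(dirs[i], dirs[i + 1]), -1.0, 1.0))
        dtheta = float(np.arccos(cosang))
        w = float(np.exp(-dtheta))
        W[i, i + 1] = W[i + 1, i] = w
    return SkeletonGraph(vertices=JUNCTION_ORDER, W=W)


def leading_eigenvectors(L: np.ndarray, k: int = 3) -> np.ndarray:
    """First k non-trivial eigenvectors of a normalized Laplacian.

    Eigenvectors are sorted by ascending eigenvalue; the smallest-eigenvalue
    (trivial) component is discarded and the next ``k`` returned as columns.
    Signs are fixed so each vector's largest-magnitude entry is positive,
    making the basis deterministic.
    """
    L = np.asarray(L, dtype=float)
    n = len(L)
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1})")
    vals, vecs = np.linalg.eigh(L)
    order = np.argsort(vals)
    basis = vecs[:, order[1:k + 1]].copy()
    for j in range(basis.shape[1]):
        idx = int(np.argmax(np.abs(basis[:, j])))
        if basis[idx, j] < 0:
            basis[:, j] = -basis[:, j]
    return basis
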