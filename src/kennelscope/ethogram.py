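"""Behavioural report: durations, bouts, activity, distance, grid occupancy.

Turns per-frame posture labels and the ground-plane trajectory into the
quantities an ethologist scores by hand: total duration and bout count per
behaviour, a per-interval breakdown (e.g. every 5 minutes), time spent
moving and distance travelled, and the time spent in each cell of a 3 x 3
grid over the pen floor.  Everything exports to plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depth_scene import Trajectory

ANNOTATION_COLUMNS = ["frame", "time_s", "posture", "x_m", "y_m"]
SUMMARY_COLUMNS = ["label", "duration_s", "bouts", "frames"]
INTERVAL_COLUMNS = ["interval_id", "label", "duration_s"]
GRID_COLUMNS = ["row", "col", "seconds"]

UNSCORED = "unscored"  # frames with no usable posture label


def annotations_frame(frames, times, postures, xy) -> pd.DataFrame:
    """Assemble the canonical per-frame annotation table."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    return pd.DataFrame({"frame": np.asarray(frames, dtype=int),
                         "time_s": np.asarray(times, dtype=float),
                         "posture": list(postures),
                         "x_m": xy[:, 0], "y_m": xy[:, 1]},
                        columns=ANNOTATION_COLUMNS)


@dataclass
class BehaviourSummary:
    """Per-label totals plus the per-interval breakdown."""

    totals: pd.DataFrame      # SUMMARY_COLUMNS
    intervals: pd.DataFrame   # INTERVAL_COLUMNS
    total_duration_s: float
    frame_period_s: float


def _bout_count(labels: np.ndarray, label: str,
                min_bout_frames: int = 1) -> int:
    mask = labels == label
    if not mask.any():
        return 0
    starts = np.flatnonzero(mask & ~np.r_[False, mask[:-1]])
    if min_bout_frames <= 1:
        return len(starts)
    ends = np.flatnonzero(mask & ~np.r_[mask[1:], False])
    return int(np.sum(ends - starts + 1 >= min_bout_frames))


def summarize(annotations: pd.DataFrame, interval_s: float = 300.0,
              fps: float = None, min_bout_s: float = 0.0) -> BehaviourSummary:
    """Durations, bout counts and an interval table for one recording.

    Duration of a label is its frame count times the frame period; a bout
    is a maximal run of identical labels (optionally filtered by a minimum
    bout duration, off by default).  The interval table tiles the video
    with ``interval_s``-second bins, the last possibly short.  Frames
    whose posture is missing or unknown are reported as "unscored" but
    still count toward total time.
    """
    if len(annotations) == 0:
        raise ValueError("annotations must be non-empty")
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    times = np.asarray(annotations["time_s"], dtype=float)
    if fps is None:
        fps = 1.0 / np.median(np.diff(times)) if len(times) > 1 else 1.0
    period = 1.0 / fps
    labels = np.array([p if isinstance(p, str) and p not in ("", "unknown")
                       else UNSCORED for p in annotations["posture"]],
                      dtype=object)
    uniq = sorted(set(labels))
    min_bout_frames = max(int(np.ceil(min_bout_s * fps)), 1)
    rows = []
    for label in uniq:
        n = int(np.sum(labels == label))
        rows.append({"label": label, "duration_s": n * period,
                     "bouts": _bout_count(labels, label, min_bout_frames),
                     "frames": n})
    totals = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    t0 = times[0]
    interval_ids = np.floor((times - t0) / interval_s).astype(int)
    irows = []
    for iid in range(int(interval_ids.max()) + 1):
        in_iv = interval_ids == iid
        for label in uniq:
            n = int(np.sum(in_iv & (labels == label)))
            irows.append({"interval_id": iid, "label": label,
                          "duration_s": n * period})
    intervals = pd.DataFrame(irows, columns=INTERVAL_COLUMNS)
    return BehaviourSummary(totals=totals, intervals=intervals,
                            total_duration_s=len(labels) * period,
                            frame_period_s=period)


def activity_metrics(traj: Trajectory,
                     speed_threshold: float = 0.1) -> tuple:
    """(time moving in seconds, distance travelled in metres).

    Distance is the summed consecutive displacement (path length, not net
    displacement); time moving counts the frame periods whose instantaneous
    speed exceeds the threshold.
    """
    if len(traj) < 2:
        return 0.0, 0.0
    xy = traj.xy
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dts = np.diff(traj.t)
    speeds = steps / dts
    time_moving = float(np.sum(dts[speeds > speed_threshold]))
    return time_moving, float(steps.sum())


def grid_occupancy(traj: Trajectory, pen_bounds,
                   shape=(3, 3)) -> np.ndarray:
    """Seconds spent in each cell of a grid over the pen floor.

    Cells are half-open ``[lo, hi)`` intervals indexed row-major from the
    pen origin (row = y, col = x); positions on the outer boundary are
    credited to the last cell.  Each frame contributes one frame period.
    """
    bw, bh = pen_bounds
    nr, nc = shape
    occ = np.zeros(shape)
    if len(traj) == 0:
        return occ
    period = 1.0 / traj.fps
    cols = np.minimum((np.asarray(traj.x) / (bw / nc)).astype(int), nc - 1)
    rows = np.minimum((np.asarray(traj.y) / (bh / nr)).astype(int), nr - 1)
    np.add.at(occ, (rows, cols), period)
    return occ


def occupancy_frame(occ: np.ndarray) -> pd.DataFrame:
    nr, nc = occ.shape
    rows = [{"row": r, "col": c, "seconds": float(occ[r, c])}
            for r in range(nr) for c in range(nc)]
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def occupancy_from_frame(df: pd.DataFrame) -> np.ndarray:
    nr = int(df["row"].max()) + 1
    nc = int(df["col"].max()) + 1
    occ = np.zeros((nr, nc))
    for _, row in df.iterrows():
        occ[int(row["row"]), int(row["col"])] = row["seconds"]
    return occ


def export_csv(obj, path) -> None:
    """Write annotations / summary / occupancy to CSV (dot decimal, no index).

    Column order is fixed by the schema constants of this module so that
    re-importing round-trips.
    """
    if isinstance(obj, BehaviourSummary):
        obj.totals.to_csv(path, index=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    elif isinstance(obj, np.ndarray):
        occupancy_frame(obj).to_csv(path, index=False)
    else:
        raise TypeError(f"cannot export {type(obj).__name__}")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
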