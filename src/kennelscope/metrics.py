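"""Evaluation surface: PCP, posture confusion and manual-vs-auto agreement.

PCP (Percentage of Correctly estimated body Parts) follows the convention
from human pose estimation: a part counts as correct when both predicted
endpoints lie within ``alpha`` times the ground-truth part length of the
matching ground-truth endpoints (alpha = 0.5 by default).  Confusion
matrices are column-normalised against the ground truth.  Agreement between
automated and manual scoring uses Spearman rank correlation of per-clip
behaviour durations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .skeleton import PART_NAMES, Skeleton, to_plane

POSTURE_LABELS = ("stand", "locomotion", "sit", "lie")


@dataclass
class PCPResult:
    """Fraction of correctly localised parts, per part and overall."""

    per_part: dict            # part -> fraction in [0, 1]
    overall: float            # mean over evaluated parts
    alpha: float
    n_frames: int = 1

    @property
    def percentage(self) -> float:
        return 100.0 * self.overall


def _part_correct(pred_seg: np.ndarray, gt_seg: np.ndarray,
                  alpha: float) -> bool:
    """Endpoint correspondence picks the pairing with smaller summed error."""
    p = to_plane(pred_seg)
    g = to_plane(gt_seg)
    length = np.linalg.norm(g[1] - g[0])
    direct = (np.linalg.norm(p[0] - g[0]), np.linalg.norm(p[1] - g[1]))
    swapped = (np.linalg.norm(p[0] - g[1]), np.linalg.norm(p[1] - g[0]))
    pair = direct if sum(direct) <= sum(swapped) else swapped
    return max(pair) <= alpha * length


def pcp(predicted: Skeleton, gt: Skeleton, alpha: float = 0.5) -> PCPResult:
    """PCP of a single predicted skeleton against its ground truth.

    Parts with zero ground-truth length (omitted parts) are excluded.
    """
    pred_parts = set(predicted.segments)
    gt_parts = set(gt.segments)
    if pred_parts != gt_parts:
        raise ValueError("predicted and GT skeletons carry different parts")
    per_part = {}
    for name in PART_NAMES:
        if name not in gt.segments:
            continue
        if gt.part_length(name) < 1e-9:
            continue
        per_part[name] = float(_part_correct(predicted.segments[name],
                                             gt.segments[name], alpha))
    if not per_part:
        raise ValueError("no parts with positive ground-truth length")
    return PCPResult(per_part=per_part,
                     overall=float(np.mean(list(per_part.values()))),
                     alpha=alpha)


def pcp_frames(predicted, gt, alpha: float = 0.5,
               average: str = "frames") -> PCPResult:
    """PCP over many frames.

    ``average='frames'`` averages parts within each frame first, then over
    frames; ``average='parts'`` pools all parts of all frames.  Both views
    are standard and give identical results when every frame evaluates the
    same part set.
    """
    if average not in ("frames", "parts"):
        raise ValueError("average must be 'frames' or 'parts'")
    results = [pcp(p, g, alpha) for p, g in zip(predicted, gt)]
    per_part = {}
    for name in PART_NAMES:
        vals = [r.per_part[name] for r in results if name in r.per_part]
        if vals:
            per_part[name] = float(np.mean(vals))
    if average == "frames":
        overall = float(np.mean([r.overall for r in results]))
    else:
        pooled = [v for r in results for v in r.per_part.values()]
        overall = float(np.mean(pooled))
    return PCPResult(per_part=per_part, overall=overall, alpha=alpha,
                     n_frames=len(results))


@dataclass
class ConfusionMatrix:
    """Posture confusion: rows are predictions, columns ground truth."""

    counts: np.ndarray        # (4, 4) ints
    labels: tuple = POSTURE_LABELS

    @property
    def percentages(self) -> np.ndarray:
        """Per-cell percentage of the column (ground-truth) total."""
        col = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / col
        return np.where(col > 0, pct, 0.0)

    @property
    def diagonal_accuracy(self) -> dict:
        pct = self.percentages
        return {lab: float(pct[i, i]) for i, lab in enumerate(self.labels)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"pred_{l}" for l in self.labels],
                            columns=[f"gt_{l}" for l in self.labels])


def confusion(pred_labels, gt_labels,
              labels=POSTURE_LABELS) -> ConfusionMatrix:
    """Count-based confusion matrix of per-frame posture labels."""
    pred_labels = list(pred_labels)
    gt_labels = list(gt_labels)
    if len(pred_labels) != len(gt_labels):
        raise ValueError("prediction and ground truth length mismatch")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for p, g in zip(pred_labels, gt_labels):
        if p in index and g in index:
            counts[index[p], index[g]] += 1
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


# ---------------------------------------------------------------------------
# agreement

def spearman_rho(a, b) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return np.nan
    return float(stats.spearmanr(a, b).statistic)


def _exact_permutation_p(a, b, observed: float) -> float:
    """Two-sided p-value over all rank permutations (small n only)."""
    n = len(a)
    count = 0
    total = 0
    b = np.asarray(b, dtype=float)
    for perm in itertools.permutations(range(n)):
        r = spearman_rho(a, b[list(perm)])
        total += 1
        if abs(r) >= abs(observed) - 1e-12:
            count += 1
    return count / total


def spearman_test(a, b, exact_max_n: int = 8) -> tuple:
    """(rho, two-sided p).  Exact permutation p for n <= exact_max_n,
    t-approximation otherwise; (nan, nan) for constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rho = spearman_rho(a, b)
    if np.isnan(rho):
        return np.nan, np.nan
    if len(a) <= exact_max_n:
        return rho, _exact_permutation_p(a, b, rho)
    return rho, float(stats.spearmanr(a, b).pvalue)


@dataclass
class AgreementReport:
    """Per-label rank agreement between automated and manual durations."""

    table: pd.DataFrame       # label, rho, p_value, n_clips
    breakdown: pd.DataFrame   # clip, label, auto_s, gt_s (bar-plot data)


def agreement(auto_durations: pd.DataFrame,
              gt_durations: pd.DataFrame) -> AgreementReport:
    """Spearman agreement across clips, one test per behaviour label.

    Both inputs are tables with one row per clip and one column per
    behaviour label (seconds).  At least 3 clips are required.
    """
    labels = [c for c in auto_durations.columns if c in gt_durations.columns]
    if len(auto_durations) < 3:
        raise ValueError("need at least 3 clips per label")
    rows = []
    breakdown = []
    for label in labels:
        a = np.asarray(auto_durations[label], dtype=float)
        g = np.asarray(gt_durations[label], dtype=float)
        rho, p = spearman_test(a, g)
        rows.append({"label": label, "rho": rho, "p_value": p,
                     "n_clips": len(a)})
        for clip in range(len(a)):
            breakdown.append({"clip": clip, "label": label,
                              "auto_s": float(a[clip]),
                              "gt_s": float(g[clip])})
    return AgreementReport(table=pd.DataFrame(rows),
                           breakdown=pd.DataFrame(breakdown))
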