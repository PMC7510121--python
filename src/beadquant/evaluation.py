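"""Instance-level segmentation evaluation: matching, precision/recall,
per-bead Jaccard, and stratified summaries.

Precision = TP / (TP + FP) and Recall = TP / (TP + FN), where a true
positive is a predicted instance matched one-to-one to a ground-truth
instance by greedy intersection-over-union (Jaccard) matching at a
configurable threshold.  Test populations are additionally stratified
into low (< 100) and high (>= 100) bead-count images to check
segmentation consistency across beading severity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import SegmentationResult
from .errors import FormatError
from .synthetic import Droplet, SyntheticScene

DEFAULT_IOU_MIN = 0.3
STRATA_THRESHOLD = 100


@dataclass
class MatchResult:
    """One-to-one matching between predicted and truth instances."""

    matches: list[tuple[int, int, float]]  # (pred_label, truth_label, iou)
    fp_labels: list[int]
    fn_labels: list[int]
    iou_min: float = DEFAULT_IOU_MIN

    @property
    def n_tp(self) -> int:
        return len(self.matches)

    @property
    def n_fp(self) -> int:
        return len(self.fp_labels)

    @property
    def n_fn(self) -> int:
        return len(self.fn_labels)


@dataclass
class EvaluationScores:
    precision: float  # NaN when undefined (no predictions)
    recall: float
    mean_jaccard: float
    jaccard_sd: float
    per_bead_jaccard: list[float] = field(default_factory=list)

    @property
    def precision_defined(self) -> bool:
        return not math.isnan(self.precision)


def match_instances(
    pred: SegmentationResult,
    truth: SegmentationResult,
    iou_min: float = DEFAULT_IOU_MIN,
) -> MatchResult:
    """Greedy one-to-one IoU matching in descending IoU order.

    All pred x truth IoUs (with overlapping bounding boxes) are computed;
    pairs are accepted greedily by descending IoU (ties broken by
    ascending pred then truth label) while both sides are unmatched and
    IoU >= ``iou_min``.  Leftover predictions are false positives,
    leftover truths false negatives.
    """
    if tuple(pred.source_shape) != tuple(truth.source_shape):
        raise FormatError(
            f"shape mismatch: pred {pred.source_shape} vs truth {truth.source_shape}"
        )
    pairs: list[tuple[float, int, int]] = []
    for p in pred.instances:
        for t in truth.instances:
            iou = p.iou(t)
            if iou >= iou_min:
                pairs.append((iou, p.label_id, t.label_id))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for iou, pl, tl in pairs:
        if pl in used_p or tl in used_t:
            continue
        used_p.add(pl)
        used_t.add(tl)
        matches.append((pl, tl, iou))
    fp = [p.label_id for p in pred.instances if p.label_id not in used_p]
    fn = [t.label_id for t in truth.instances if t.label_id not in used_t]
    return MatchResult(matches=matches, fp_labels=fp, fn_labels=fn, iou_min=iou_min)


def optimal_match_counts(
    pred: SegmentationResult,
    truth: SegmentationResult,
    iou_min: float = DEFAULT_IOU_MIN,
) -> tuple[int, float]:
    """Brute-force optimal one-to-one assignment: (max matches, best total
    IoU among maximum matchings).  Exponential; intended as an independent
    oracle on small fixtures only."""
    preds = pred.instances
    truths = truth.instances
    iou = {
        (p.label_id, t.label_id): p.iou(t)
        for p in preds
        for t in truths
        if p.iou(t) >= iou_min
    }
    best = (0, 0.0)
    t_labels = [t.label_id for t in truths]
    for r in range(min(len(preds), len(truths)), -1, -1):
        found = False
        for p_subset in itertools.combinations([p.label_id for p in preds], r):
            for t_perm in itertools.permutations(t_labels, r):
                if all((pl, tl) in iou for pl, tl in zip(p_subset, t_perm)):
                    total = sum(iou[(pl, tl)] for pl, tl in zip(p_subset, t_perm))
                    if (r, total) > best:
                        best = (r, total)
                    found = True
        if found:
            break  # no larger matching exists
    return best


def score(match: MatchResult) -> EvaluationScores:
    """Precision/recall per their defining ratios plus matched-pair
    Jaccard statistics.  Precision is NaN-flagged when there are no
    predictions; recall is 0 when truths exist but none are found."""
    tp, fp, fn = match.n_tp, match.n_fp, match.n_fn
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    jaccards = [iou for _, _, iou in match.matches]
    if jaccards:
        mean_j = float(np.mean(jaccards))
        sd_j = float(np.std(jaccards, ddof=1)) if len(jaccards) > 1 else 0.0
    else:
        mean_j, sd_j = float("nan"), float("nan")
    return EvaluationScores(
        precision=precision,
        recall=recall,
        mean_jaccard=mean_j,
        jaccard_sd=sd_j,
        per_bead_jaccard=jaccards,
    )


def evaluate_pair(
    pred: SegmentationResult,
    truth: SegmentationResult,
    iou_min: float = DEFAULT_IOU_MIN,
) -> EvaluationScores:
    return score(match_instances(pred, truth, iou_min=iou_min))


def _mean_sem(values: list[float]) -> dict[str, float]:
    arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if arr.size == 0:
        return {"mean": float("nan"), "sem": float("nan"), "n": 0}
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "sem": sd / math.sqrt(arr.size), "n": int(arr.size)}


def stratified_report(
    scores_with_counts: list[tuple[EvaluationScores, int]],
    strata_threshold: int = STRATA_THRESHOLD,
) -> dict[str, dict[str, dict[str, float]]]:
    """Mean +/- SEM of precision and recall per bead-count stratum.

    Images are split into a low (< threshold) and a high (>= threshold)
    truth-bead-count stratum; empty strata are omitted from the report.
    """
    groups: dict[str, list[EvaluationScores]] = {"low": [], "high": [], "overall": []}
    for sc, count in scores_with_counts:
        groups["overall"].append(sc)
        groups["low" if count < strata_threshold else "high"].append(sc)
    report: dict[str, dict[str, dict[str, float]]] = {}
    for name, members in groups.items():
        if not members:
            continue
        report[name] = {
            "precision": _mean_sem([m.precision for m in members]),
            "recall": _mean_sem([m.recall for m in members]),
        }
    return report


def droplet_rejection_rate(pred: SegmentationResult, droplets: list[Droplet]) -> float:
    """1 - (droplets detected) / (droplets placed).

    Droplets are known only for synthetic scenes; one counts as detected
    when some predicted mask covers its center pixel.  This is the
    synthetic analogue of correctly ignoring autofluorescent lipid
    droplets (the "true negative" confounders).
    """
    if not droplets:
        return float("nan")
    detected = 0
    for d in droplets:
        r, c = int(round(d.center[0])), int(round(d.center[1]))
        for inst in pred.instances:
            r0, r1, c0, c1 = inst.bbox
            if r0 <= r < r1 and c0 <= c < c1 and inst.crop[r - r0, c - c0]:
                detected += 1
                break
    return 1.0 - detected / len(droplets)


def evaluate_scene(scene: SyntheticScene, pred: SegmentationResult, iou_min: float = DEFAULT_IOU_MIN):
    """(scores, truth bead count, droplet rejection rate) for one scene."""
    sc = evaluate_pair(pred, scene.truth, iou_min=iou_min)
    return sc, len(scene.truth), droplet_rejection_rate(pred, scene.droplets)
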