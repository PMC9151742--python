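"""Scoring of tracked fire perimeters against reference perimeter sets.

The comparison is area-based: inside a fixed region, every point is either
burned or unburned according to each source, giving a 2x2 confusion matrix
of areas (TN, FP, FN, TP) from which the usual agreement metrics follow —
burned-area ratio, accuracy, precision, recall, intersection-over-union
and F1.  Scores can be computed regionally (all perimeters pooled) or per
reference fire, where each reference fire is compared against the union of
the tracked fires that spatially overlap it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union


@dataclass
class ConfusionMatrix:
    """Burned/unburned confusion matrix of areas (any consistent unit)."""

    TN: float
    FP: float
    FN: float
    TP: float

    def __post_init__(self):
        for name in ("TN", "FP", "FN", "TP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def pred_burned(self) -> float:
        """Total burned area according to the tracked perimeters (FP+TP)."""
        return self.FP + self.TP

    @property
    def ref_burned(self) -> float:
        """Total burned area according to the reference (FN+TP)."""
        return self.FN + self.TP

    @property
    def area_total(self) -> float:
        return self.TN + self.FP + self.FN + self.TP


@dataclass
class PerimeterScores:
    """Agreement metrics; undefined entries (zero denominator) are None."""

    ratio: float | None
    accuracy: float | None
    precision: float | None
    recall: float | None
    iou: float | None
    f1: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {"ratio": self.ratio, "accuracy": self.accuracy,
                "precision": self.precision, "recall": self.recall,
                "iou": self.iou, "f1": self.f1}


def area_confusion(pred: BaseGeometry, ref: BaseGeometry,
                   region: BaseGeometry) -> ConfusionMatrix:
    """Confusion matrix of areas between predicted and reference burned
    polygons inside ``region`` (all in the same equal-area plane).

    TP is the predicted-and-reference overlap, FP predicted-only,
    FN reference-only, and TN the remainder of the region; the four cells
    sum to the region area exactly (to clipping tolerance)."""
    pred_u = unary_union([pred]) if not pred.is_empty else pred
    ref_u = unary_union([ref]) if not ref.is_empty else ref
    if not region.covers(unary_union([pred_u, ref_u]).buffer(-1e-9)):
        raise ValueError("region must cover the union of pred and ref polygons")
    tp = pred_u.intersection(ref_u).area
    fp = pred_u.difference(ref_u).area
    fn = ref_u.difference(pred_u).area
    tn = region.area - tp - fp - fn
    return ConfusionMatrix(TN=max(tn, 0.0), FP=fp, FN=fn, TP=tp)


def perimeter_scores(cm: ConfusionMatrix) -> PerimeterScores:
    """Agreement metrics from a confusion matrix.

    ratio = pred burned / ref burned; accuracy = (TP+TN)/total;
    precision = TP/(TP+FP); recall = TP/(TP+FN); iou = TP/(TP+FP+FN);
    f1 = harmonic mean of precision and recall.  Any metric whose
    denominator is zero is reported as None."""
    def _div(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    precision = _div(cm.TP, cm.pred_burned)
    recall = _div(cm.TP, cm.ref_burned)
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    return PerimeterScores(
        ratio=_div(cm.pred_burned, cm.ref_burned),
        accuracy=_div(cm.TP + cm.TN, cm.area_total),
        precision=precision,
        recall=recall,
        iou=_div(cm.TP, cm.TP + cm.FP + cm.FN),
        f1=f1,
    )


def match_by_overlap(
    pred_fires: dict[int, BaseGeometry],
    ref_fires: dict[int, BaseGeometry],
) -> tuple[dict[int, set[int]], set[int], set[int]]:
    """Match tracked fires to reference fires by positive area overlap.

    Returns ``(mapping, unmatched_ref, unmatched_pred)`` where ``mapping``
    sends each reference id to the set of tracked ids overlapping it.  A
    tracked fire may overlap (and be mapped to) several reference fires."""
    mapping: dict[int, set[int]] = {}
    matched_pred: set[int] = set()
    for rid, rgeom in ref_fires.items():
        hits = {pid for pid, pgeom in pred_fires.items()
                if pgeom.intersection(rgeom).area > 0}
        if hits:
            mapping[rid] = hits
            matched_pred |= hits
    unmatched_ref = set(ref_fires) - set(mapping)
    unmatched_pred = set(pred_fires) - matched_pred
    return mapping, unmatched_ref, unmatched_pred


@dataclass
class ScoreSummary:
    """Mean and 1-sigma spread of per-fire scores over reference fires."""

    mean: PerimeterScores
    sd: PerimeterScores
    n: int


def per_fire_scores(
    mapping: dict[int, set[int]],
    pred_fires: dict[int, BaseGeometry],
    ref_fires: dict[int, BaseGeometry],
) -> ScoreSummary:
    """Score each reference fire against the union of its matched tracked
    fires; report the mean and population standard deviation over
    reference fires.  Per-fire accuracy is undefined (there is no per-fire
    background region) and reported as None."""
    if not mapping:
        raise ValueError("mapping is empty: no reference fire has a match")
    per_metric: dict[str, list[float]] = {
        m: [] for m in ("ratio", "precision", "recall", "iou", "f1")}
    for rid, pids in mapping.items():
        ref = ref_fires[rid]
        pred = unary_union([pred_fires[p] for p in pids])
        tp = pred.intersection(ref).area
        # full coverage can leave a ~1e-9 negative residue from clipping
        cm = ConfusionMatrix(TN=0.0, FP=max(pred.area - tp, 0.0),
                             FN=max(ref.area - tp, 0.0), TP=tp)
        s = perimeter_scores(cm)
        for m in per_metric:
            v = getattr(s, m)
            if v is not None:
                per_metric[m].append(v)

    def _stat(fn) -> PerimeterScores:
        vals = {m: (fn(v) if v else None) for m, v in per_metric.items()}
        return PerimeterScores(ratio=vals["ratio"], accuracy=None,
                               precision=vals["precision"], recall=vals["recall"],
                               iou=vals["iou"], f1=vals["f1"])

    mean = _stat(lambda v: float(np.mean(v)))
    sd = _stat(lambda v: float(np.std(v)))  # population sd
    return ScoreSummary(mean=mean, sd=sd, n=len(mapping))
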