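"""Evaluation metrics: pixel confusion counts, accuracy / specificity /
precision / recall / F1, Dice, panoptic quality, and precision–recall sweeps.

Pixel metrics binarize both prediction and ground truth to tooth-class
pixels versus everything else, which keeps them comparable with binary
segmentation baselines.  Dataset-level numbers are means over images, not
pooled pixels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .inference import PanopticResult, assign_pixels, decide_classes
from .model import ModelOutput
from .phantom import PanopticSample
from .vocab import DEFAULT_VOCABULARY, Vocabulary

__all__ = ["MetricReport", "confusion", "metrics", "dice_from_counts",
           "panoptic_quality", "evaluate_sample", "pr_curve",
           "pr_curve_to_csv", "aggregate_reports"]


@dataclass
class MetricReport:
    """Pixel confusion counts and the derived metric suite.

    ``undefined_flags`` lists metrics whose denominator was zero; those are
    reported as 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    specificity: float
    precision: float
    recall: float
    f1: float
    dice: float
    pq: float = 0.0
    sq: float = 0.0
    rq: float = 0.0
    undefined_flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["undefined_flags"] = list(self.undefined_flags)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MetricReport":
        d = json.loads(Path(path).read_text())
        d["undefined_flags"] = tuple(d["undefined_flags"])
        return cls(**d)

    def as_table(self) -> str:
        rows = [("TP", self.tp), ("TN", self.tn), ("FP", self.fp),
                ("FN", self.fn), ("accuracy", self.accuracy),
                ("specificity", self.specificity),
                ("precision", self.precision), ("recall", self.recall),
                ("F1", self.f1), ("Dice", self.dice),
                ("PQ", self.pq), ("SQ", self.sq), ("RQ", self.rq)]
        width = max(len(k) for k, _ in rows)
        lines = [f"{k:<{width}}  " + (f"{v:.4f}" if isinstance(v, float)
                                      else str(v)) for k, v in rows]
        return "\n".join(lines)


def _tooth_mask_pred(pred: PanopticResult, vocab: Vocabulary) -> np.ndarray:
    mask = np.zeros(pred.id_map.shape, dtype=bool)
    for seg in pred.segments:
        if vocab.is_thing(seg.category_id):
            mask |= pred.id_map == seg.id
    return mask


def _tooth_mask_truth(truth: PanopticSample, vocab: Vocabulary) -> np.ndarray:
    mask = np.zeros(truth.image.shape, dtype=bool)
    for i in truth.thing_indices(vocab):
        mask |= truth.masks[i].astype(bool)
    return mask


def confusion(pred: PanopticResult, truth: PanopticSample,
              vocab: Vocabulary = DEFAULT_VOCABULARY
              ) -> tuple[int, int, int, int]:
    """Pixel (TP, TN, FP, FN) after binarizing to tooth vs everything else."""
    if pred.id_map.shape != truth.image.shape:
        raise ValueError(
            f"shape mismatch: prediction {pred.id_map.shape} vs ground truth "
            f"{truth.image.shape}")
    p = _tooth_mask_pred(pred, vocab)
    t = _tooth_mask_truth(truth, vocab)
    tp = int((p & t).sum())
    tn = int((~p & ~t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    return tp, tn, fp, fn


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(tp: int, tn: int, fp: int, fn: int) -> MetricReport:
    """Accuracy, specificity, precision, recall, F1 and Dice from counts.

    Ratios with a zero denominator are reported as 0 and flagged.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    flags: list[str] = []
    accuracy = _ratio(tp + tn, tp + fn + tn + fp, "accuracy", flags)
    specificity = _ratio(tn, tn + fp, "specificity", flags)
    precision = _ratio(tp, tp + fp, "precision", flags)
    recall = _ratio(tp, tp + fn, "recall", flags)
    f1 = _ratio(2.0 * precision * recall, precision + recall, "f1", flags)
    dice = _ratio(2.0 * tp, 2.0 * tp + fp + fn, "dice", flags)
    return MetricReport(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=accuracy,
                        specificity=specificity, precision=precision,
                        recall=recall, f1=f1, dice=dice,
                        undefined_flags=tuple(flags))


def dice_from_counts(tp: int, fp: int, fn: int) -> float:
    den = 2 * tp + fp + fn
    return 2.0 * tp / den if den else 0.0


# --------------------------------------------------------------------------
# panoptic quality
# --------------------------------------------------------------------------

def _segments_as_masks(id_map: np.ndarray, seg_ids: list[int]) -> np.ndarray:
    return np.stack([id_map == sid for sid in seg_ids]) if seg_ids else \
        np.zeros((0, *id_map.shape), dtype=bool)


def panoptic_quality(pred: PanopticResult, truth: PanopticSample,
                     vocab: Vocabulary = DEFAULT_VOCABULARY
                     ) -> tuple[float, float, float]:
    """(PQ, SQ, RQ) with the standard unique matching at IoU > 0.5.

    Segments of the same category match when their IoU exceeds 0.5 (such
    matches are provably one-to-one).  SQ is the mean IoU over matches, RQ
    the segment-level F1 ``TP / (TP + FP/2 + FN/2)``, and PQ their product.
    """
    if pred.id_map.shape != truth.image.shape:
        raise ValueError("prediction and ground truth differ in size")
    pred_info = [(seg.id, seg.category_id) for seg in pred.segments]
    pred_masks = _segments_as_masks(pred.id_map,
                                    [sid for sid, _ in pred_info])
    truth_masks = truth.masks.astype(bool)
    n_pred, n_truth = len(pred_info), len(truth_masks)
    matched_ious: list[float] = []
    used_pred: set[int] = set()
    for ti in range(n_truth):
        t_mask = truth_masks[ti]
        t_cat = int(truth.classes[ti])
        for pi in range(n_pred):
            if pi in used_pred or pred_info[pi][1] != t_cat:
                continue
            inter = int((t_mask & pred_masks[pi]).sum())
            if inter == 0:
                continue
            union = int((t_mask | pred_masks[pi]).sum())
            iou = inter / union
            if iou > 0.5:
                matched_ious.append(iou)
                used_pred.add(pi)
                break
    tp = len(matched_ious)
    fp = n_pred - tp
    fn = n_truth - tp
    sq = float(np.mean(matched_ious)) if matched_ious else 0.0
    den = tp + 0.5 * fp + 0.5 * fn
    rq = tp / den if den else 0.0
    return sq * rq, sq, rq


def evaluate_sample(pred: PanopticResult, truth: PanopticSample,
                    vocab: Vocabulary = DEFAULT_VOCABULARY) -> MetricReport:
    """Full per-image report: pixel metrics plus PQ/SQ/RQ."""
    report = metrics(*confusion(pred, truth, vocab))
    pq, sq, rq = panoptic_quality(pred, truth, vocab)
    report.pq, report.sq, report.rq = pq, sq, rq
    return report


def aggregate_reports(reports: list[MetricReport]) -> MetricReport:
    """Mean-over-images aggregation (counts are summed, metrics averaged)."""
    if not reports:
        raise ValueError("no reports to aggregate")

    def mean(attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in reports]))

    return MetricReport(
        tp=sum(r.tp for r in reports), tn=sum(r.tn for r in reports),
        fp=sum(r.fp for r in reports), fn=sum(r.fn for r in reports),
        accuracy=mean("accuracy"), specificity=mean("specificity"),
        precision=mean("precision"), recall=mean("recall"), f1=mean("f1"),
        dice=mean("dice"), pq=mean("pq"), sq=mean("sq"), rq=mean("rq"),
        undefined_flags=tuple(sorted({f for r in reports
                                      for f in r.undefined_flags})))


# --------------------------------------------------------------------------
# precision–recall sweep
# --------------------------------------------------------------------------

def pr_curve(outputs: list[ModelOutput], truths: list[PanopticSample],
             thresholds: list[float], class_threshold: float = 0.4,
             vocab: Vocabulary = DEFAULT_VOCABULARY
             ) -> list[tuple[float, float, float]]:
    """Sweep the pixel-confidence threshold; returns (t, precision, recall).

    Pixel assignment is rerun at every threshold; precision and recall are
    the per-image tooth-vs-rest values averaged over images.  An image with
    no predicted tooth pixels contributes precision 1 (nothing asserted,
    nothing wrong).
    """
    if not thresholds:
        raise ValueError("thresholds must be a non-empty list")
    if list(thresholds) != sorted(set(thresholds)):
        raise ValueError("thresholds must be strictly increasing")
    if any(not 0.0 <= t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    if len(outputs) != len(truths):
        raise ValueError("outputs and truths differ in length")
    kept_per_image = [decide_classes(o.class_probs) for o in outputs]
    points = []
    for t in thresholds:
        precisions, recalls = [], []
        for out, truth, kept in zip(outputs, truths, kept_per_image):
            id_map = assign_pixels(out.mask_scores, kept,
                                   class_threshold=class_threshold,
                                   pixel_threshold=t, full_hw=out.image_hw)
            pred_tooth = id_map > 0
            true_tooth = _tooth_mask_truth(truth, vocab)
            tp = int((pred_tooth & true_tooth).sum())
            fp = int((pred_tooth & ~true_tooth).sum())
            fn = int((~pred_tooth & true_tooth).sum())
            precisions.append(tp / (tp + fp) if tp + fp else 1.0)
            recalls.append(tp / (tp + fn) if tp + fn else 1.0)
        points.append((float(t), float(np.mean(precisions)),
                       float(np.mean(recalls))))
    return points


def pr_curve_to_csv(points: list[tuple[float, float, float]],
                    path: str | Path) -> None:
    lines = ["threshold,precision,recall"]
    lines += [f"{t:.6f},{p:.6f},{r:.6f}" for t, p, r in points]
    Path(path).write_text("\n".join(lines) + "\n")
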