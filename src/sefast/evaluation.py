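"""Detection-style evaluation: IoU, precision/recall, AP and mAP@0.5.

A prediction is a box with one confidence per class; for each class every
(box, score) pair is treated as a detection and matched greedily against
the ground-truth boxes carrying that class label at an IoU threshold
(default 0.5, each ground-truth box matchable once).  Average precision is
the area under the resulting precision–recall curve with all-point
interpolation (the precision envelope integrated over recall), and mAP is
the mean over classes with positive support.  Because the label set is
multi-label, the summary also reports thresholded per-class precision,
recall and accuracy at a 0.5 score cut — a second reading of per-class
performance alongside AP.

The module also hosts the desk-scale comparison harness that trains the
tiny network per (SE placement, loss, focal exponent) cell on a synthetic
corpus and tabulates per-class metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .detection import DetectorSpec, oracle_detect
from .formats import AVARecord, BoundingBox, LabelMap
from .losses import LossConfig, compute_class_weights, make_loss
from .network import NetConfig, SEFastNet, fit
from .pipeline import ClipDataset, clip_dataset, split_dataset

__all__ = [
    "iou",
    "ConfusionCounts",
    "precision_recall",
    "average_precision",
    "PredictedBox",
    "ClassMetrics",
    "EvalSummary",
    "evaluate",
    "train_and_evaluate",
    "compare_losses",
]


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area over union area of two boxes; 0 when disjoint."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); empty denominators give 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return p, r


def average_precision(
    detections: Sequence[tuple[float, tuple, BoundingBox]],
    gts: Mapping[tuple, Sequence[BoundingBox]],
    iou_thr: float = 0.5,
) -> float:
    """All-point-interpolated AP for one class.

    ``detections`` are (score, group_key, box) with group_key identifying the
    frame (e.g. (video_id, second)); ``gts`` maps group keys to that frame's
    ground-truth boxes for the class.  Detections sweep in descending score
    (ties broken by input order); each ground-truth box is matchable once.
    """
    n_gt = sum(len(v) for v in gts.values())
    if n_gt == 0 or not detections:
        return 0.0
    order = sorted(range(len(detections)), key=lambda i: (-detections[i][0], i))
    taken: set[tuple] = set()
    tp_flags = np.zeros(len(order), dtype=bool)
    for rank, i in enumerate(order):
        _, key, box = detections[i]
        best_j, best_iou = None, iou_thr
        for j, gt_box in enumerate(gts.get(key, ())):
            if (key, j) in taken:
                continue
            v = iou(box, gt_box)
            if v > best_iou or (v == best_iou and best_j is None and v >= iou_thr):
                best_j, best_iou = j, v
        if best_j is not None:
            taken.add((key, best_j))
            tp_flags[rank] = True
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope, integrated over recall (all-point interpolation)
    mrec = np.concatenate(([0.0], recall, [recall[-1]]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


@dataclass(frozen=True)
class PredictedBox:
    """One predicted box with per-class confidences.

    ``box_score`` is the detector confidence; the detection score used for a
    class's AP sweep is ``box_score · scores[c]``.
    """

    video_id: str
    timestamp_s: int
    box: BoundingBox
    scores: tuple[float, ...]
    box_score: float = 1.0


@dataclass(frozen=True)
class ClassMetrics:
    ap: float
    precision: float
    recall: float
    accuracy: float
    support: int


@dataclass
class EvalSummary:
    per_class: dict[str, ClassMetrics]
    mAP: float
    iou_threshold: float = 0.5

    def minority_posture_recall(self, labels: LabelMap) -> float:
        """Mean thresholded recall over the two recumbent (minority) postures."""
        from .formats import LATERAL, STERNAL

        return float(np.mean([self.per_class[STERNAL].recall,
                              self.per_class[LATERAL].recall]))

    def macro_posture_recall(self, labels: LabelMap) -> float:
        names = [labels.by_id(i).name for i in labels.posture_ids]
        return float(np.mean([self.per_class[n].recall for n in names]))


def evaluate(predictions: Sequence[PredictedBox], gts: Sequence[AVARecord],
             labels: LabelMap, iou_thr: float = 0.5,
             score_threshold: float = 0.5) -> EvalSummary:
    """Score box-level multi-label predictions against annotations.

    AP follows the detection protocol above.  The thresholded metrics first
    associate predicted boxes with annotated entities (greedy IoU at
    ``iou_thr``, ordered by ``box_score``): precision/recall per class count
    a matched pair as TP when the class score clears ``score_threshold`` and
    the label is present; annotated entities with no associated prediction
    count as FN for each of their labels; accuracy is the fraction of
    associated pairs whose thresholded decision equals the label.
    """
    if not gts:
        raise ValueError("cannot evaluate against an empty ground-truth set")
    n_classes = len(labels)

    # --- per-class AP over all (box, class, score) detections
    per_class_ap = {}
    support = {}
    for entry in labels:
        cls_dets = [
            (p.box_score * p.scores[entry.id - 1], (p.video_id, p.timestamp_s), p.box)
            for p in predictions
        ]
        cls_gts: dict[tuple, list[BoundingBox]] = {}
        for rec in gts:
            if rec.action_id == entry.id:
                cls_gts.setdefault((rec.video_id, rec.timestamp_s), []).append(rec.box)
        support[entry.name] = sum(len(v) for v in cls_gts.values())
        per_class_ap[entry.name] = (
            average_precision(cls_dets, cls_gts, iou_thr) if support[entry.name] else 0.0
        )

    # --- thresholded association metrics
    gt_groups: dict[tuple[str, int], dict[int, tuple[BoundingBox, set[int]]]] = {}
    for rec in gts:
        slot = gt_groups.setdefault((rec.video_id, rec.timestamp_s), {})
        box, actions = slot.setdefault(rec.entity_id, (rec.box, set()))
        actions.add(rec.action_id)

    order = sorted(range(len(predictions)),
                   key=lambda i: (-predictions[i].box_score, i))
    taken: set[tuple[str, int, int]] = set()
    pairs: list[tuple[PredictedBox, set[int]]] = []
    unmatched_preds: list[PredictedBox] = []
    for i in order:
        p = predictions[i]
        slot = gt_groups.get((p.video_id, p.timestamp_s), {})
        best_e, best_v = None, iou_thr
        for entity_id, (box, _) in sorted(slot.items()):
            if (p.video_id, p.timestamp_s, entity_id) in taken:
                continue
            v = iou(p.box, box)
            if v > best_v or (v == best_v and best_e is None and v >= iou_thr):
                best_e, best_v = entity_id, v
        if best_e is None:
            unmatched_preds.append(p)
        else:
            taken.add((p.video_id, p.timestamp_s, best_e))
            pairs.append((p, slot[best_e][1]))
    missed_labels: list[set[int]] = [
        actions
        for (video_id, sec), slot in gt_groups.items()
        for entity_id, (box, actions) in slot.items()
        if (video_id, sec, entity_id) not in taken
    ]

    per_class = {}
    ap_values = []
    for entry in labels:
        tp = fp = fn = correct = 0
        for p, actions in pairs:
            pred_pos = p.scores[entry.id - 1] >= score_threshold
            actual = entry.id in actions
            tp += pred_pos and actual
            fp += pred_pos and not actual
            fn += (not pred_pos) and actual
            correct += pred_pos == actual
        for p in unmatched_preds:
            fp += p.scores[entry.id - 1] >= score_threshold
        for actions in missed_labels:
            fn += entry.id in actions
        p_val, r_val = precision_recall(ConfusionCounts(tp, fp, fn))
        accuracy = correct / len(pairs) if pairs else 0.0
        per_class[entry.name] = ClassMetrics(
            ap=per_class_ap[entry.name],
            precision=p_val,
            recall=r_val,
            accuracy=accuracy,
            support=support[entry.name],
        )
        if support[entry.name] > 0:
            ap_values.append(per_class_ap[entry.name])
    mAP = float(np.mean(ap_values)) if ap_values else 0.0
    return EvalSummary(per_class=per_class, mAP=mAP, iou_threshold=iou_thr)


# ---------------------------------------------------------------------------
# desk-scale training/evaluation harness


def _loss_config(kind: str, r: int, train_y: np.ndarray) -> LossConfig:
    if kind.startswith("cw"):
        counts = train_y.sum(axis=0).astype(int)
        return LossConfig(kind=kind, r=r, weights=compute_class_weights(counts))
    return LossConfig(kind=kind, r=r)


def train_and_evaluate(corpus, net_cfg: NetConfig, loss_kind: str = "cw_f",
                       r: int = 2, seed: int = 0, epochs: int = 5,
                       batch_size: int = 16, lr: float = 3e-3,
                       downsample: int = 8, augment: float = 0.25,
                       detector: DetectorSpec | None = None,
                       data: ClipDataset | None = None) -> dict:
    """Train the network on a corpus and evaluate on the held-out split.

    Returns a dict with the trained ``net``, the classifier-only summary
    (``summary`` — ground-truth boxes as input, the protocol used for the
    loss/placement comparison) and, when a ``detector`` is supplied, the
    end-to-end summary (``summary_detected``) where the recognizer runs on
    detector boxes and entities the detector missed count as undetected.
    """
    from .network import predict_proba

    data = data if data is not None else clip_dataset(corpus, downsample=downsample)
    train_idx, test_idx = split_dataset(range(len(data)), seed=seed)
    train_set = data.subset(train_idx)
    test_set = data.subset(test_idx)
    loss_cfg = _loss_config(loss_kind, r, train_set.y)
    net = SEFastNet(net_cfg, seed=seed)
    history = fit(net, train_set, make_loss(loss_cfg), epochs=epochs,
                  batch_size=batch_size, lr=lr, seed=seed, augment=augment)

    test_keys = set(test_set.keys)
    test_records = [rec for rec in corpus.records
                    if (rec.video_id, rec.timestamp_s) in test_keys]

    probs = predict_proba(net, test_set)
    predictions = [
        PredictedBox(video_id, sec, BoundingBox(*test_set.boxes[i]),
                     tuple(float(v) for v in probs[i]))
        for i, (video_id, sec) in enumerate(test_set.keys)
    ]
    summary = evaluate(predictions, test_records, corpus.labels)
    out = {"net": net, "history": history, "summary": summary,
           "n_train": len(train_set), "n_test": len(test_set)}

    if detector is not None:
        detections = oracle_detect(test_records, detector)
        key_to_idx = {key: i for i, key in enumerate(test_set.keys)}
        det_predictions = []
        batch_items = [d for d in detections
                       if (d.video_id, d.timestamp_s) in key_to_idx]
        if batch_items:
            slow, fast, _, _ = test_set.tensors(
                [key_to_idx[(d.video_id, d.timestamp_s)] for d in batch_items]
            )
            rois = [(i, *d.box.as_tuple()) for i, d in enumerate(batch_items)]
            det_probs = net.predict_proba(slow, fast, rois)
            det_predictions = [
                PredictedBox(d.video_id, d.timestamp_s, d.box,
                             tuple(float(v) for v in det_probs[i]),
                             box_score=d.score)
                for i, d in enumerate(batch_items)
            ]
        out["summary_detected"] = evaluate(det_predictions, test_records, corpus.labels)
        out["detections"] = detections
    return out


def compare_losses(corpus, net_cfg: NetConfig,
                   losses: Sequence[str] = ("bce_f", "cw_f"),
                   r_values: Sequence[int] = (2, 3, 4),
                   placements: Sequence[str] = ("end",),
                   seeds: Sequence[int] = (0, 1, 2),
                   epochs: int = 5, out_dir: str | Path | None = None,
                   **train_kw):
    """Grid harness over (SE placement × loss × focal exponent × seed).

    Each cell trains the network from scratch on the corpus and reports both
    thresholded per-class accuracy/recall and per-class AP (the two candidate
    readings of a per-class score).  With ``out_dir`` the harness is
    resumable: finished cells are stored as JSON and skipped on re-run.
    Returns a pandas DataFrame with one row per cell.
    """
    import pandas as pd
    from dataclasses import replace as dc_replace

    data = clip_dataset(corpus, downsample=train_kw.pop("downsample", 8))
    rows = []
    for placement in placements:
        cfg = dc_replace(net_cfg, se_placement=placement)
        for loss_kind in losses:
            for r in r_values:
                for seed in seeds:
                    cell_id = f"{placement}_{loss_kind}_r{r}_s{seed}"
                    cache = Path(out_dir) / f"{cell_id}.json" if out_dir else None
                    if cache is not None and cache.exists():
                        rows.append(json.loads(cache.read_text()))
                        continue
                    try:
                        res = train_and_evaluate(
                            corpus, cfg, loss_kind=loss_kind, r=r, seed=seed,
                            epochs=epochs, data=data, **train_kw
                        )
                    except ValueError as exc:
                        import logging

                        logging.getLogger(__name__).warning(
                            "skipping infeasible cell %s: %s", cell_id, exc)
                        continue
                    summary: EvalSummary = res["summary"]
                    row = {
                        "placement": placement,
                        "loss": loss_kind,
                        "r": r,
                        "seed": seed,
                        "mAP": summary.mAP,
                        "minority_posture_recall":
                            summary.minority_posture_recall(corpus.labels),
                        "macro_posture_recall":
                            summary.macro_posture_recall(corpus.labels),
                    }
                    for name, m in summary.per_class.items():
                        short = name.split()[0].lower()
                        row[f"ap_{short}"] = m.ap
                        row[f"acc_{short}"] = m.accuracy
                        row[f"recall_{short}"] = m.recall
                    rows.append(row)
                    if cache is not None:
                        cache.parent.mkdir(parents=True, exist_ok=True)
                        cache.write_text(json.dumps(row))
    return pd.DataFrame(rows)
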