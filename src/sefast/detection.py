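"""Pluggable animal-detection stage feeding boxes to the recognizer.

Recognition is box-conditioned, so a detector must run first.  Two sources
are supported: an *oracle* detector that derives detections from ground
truth under controlled degradation (coordinate jitter, dropped boxes, false
positives) — the stand-in used for desk-scale experiments — and an *import*
adapter that reads any external detector's output from the detection-JSON
format (see :mod:`sefast.formats`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats import AVARecord, BoundingBox, DetectionRecord

__all__ = ["DetectorSpec", "oracle_detect", "attach_detections", "MatchResult"]


@dataclass(frozen=True)
class DetectorSpec:
    """Oracle-detector degradation parameters (all off by default)."""

    kind: str = "oracle"
    jitter_sd: float = 0.0  # Gaussian corner jitter, normalized units
    drop_rate: float = 0.0  # probability of missing a ground-truth box
    false_positive_rate: float = 0.0  # expected spurious boxes per second
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("oracle", "imported"):
            raise ValueError(f"detector kind must be 'oracle' or 'imported', got {self.kind!r}")
        if not 0.0 <= self.drop_rate < 1.0:
            raise ValueError(f"drop_rate must lie in [0, 1), got {self.drop_rate}")
        if self.jitter_sd < 0 or self.false_positive_rate < 0:
            raise ValueError("jitter_sd and false_positive_rate must be non-negative")


def _jittered_box(box: BoundingBox, rng: np.random.Generator,
                  sd: float) -> tuple[BoundingBox, float]:
    deltas = rng.normal(0.0, sd, size=4) if sd > 0 else np.zeros(4)
    x1, y1, x2, y2 = np.asarray(box.as_tuple()) + deltas
    x1, x2 = sorted((float(np.clip(x1, 0.0, 1.0)), float(np.clip(x2, 0.0, 1.0))))
    y1, y2 = sorted((float(np.clip(y1, 0.0, 1.0)), float(np.clip(y2, 0.0, 1.0))))
    eps = 1e-3
    x2 = min(1.0, max(x2, x1 + eps))
    x1 = min(x1, x2 - eps)
    y2 = min(1.0, max(y2, y1 + eps))
    y1 = min(y1, y2 - eps)
    score = float(np.clip(1.0 - np.mean(np.abs(deltas)), 0.05, 1.0))
    return BoundingBox(x1, y1, x2, y2), score


def oracle_detect(gt: Iterable[AVARecord], spec: DetectorSpec) -> list[DetectionRecord]:
    """Emit detections derived from ground truth under the spec's degradation.

    Per annotated (video, second, entity): with probability ``1 − drop_rate``
    the ground-truth box is emitted with Gaussian corner jitter (clipped to
    [0, 1]) and a score of ``1 − mean|jitter|``.  Additional uniform random
    boxes appear at ``false_positive_rate`` per annotated second, with low
    scores.  Deterministic given ``spec.seed``.
    """
    if spec.kind != "oracle":
        raise ValueError("oracle_detect requires an oracle DetectorSpec")
    rng = np.random.default_rng(spec.seed)
    seen: set[tuple[str, int, int]] = set()
    out: list[DetectionRecord] = []
    for rec in gt:
        if rec.key in seen:
            continue
        seen.add(rec.key)
        if rng.uniform() < spec.drop_rate:
            continue
        box, score = _jittered_box(rec.box, rng, spec.jitter_sd)
        out.append(DetectionRecord(rec.video_id, rec.timestamp_s, box, score))
        for _ in range(rng.poisson(spec.false_positive_rate)):
            x1, y1 = rng.uniform(0.0, 0.7, size=2)
            w, h = rng.uniform(0.1, 0.3, size=2)
            fp_box = BoundingBox(x1, y1, min(1.0, x1 + w), min(1.0, y1 + h))
            out.append(
                DetectionRecord(rec.video_id, rec.timestamp_s, fp_box,
                                float(rng.uniform(0.1, 0.5)))
            )
    return out


def _iou(a: BoundingBox, b: BoundingBox) -> float:
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


@dataclass
class MatchResult:
    """Outcome of greedy detection ↔ ground-truth association."""

    matched: list[tuple[DetectionRecord, list[int]]]  # detection, its GT action ids
    unmatched_detections: list[DetectionRecord]  # carry empty label sets
    missed_gt: list[tuple[str, int, int]]  # (video, second, entity) with no detection


def attach_detections(detections: Sequence[DetectionRecord],
                      records: Sequence[AVARecord],
                      iou_threshold: float = 0.5) -> MatchResult:
    """Associate detections with annotated entities per (video, second).

    Greedy matching in descending score order (ties by input index) at the
    given IoU threshold.  Unmatched detections carry empty label lists;
    annotated entities no detection reached are reported as missed — the
    failure mode where recognition never runs because detection failed.
    """
    gt_groups: dict[tuple[str, int], dict[int, tuple[BoundingBox, list[int]]]] = {}
    for rec in records:
        slot = gt_groups.setdefault((rec.video_id, rec.timestamp_s), {})
        box, actions = slot.setdefault(rec.entity_id, (rec.box, []))
        actions.append(rec.action_id)

    matched: list[tuple[DetectionRecord, list[int]]] = []
    unmatched: list[DetectionRecord] = []
    taken: set[tuple[str, int, int]] = set()

    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, i))
    for i in order:
        det = detections[i]
        slot = gt_groups.get((det.video_id, det.timestamp_s), {})
        best_entity, best_iou = None, iou_threshold
        for entity_id, (box, _) in sorted(slot.items()):
            if (det.video_id, det.timestamp_s, entity_id) in taken:
                continue
            iou_val = _iou(det.box, box)
            if iou_val > best_iou or (iou_val == best_iou and best_entity is None
                                      and iou_val >= iou_threshold):
                best_entity, best_iou = entity_id, iou_val
        if best_entity is None:
            unmatched.append(det)
        else:
            taken.add((det.video_id, det.timestamp_s, best_entity))
            matched.append((det, list(slot[best_entity][1])))

    missed = [
        (video_id, sec, entity_id)
        for (video_id, sec), slot in gt_groups.items()
        for entity_id in slot
        if (video_id, sec, entity_id) not in taken
    ]
    return MatchResult(matched=matched, unmatched_detections=unmatched,
                       missed_gt=sorted(missed))
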