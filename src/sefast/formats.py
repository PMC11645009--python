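"""Label taxonomy and on-disk annotation formats.

The recognition task uses a five-class taxonomy for a horse kept in an
individual stall: three mutually exclusive *postures* (Standing, Sternal
recumbency, Lateral recumbency) and two *behaviors* (Eating, Sleeping) that
may co-occur with a posture.  Sleeping can accompany any posture; Eating —
the horse lowering its head to feed off the ground — only occurs while
Standing.  This module owns that taxonomy, the AVA-style spatio-temporal
annotation CSV (one row per video/second/box/action/entity, normalized box
coordinates), and a small JSON carrier for detector output.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FormatError",
    "ValidationError",
    "CombinationError",
    "LabelEntry",
    "LabelMap",
    "BoundingBox",
    "AVARecord",
    "DetectionRecord",
    "load_label_map",
    "write_label_map",
    "read_ava_csv",
    "write_ava_csv",
    "read_detection_json",
    "write_detection_json",
    "validate_combinations",
]

POSTURE = "posture"
BEHAVIOR = "behavior"

STANDING = "Standing"
STERNAL = "Sternal recumbency"
LATERAL = "Lateral recumbency"
EATING = "Eating"
SLEEPING = "Sleeping"


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """A parsed value violates a field-level invariant."""


class CombinationError(ValidationError):
    """An annotation set violates the posture/behavior combination rules."""


@dataclass(frozen=True)
class LabelEntry:
    id: int
    name: str
    kind: str  # POSTURE or BEHAVIOR


@dataclass(frozen=True)
class LabelMap:
    """Validated collection of label entries with contiguous 1-based ids."""

    entries: tuple[LabelEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if not ids:
            raise FormatError("label map is empty")
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise FormatError(f"label ids must be contiguous from 1, got {sorted(ids)}")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise FormatError("duplicate label names")
        for e in self.entries:
            if e.kind not in (POSTURE, BEHAVIOR):
                raise FormatError(f"unknown label kind {e.kind!r} for {e.name!r}")

    @classmethod
    def default(cls) -> "LabelMap":
        """The builtin stall-horse taxonomy: 3 postures + 2 behaviors."""
        return cls(
            entries=(
                LabelEntry(1, STANDING, POSTURE),
                LabelEntry(2, STERNAL, POSTURE),
                LabelEntry(3, LATERAL, POSTURE),
                LabelEntry(4, EATING, BEHAVIOR),
                LabelEntry(5, SLEEPING, BEHAVIOR),
            )
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_id(self, label_id: int) -> LabelEntry:
        for e in self.entries:
            if e.id == label_id:
                return e
        raise KeyError(label_id)

    def id_of(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.id
        raise KeyError(name)

    @property
    def posture_ids(self) -> tuple[int, ...]:
        return tuple(e.id for e in self.entries if e.kind == POSTURE)

    @property
    def behavior_ids(self) -> tuple[int, ...]:
        return tuple(e.id for e in self.entries if e.kind == BEHAVIOR)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in sorted(self.entries, key=lambda e: e.id))


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in normalized image coordinates, corners in [0, 1]."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x1 < self.x2 <= 1.0 and 0.0 <= self.y1 < self.y2 <= 1.0):
            raise ValidationError(
                f"invalid box ({self.x1}, {self.y1}, {self.x2}, {self.y2}): "
                "need 0 <= x1 < x2 <= 1 and 0 <= y1 < y2 <= 1"
            )

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)


@dataclass(frozen=True)
class AVARecord:
    """One spatio-temporal annotation row: who does what, where, and when."""

    video_id: str
    timestamp_s: int
    box: BoundingBox
    action_id: int
    entity_id: int = 0

    def __post_init__(self) -> None:
        if self.timestamp_s < 0:
            raise ValidationError(f"negative timestamp {self.timestamp_s}")
        if self.entity_id < 0:
            raise ValidationError(f"negative entity id {self.entity_id}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.video_id, self.timestamp_s, self.entity_id)


@dataclass(frozen=True)
class DetectionRecord:
    """One detector output box with a confidence score."""

    video_id: str
    timestamp_s: int
    box: BoundingBox
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"detection score {self.score} outside [0, 1]")


def validate_combinations(records: Iterable[AVARecord], labels: LabelMap) -> None:
    """Check the posture/behavior rules over every (video, second, entity) group.

    Each group must contain exactly one posture, at most one Sleeping row,
    and Eating only together with Standing.  Raises :class:`CombinationError`
    naming the offending group.
    """
    posture_ids = set(labels.posture_ids)
    try:
        eating_id = labels.id_of(EATING)
        standing_id = labels.id_of(STANDING)
        sleeping_id = labels.id_of(SLEEPING)
    except KeyError:  # custom map without the default behavior names
        eating_id = standing_id = sleeping_id = None

    groups: dict[tuple[str, int, int], list[int]] = {}
    for rec in records:
        if rec.action_id not in {e.id for e in labels}:
            raise ValidationError(
                f"action id {rec.action_id} not in label map (group {rec.key})"
            )
        groups.setdefault(rec.key, []).append(rec.action_id)
    for key, actions in groups.items():
        n_postures = sum(1 for a in actions if a in posture_ids)
        if n_postures != 1:
            raise CombinationError(
                f"group {key} has {n_postures} posture labels, expected exactly 1"
            )
        if len(actions) != len(set(actions)):
            raise CombinationError(f"group {key} has duplicate action labels")
        if sleeping_id is not None and actions.count(sleeping_id) > 1:
            raise CombinationError(f"group {key} has multiple Sleeping labels")
        if eating_id is not None and eating_id in actions and standing_id not in actions:
            raise CombinationError(
                f"group {key} has Eating without Standing (feeding only occurs upright)"
            )


def load_label_map(path: str | Path | None = None) -> LabelMap:
    """Read a label map from a TSV file ``id<TAB>name<TAB>kind``.

    With ``path=None`` the builtin default taxonomy is returned.
    """
    if path is None:
        return LabelMap.default()
    entries = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
        try:
            label_id = int(parts[0])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer id {parts[0]!r}") from exc
        entries.append(LabelEntry(label_id, parts[1], parts[2]))
    return LabelMap(tuple(entries))


def write_label_map(labels: LabelMap, path: str | Path) -> None:
    lines = [f"{e.id}\t{e.name}\t{e.kind}" for e in sorted(labels, key=lambda e: e.id)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ava_csv(path: str | Path, labels: LabelMap | None = None) -> list[AVARecord]:
    """Read AVA-style rows ``video_id,timestamp,x1,y1,x2,y2,action_id,entity_id``.

    Records are validated individually and then as a set against the
    combination rules; input order is preserved.
    """
    labels = labels or LabelMap.default()
    records: list[AVARecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), 1):
            if not row:
                continue
            if len(row) != 8:
                raise FormatError(f"{path}:{lineno}: expected 8 columns, got {len(row)}")
            try:
                box = BoundingBox(*(float(v) for v in row[2:6]))
                rec = AVARecord(
                    video_id=row[0],
                    timestamp_s=int(row[1]),
                    box=box,
                    action_id=int(row[6]),
                    entity_id=int(row[7]),
                )
            except (ValueError, ValidationError) as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    validate_combinations(records, labels)
    return records


def write_ava_csv(records: Sequence[AVARecord], path: str | Path,
                  labels: LabelMap | None = None) -> int:
    """Write records as AVA CSV (coordinates with 3 decimals); returns row count."""
    labels = labels or LabelMap.default()
    validate_combinations(records, labels)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        for rec in records:
            writer.writerow(
                [
                    rec.video_id,
                    rec.timestamp_s,
                    f"{rec.box.x1:.3f}",
                    f"{rec.box.y1:.3f}",
                    f"{rec.box.x2:.3f}",
                    f"{rec.box.y2:.3f}",
                    rec.action_id,
                    rec.entity_id,
                ]
            )
    return len(records)


def read_detection_json(path: str | Path) -> list[DetectionRecord]:
    """Read a JSON array of detections (video_id, timestamp_s, box, score)."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, list):
        raise FormatError(f"{path}: expected a JSON array of detections")
    out = []
    for i, obj in enumerate(data):
        try:
            out.append(
                DetectionRecord(
                    video_id=obj["video_id"],
                    timestamp_s=int(obj["timestamp_s"]),
                    box=BoundingBox(*(float(v) for v in obj["box"])),
                    score=float(obj["score"]),
                )
            )
        except ValidationError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: bad detection at index {i}: {exc}") from exc
    return out


def write_detection_json(detections: Sequence[DetectionRecord], path: str | Path) -> int:
    payload = [
        {
            "video_id": d.video_id,
            "timestamp_s": d.timestamp_s,
            "box": [round(v, 6) for v in d.box.as_tuple()],
            "score": round(d.score, 6),
        }
        for d in detections
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    return len(payload)
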