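"""Seeded synthetic stall videos with exact ground-truth annotations.

The study conditions this generator emulates: a fixed overhead/beam camera
watching a single horse in an individual stall, 16:9 frames, videos of 60 s,
and a 32-video corpus whose posture/behavior composition follows the
observed counts

    Standing 3, Standing+Eating 11, Standing+Sleeping 4,
    Sternal recumbency 4, Sternal+Sleeping 3,
    Lateral recumbency 3, Lateral+Sleeping 4.

The animal is a blob built from ellipses whose silhouette makes the three
postures geometrically separable (upright body on legs; chest-down compact
mound; flat elongated form), while behaviors add distinguishing cues:
Eating lowers the head to the ground with a periodic bobbing motion, and
Sleeping freezes the animal, darkens the scene (night footage) and closes
the eye.  Every annotated box is computed from the rendered animal mask
itself, so ground truth is exact by construction.

Default rendering is desk-scale 256×144 @ 10 fps (same 16:9 aspect as the
source footage's 1920×1080 @ 30); :meth:`RenderConfig.paper_scale` restores
the full resolution.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats import (
    AVARecord,
    BoundingBox,
    DetectionRecord,
    EATING,
    LATERAL,
    LabelMap,
    SLEEPING,
    STANDING,
    STERNAL,
    validate_combinations,
    write_ava_csv,
    write_detection_json,
    write_label_map,
)

__all__ = [
    "Combo",
    "TABLE_COMBOS",
    "COMBO_VIDEO_COUNTS",
    "default_combo_probs",
    "SceneScript",
    "ScriptState",
    "RenderConfig",
    "sample_scene_script",
    "render_video",
    "build_corpus",
    "generate_corpus",
    "load_corpus",
    "Corpus",
    "stratified_combo_assignment",
]

Combo = tuple[str, tuple[str, ...]]

#: The seven legal posture/behavior combinations observed in the source data.
TABLE_COMBOS: tuple[Combo, ...] = (
    (STANDING, ()),
    (STANDING, (EATING,)),
    (STANDING, (SLEEPING,)),
    (STERNAL, ()),
    (STERNAL, (SLEEPING,)),
    (LATERAL, ()),
    (LATERAL, (SLEEPING,)),
)

#: Number of 60 s videos per combination in the reference corpus (total 32).
COMBO_VIDEO_COUNTS: tuple[int, ...] = (3, 11, 4, 4, 3, 3, 4)


def default_combo_probs() -> dict[Combo, float]:
    total = sum(COMBO_VIDEO_COUNTS)
    return {combo: n / total for combo, n in zip(TABLE_COMBOS, COMBO_VIDEO_COUNTS)}


def _check_combo(posture: str, behaviors: Sequence[str]) -> None:
    behaviors = tuple(behaviors)
    if (posture, tuple(sorted(behaviors))) not in {
        (p, tuple(sorted(b))) for p, b in TABLE_COMBOS
    }:
        raise ValueError(
            f"illegal posture/behavior combination: {posture!r} + {behaviors!r} "
            "(Eating only occurs while Standing; behaviors are Eating/Sleeping)"
        )


@dataclass(frozen=True)
class ScriptState:
    posture: str
    behaviors: tuple[str, ...]
    duration_s: int

    def __post_init__(self) -> None:
        if self.duration_s < 1:
            raise ValueError("state duration must be a positive integer")
        _check_combo(self.posture, self.behaviors)


@dataclass(frozen=True)
class SceneScript:
    """What happens in one synthetic video, plus its stall appearance."""

    states: tuple[ScriptState, ...]
    texture_seed: int = 0
    animal_color: tuple[int, int, int] = (120, 82, 52)
    base_x: float = 0.5  # horizontal animal position as a fraction of width

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("scene script needs at least one state")
        if not 0.2 <= self.base_x <= 0.8:
            raise ValueError("base_x must keep the animal inside the stall (0.2..0.8)")

    @property
    def duration_s(self) -> int:
        return sum(s.duration_s for s in self.states)


@dataclass(frozen=True)
class RenderConfig:
    width: int = 256
    height: int = 144
    fps: int = 10
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps < 1:
            raise ValueError("fps must be >= 1")
        if self.width < 64 or self.height < 64 * 9 // 16:
            raise ValueError("render size too small (need width >= 64)")

    @classmethod
    def paper_scale(cls, **overrides) -> "RenderConfig":
        """Source-footage geometry: 1920×1080 @ 30 fps."""
        kw = dict(width=1920, height=1080, fps=30)
        kw.update(overrides)
        return cls(**kw)


def sample_scene_script(seed: int, duration_s: int,
                        combo_probs: Mapping[Combo, float] | None = None,
                        n_segments: int = 1) -> SceneScript:
    """Draw a scene script deterministically from ``seed``.

    ``combo_probs`` must put probability mass only on the seven legal
    combinations and sum to one.  With ``n_segments > 1`` the duration is
    split evenly and each segment's combination is drawn independently.
    """
    probs = dict(combo_probs) if combo_probs is not None else default_combo_probs()
    for (posture, behaviors), p in probs.items():
        if p < 0:
            raise ValueError("combination probabilities must be non-negative")
        if p > 0:
            _check_combo(posture, behaviors)
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"combination probabilities sum to {total}, expected 1")
    if duration_s < n_segments:
        raise ValueError("duration shorter than the number of segments")

    rng = np.random.default_rng(seed)
    combos = list(probs.keys())
    p = np.asarray([probs[c] for c in combos], dtype=float)
    p = p / p.sum()
    seg_len = duration_s // n_segments
    states = []
    for i in range(n_segments):
        dur = seg_len if i < n_segments - 1 else duration_s - seg_len * (n_segments - 1)
        posture, behaviors = combos[rng.choice(len(combos), p=p)]
        states.append(ScriptState(posture, tuple(behaviors), dur))
    color = tuple(int(v) for v in rng.integers([90, 60, 35], [150, 105, 70]))
    return SceneScript(
        states=tuple(states),
        texture_seed=int(rng.integers(0, 2**31 - 1)),
        animal_color=color,  # type: ignore[arg-type]
        base_x=float(rng.uniform(0.35, 0.65)),
    )


# ---------------------------------------------------------------------------
# rendering


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    return ((yy - cy) / max(ry, 1e-6)) ** 2 + ((xx - cx) / max(rx, 1e-6)) ** 2 <= 1.0


def _rect(h: int, w: int, y1: float, y2: float, x1: float, x2: float) -> np.ndarray:
    mask = np.zeros((h, w), dtype=bool)
    iy1, iy2 = int(max(0, round(y1))), int(min(h, round(y2)))
    ix1, ix2 = int(max(0, round(x1))), int(min(w, round(x2)))
    if iy2 > iy1 and ix2 > ix1:
        mask[iy1:iy2, ix1:ix2] = True
    return mask


def _animal_mask(state: ScriptState, cfg: RenderConfig, base_x: float,
                 frame_in_state: int, jitter: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Silhouette mask and eye-region mask for one frame."""
    h, w = cfg.height, cfg.width
    cx = base_x * w + jitter[0]
    ground = 0.84 * h
    eating = EATING in state.behaviors
    parts = []

    if state.posture == STANDING:
        body_cy = 0.52 * h + jitter[1]
        body = _ellipse(h, w, body_cy, cx, 0.105 * h, 0.145 * w)
        parts.append(body)
        for off in (-0.105, -0.05, 0.05, 0.105):
            x0 = cx + off * w
            parts.append(_rect(h, w, body_cy, ground, x0 - 0.007 * w, x0 + 0.007 * w))
        if eating:
            bob = 0.025 * h * np.sin(2 * np.pi * 1.5 * frame_in_state / cfg.fps)
            head_cy = 0.74 * h + bob
            head_cx = cx + 0.185 * w
            parts.append(_ellipse(h, w, head_cy, head_cx, 0.05 * h, 0.042 * w))
            # neck from shoulder down to the head
            steps = 6
            for i in range(steps + 1):
                f = i / steps
                ny = body_cy * (1 - f) + head_cy * f
                nx = (cx + 0.12 * w) * (1 - f) + head_cx * f
                parts.append(_ellipse(h, w, ny, nx, 0.028 * h, 0.02 * w))
        else:
            head_cy = 0.36 * h + jitter[1]
            head_cx = cx + 0.175 * w
            parts.append(_ellipse(h, w, head_cy, head_cx, 0.052 * h, 0.04 * w))
            parts.append(_ellipse(h, w, (body_cy + head_cy) / 2, cx + 0.14 * w,
                                  0.07 * h, 0.03 * w))
    elif state.posture == STERNAL:
        body_cy = 0.745 * h + jitter[1]
        parts.append(_ellipse(h, w, body_cy, cx, 0.085 * h, 0.165 * w))
        head_cy = 0.585 * h + jitter[1]
        head_cx = cx + 0.155 * w
        parts.append(_ellipse(h, w, head_cy, head_cx, 0.05 * h, 0.038 * w))
        parts.append(_ellipse(h, w, (body_cy + head_cy) / 2, cx + 0.13 * w,
                              0.06 * h, 0.028 * w))
    elif state.posture == LATERAL:
        body_cy = 0.785 * h + jitter[1]
        parts.append(_ellipse(h, w, body_cy, cx, 0.062 * h, 0.19 * w))
        head_cy = 0.80 * h + jitter[1]
        head_cx = cx + 0.225 * w
        parts.append(_ellipse(h, w, head_cy, head_cx, 0.042 * h, 0.045 * w))
        # outstretched legs
        parts.append(_rect(h, w, body_cy - 0.018 * h, body_cy + 0.018 * h,
                           cx - 0.27 * w, cx - 0.17 * w))
    else:  # pragma: no cover - ScriptState validates postures
        raise ValueError(f"unknown posture {state.posture!r}")

    mask = np.zeros((h, w), dtype=bool)
    for p in parts:
        mask |= p

    eye = _ellipse(h, w, head_cy - 0.012 * h, head_cx + 0.012 * w,
                   0.012 * h, 0.01 * w) & mask
    return mask, eye


def _background(cfg: RenderConfig, texture_seed: int) -> np.ndarray:
    rng = np.random.default_rng(texture_seed)
    h, w = cfg.height, cfg.width
    coarse = rng.normal(0.0, 14.0, size=(10, 16, 3))
    # bilinear upsample of a coarse random grid -> smooth wall/bedding texture
    ys = np.linspace(0, coarse.shape[0] - 1, h)
    xs = np.linspace(0, coarse.shape[1] - 1, w)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, coarse.shape[0] - 1)
    x1 = np.minimum(x0 + 1, coarse.shape[1] - 1)
    fy = (ys - y0)[:, None, None]
    fx = (xs - x0)[None, :, None]
    tex = (
        coarse[y0][:, x0] * (1 - fy) * (1 - fx)
        + coarse[y0][:, x1] * (1 - fy) * fx
        + coarse[y1][:, x0] * fy * (1 - fx)
        + coarse[y1][:, x1] * fy * fx
    )
    base = np.array([168.0, 156.0, 138.0])
    bg = base + tex
    # darker bedding below the floor line
    floor = int(0.84 * h)
    bg[floor:] *= 0.82
    return np.clip(bg, 0, 255)


def render_video(script: SceneScript, cfg: RenderConfig, video_id: str = "v00",
                 labels: LabelMap | None = None, return_masks: bool = False):
    """Render one video; returns ``(frames, records)`` (+ masks if requested).

    ``frames`` is a (T, H, W, 3) uint8 array with T = duration × fps.  One
    annotation group per second is emitted for entity 0: its box is the tight
    normalized bounding rectangle of the animal silhouette over that second.
    Deterministic given ``cfg.seed`` and the script.
    """
    labels = labels or LabelMap.default()
    h, w = cfg.height, cfg.width
    rng = np.random.default_rng(cfg.seed)
    bg = _background(cfg, script.texture_seed)
    duration = script.duration_s
    n_frames = duration * cfg.fps
    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    masks = np.zeros((n_frames, h, w), dtype=bool) if return_masks else None
    records: list[AVARecord] = []
    color = np.asarray(script.animal_color, dtype=float)

    # schedule: state per second
    per_second: list[ScriptState] = []
    for state in script.states:
        per_second.extend([state] * state.duration_s)

    frame_idx = 0
    frame_in_state = 0
    prev_state = None
    for sec, state in enumerate(per_second):
        sleeping = SLEEPING in state.behaviors
        if state is not prev_state:
            frame_in_state = 0
            prev_state = state
        sec_masks = []
        for k in range(cfg.fps):
            # awake animals shift weight sideways between frames; sleepers are still
            jitter = (0, 0) if sleeping else (int(rng.integers(-1, 2)), 0)
            mask, eye = _animal_mask(state, cfg, script.base_x, frame_in_state, jitter)
            # day for awake scenes, night for sleeping ones, with slow drift
            illum = (0.55 if sleeping else 1.0) * (
                1.0 + 0.06 * np.sin(2 * np.pi * frame_idx / max(n_frames, 1))
            )
            frame = bg * illum
            shade = 1.0 - 0.25 * (np.arange(h) / h)[:, None]  # simple body shading
            animal = color[None, None, :] * shade[..., None] * illum
            frame = np.where(mask[..., None], animal, frame)
            if sleeping:
                frame[eye] = frame[eye] * 0.3  # closed, dark eye
            else:
                frame[eye] = np.minimum(frame[eye] + 90.0, 255.0)  # open, bright eye
            frame += rng.normal(0.0, cfg.noise_sd, size=frame.shape)
            frames[frame_idx] = np.clip(frame, 0, 255).astype(np.uint8)
            if masks is not None:
                masks[frame_idx] = mask
            sec_masks.append(mask)
            frame_idx += 1
            frame_in_state += 1
        union = np.logical_or.reduce(sec_masks)
        ys, xs = np.nonzero(union)
        box = BoundingBox(
            x1=float(xs.min()) / w,
            y1=float(ys.min()) / h,
            x2=float(xs.max() + 1) / w,
            y2=float(ys.max() + 1) / h,
        )
        actions = [labels.id_of(state.posture)]
        actions += [labels.id_of(b) for b in state.behaviors]
        for action in actions:
            records.append(AVARecord(video_id, sec, box, action, entity_id=0))

    validate_combinations(records, labels)
    if return_masks:
        return frames, records, masks
    return frames, records


# ---------------------------------------------------------------------------
# corpus


def stratified_combo_assignment(n_videos: int) -> list[Combo]:
    """Apportion combos to ``n_videos`` following the reference composition.

    For 32 videos this reproduces the reference counts exactly; otherwise
    quotas ``count·n/32`` are apportioned by largest remainder with ties
    broken by combo order.
    """
    total = sum(COMBO_VIDEO_COUNTS)
    quotas = [c * n_videos / total for c in COMBO_VIDEO_COUNTS]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    short = n_videos - sum(counts)
    for i in remainders[:short]:
        counts[i] += 1
    out: list[Combo] = []
    for combo, c in zip(TABLE_COMBOS, counts):
        out.extend([combo] * c)
    return out


@dataclass
class Corpus:
    """A rendered corpus: annotations plus per-video frame access."""

    labels: LabelMap
    records: list[AVARecord]
    manifest: dict
    root: Path | None = None
    _frames: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def video_ids(self) -> list[str]:
        return list(self.manifest["videos"].keys())

    @property
    def fps(self) -> int:
        return int(self.manifest["fps"])

    @property
    def width(self) -> int:
        return int(self.manifest["width"])

    @property
    def height(self) -> int:
        return int(self.manifest["height"])

    def frames(self, video_id: str) -> np.ndarray:
        if video_id not in self._frames:
            if self.root is None:
                raise KeyError(f"no frames for {video_id!r}")
            import imageio.v3 as iio

            vdir = self.root / "frames" / video_id
            paths = sorted(vdir.glob("*.jpg"))
            if not paths:
                raise FileNotFoundError(f"no frames under {vdir}")
            self._frames[video_id] = np.stack([iio.imread(p) for p in paths])
        return self._frames[video_id]

    def gt_detections(self) -> list[DetectionRecord]:
        """Ground-truth boxes re-expressed as unit-score detections."""
        seen = set()
        out = []
        for rec in self.records:
            key = (rec.video_id, rec.timestamp_s, rec.entity_id)
            if key in seen:
                continue
            seen.add(key)
            out.append(DetectionRecord(rec.video_id, rec.timestamp_s, rec.box, 1.0))
        return out


def _make_scripts(n_videos: int, duration_s: int, seed: int, stratified: bool,
                  combo_probs: Mapping[Combo, float] | None) -> list[SceneScript]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_videos + 1)
    order_rng = np.random.default_rng(children[-1])
    scripts = []
    if stratified:
        combos = stratified_combo_assignment(n_videos)
        order = order_rng.permutation(n_videos)
        combos = [combos[i] for i in order]
        for i in range(n_videos):
            vseed = int(children[i].generate_state(1)[0] % (2**31 - 1))
            base = sample_scene_script(vseed, duration_s, combo_probs=None)
            posture, behaviors = combos[i]
            scripts.append(
                replace(base, states=(ScriptState(posture, behaviors, duration_s),))
            )
    else:
        for i in range(n_videos):
            vseed = int(children[i].generate_state(1)[0] % (2**31 - 1))
            scripts.append(sample_scene_script(vseed, duration_s, combo_probs))
    return scripts


def generate_corpus(n_videos: int = 32, duration_s: int = 60,
                    cfg: RenderConfig | None = None, seed: int = 0,
                    stratified: bool = True,
                    combo_probs: Mapping[Combo, float] | None = None,
                    labels: LabelMap | None = None) -> Corpus:
    """Render a corpus in memory (no files written)."""
    cfg = cfg or RenderConfig()
    labels = labels or LabelMap.default()
    scripts = _make_scripts(n_videos, duration_s, seed, stratified, combo_probs)
    records: list[AVARecord] = []
    frames: dict[str, np.ndarray] = {}
    videos = {}
    for i, script in enumerate(scripts):
        video_id = f"horse_{i:03d}"
        vcfg = replace(cfg, seed=script.texture_seed ^ 0x5EFA57)
        vframes, vrecords = render_video(script, vcfg, video_id, labels)
        frames[video_id] = vframes
        records.extend(vrecords)
        videos[video_id] = {
            "combo": [script.states[0].posture, list(script.states[0].behaviors)],
            "duration_s": duration_s,
            "n_frames": int(vframes.shape[0]),
        }
    manifest = {
        "videos": videos,
        "width": cfg.width,
        "height": cfg.height,
        "fps": cfg.fps,
        "seed": seed,
        "stratified": stratified,
    }
    return Corpus(labels=labels, records=records, manifest=manifest, _frames=frames)


def build_corpus(out_dir: str | Path, n_videos: int = 32, duration_s: int = 60,
                 cfg: RenderConfig | None = None, seed: int = 0,
                 stratified: bool = True,
                 combo_probs: Mapping[Combo, float] | None = None,
                 labels: LabelMap | None = None,
                 overwrite: bool = False) -> Corpus:
    """Render a corpus and write it to ``out_dir``.

    Layout: ``frames/{video_id}/{frame:06d}.jpg``, ``ava.csv``,
    ``detections.json`` (ground-truth boxes), ``labelmap.tsv`` and
    ``manifest.yaml``.  Refuses to touch an existing non-empty directory
    unless ``overwrite=True``.
    """
    import imageio.v3 as iio
    import yaml

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{out} exists and is not empty (use overwrite=True)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    corpus = generate_corpus(n_videos, duration_s, cfg, seed, stratified,
                             combo_probs, labels)
    for video_id in corpus.video_ids:
        vdir = out / "frames" / video_id
        vdir.mkdir(parents=True)
        for i, frame in enumerate(corpus.frames(video_id)):
            iio.imwrite(vdir / f"{i:06d}.jpg", frame, quality=92)
    write_ava_csv(corpus.records, out / "ava.csv", corpus.labels)
    write_detection_json(corpus.gt_detections(), out / "detections.json")
    write_label_map(corpus.labels, out / "labelmap.tsv")
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(corpus.manifest, fh, sort_keys=True)
    corpus.root = out
    return corpus


def load_corpus(root: str | Path) -> Corpus:
    """Load a corpus previously written by :func:`build_corpus` (frames lazy)."""
    import yaml

    from .formats import load_label_map, read_ava_csv

    root = Path(root)
    with open(root / "manifest.yaml", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    labels = load_label_map(root / "labelmap.tsv")
    records = read_ava_csv(root / "ava.csv", labels)
    return Corpus(labels=labels, records=records, manifest=manifest, root=root)
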