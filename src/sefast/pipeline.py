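"""Dual-rate frame extraction, dataset splitting, clip assembly, augmentation.

The recognition network consumes 64-frame windows sampled two ways: a slow
view of N_slow = L/S_slow = 64/16 = 4 frames and a fast view of
N_fast = L/S_fast = 64/2 = 32 frames.  Because S_slow is a multiple of
S_fast the slow view's indices are a subset of the fast view's.  Annotation
lives on 1 fps keyframes; dense frames exist only to fill the clip windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .formats import AVARecord, LabelMap
from .synthetic import Corpus

__all__ = [
    "ExtractionPlan",
    "planned_frame_counts",
    "extract_frames",
    "split_dataset",
    "ClipPair",
    "make_clip_pair",
    "color_jitter",
    "add_noise",
    "clahe",
    "ClipDataset",
    "clip_dataset",
]


@dataclass(frozen=True)
class ExtractionPlan:
    """Which frame rates to extract, and which rate carries annotations."""

    rates: tuple[int, ...] = (30, 1)
    labeled_rate: int = 1

    def __post_init__(self) -> None:
        if self.labeled_rate not in self.rates:
            raise ValueError(
                f"labeled rate {self.labeled_rate} not among extraction rates {self.rates}"
            )
        if any(r < 1 for r in self.rates):
            raise ValueError("extraction rates must be >= 1 fps")


def planned_frame_counts(n_videos: int, duration_s: int,
                         plan: ExtractionPlan = ExtractionPlan()) -> dict:
    """Frame-count arithmetic for an ``n_videos × duration_s`` corpus.

    Returns per-rate counts, the total over all rates, and the labeled-frame
    count (one annotated keyframe per second at the labeled rate).
    """
    per_rate = {r: n_videos * duration_s * r for r in plan.rates}
    return {
        "per_rate": per_rate,
        "total": sum(per_rate.values()),
        "labeled": n_videos * duration_s * plan.labeled_rate,
    }


def extract_frames(source: np.ndarray | str | Path, source_fps: int,
                   plan: ExtractionPlan = ExtractionPlan(),
                   out_dir: str | Path | None = None) -> dict[int, list[int]]:
    """Subsample a decoded frame sequence at each requested rate.

    ``source`` is either a (T, H, W, C) array or a directory of frame images
    (sorted lexically).  Each requested rate must divide ``source_fps``; a
    trailing partial second is dropped.  Returns rate → selected source frame
    indices; with ``out_dir`` the selected frames are also written as
    ``rate_{r}/{i:06d}.jpg``.
    """
    if isinstance(source, (str, Path)):
        paths = sorted(Path(source).glob("*.jpg")) + sorted(Path(source).glob("*.png"))
        if not paths:
            raise IOError(f"no frames found under {source}")
        n_frames = len(paths)
        frames = None
    else:
        frames = np.asarray(source)
        n_frames = frames.shape[0]
        paths = None

    duration = n_frames // source_fps
    selected: dict[int, list[int]] = {}
    for rate in plan.rates:
        if source_fps % rate:
            raise ValueError(f"rate {rate} does not divide source fps {source_fps}")
        step = source_fps // rate
        selected[rate] = list(range(0, duration * source_fps, step))

    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        for rate, idxs in selected.items():
            rdir = out / f"rate_{rate}"
            rdir.mkdir(parents=True, exist_ok=True)
            for j, i in enumerate(idxs):
                frame = frames[i] if frames is not None else iio.imread(paths[i])
                iio.imwrite(rdir / f"{j:06d}.jpg", frame, quality=92)
    return selected


def split_dataset(items: Sequence, ratio: tuple[float, float] = (0.8, 0.2),
                  seed: int = 0) -> tuple[list, list]:
    """Seeded shuffle split; sizes are ``round(n·frac)`` with remainder to train.

    The two parts are disjoint and exhaustive.
    """
    train_frac, test_frac = ratio
    if abs(train_frac + test_frac - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {ratio}")
    items = list(items)
    n = len(items)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    n_test = int(round(n * test_frac))
    order = np.random.default_rng(seed).permutation(n)
    test = [items[i] for i in order[:n_test]]
    train = [items[i] for i in order[n_test:]]
    return train, test


@dataclass(frozen=True)
class ClipPair:
    """Slow and fast frame-index views of one L-frame window.

    Indices are raw (possibly out of video range at the edges); sampling
    clamps them to valid frames, which repeats the boundary frame.
    """

    window_start: int
    window_len: int = 64
    s_slow: int = 16
    s_fast: int = 2

    def __post_init__(self) -> None:
        if self.window_len % self.s_slow or self.window_len % self.s_fast:
            raise ValueError(
                f"window {self.window_len} not divisible by strides "
                f"({self.s_slow}, {self.s_fast})"
            )
        if self.s_slow % self.s_fast:
            raise ValueError("slow stride must be a multiple of the fast stride")

    @property
    def n_slow(self) -> int:
        return self.window_len // self.s_slow

    @property
    def n_fast(self) -> int:
        return self.window_len // self.s_fast

    @property
    def slow_indices(self) -> list[int]:
        return list(range(self.window_start, self.window_start + self.window_len,
                          self.s_slow))

    @property
    def fast_indices(self) -> list[int]:
        return list(range(self.window_start, self.window_start + self.window_len,
                          self.s_fast))

    def gather(self, frames: np.ndarray, which: str = "fast") -> np.ndarray:
        idx = self.fast_indices if which == "fast" else self.slow_indices
        clamped = np.clip(idx, 0, frames.shape[0] - 1)
        return frames[clamped]


def make_clip_pair(center_second: int, fps: int, window_len: int = 64,
                   s_slow: int = 16, s_fast: int = 2) -> ClipPair:
    """Window of ``window_len`` frames centered on the annotated second's frame.

    The annotated second ``t`` maps to frame ``t·fps`` (the first frame of
    that second); edges are handled at sampling time by clamping, i.e.
    repeating the first/last frame.
    """
    anchor = center_second * fps
    return ClipPair(window_start=anchor - window_len // 2, window_len=window_len,
                    s_slow=s_slow, s_fast=s_fast)


# ---------------------------------------------------------------------------
# photometric augmentations (annotation geometry is never touched)


def _check_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.dtype != np.uint8 or arr.ndim not in (2, 3):
        raise TypeError("expected an 8-bit image (H×W or H×W×C uint8)")
    return arr


def color_jitter(image: np.ndarray, brightness: float = 0.0, contrast: float = 0.0,
                 saturation: float = 0.0, seed: int = 0) -> np.ndarray:
    """Randomly scale brightness/contrast/saturation, each by a factor drawn
    uniformly from [1−s, 1+s].  Zero strengths reproduce the input exactly."""
    arr = _check_image(image)
    if brightness == contrast == saturation == 0.0:
        return arr.copy()
    rng = np.random.default_rng(seed)
    fb = rng.uniform(1 - brightness, 1 + brightness)
    fc = rng.uniform(1 - contrast, 1 + contrast)
    fs = rng.uniform(1 - saturation, 1 + saturation)
    out = arr.astype(np.float32) * fb
    mean = out.mean()
    out = mean + (out - mean) * fc
    if arr.ndim == 3 and arr.shape[-1] == 3 and saturation != 0.0:
        gray = out.mean(axis=-1, keepdims=True)
        out = gray + (out - gray) * fs
    return np.clip(out, 0, 255).astype(np.uint8)


def add_noise(image: np.ndarray, sd: float, seed: int = 0) -> np.ndarray:
    """Add seeded Gaussian pixel noise (gray-level units); sd=0 is identity."""
    arr = _check_image(image)
    if sd == 0.0:
        return arr.copy()
    rng = np.random.default_rng(seed)
    out = arr.astype(np.float32) + rng.normal(0.0, sd, size=arr.shape)
    return np.clip(out, 0, 255).astype(np.uint8)


def clahe(image: np.ndarray, clip_limit: float = 2.0,
          tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (deterministic).

    ``clip_limit`` follows the common histogram-clip convention where 2.0 is
    a mild setting; it is mapped to scikit-image's fractional clip limit as
    ``clip_limit / 256``.  ``tile_grid`` gives the number of contextual tiles
    per axis.
    """
    from skimage import exposure

    arr = _check_image(image)
    kernel = (max(1, arr.shape[0] // tile_grid[0]), max(1, arr.shape[1] // tile_grid[1]))
    img = arr.astype(np.float64) / 255.0
    if arr.ndim == 3:
        out = np.stack(
            [
                exposure.equalize_adapthist(img[..., c], kernel_size=kernel,
                                            clip_limit=clip_limit / 256.0)
                for c in range(arr.shape[-1])
            ],
            axis=-1,
        )
    else:
        out = exposure.equalize_adapthist(img, kernel_size=kernel,
                                          clip_limit=clip_limit / 256.0)
    return np.clip(out * 255.0, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# clip dataset assembly for training/evaluation


@dataclass
class ClipDataset:
    """Clip windows ready for the network.

    ``clips`` holds the fast view only, as uint8 (n, N_fast, h, w, 3); the
    slow view is its every-(S_slow/S_fast)-th frame.  One ground-truth box
    and one multi-hot label vector per clip.
    """

    clips: np.ndarray
    boxes: np.ndarray  # (n, 4) normalized x1,y1,x2,y2
    y: np.ndarray  # (n, C) multi-hot
    keys: list[tuple[str, int]]  # (video_id, second)
    labels: LabelMap
    alpha: int = 8  # S_slow // S_fast

    def __len__(self) -> int:
        return self.clips.shape[0]

    def subset(self, indices: Iterable[int]) -> "ClipDataset":
        idx = list(indices)
        return ClipDataset(self.clips[idx], self.boxes[idx], self.y[idx],
                           [self.keys[i] for i in idx], self.labels, self.alpha)

    def tensors(self, indices: Sequence[int] | None = None,
                rng: np.random.Generator | None = None,
                augment: float = 0.0):
        """Float network inputs: (slow, fast, rois, y) for the given clips.

        With ``augment > 0`` each selected clip is, with that probability,
        photometrically perturbed (brightness/contrast scaling plus Gaussian
        noise) — geometry and labels are untouched.
        """
        idx = np.arange(len(self)) if indices is None else np.asarray(indices)
        fast = self.clips[idx].astype(np.float32)
        if augment > 0.0 and rng is not None:
            for i in range(fast.shape[0]):
                if rng.uniform() < augment:
                    fb = rng.uniform(0.8, 1.2)
                    fc = rng.uniform(0.8, 1.2)
                    m = fast[i].mean()
                    fast[i] = m + (fast[i] * fb - m) * fc
                    fast[i] += rng.normal(0.0, 6.0, size=fast[i].shape).astype(np.float32)
            np.clip(fast, 0, 255, out=fast)
        fast = (fast / 255.0 - 0.45) / 0.225
        fast = fast.transpose(0, 4, 1, 2, 3)  # (B, 3, T, H, W)
        slow = fast[:, :, ::self.alpha]
        rois = [(i, *self.boxes[j]) for i, j in enumerate(idx)]
        return slow, np.ascontiguousarray(fast), rois, self.y[idx]


def clip_dataset(corpus: Corpus, downsample: int = 4, window_len: int = 64,
                 s_slow: int = 16, s_fast: int = 2) -> ClipDataset:
    """Assemble one clip per annotated second from a corpus.

    Frames are spatially reduced by ``downsample`` via block averaging (the
    corpus default 256×144 becomes 64×36 network input).
    """
    labels = corpus.labels
    n_classes = len(labels)
    groups: dict[tuple[str, int], list[AVARecord]] = {}
    for rec in corpus.records:
        groups.setdefault((rec.video_id, rec.timestamp_s), []).append(rec)

    clips, boxes, ys, keys = [], [], [], []
    for video_id in corpus.video_ids:
        frames = corpus.frames(video_id)
        t, h, w, _ = frames.shape
        if h % downsample or w % downsample:
            raise ValueError(f"frame size {h}×{w} not divisible by {downsample}")
        small = (
            frames.reshape(t, h // downsample, downsample, w // downsample,
                           downsample, 3)
            .mean(axis=(2, 4))
            .astype(np.uint8)
        )
        seconds = sorted(s for v, s in groups if v == video_id)
        for sec in seconds:
            recs = groups[(video_id, sec)]
            pair = make_clip_pair(sec, corpus.fps, window_len, s_slow, s_fast)
            clips.append(pair.gather(small, "fast"))
            boxes.append(recs[0].box.as_tuple())
            yvec = np.zeros(n_classes, dtype=np.float32)
            for rec in recs:
                yvec[rec.action_id - 1] = 1.0
            ys.append(yvec)
            keys.append((video_id, sec))
    return ClipDataset(
        clips=np.stack(clips),
        boxes=np.asarray(boxes, dtype=np.float32),
        y=np.stack(ys),
        keys=keys,
        labels=labels,
        alpha=s_slow // s_fast,
    )
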