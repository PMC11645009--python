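"""Multi-label loss family for imbalanced posture/behavior recognition.

The classifier emits one logit per class and is trained as independent
binary problems (multi-label sigmoid outputs).  Four variants are provided:

- ``bce``   — plain binary cross-entropy, mean over elements;
- ``cw``    — class-weighted BCE: each class's elementwise loss is scaled by
  an inverse-frequency weight ``w_c = (Σ_j n_j) / (C · n_c)`` computed from
  per-class positive-label counts, so rare classes (the recumbent postures)
  contribute more to the gradient;
- ``bce_f`` / ``cw_f`` — the above with focal modulation: each element is
  further scaled by ``r · (1 − p_t)^r`` where ``p_t`` is the predicted
  probability of the true binary outcome, down-weighting easy examples.
  The leading factor ``r`` is deliberate (it matches the formulation this
  pipeline adopts); pass ``orthodox_focal=True`` for the conventional
  ``(1 − p_t)^r`` factor.  A constant factor only rescales the gradient, so
  the two differ by an effective learning rate.

All computations run on the package's autograd tensors, so the same code
path serves both the pure-array API and training.  Logits are processed with
stable log-sigmoid arithmetic: losses stay finite for |logit| well beyond 50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ._autograd import Tensor

__all__ = [
    "ClassWeights",
    "LossConfig",
    "compute_class_weights",
    "bce_elementwise",
    "cw_loss",
    "focal_modulate",
    "make_loss",
    "LOSS_KINDS",
]

LOSS_KINDS = ("bce", "cw", "bce_f", "cw_f")


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights derived from positive-label counts."""

    w: tuple[float, ...]
    source_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.w):
            raise ValueError("class weights must be positive")

    def __len__(self) -> int:
        return len(self.w)

    def as_array(self, dtype=np.float64) -> np.ndarray:
        return np.asarray(self.w, dtype=dtype)


def compute_class_weights(counts: Sequence[int]) -> ClassWeights:
    """Inverse-frequency class weights: ``w_i = (Σ_j n_j) / (C · n_i)``.

    Balanced counts give unit weights; halving a class's count doubles its
    weight; scaling all counts by a constant leaves the weights unchanged.
    Zero counts are rejected — a class that never occurs has no meaningful
    weight and should be merged or dropped by the caller.
    """
    counts = tuple(int(c) for c in counts)
    if any(c <= 0 for c in counts):
        raise ValueError(
            "all class counts must be positive; merge or drop classes with zero count"
        )
    total = sum(counts)
    n_classes = len(counts)
    w = tuple(total / (n_classes * c) for c in counts)
    return ClassWeights(w=w, source_counts=counts)


@dataclass(frozen=True)
class LossConfig:
    """Selects one of the four loss variants and its parameters."""

    kind: str = "cw_f"
    r: int = 2
    weights: ClassWeights | None = None
    orthodox_focal: bool = False

    def __post_init__(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"loss kind must be one of {LOSS_KINDS}, got {self.kind!r}")
        if self.kind.startswith("cw") and self.weights is None:
            raise ValueError(f"loss kind {self.kind!r} requires class weights")
        if self.kind.endswith("_f"):
            if not isinstance(self.r, int) or self.r < 1:
                raise ValueError(f"focal exponent r must be an integer >= 1, got {self.r}")


def _coerce(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def bce_elementwise(y, logits) -> Tensor:
    """Stable elementwise binary cross-entropy on logits.

    Uses the identity ``−[y·log σ(x) + (1−y)·log(1−σ(x))] = softplus(x) − x·y``.
    """
    y_t = _coerce(y)
    x = _coerce(logits)
    return x.softplus() - x * y_t


def cw_loss(y, logits, weights: ClassWeights):
    """Class-weighted BCE.

    Parameters are an N×C binary target matrix, an N×C logit matrix and the
    per-class weights.  Returns ``(scalar_mean, per_element)``; with unit
    weights the scalar is exactly the plain BCE mean.
    """
    y_arr = np.atleast_2d(np.asarray(y, dtype=float))
    if y_arr.shape[-1] != len(weights):
        raise ValueError(
            f"target has {y_arr.shape[-1]} classes but weights have {len(weights)}"
        )
    per_element = bce_elementwise(y_arr, logits) * weights.as_array()
    if per_element.shape != y_arr.shape:
        raise ValueError(
            f"shape mismatch: targets {y_arr.shape}, losses {per_element.shape}"
        )
    return per_element.mean(), per_element


def focal_modulate(per_element_loss, y, logits, r: int = 2,
                   orthodox_focal: bool = False) -> Tensor:
    """Apply focal modulation ``r·(1−p_t)^r`` elementwise, then reduce by mean.

    ``p_t`` is the probability the model assigns to the true binary outcome:
    ``σ(logit)`` where the label is 1, ``1−σ(logit)`` where it is 0.  With
    ``orthodox_focal=True`` the leading factor ``r`` is dropped.
    """
    if not isinstance(r, (int, np.integer)) or r < 1:
        raise ValueError(f"focal exponent r must be an integer >= 1, got {r!r}")
    if not 2 <= r <= 4:
        warnings.warn(
            f"focal exponent r={r} outside the well-behaved range [2, 4]; "
            "accuracy typically degrades there",
            stacklevel=2,
        )
    y_arr = np.asarray(y, dtype=float)
    x = _coerce(logits)
    loss = _coerce(per_element_loss)
    p = x.sigmoid()
    # 1 - p_t = |y - p| for binary y, written without abs to stay differentiable
    one_minus_pt = p * (1.0 - 2.0 * y_arr) + y_arr
    factor = one_minus_pt**r
    if not orthodox_focal:
        factor = factor * float(r)
    return (factor * loss).mean()


def make_loss(cfg: LossConfig) -> Callable:
    """Build ``loss(y, logits) -> Tensor`` (0-d) for the configured variant."""
    unit_weights = None

    def loss(y, logits) -> Tensor:
        nonlocal unit_weights
        y_arr = np.atleast_2d(np.asarray(y, dtype=float))
        if cfg.kind.startswith("cw"):
            weights = cfg.weights
        else:
            if unit_weights is None or len(unit_weights) != y_arr.shape[-1]:
                unit_weights = ClassWeights(
                    w=(1.0,) * y_arr.shape[-1],
                    source_counts=(1,) * y_arr.shape[-1],
                )
            weights = unit_weights
        scalar, per_element = cw_loss(y_arr, logits, weights)
        if cfg.kind.endswith("_f"):
            return focal_modulate(per_element, y_arr, logits, r=cfg.r,
                                  orthodox_focal=cfg.orthodox_focal)
        return scalar

    return loss
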