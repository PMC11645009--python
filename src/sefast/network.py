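"""Dual-pathway spatio-temporal network with squeeze-and-excitation attention.

The model follows the SlowFast design: a *slow* pathway sees N_slow = 4
frames of a 64-frame window (stride 16) at full channel width C_slow, and a
*fast* pathway sees N_fast = 32 frames (stride 2) at a fraction
β = 1/8 of the channels (C_fast = β·C_slow).  At matched stages the fast
pathway is folded into the slow one through lateral connections — a
time-strided convolution (stride α = S_slow/S_fast = 8, kernel 5×1²,
2·C_fast output channels) whose output is concatenated onto the slow
channels.  A squeeze-and-excitation (SE) block — global average pool to a
per-channel descriptor, two-layer bottleneck, sigmoid gate, channel
rescale — can be placed at the front of the slow pathway (after the stem)
or at its end (after the last stage, before the final fusion); the *end*
placement is the default.  Classification is box-conditioned: the fused
final feature map is average-pooled over each annotated/detected region and
passed to a linear multi-label head with one sigmoid output per class.

Two presets exist: ``tiny`` (single-conv stages, C_slow = 16, CPU-friendly;
the default for desk-scale experiments) and ``resnet50-3d`` (bottleneck
stages 3-4-6-3 with C_slow = 64 stem width, the full-fidelity geometry).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor

__all__ = [
    "NetConfig",
    "SEFastNet",
    "se_squeeze",
    "se_excite",
    "se_scale",
    "lateral_fuse",
    "fit",
    "predict_proba",
]

SE_PLACEMENTS = ("none", "front", "end")


@dataclass(frozen=True)
class NetConfig:
    backbone: str = "tiny"  # "tiny" | "resnet50-3d"
    c_slow: int = 16
    beta: float = 1.0 / 8.0
    window_len: int = 64
    s_slow: int = 16
    s_fast: int = 2
    se_placement: str = "end"
    se_reduction: int = 16
    num_classes: int = 5
    lateral_connection_count: int = 4
    input_hw: tuple[int, int] = (36, 64)

    def __post_init__(self) -> None:
        if self.window_len % self.s_slow or self.window_len % self.s_fast:
            raise ValueError(
                f"window length {self.window_len} must be divisible by both strides"
            )
        c_fast = self.beta * self.c_slow
        if c_fast < 1 or abs(c_fast - round(c_fast)) > 1e-9:
            raise ValueError(
                f"beta·C_slow = {c_fast} must be a positive integer "
                f"(beta={self.beta}, C_slow={self.c_slow})"
            )
        if self.se_placement not in SE_PLACEMENTS:
            raise ValueError(f"se_placement must be one of {SE_PLACEMENTS}")
        if self.backbone not in ("tiny", "resnet50-3d"):
            raise ValueError(f"unknown backbone preset {self.backbone!r}")
        if self.s_slow % self.s_fast:
            raise ValueError("slow stride must be a multiple of the fast stride")

    @property
    def n_slow(self) -> int:
        return self.window_len // self.s_slow

    @property
    def n_fast(self) -> int:
        return self.window_len // self.s_fast

    @property
    def c_fast(self) -> int:
        return int(round(self.beta * self.c_slow))

    @property
    def alpha(self) -> int:
        return self.s_slow // self.s_fast

    @classmethod
    def tiny(cls, **overrides) -> "NetConfig":
        kw = dict(backbone="tiny", c_slow=16, input_hw=(18, 32))
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def resnet50_3d(cls, **overrides) -> "NetConfig":
        kw = dict(backbone="resnet50-3d", c_slow=64)
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# squeeze-and-excitation primitives (array-level, used by the module below)


def se_squeeze(u: np.ndarray) -> np.ndarray:
    """Global average pool of a (C, T, H, W) or (N, C, T, H, W) map to per-channel
    descriptors.  Time is included in the pool: the map at the end of the slow
    pathway is temporal, so the channel descriptor averages over T as well as
    space."""
    u = np.asarray(u)
    if u.ndim == 4:
        return u.mean(axis=(1, 2, 3))
    if u.ndim == 5:
        return u.mean(axis=(2, 3, 4))
    raise ValueError(f"expected a 4-D or 5-D feature map, got shape {u.shape}")


def se_excite(z: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Excitation gate s = sigmoid(W2 · relu(W1 · z)); each s_c lies in (0, 1).

    ``w1`` maps C → C/ratio and ``w2`` maps C/ratio → C (rows × columns =
    outputs × inputs)."""
    z = np.asarray(z, dtype=float)
    w1 = np.atleast_2d(np.asarray(w1, dtype=float))
    w2 = np.atleast_2d(np.asarray(w2, dtype=float))
    if w1.shape[1] != z.shape[-1] or w2.shape[1] != w1.shape[0]:
        raise ValueError(
            f"inconsistent SE shapes: z {z.shape}, W1 {w1.shape}, W2 {w2.shape}"
        )
    hidden = np.maximum(z @ w1.T, 0.0)
    x = hidden @ w2.T
    return 1.0 / (1.0 + np.exp(-x))


def se_scale(u: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Rescale each channel of the feature map by its excitation weight."""
    u = np.asarray(u)
    s = np.asarray(s)
    channel_axis = 0 if u.ndim == 4 else 1
    if s.shape[-1] != u.shape[channel_axis]:
        raise ValueError(
            f"excitation length {s.shape[-1]} != channel count {u.shape[channel_axis]}"
        )
    extra = u.ndim - channel_axis - 1
    return u * s.reshape(s.shape + (1,) * extra)


def lateral_fuse(fast_feat: Tensor | np.ndarray, slow_feat: Tensor | np.ndarray,
                 weights: Tensor | np.ndarray, bias: Tensor | np.ndarray | None = None,
                 alpha: int = 8) -> Tensor:
    """Fuse fast-pathway features into the slow pathway at one stage.

    The fast map (N, C_fast, α·T, H, W) is transformed by a time-strided
    convolution (kernel 5×1², stride α, padding 2, output channels = rows of
    ``weights``) and concatenated onto the slow channels.  Spatial dimensions
    must already match."""
    fast_t = fast_feat if isinstance(fast_feat, Tensor) else Tensor(fast_feat)
    slow_t = slow_feat if isinstance(slow_feat, Tensor) else Tensor(slow_feat)
    w = weights if isinstance(weights, Tensor) else Tensor(weights)
    if fast_t.shape[-2:] != slow_t.shape[-2:]:
        raise ValueError(
            f"incompatible spatial dims: fast {fast_t.shape[-2:]}, slow {slow_t.shape[-2:]}"
        )
    if fast_t.shape[2] != alpha * slow_t.shape[2]:
        raise ValueError(
            f"fast temporal length {fast_t.shape[2]} != alpha·slow ({alpha}×{slow_t.shape[2]})"
        )
    b = bias if (bias is None or isinstance(bias, Tensor)) else Tensor(bias)
    transformed = ag.conv3d(fast_t, w, b, stride=(alpha, 1, 1), padding=(2, 0, 0))
    return ag.concatenate([slow_t, transformed], axis=1)


# ---------------------------------------------------------------------------
# the network


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class SEFastNet:
    """Box-conditioned multi-label classifier over slow/fast clip pairs."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}
        self.lateral_calls = 0  # instrumentation: fusions touched per forward
        rng = np.random.default_rng(seed)
        if cfg.backbone == "tiny":
            self._build_tiny(rng)
        else:
            self._build_resnet(rng)

    # -- construction -----------------------------------------------------

    def _add_conv(self, rng, name: str, cin: int, cout: int, k: tuple[int, int, int]):
        fan_in = cin * int(np.prod(k))
        self.params[f"{name}.w"] = Tensor(
            _he_init(rng, (cout, cin) + k, fan_in), requires_grad=True
        )
        self.params[f"{name}.b"] = Tensor(
            np.zeros(cout, dtype=np.float32), requires_grad=True
        )

    def _add_se(self, rng, name: str, channels: int):
        hidden = max(1, channels // self.cfg.se_reduction)
        self.params[f"{name}.w1"] = Tensor(
            _he_init(rng, (hidden, channels), channels), requires_grad=True
        )
        self.params[f"{name}.w2"] = Tensor(
            _he_init(rng, (channels, hidden), hidden), requires_grad=True
        )
        # small positive first-layer bias keeps the narrow bottleneck alive at init
        self.params[f"{name}.b1"] = Tensor(
            np.full(hidden, 0.1, dtype=np.float32), requires_grad=True
        )
        self.params[f"{name}.b2"] = Tensor(
            np.zeros(channels, dtype=np.float32), requires_grad=True
        )

    def _build_tiny(self, rng) -> None:
        cfg = self.cfg
        cs, cf = cfg.c_slow, cfg.c_fast
        self._slow_channels = [cs, 2 * cs, 2 * cs, 2 * cs]
        self._fast_channels = [cf, 2 * cf, 2 * cf, 2 * cf]
        slow_kt = [1, 1, 3, 3]
        self._slow_kt = slow_kt
        self._add_conv(rng, "slow.stem", 3, cs, (1, 3, 3))
        self._add_conv(rng, "fast.stem", 3, cf, (3, 3, 3))
        prev_s, prev_f = cs, cf
        for i, (c_s, c_f, kt) in enumerate(
            zip(self._slow_channels[1:], self._fast_channels[1:], slow_kt[1:]), start=2
        ):
            self._add_conv(rng, f"lateral{i - 1}", prev_f, 2 * prev_f, (5, 1, 1))
            self._add_conv(rng, f"slow.s{i}", prev_s + 2 * prev_f, c_s, (kt, 3, 3))
            self._add_conv(rng, f"fast.s{i}", prev_f, c_f, (3, 3, 3))
            prev_s, prev_f = c_s, c_f
        self._add_conv(rng, "lateral_final", prev_f, 2 * prev_f, (5, 1, 1))
        if cfg.se_placement == "front":
            self._add_se(rng, "se", cs)
        elif cfg.se_placement == "end":
            self._add_se(rng, "se", prev_s)
        fused = prev_s + 2 * prev_f
        self.params["head.w"] = Tensor(
            _he_init(rng, (fused, cfg.num_classes), fused), requires_grad=True
        )
        self.params["head.b"] = Tensor(
            np.zeros(cfg.num_classes, dtype=np.float32), requires_grad=True
        )

    def _build_resnet(self, rng) -> None:
        cfg = self.cfg
        cs, cf = cfg.c_slow, cfg.c_fast  # stem widths, 64 / 8
        self._blocks = (3, 4, 6, 3)
        self._stage_out_slow = [4 * cs, 8 * cs, 16 * cs, 32 * cs]  # 256..2048
        self._stage_out_fast = [4 * cf, 8 * cf, 16 * cf, 32 * cf]  # 32..256
        self._slow_kt = [1, 1, 3, 3]
        self._add_conv(rng, "slow.stem", 3, cs, (1, 7, 7))
        self._add_conv(rng, "fast.stem", 3, cf, (5, 7, 7))
        prev_s, prev_f = cs, cf
        for s, (nb, c_s, c_f, kt) in enumerate(
            zip(self._blocks, self._stage_out_slow, self._stage_out_fast, self._slow_kt),
            start=2,
        ):
            # lateral connections feed the first three stages; the fourth
            # fusion is the final one after res5 (4 fusion points in total)
            if s <= 4:
                self._add_conv(rng, f"lateral{s - 1}", prev_f, 2 * prev_f, (5, 1, 1))
                in_s = prev_s + 2 * prev_f
            else:
                in_s = prev_s
            in_f = prev_f
            for b in range(nb):
                mid_s, mid_f = c_s // 4, c_f // 4
                self._add_conv(rng, f"slow.res{s}.{b}.a", in_s if b == 0 else c_s,
                               mid_s, (kt, 1, 1))
                self._add_conv(rng, f"slow.res{s}.{b}.b", mid_s, mid_s, (1, 3, 3))
                self._add_conv(rng, f"slow.res{s}.{b}.c", mid_s, c_s, (1, 1, 1))
                self._add_conv(rng, f"fast.res{s}.{b}.a", in_f if b == 0 else c_f,
                               mid_f, (3, 1, 1))
                self._add_conv(rng, f"fast.res{s}.{b}.b", mid_f, mid_f, (1, 3, 3))
                self._add_conv(rng, f"fast.res{s}.{b}.c", mid_f, c_f, (1, 1, 1))
                if b == 0:
                    self._add_conv(rng, f"slow.res{s}.skip", in_s, c_s, (1, 1, 1))
                    self._add_conv(rng, f"fast.res{s}.skip", in_f, c_f, (1, 1, 1))
            prev_s, prev_f = c_s, c_f
        self._add_conv(rng, "lateral_final", prev_f, 2 * prev_f, (5, 1, 1))
        if cfg.se_placement == "front":
            self._add_se(rng, "se", cs)
        elif cfg.se_placement == "end":
            self._add_se(rng, "se", prev_s)
        fused = prev_s + 2 * prev_f
        self.params["head.w"] = Tensor(
            _he_init(rng, (fused, cfg.num_classes), fused), requires_grad=True
        )
        self.params["head.b"] = Tensor(
            np.zeros(cfg.num_classes, dtype=np.float32), requires_grad=True
        )

    # -- forward ----------------------------------------------------------

    @staticmethod
    def _norm(x: Tensor) -> Tensor:
        """Per-sample, per-channel normalization over (T, H, W); batch-free,
        so train and inference behave identically."""
        return ag.instance_norm(x)

    def _conv(self, name: str, x: Tensor, stride, padding) -> Tensor:
        return ag.conv3d(x, self.params[f"{name}.w"], self.params[f"{name}.b"],
                         stride=stride, padding=padding)

    def _se_apply(self, x: Tensor, force_unit_excitation: bool) -> Tensor:
        if force_unit_excitation:
            return x * 1.0
        z = x.mean(axis=(2, 3, 4))  # (N, C) squeeze, time included
        hidden = (z @ self.params["se.w1"].transpose((1, 0))
                  + self.params["se.b1"]).relu()
        s = (hidden @ self.params["se.w2"].transpose((1, 0))
             + self.params["se.b2"]).sigmoid()
        return x * s.reshape(s.shape[0], s.shape[1], 1, 1, 1)

    def _lateral(self, name: str, fast: Tensor, slow: Tensor) -> Tensor:
        self.lateral_calls += 1
        return lateral_fuse(fast, slow, self.params[f"{name}.w"],
                            self.params[f"{name}.b"], alpha=self.cfg.alpha)

    def forward(self, slow: np.ndarray | Tensor, fast: np.ndarray | Tensor,
                rois: Sequence[tuple[int, float, float, float, float]],
                force_unit_excitation: bool = False) -> Tensor:
        """Per-box logits of shape (len(rois), num_classes).

        ``slow``/``fast`` are (B, 3, T, H, W) clips; ``rois`` are
        ``(batch_index, x1, y1, x2, y2)`` normalized boxes.  Detection is a
        prerequisite of recognition: an empty box list is an error."""
        if len(rois) == 0:
            raise ValueError("at least one box is required (detection precedes recognition)")
        self.lateral_calls = 0
        xs = slow if isinstance(slow, Tensor) else Tensor(slow)
        xf = fast if isinstance(fast, Tensor) else Tensor(fast)
        if self.cfg.backbone == "tiny":
            fused = self._forward_tiny(xs, xf, force_unit_excitation)
        else:
            fused = self._forward_resnet(xs, xf, force_unit_excitation)
        pooled = ag.roi_pool(fused, rois)
        return pooled @ self.params["head.w"] + self.params["head.b"]

    def _forward_tiny(self, xs: Tensor, xf: Tensor, force_unit: bool) -> Tensor:
        cfg = self.cfg
        s = self._norm(self._conv("slow.stem", xs, (1, 2, 2), (0, 1, 1))).relu()
        f = self._norm(self._conv("fast.stem", xf, (1, 2, 2), (1, 1, 1))).relu()
        if cfg.se_placement == "front":
            s = self._se_apply(s, force_unit)
        for i in range(2, 5):
            kt = self._slow_kt[i - 1]
            s = self._lateral(f"lateral{i - 1}", f, s)
            s = self._norm(self._conv(f"slow.s{i}", s, (1, 2, 2), (kt // 2, 1, 1))).relu()
            f = self._norm(self._conv(f"fast.s{i}", f, (1, 2, 2), (1, 1, 1))).relu()
        if cfg.se_placement == "end":
            s = self._se_apply(s, force_unit)
        return self._lateral("lateral_final", f, s)

    def _forward_resnet(self, xs: Tensor, xf: Tensor, force_unit: bool) -> Tensor:
        cfg = self.cfg
        s = self._norm(self._conv("slow.stem", xs, (1, 2, 2), (0, 3, 3))).relu()
        f = self._norm(self._conv("fast.stem", xf, (1, 2, 2), (2, 3, 3))).relu()
        if cfg.se_placement == "front":
            s = self._se_apply(s, force_unit)
        for stage, (nb, kt) in enumerate(zip(self._blocks, self._slow_kt), start=2):
            if stage <= 4:
                s = self._lateral(f"lateral{stage - 1}", f, s)
            stride = (1, 2, 2)
            for b in range(nb):
                s = self._res_block("slow", stage, b, s, kt,
                                    stride if b == 0 else (1, 1, 1))
                f = self._res_block("fast", stage, b, f, 3,
                                    stride if b == 0 else (1, 1, 1))
        if cfg.se_placement == "end":
            s = self._se_apply(s, force_unit)
        return self._lateral("lateral_final", f, s)

    def _res_block(self, path: str, stage: int, b: int, x: Tensor, kt: int,
                   stride) -> Tensor:
        name = f"{path}.res{stage}.{b}"
        h = self._norm(self._conv(f"{name}.a", x, (1, 1, 1), (kt // 2, 0, 0))).relu()
        h = self._norm(self._conv(f"{name}.b", h, stride, (0, 1, 1))).relu()
        h = self._norm(self._conv(f"{name}.c", h, (1, 1, 1), (0, 0, 0)))
        if b == 0:
            x = self._conv(f"{path}.res{stage}.skip", x, stride, (0, 0, 0))
        return (h + x).relu()

    # -- inference and persistence ----------------------------------------

    def predict_proba(self, slow, fast, rois, batch_size: int = 32) -> np.ndarray:
        """Per-box class probabilities (sigmoid of logits), computed without
        building a gradient graph."""
        out = []
        with ag.no_grad():
            roi_arr = list(rois)
            batch_ids = sorted({r[0] for r in roi_arr})
            for start in range(0, len(batch_ids), batch_size):
                ids = batch_ids[start:start + batch_size]
                remap = {bi: i for i, bi in enumerate(ids)}
                sub_rois = [(remap[r[0]], *r[1:]) for r in roi_arr if r[0] in remap]
                logits = self.forward(slow[ids], fast[ids], sub_rois)
                out.append(1.0 / (1.0 + np.exp(-logits.data)))
        return np.concatenate(out, axis=0)

    def save(self, path: str | Path) -> None:
        """Checkpoint: one npz with every parameter plus the embedded config."""
        arrays = {k: p.data for k, p in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SEFastNet":
        data = np.load(path)
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["input_hw"] = tuple(cfg_dict["input_hw"])
        net = cls(NetConfig(**cfg_dict))
        for key in net.params:
            net.params[key] = Tensor(data[key], requires_grad=True)
        return net


# ---------------------------------------------------------------------------
# training


def fit(net: SEFastNet, data, loss_fn, epochs: int = 4, batch_size: int = 16,
        lr: float = 3e-3, seed: int = 0, augment: float = 0.5,
        verbose: bool = False) -> list[float]:
    """Train on a :class:`~sefast.pipeline.ClipDataset` with Adam.

    Augmentation (photometric only) is applied online to a random subset of
    each batch, reseeded per epoch from ``seed``.  Returns the mean training
    loss per epoch; fully deterministic given ``seed``.
    """
    opt = ag.Adam(net.params, lr=lr)
    history = []
    n = len(data)
    for epoch in range(epochs):
        rng = np.random.default_rng(np.random.SeedSequence((seed, epoch)))
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            slow, fast, rois, y = data.tensors(idx, rng=rng, augment=augment)
            logits = net.forward(slow, fast, rois)
            loss = loss_fn(y, logits)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}: loss {history[-1]:.4f}")
    return history


def predict_proba(net: SEFastNet, data, batch_size: int = 32) -> np.ndarray:
    """Class probabilities for every clip of a dataset (one box per clip)."""
    out = []
    with ag.no_grad():
        for start in range(0, len(data), batch_size):
            idx = np.arange(start, min(start + batch_size, len(data)))
            slow, fast, rois, _ = data.tensors(idx)
            logits = net.forward(slow, fast, rois)
            out.append(1.0 / (1.0 + np.exp(-logits.data)))
    return np.concatenate(out, axis=0)
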