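"""Teacher and student despeckling networks built from declarative specs.

The **teacher** is a U-Net-style encoder–decoder: conv/BN/LeakyReLU blocks,
2×2 max-pooling down to a small-spatial/high-depth bottleneck (4×4×1024 for
a 64×64 input at the default depth 4), a mirrored decoder using nearest-
neighbour 2× upsampling followed by convolution, and skip connections that
concatenate encoder features into the matching decoder stage.  The final
convolution is linear and maps back to the input channel count, so the
network maps ``H×W×C → H×W×C``.

The **student** is deliberately uniform and shallow: an input block, a
stack of identically-shaped conv/BN/LeakyReLU blocks (16 by default) at
constant spatial size — no pooling, no bottleneck — and a linear output
convolution.

Both networks offer an optional global residual head (``output = input +
correction``) whose final convolution is zero-initialized, so training
starts exactly at the identity map.  For a denoiser this is the natural
starting point — the first gradient steps then learn the noise rather
than having to rediscover the image — and it keeps the PSNR-normalized
objective well-behaved from the first batch (the divisor starts at the
noisy input's PSNR instead of an arbitrary initialization's).

``width_multiplier`` scales every filter count so the same topology can be
trained quickly on one CPU; it is recorded on the handle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Conv2d, ConvBlock, MaxPool2d, Module, Tensor, UpsampleNearest2d, concat, no_grad,
)


@dataclass
class ConvBlockSpec:
    """Conv → batch-norm → leaky-rectifier settings shared by both networks."""

    filters: int = 64
    kernel: int = 3
    activation: float = 0.2           # LeakyReLU negative slope
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.filters < 1:
            raise ValueError("filters must be >= 1")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")


@dataclass
class TeacherSpec:
    """Encoder–decoder teacher: depth pooling stages down to the bottleneck."""

    input_size: tuple[int, int, int] = (64, 64, 3)
    base_filters: int = 64
    depth: int = 4
    bottleneck_filters: int = 1024
    skip_connections: bool = True
    width_multiplier: float = 1.0
    residual_output: bool = False
    block: ConvBlockSpec = field(default_factory=ConvBlockSpec)

    def __post_init__(self) -> None:
        h, w, c = self.input_size
        if c not in (1, 3):
            raise ValueError("channel count must be 1 or 3")
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must be in (0, 1]")
        if h % 2 ** self.depth or w % 2 ** self.depth:
            raise ValueError(
                f"input sides {h}x{w} must be divisible by 2^depth = {2 ** self.depth}")

    def stage_filters(self) -> list[int]:
        """Per-stage encoder filter counts (doubling, capped at the bottleneck)."""
        m = self.width_multiplier
        return [max(1, int(round(min(self.base_filters * 2 ** k,
                                     self.bottleneck_filters) * m)))
                for k in range(self.depth)]

    @property
    def bottleneck_width(self) -> int:
        return max(1, int(round(self.bottleneck_filters * self.width_multiplier)))

    @property
    def bottleneck_side(self) -> int:
        return self.input_size[0] // 2 ** self.depth


@dataclass
class StudentSpec:
    """Uniform-block student: constant spatial size, no bottleneck."""

    input_size: tuple[int, int, int] = (64, 64, 3)
    n_blocks: int = 16
    filters: int = 64
    residual_output: bool = False
    block: ConvBlockSpec = field(default_factory=ConvBlockSpec)

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.filters < 1:
            raise ValueError("filters must be >= 1")
        if self.input_size[2] not in (1, 3):
            raise ValueError("channel count must be 1 or 3")


class TeacherNet(Module):
    def __init__(self, spec: TeacherSpec, rng: np.random.Generator):
        c = spec.input_size[2]
        fs = spec.stage_filters()
        blk = spec.block
        self.skip_connections = spec.skip_connections
        self.enc = []
        prev = c
        for f in fs:
            self.enc.append(ConvBlock(prev, f, blk.kernel, blk.activation,
                                      blk.batch_norm, rng=rng))
            prev = f
        self.pool = MaxPool2d(2)
        self.bottleneck = ConvBlock(prev, spec.bottleneck_width, blk.kernel,
                                    blk.activation, blk.batch_norm, rng=rng)
        self.up = UpsampleNearest2d(2)
        self.dec_up = []        # conv after upsampling
        self.dec_fuse = []      # conv after skip concatenation
        prev = spec.bottleneck_width
        for f in reversed(fs):
            self.dec_up.append(ConvBlock(prev, f, blk.kernel, blk.activation,
                                         blk.batch_norm, rng=rng))
            fuse_in = 2 * f if spec.skip_connections else f
            self.dec_fuse.append(ConvBlock(fuse_in, f, blk.kernel, blk.activation,
                                           blk.batch_norm, rng=rng))
            prev = f
        self.residual_output = spec.residual_output
        # residual nets start exactly at the identity: the head is zero-init
        self.head = Conv2d(prev, c, blk.kernel, rng=rng,
                           zero_init=spec.residual_output)

    def forward(self, x: Tensor) -> Tensor:
        inp = x
        skips = []
        for enc in self.enc:
            x = enc(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for up_conv, fuse, skip in zip(self.dec_up, self.dec_fuse, reversed(skips)):
            x = up_conv(self.up(x))
            if self.skip_connections:
                x = concat([skip, x], axis=-1)
            x = fuse(x)
        x = self.head(x)
        if self.residual_output:
            x = inp + x
        return x


class StudentNet(Module):
    def __init__(self, spec: StudentSpec, rng: np.random.Generator):
        c = spec.input_size[2]
        blk = spec.block
        self.residual_output = spec.residual_output
        self.stem = ConvBlock(c, spec.filters, blk.kernel, blk.activation,
                              blk.batch_norm, rng=rng)
        self.blocks = [ConvBlock(spec.filters, spec.filters, blk.kernel,
                                 blk.activation, blk.batch_norm, rng=rng)
                       for _ in range(spec.n_blocks)]
        # residual nets start exactly at the identity: the head is zero-init
        self.head = Conv2d(spec.filters, c, blk.kernel, rng=rng,
                           zero_init=spec.residual_output)

    def forward(self, x: Tensor) -> Tensor:
        y = self.stem(x)
        for block in self.blocks:
            y = block(y)
        y = self.head(y)
        if self.residual_output:
            y = x + y
        return y


@dataclass
class NetworkHandle:
    """A built network plus the spec and seed that produced it."""

    module: Module
    spec: TeacherSpec | StudentSpec
    seed: int
    kind: str                                   # "teacher" | "student"

    @property
    def parameter_count(self) -> int:
        return self.module.parameter_count()

    def _validate(self, x: np.ndarray) -> None:
        c_expected = self.spec.input_size[2]
        if x.ndim != 4 or x.shape[3] != c_expected:
            raise ValueError(
                f"expected (N, H, W, {c_expected}) input, got shape {x.shape}")
        if self.kind == "teacher":
            d = 2 ** self.spec.depth
            if x.shape[1] % d or x.shape[2] % d:
                raise ValueError(
                    f"teacher input sides {x.shape[1:3]} must be divisible by {d}")

    def forward_tensor(self, x: Tensor, training: bool = False) -> Tensor:
        """Run the graph-building forward pass (used by the trainers)."""
        self._validate(x.data if isinstance(x, Tensor) else x)
        self.module.train() if training else self.module.eval()
        return self.module(x)

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Inference on a numpy batch; layout is preserved.

        Accepts ``(N, H, W)`` or channels-last ``(N, H, W, C)``; the
        computation runs in float32, the network's parameter precision.
        """
        batch = np.asarray(batch)
        squeeze = batch.ndim == 3
        x = batch[..., None] if squeeze else batch
        x = x.astype(np.float32, copy=False)
        self._validate(x)
        self.module.eval()
        with no_grad():
            out = self.module(Tensor(x)).data
        out = out.astype(np.float64)
        return out[..., 0] if squeeze else out


def build_teacher(spec: TeacherSpec | None = None, seed: int = 0) -> NetworkHandle:
    """Build (and deterministically initialize) the teacher network."""
    spec = spec or TeacherSpec()
    rng = np.random.default_rng(seed)
    return NetworkHandle(TeacherNet(spec, rng), spec, seed, "teacher")


def build_student(spec: StudentSpec | None = None, seed: int = 0) -> NetworkHandle:
    """Build (and deterministically initialize) the student network."""
    spec = spec or StudentSpec()
    rng = np.random.default_rng(seed)
    return NetworkHandle(StudentNet(spec, rng), spec, seed, "student")


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(handle: NetworkHandle, path: str) -> None:
    """Save weights plus the spec and seed in a single ``.npz`` container."""
    meta = {"kind": handle.kind, "seed": handle.seed,
            "spec": asdict(handle.spec)}
    state = handle.module.named_state()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str) -> NetworkHandle:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    spec_d = meta["spec"]
    block = ConvBlockSpec(**spec_d.pop("block"))
    spec_d["input_size"] = tuple(spec_d["input_size"])
    if meta["kind"] == "teacher":
        handle = build_teacher(TeacherSpec(block=block, **spec_d), seed=meta["seed"])
    else:
        handle = build_student(StudentSpec(block=block, **spec_d), seed=meta["seed"])
    handle.module.load_state(state)
    return handle
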