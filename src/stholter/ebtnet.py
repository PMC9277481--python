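"""1D bidirectional shifted-window transformer (EBTnet) for ECG.

A U-Net-shaped encoder/decoder whose blocks are window-restricted
multi-head self-attention over 1D feature sequences.  Successive blocks
cycle through three window alignments — unshifted, forward-shifted and
backward-shifted by half a window — so features near window boundaries
mix with both neighbors.  Shifting is a plain cyclic roll of the feature
sequence (no attention masking).  One shared single-lead model serves all
leads; the denoising and segmentation variants differ only in the final
linear projection.

Geometry defaults target 7168-sample (14.336 s at 500 Hz) input patches:
a stride-2 patch embedding brings the sequence to 3584 positions, which
stays divisible by the fixed window size of 112 through three halvings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import LayerNorm, Linear, Module, Parameter, Tensor, concat

MODES = ("unshifted", "forward", "backward")


class ConfigError(ValueError):
    """Model geometry is inconsistent."""


@dataclass
class ModelConfig:
    input_length: int = 7168
    window_size: int = 112
    patch_kernel: int = 4
    patch_stride: int = 2
    stage_depths: tuple[int, ...] = (3, 3, 3, 3)
    stage_channels: tuple[int, ...] = (32, 64, 128, 256)
    stage_heads: tuple[int, ...] = (2, 4, 8, 8)
    mlp_ratio: int = 4
    task: str = "denoise"
    n_classes: int = 3

    def __post_init__(self):
        self.stage_depths = tuple(self.stage_depths)
        self.stage_channels = tuple(self.stage_channels)
        self.stage_heads = tuple(self.stage_heads)
        if self.task not in ("denoise", "segment"):
            raise ConfigError(f"unknown task {self.task!r}")
        if self.window_size % 2:
            raise ConfigError("window size must be even (shift is half a window)")
        if self.input_length % self.patch_stride:
            raise ConfigError("input length must be divisible by the embed stride")
        n = len(self.stage_depths)
        if not (len(self.stage_channels) == len(self.stage_heads) == n):
            raise ConfigError("stage depths/channels/heads must align")
        for d in self.stage_depths:
            if d % 3:
                raise ConfigError("stage depth must be a multiple of 3 "
                                  "(unshifted/forward/backward triplets)")
        for c, h in zip(self.stage_channels, self.stage_heads):
            if c % h:
                raise ConfigError("channels must be divisible by heads")
        length = self.input_length // self.patch_stride
        for i in range(n):
            if length % self.window_size:
                raise ConfigError(
                    f"stage {i} length {length} not divisible by window "
                    f"{self.window_size}")
            if i < n - 1:
                if length % 2:
                    raise ConfigError("stage length must halve evenly")
                length //= 2

    @property
    def shift(self) -> int:
        return self.window_size // 2

    @property
    def embed_length(self) -> int:
        return self.input_length // self.patch_stride

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def mode_sequence(depth: int) -> tuple[str, ...]:
    """Block shift modes within a stage: (unshifted, forward, backward) tiled."""
    return tuple(MODES[i % 3] for i in range(depth))


# ---------------------------------------------------------------------------
# window partitioning (numpy; the model applies the same index arithmetic
# through differentiable roll/reshape ops)
# ---------------------------------------------------------------------------

def partition_windows(x: np.ndarray, window_size: int,
                      mode: str = "unshifted") -> np.ndarray:
    """Split a [L, ...] feature sequence into [L/window, window, ...] windows.

    ``forward`` first moves the leading half-window to the tail (cyclic roll
    by −window/2); ``backward`` moves the trailing half-window to the front
    (roll by +window/2).  :func:`merge_windows` is the exact inverse.
    """
    x = np.asarray(x)
    L = x.shape[0]
    if L % window_size:
        raise ValueError(f"length {L} not divisible by window {window_size}")
    shift = window_size // 2
    if mode == "forward":
        x = np.roll(x, -shift, axis=0)
    elif mode == "backward":
        x = np.roll(x, shift, axis=0)
    elif mode != "unshifted":
        raise ValueError(f"unknown mode {mode!r}")
    return x.reshape((L // window_size, window_size) + x.shape[1:])


def merge_windows(windows: np.ndarray, mode: str = "unshifted") -> np.ndarray:
    """Inverse of :func:`partition_windows`."""
    windows = np.asarray(windows)
    n_win, window_size = windows.shape[:2]
    x = windows.reshape((n_win * window_size,) + windows.shape[2:])
    shift = window_size // 2
    if mode == "forward":
        x = np.roll(x, shift, axis=0)
    elif mode == "backward":
        x = np.roll(x, -shift, axis=0)
    elif mode != "unshifted":
        raise ValueError(f"unknown mode {mode!r}")
    return x


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class PatchEmbed(Module):
    """Strided framed projection: kernel 4, stride 2, padding 1 → L/2."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 kernel: int = 4, stride: int = 2):
        self.kernel = kernel
        self.stride = stride
        self.proj = Linear(kernel, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, L = x.shape
        if L % self.stride:
            raise ConfigError(f"input length {L} not divisible by stride {self.stride}")
        pad = (self.kernel - self.stride) // 2
        zeros = Tensor(np.zeros((B, pad)))
        padded = concat([zeros, x, zeros], axis=1)          # [B, L + 2·pad]
        idx = (np.arange(L // self.stride)[:, None] * self.stride
               + np.arange(self.kernel)[None, :])           # [L/2, kernel]
        frames = padded.take(idx, axis=1)                   # [B, L/2, kernel]
        return self.proj(frames)


class WindowAttention(Module):
    """Multi-head self-attention within fixed windows, with a learned
    relative-position bias per head over offsets in (−M, M)."""

    def __init__(self, channels: int, n_heads: int, window_size: int,
                 rng: np.random.Generator):
        if channels % n_heads:
            raise ConfigError("channels must be divisible by heads")
        self.n_heads = n_heads
        self.window_size = window_size
        self.head_dim = channels // n_heads
        self.q = Linear(channels, channels, rng)
        self.k = Linear(channels, channels, rng)
        self.v = Linear(channels, channels, rng)
        self.proj = Linear(channels, channels, rng)
        self.bias_table = Parameter(np.zeros((n_heads, 2 * window_size - 1)))
        offs = np.arange(window_size)
        self._rel_index = offs[:, None] - offs[None, :] + window_size - 1

    def forward(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        M, H, d = self.window_size, self.n_heads, self.head_dim
        nW = L // M

        def split_heads(t: Tensor) -> Tensor:
            return (t.reshape(B, nW, M, H, d)
                     .transpose((0, 1, 3, 2, 4)))          # [B, nW, H, M, d]

        q = split_heads(self.q(x.reshape(B, nW, M, C)))
        k = split_heads(self.k(x.reshape(B, nW, M, C)))
        v = split_heads(self.v(x.reshape(B, nW, M, C)))
        bias = self.bias_table.take(self._rel_index, axis=1)  # [H, M, M]
        scores = q @ k.transpose((0, 1, 2, 4, 3)) * (1.0 / np.sqrt(d)) + bias
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose((0, 1, 3, 2, 4)).reshape(B, L, C)
        return self.proj(out)


class SwtBlock(Module):
    """Pre-norm transformer block under one shift mode.

    y1 = x + SW-MSA(LN(x)) with the sequence cyclically rolled by ±M/2
    around the attention for the forward/backward modes;
    y = y1 + MLP(LN(y1)), MLP = Linear → GELU → Linear (×mlp_ratio wide).
    """

    def __init__(self, channels: int, n_heads: int, window_size: int,
                 mode: str, mlp_ratio: int, rng: np.random.Generator):
        if mode not in MODES:
            raise ConfigError(f"unknown shift mode {mode!r}")
        self.mode = mode
        self.shift = window_size // 2
        self.ln1 = LayerNorm(channels)
        self.attn = WindowAttention(channels, n_heads, window_size, rng)
        self.ln2 = LayerNorm(channels)
        self.fc1 = Linear(channels, mlp_ratio * channels, rng)
        self.fc2 = Linear(mlp_ratio * channels, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.ln1(x)
        if self.mode == "forward":
            h = h.roll(-self.shift, axis=1)
        elif self.mode == "backward":
            h = h.roll(self.shift, axis=1)
        h = self.attn(h)
        if self.mode == "forward":
            h = h.roll(self.shift, axis=1)
        elif self.mode == "backward":
            h = h.roll(-self.shift, axis=1)
        y1 = x + h
        return y1 + self.fc2(self.fc1(self.ln2(y1)).gelu())


class Stage(Module):
    """A run of blocks cycling unshifted → forward → backward."""

    def __init__(self, depth: int, channels: int, n_heads: int,
                 window_size: int, mlp_ratio: int, rng: np.random.Generator):
        self.blocks = [
            SwtBlock(channels, n_heads, window_size, mode, mlp_ratio, rng)
            for mode in mode_sequence(depth)
        ]

    @property
    def modes(self) -> tuple[str, ...]:
        return tuple(b.mode for b in self.blocks)

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x


class Downsample(Module):
    """Halve the length, pairing neighbors into channels, then project."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.proj = Linear(2 * c_in, c_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        return self.proj(x.reshape(B, L // 2, 2 * C))


class Upsample(Module):
    """Double the length via a learned projection to 2× sub-positions."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_out = c_out
        self.proj = Linear(c_in, 2 * c_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        return self.proj(x).reshape(B, 2 * L, self.c_out)


class EBTNet(Module):
    """Encoder–decoder with bidirectional shifted-window attention blocks."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.stage_channels
        heads = config.stage_heads
        depths = config.stage_depths
        W, R = config.window_size, config.mlp_ratio
        n = len(depths)

        # encoder (the inheritable subset: patch_embed + enc_stages + downsamples)
        self.patch_embed = PatchEmbed(ch[0], rng, kernel=config.patch_kernel,
                                      stride=config.patch_stride)
        self.enc_stages = [Stage(depths[i], ch[i], heads[i], W, R, rng)
                           for i in range(n)]
        self.downsamples = [Downsample(ch[i], ch[i + 1], rng)
                            for i in range(n - 1)]

        # decoder
        self.upsamples = [Upsample(ch[i + 1], ch[i], rng)
                          for i in reversed(range(n - 1))]
        self.fuse = [Linear(2 * ch[i], ch[i], rng)
                     for i in reversed(range(n - 1))]
        self.dec_stages = [Stage(depths[i], ch[i], heads[i], W, R, rng)
                           for i in reversed(range(n - 1))]

        # final ×2 upsample restores the pre-embedding resolution
        self.head_up = Upsample(ch[0], ch[0], rng)
        out_ch = 1 if config.task == "denoise" else config.n_classes
        self.head_proj = Linear(ch[0], out_ch, rng)

    # -- encoder/decoder surfaces ------------------------------------------
    def encode(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        if x.shape[1] != self.config.input_length:
            raise ConfigError(
                f"expected input length {self.config.input_length}, "
                f"got {x.shape[1]}")
        h = self.patch_embed(x)
        skips: list[Tensor] = []
        for i, stage in enumerate(self.enc_stages):
            h = stage(h)
            if i < len(self.downsamples):
                skips.append(h)
                h = self.downsamples[i](h)
        return h, skips

    def decode(self, bottleneck: Tensor, skips: list[Tensor]) -> Tensor:
        if len(skips) != len(self.upsamples):
            raise ConfigError(
                f"expected {len(self.upsamples)} skip connections, "
                f"got {len(skips)}")
        h = bottleneck
        for up, fuse, stage, skip in zip(self.upsamples, self.fuse,
                                         self.dec_stages, reversed(skips)):
            h = up(h)
            h = fuse(concat([h, skip], axis=-1))
            h = stage(h)
        return h

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.atleast_2d(x))
        bottleneck, skips = self.encode(x)
        features = self.decode(bottleneck, skips)
        out = self.head_proj(self.head_up(features))
        if self.config.task == "denoise":
            B, L, _ = out.shape
            return out.reshape(B, L)
        return out                                          # [B, L, n_classes]

    def predict(self, signal: np.ndarray) -> np.ndarray:
        """Inference on a [L] or [B, L] array; returns numpy output."""
        squeeze = np.asarray(signal).ndim == 1
        out = self.forward(np.atleast_2d(signal)).data
        if self.config.task == "segment":
            out = np.argmax(out, axis=-1)
        return out[0] if squeeze else out

    # -- inheritance support -------------------------------------------------
    ENCODER_PREFIXES = ("patch_embed.", "enc_stages.", "downsamples.")

    def encoder_state_dict(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.state_dict().items()
                if k.startswith(self.ENCODER_PREFIXES)}

    def load_encoder(self, encoder_state: dict[str, np.ndarray]) -> None:
        expected = set(self.encoder_state_dict())
        if set(encoder_state) != expected:
            raise ConfigError("encoder geometry mismatch between tasks")
        try:
            self.load_state_dict(encoder_state)
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"encoder geometry mismatch: {exc}") from exc


# ---------------------------------------------------------------------------
# checkpointing: single npz archive holding config JSON + named tensors
# ---------------------------------------------------------------------------

def save_checkpoint(model: EBTNet, path) -> None:
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["config"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> EBTNet:
    with np.load(path) as archive:
        config = ModelConfig.from_dict(
            json.loads(bytes(archive["config"].tobytes()).decode()))
        state = {k[len("param/"):]: archive[k]
                 for k in archive.files if k.startswith("param/")}
    model = EBTNet(config, seed=0)
    model.load_state_dict(state)
    return model
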