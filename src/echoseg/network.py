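"""Segmentation architecture: residual blocks, fused spatial-channel
attention, and the attention-gated U-Net assembly.

The network is a U-Net whose level blocks are residual (two conv+BN+ReLU
layers plus a projected identity, ``u = c(v, w_h) + w v``) and whose skip
connections pass through a Spatial-Channel Attention Block (SCAB) before
being concatenated into the decoder.  SCAB runs the input through a
spatial gate (channel-wise max/mean maps -> conv -> sigmoid) and a channel
gate (global max/avg pooling -> shared bottleneck MLP -> sigmoid), then
concatenates the two gated copies and projects back to the input width.
RSCAB embeds SCAB behind a 1x1 dimension-raising convolution and carries
the ungated input forward through concatenation, so shallow attention
survives into deeper features.

The residual identity means the block's input-output Jacobian is
``I + dc/dv``: gradients cannot vanish through a stack of such blocks,
which is the point of using them on noisy, low-contrast ultrasound.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autograd import Tensor, concat
from .errors import ConfigError
from .nn import BatchNorm2d, Conv2d, Module, ModuleList

__all__ = [
    "ArchConfig",
    "ResidualBlock",
    "SpatialAttention",
    "ChannelAttention",
    "SCAB",
    "RSCAB",
    "AttentionUNet",
    "build_model",
    "predict_probs",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters.

    ``depth`` counts encoder levels including the bottleneck; channels
    double and spatial size halves at each level, so inputs must be
    divisible by ``2**(depth-1)``.  ``attention`` selects where the fused
    attention sits: ``"scab"`` gates the skip connections (default),
    ``"rscab"`` additionally appends an RSCAB to every level block,
    ``"none"`` gives a plain residual U-Net.
    """

    depth: int = 4
    base_channels: int = 16
    kernel_size: int = 3
    attention: str = "scab"
    spatial_kernel: int = 7
    channel_reduction: int = 4
    input_size: tuple[int, int] = (64, 64)

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigError(f"depth must be >= 2, got {self.depth}")
        if self.base_channels < 1:
            raise ConfigError(
                f"base_channels must be >= 1, got {self.base_channels}"
            )
        if self.kernel_size < 1:
            raise ConfigError(f"kernel_size must be >= 1, got {self.kernel_size}")
        if self.attention not in ("scab", "rscab", "none"):
            raise ConfigError(
                f"attention must be 'scab', 'rscab' or 'none', got {self.attention!r}"
            )
        p, q = self.input_size
        div = 2 ** (self.depth - 1)
        if p % div or q % div:
            raise ConfigError(
                f"input_size {self.input_size} not divisible by 2^(depth-1)={div}"
            )

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.depth)]


class ResidualBlock(Module):
    """u = c(v, w_h) + w v with c = two conv+BN+ReLU layers.

    The projection ``w`` is a 1x1 convolution, present when input and
    output widths differ (or when forced); otherwise the identity is used.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 force_projection: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, kernel_size, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, kernel_size, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        if in_channels != out_channels or force_projection:
            self.project = Conv2d(in_channels, out_channels, 1, bias=False, rng=rng)
        else:
            self.project = None

    def forward(self, v: Tensor) -> Tensor:
        c = self.bn1(self.conv1(v)).relu()
        c = self.bn2(self.conv2(c)).relu()
        skip = v if self.project is None else self.project(v)
        return c + skip


class SpatialAttention(Module):
    """Where-to-look gate: channel-wise max/mean maps -> conv -> sigmoid."""

    def __init__(self, kernel_size: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel_size, bias=True, rng=rng)

    def gate(self, b: Tensor) -> Tensor:
        mx = b.max(axis=1, keepdims=True)
        mn = b.mean(axis=1, keepdims=True)
        return self.conv(concat([mx, mn], axis=1)).sigmoid()

    def forward(self, b: Tensor) -> Tensor:
        return b * self.gate(b)


class ChannelAttention(Module):
    """Which-features-matter gate: global max+avg pooling through a shared
    bottleneck MLP (1x1 convolutions), summed and squashed to (0, 1)."""

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = channels // reduction
        if hidden < 1:
            raise ConfigError(
                f"channel_reduction={reduction} leaves no hidden unit for "
                f"{channels} channels"
            )
        self.fc1 = Conv2d(channels, hidden, 1, bias=True, rng=rng)
        self.fc2 = Conv2d(hidden, channels, 1, bias=True, rng=rng)

    def gate(self, b: Tensor) -> Tensor:
        pmax = b.max(axis=(2, 3), keepdims=True)
        pavg = b.mean(axis=(2, 3), keepdims=True)
        z = self.fc2(self.fc1(pmax).relu()) + self.fc2(self.fc1(pavg).relu())
        return z.sigmoid()

    def forward(self, b: Tensor) -> Tensor:
        return b * self.gate(b)


class SCAB(Module):
    """Spatial-Channel Attention Block.

    Concatenates the spatially gated and channel-gated copies of the input
    (2G channels) and projects back to G channels with a 1x1 convolution so
    the output composes with skip concatenation.
    """

    def __init__(self, channels: int, spatial_kernel: int = 7, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.project = Conv2d(2 * channels, channels, 1, bias=True, rng=rng)

    def forward(self, b: Tensor) -> Tensor:
        return self.project(concat([self.spatial(b), self.channel(b)], axis=1))


class RSCAB(Module):
    """Residual SCAB: attention behind a 1x1 dimension-raising convolution,
    with the ungated input carried forward through concatenation.

    d_att = SCAB(conv1x1(d)); output = conv1x1(Cat(d_att, d)).
    """

    def __init__(self, in_channels: int, out_channels: int,
                 spatial_kernel: int = 7, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.raise_conv = Conv2d(in_channels, out_channels, 1, bias=True, rng=rng)
        self.scab = SCAB(out_channels, spatial_kernel, reduction, rng=rng)
        self.fuse_conv = Conv2d(out_channels + in_channels, out_channels, 1,
                                bias=True, rng=rng)

    def forward(self, d: Tensor) -> Tensor:
        d_att = self.scab(self.raise_conv(d))
        return self.fuse_conv(concat([d_att, d], axis=1))


class _UpBlock(Module):
    """2x bilinear upsampling followed by a channel-halving conv+BN+ReLU."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x.upsample2x())).relu()


class AttentionUNet(Module):
    """Residual U-Net with attention-gated skip connections.

    Encoder: one residual block per level, 2x2 max pooling between levels.
    Each skip is passed through SCAB before concatenation with the
    upsampled decoder stream; a residual block then fuses the pair.  A
    final 1x1 convolution + sigmoid yields per-pixel foreground
    probabilities at the input resolution.
    """

    def __init__(self, arch: ArchConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.arch = arch
        ch = arch.channels
        k = arch.kernel_size

        self.encoder = ModuleList()
        self.block_attention = ModuleList() if arch.attention == "rscab" else None
        for i in range(arch.depth):
            cin = 1 if i == 0 else ch[i - 1]
            self.encoder.append(ResidualBlock(cin, ch[i], k, rng=rng))
            if self.block_attention is not None:
                self.block_attention.append(
                    RSCAB(ch[i], ch[i], arch.spatial_kernel,
                          arch.channel_reduction, rng=rng)
                )

        self.upsamplers = ModuleList()
        self.skip_attention = ModuleList() if arch.attention != "none" else None
        self.decoder = ModuleList()
        for i in range(arch.depth - 2, -1, -1):
            self.upsamplers.append(_UpBlock(ch[i + 1], ch[i], rng=rng))
            if self.skip_attention is not None:
                self.skip_attention.append(
                    SCAB(ch[i], arch.spatial_kernel, arch.channel_reduction, rng=rng)
                )
            self.decoder.append(ResidualBlock(2 * ch[i], ch[i], k, rng=rng))

        self.head = Conv2d(ch[0], 1, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W) input, got {x.shape}")
        div = 2 ** (self.arch.depth - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ConfigError(
                f"input size {x.shape[2:]} not divisible by 2^(depth-1)={div}"
            )
        skips = []
        for i, block in enumerate(self.encoder):
            x = block(x)
            if self.block_attention is not None:
                x = self.block_attention[i](x)
            if i < self.arch.depth - 1:
                skips.append(x)
                x = x.maxpool2x2()
        for j, (up, dec) in enumerate(zip(self.upsamplers, self.decoder)):
            skip = skips[-(j + 1)]
            if self.skip_attention is not None:
                skip = self.skip_attention[j](skip)
            x = up(x)
            x = dec(concat([skip, x], axis=1))
        return self.head(x).sigmoid()


def build_model(arch: ArchConfig, seed: int = 0) -> AttentionUNet:
    """Construct the network with scaled-Gaussian-initialised weights."""
    rng = np.random.default_rng(seed)
    return AttentionUNet(arch, rng=rng)


def predict_probs(model: AttentionUNet, images: np.ndarray,
                  batch_size: int = 8) -> np.ndarray:
    """Run inference (eval mode) on a (N, H, W) image stack; returns (N, H, W)
    per-pixel foreground probabilities."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    was_training = any(m.training for m in model.modules())
    model.eval()
    outs = []
    for i in range(0, images.shape[0], batch_size):
        batch = Tensor(images[i:i + batch_size, None, :, :])
        outs.append(model(batch).data[:, 0])
    if was_training:
        model.train()
    return np.concatenate(outs, axis=0)


def save_checkpoint(model: AttentionUNet, path) -> None:
    """Serialize weights + architecture config (npz with embedded JSON)."""
    cfg = asdict(model.arch)
    cfg["input_size"] = list(cfg["input_size"])
    np.savez(
        path,
        __arch__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
        **{k.replace(".", "/"): v for k, v in model.state_dict().items()},
    )


def load_checkpoint(path) -> AttentionUNet:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__arch__"]).decode())
        cfg["input_size"] = tuple(cfg["input_size"])
        arch = ArchConfig(**cfg)
        model = AttentionUNet(arch)
        state = {
            k.replace("/", "."): data[k] for k in data.files if k != "__arch__"
        }
    model.load_state_dict(state)
    return model
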