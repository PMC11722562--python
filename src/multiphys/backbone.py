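"""Hierarchical feature-extraction backbone.

The network turns an STMap (H x W x 3, with the W axis carrying time) into
a task-shared representation ``r``:

    stem (two stride-2 3x3 convs, /4)
      -> ResConv block (N1 residual layers) -> downsampler (/8)
      -> ResConv block (N2 residual layers) -> downsampler (/16)
      -> flatten to tokens
      -> stage 1: N_mp/2 integrator layers + N_mp/2 attention layers
      -> sampler (/32)
      -> stage 2: same layer pattern
      -> global average pool -> linear -> r

Each residual conv layer computes ``a_hat = GELU(BN(Conv3x3(a)));
a <- BN(Conv3x3(a_hat)) + a``. Integrator layers are pre-norm residual
(integrator then MLP); attention layers are pre-norm residual multi-head
self-attention then MLP, with logits scaled by 1/sqrt(d_head).

The channel width doubles at every downsampling step (C, 2C, 4C, 8C at
strides 4/8/16/32). Feature maps are flattened row-major so the scan runs
along the temporal (W) axis fastest. No positional encoding is added by
default; the scan and convolutions carry order, and attention alone is
permutation-equivariant (a learnable positional embedding can be switched
on via ``BackboneConfig.positional_embedding``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from ._autodiff import Tensor, concat

__all__ = [
    "BackboneConfig",
    "FeatureMap",
    "TokenSequence",
    "SharedRepresentation",
    "Stem",
    "ResConvBlock",
    "Downsample",
    "MambaIntegrator",
    "MultiPhysLayer",
    "MultiPhysBackbone",
]


@dataclass
class BackboneConfig:
    """Architecture hyper-parameters.

    H, W : STMap input size; both must be divisible by 32 (two stem strides,
        two conv downsamplers and one inter-stage sampler each halve the
        resolution).
    C_embed : embedding width C after the stem; doubles at each downsampler.
    N1, N2 : residual conv layer counts of the two ResConv blocks.
    N_mp : layers per MultiPhys stage; ceil(N/2) integrator layers followed
        by floor(N/2) attention layers (even N splits N/2 + N/2).
    n_heads : attention heads; must divide the stage channel widths.
    mlp_ratio : hidden expansion of the MLP sublayers.
    D_r : length of the task-shared representation r.
    state_size : SSM state width per channel.
    """

    H: int = 64
    W: int = 256
    C_embed: int = 32
    N1: int = 2
    N2: int = 2
    N_mp: int = 2
    n_heads: int = 4
    mlp_ratio: int = 4
    D_r: int = 128
    state_size: int = 16
    positional_embedding: bool = False
    ssm_time_invariant: bool = False

    def __post_init__(self):
        if self.H % 32 or self.W % 32:
            raise ValueError(f"H and W must be divisible by 32, got {self.H}x{self.W}")
        if self.N_mp < 1:
            raise ValueError("N_mp must be >= 1")
        for width in (4 * self.C_embed, 8 * self.C_embed):
            if width % self.n_heads:
                raise ValueError(f"n_heads={self.n_heads} must divide stage width {width}")

    @property
    def n_integrator_layers(self) -> int:
        return (self.N_mp + 1) // 2

    @property
    def n_attention_layers(self) -> int:
        return self.N_mp // 2


@dataclass
class FeatureMap:
    """Convolutional feature map with its downsampling stride."""

    values: Tensor  # (B, C, h, w)
    stride: int

    def __post_init__(self):
        if self.stride not in (4, 8, 16, 32):
            raise ValueError(f"stride must be one of 4/8/16/32, got {self.stride}")


@dataclass
class TokenSequence:
    """Flattened feature map: (B, L, C) with L = h_f * w_f."""

    tokens: Tensor
    spatial_shape: tuple

    def __post_init__(self):
        h, w = self.spatial_shape
        if self.tokens.shape[1] != h * w:
            raise ValueError(f"token count {self.tokens.shape[1]} != {h}*{w}")


@dataclass
class SharedRepresentation:
    """Pooled task-shared feature vector r, (B, D_r)."""

    r: Tensor

    def __post_init__(self):
        if not np.all(np.isfinite(self.r.data)):
            raise ValueError("shared representation contains non-finite values")


class Stem(nn.Module):
    """Two consecutive stride-2 3x3 conv + BN + GELU layers (/4 overall)."""

    def __init__(self, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(3, c_out, 3, rng, stride=2, padding=1)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, stride=2, padding=1)
        self.bn2 = nn.BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError(f"stem input spatial dims must be divisible by 4, got {x.shape[2:]}")
        x = self.bn1(self.conv1(x)).gelu()
        return self.bn2(self.conv2(x)).gelu()


class ResConvLayer(nn.Module):
    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(c, c, 3, rng)
        self.bn1 = nn.BatchNorm2d(c)
        self.conv2 = nn.Conv2d(c, c, 3, rng)
        self.bn2 = nn.BatchNorm2d(c)

    def forward(self, x: Tensor) -> Tensor:
        a_hat = self.bn1(self.conv1(x)).gelu()
        return self.bn2(self.conv2(a_hat)) + x


class ResConvBlock(nn.Module):
    """n_layers residual conv layers; spatial shape and channels preserved."""

    def __init__(self, c: int, n_layers: int, rng: np.random.Generator):
        super().__init__()
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        self.layers = nn.ModuleList(ResConvLayer(c, rng) for _ in range(n_layers))

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Downsample(nn.Module):
    """3x3 stride-2 conv + BN; halves resolution, doubles channels."""

    def __init__(self, c_in: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(c_in, 2 * c_in, 3, rng, stride=2, padding=1)
        self.bn = nn.BatchNorm2d(2 * c_in)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError(f"downsample needs even spatial dims, got {x.shape[2:]}")
        return self.bn(self.conv(x))


class Mlp(nn.Module):
    def __init__(self, c: int, ratio: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(c, ratio * c, rng)
        self.fc2 = nn.Linear(ratio * c, c, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class MambaIntegrator(nn.Module):
    """Two-path token mixer.

    Main path: Linear(C -> C/2) -> depthwise non-causal Conv -> SiLU ->
    selective scan. Vice path: the same Linear/Conv/SiLU without the scan.
    The two halves are concatenated and projected back to width C. The
    vice path keeps a scan-free view of the sequence (global context the
    sequential scan may suppress).

    ``scan_enabled=False`` is a test hook replacing the scan with identity,
    making the two paths share their functional form.
    """

    def __init__(self, c: int, state_size: int, rng: np.random.Generator,
                 time_invariant: bool = False):
        super().__init__()
        if c % 2:
            raise ValueError(f"integrator channel width must be even, got {c}")
        half = c // 2
        self.in_main = nn.Linear(c, half, rng)
        self.in_vice = nn.Linear(c, half, rng)
        self.conv_main = nn.DepthwiseConv1d(half, 3, rng)
        self.conv_vice = nn.DepthwiseConv1d(half, 3, rng)
        self.ssm = nn.SelectiveSSM(half, state_size, rng, time_invariant=time_invariant)
        self.out_proj = nn.Linear(c, c, rng)
        self.scan_enabled = True

    def forward(self, x: Tensor) -> Tensor:
        main = self.conv_main(self.in_main(x)).silu()
        if self.scan_enabled:
            main = self.ssm(main)
        vice = self.conv_vice(self.in_vice(x)).silu()
        return self.out_proj(concat([main, vice], axis=-1))


class Attention(nn.Module):
    """Multi-head self-attention with 1/sqrt(d_head) logit scaling."""

    def __init__(self, c: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if c % n_heads:
            raise ValueError(f"n_heads={n_heads} must divide width {c}")
        self.n_heads = n_heads
        self.d_head = c // n_heads
        self.qkv = nn.Linear(c, 3 * c, rng)
        self.proj = nn.Linear(c, c, rng)
        self.last_attn: np.ndarray | None = None  # (B, heads, L, L) from last forward

    def forward(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        qkv = self.qkv(x).reshape(B, L, 3, self.n_heads, self.d_head).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, h, L, d)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite attention logits")
        attn = logits.softmax(axis=-1)
        self.last_attn = attn.data
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, C)
        return self.proj(out)


class MultiPhysLayer(nn.Module):
    """Pre-norm residual layer: integrator or attention mixer, then MLP."""

    def __init__(self, c: int, kind: str, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        if kind not in ("integrator", "attention"):
            raise ValueError(f"unknown layer kind {kind!r}")
        self.kind = kind
        self.norm1 = nn.LayerNorm(c)
        if kind == "integrator":
            self.mixer = MambaIntegrator(c, cfg.state_size, rng,
                                         time_invariant=cfg.ssm_time_invariant)
        else:
            self.mixer = Attention(c, cfg.n_heads, rng)
        self.norm2 = nn.LayerNorm(c)
        self.mlp = Mlp(c, cfg.mlp_ratio, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.mixer(self.norm1(x)) + x
        return self.mlp(self.norm2(x)) + x


class Stage(nn.Module):
    """ceil(N/2) integrator layers followed by floor(N/2) attention layers."""

    def __init__(self, c: int, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        kinds = ["integrator"] * cfg.n_integrator_layers + ["attention"] * cfg.n_attention_layers
        self.layers = nn.ModuleList(MultiPhysLayer(c, k, cfg, rng) for k in kinds)

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            try:
                x = layer(x)
            except FloatingPointError as e:
                raise FloatingPointError(f"{e} (stage layer {i}, kind {layer.kind})") from e
        return x


def _to_tokens(x: Tensor) -> tuple[Tensor, tuple]:
    """(B, C, h, w) -> (B, h*w, C), row-major so w (time) varies fastest."""
    B, C, h, w = x.shape
    return x.transpose(0, 2, 3, 1).reshape(B, h * w, C), (h, w)


def _to_map(x: Tensor, spatial: tuple) -> Tensor:
    B, L, C = x.shape
    h, w = spatial
    return x.reshape(B, h, w, C).transpose(0, 3, 1, 2)


class MultiPhysBackbone(nn.Module):
    """Full feature extractor producing the task-shared representation.

    ``forward_features`` also returns the stage-2 pre-pooling token sequence
    (needed by the waveform head, which must keep a temporal axis) and the
    stride trace at the documented tap points: stem, first ResConv block,
    first downsampler, second downsampler, stage 1, stage 2.
    """

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator | int | None = None):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        C = cfg.C_embed
        self.stem = Stem(C, rng)
        self.block1 = ResConvBlock(C, cfg.N1, rng)
        self.down1 = Downsample(C, rng)
        self.block2 = ResConvBlock(2 * C, cfg.N2, rng)
        self.down2 = Downsample(2 * C, rng)
        self.stage1 = Stage(4 * C, cfg, rng)
        self.sampler = Downsample(4 * C, rng)
        self.stage2 = Stage(8 * C, cfg, rng)
        self.head = nn.Linear(8 * C, cfg.D_r, rng)
        self.stage2_width = 8 * C
        if cfg.positional_embedding:
            L1 = (cfg.H // 16) * (cfg.W // 16)
            L2 = (cfg.H // 32) * (cfg.W // 32)
            self.pos1 = Tensor(0.02 * rng.standard_normal((1, L1, 4 * C)), requires_grad=True)
            self.pos2 = Tensor(0.02 * rng.standard_normal((1, L2, 8 * C)), requires_grad=True)

    def forward_features(self, x: Tensor):
        """Returns (r, stage-2 TokenSequence, stride trace)."""
        if x.ndim == 3:  # single STMap (H, W, 3)
            x = x.reshape(1, *x.shape)
        if x.shape[-1] == 3:  # channels-last STMap batch -> (B, 3, H, W)
            x = x.transpose(0, 3, 1, 2)
        trace = []
        x = self.stem(x)
        trace.append(4)
        x = self.block1(x)
        trace.append(4)
        x = self.down1(x)
        trace.append(8)
        x = self.down2(self.block2(x))
        trace.append(16)
        tokens, spatial = _to_tokens(x)
        if self.cfg.positional_embedding:
            tokens = tokens + self.pos1
        tokens = self.stage1(tokens)
        trace.append(16)
        x = self.sampler(_to_map(tokens, spatial))
        tokens, spatial = _to_tokens(x)
        if self.cfg.positional_embedding:
            tokens = tokens + self.pos2
        tokens = self.stage2(tokens)
        trace.append(32)
        pooled = tokens.mean(axis=1)  # global average pool over space-time
        r = self.head(pooled)
        return SharedRepresentation(r=r), TokenSequence(tokens=tokens, spatial_shape=spatial), tuple(trace)

    def forward(self, x: Tensor) -> SharedRepresentation:
        return self.forward_features(x)[0]


def extract_shared(x, cfg: BackboneConfig, rng=0) -> SharedRepresentation:
    """Convenience one-shot: build a backbone from ``rng`` and run it in eval mode."""
    model = MultiPhysBackbone(cfg, rng).eval()
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=float))
    return model(x)
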