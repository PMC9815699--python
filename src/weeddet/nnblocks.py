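"""Detection-network building blocks: transformer encoder, involution, CFFI
and adaptively spatial feature fusion (ASFF).

All blocks operate on NCHW feature maps carried by :class:`FeatureMap` (a
tensor plus its pyramid level and stride) and are deterministic given their
parameters and input.  Three of them are the architectural contributions this
package exists to exercise:

* **Transformer encoder** — feature-map cells are flattened to tokens and run
  through a pre-norm multi-head self-attention sub-layer and an MLP
  sub-layer, each with a residual connection.  Placed at the low-resolution
  end of a backbone this adds global context at modest cost, which is what
  helps small, scattered objects (weeds) get noticed.
* **Involution** — the inverse symmetry of convolution: the K x K spatial
  kernel is *generated from the input at each position* by a bottleneck
  function and shared across all channels of a group (spatial-specific,
  channel-invariant).  The CFFI block pairs a 1 x 1 convolution branch with a
  1 x 1 involution branch on the top backbone map and concatenates them, so
  channel reduction loses less of the semantic content.
* **ASFF** — three pyramid levels are rescaled to a common grid and combined
  per position with softmax-normalized weights alpha/beta/gamma (one scalar
  triple per spatial position, summing to one), learned by a 1 x 1 control
  head over the concatenated rescaled maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor


@dataclass
class FeatureMap:
    """A batched feature tensor with pyramid bookkeeping."""

    values: Tensor          # (N, C, H, W)
    level: str = ""         # e.g. "P3"
    stride: int = 1         # pixels per cell w.r.t. the network input

    @property
    def shape(self):
        return self.values.shape


@dataclass
class TransformerConfig:
    embed_dim: int
    n_heads: int = 2
    mlp_ratio: float = 2.0
    use_positional_embedding: bool = False
    dropout: float = 0.0
    max_tokens: int = 256   # positional table size when embeddings are on

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")


@dataclass
class InvolutionConfig:
    kernel_size: int = 3
    groups: int = 1
    reduction_ratio: int = 2
    stride: int = 1

    def __post_init__(self):
        if self.kernel_size % 2 == 0:
            raise ValueError("involution kernel size must be odd")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def _linear(rng, d_in, d_out):
    w = Parameter(ad.kaiming(rng, (d_in, d_out), d_in))
    b = Parameter(np.zeros(d_out, dtype=ad.DTYPE))
    return w, b


class Conv(Module):
    """Convolution + bias with optional SiLU activation."""

    def __init__(self, rng, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 act: bool = True):
        self.k, self.stride, self.act = k, stride, act
        self.pad = k // 2
        self.w = Parameter(ad.kaiming(rng, (c_out, c_in, k, k), c_in * k * k))
        self.b = Parameter(np.zeros(c_out, dtype=ad.DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        y = ad.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)
        return y.silu() if self.act else y


class TransformerEncoder(Module):
    """Pre-norm transformer encoder block over flattened feature-map cells.

    Shape contract: (N, C, H, W) in, (N, C, H, W) out with C = embed_dim.
    Without positional embeddings the block is equivariant to any permutation
    of the H*W token positions.
    """

    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        self.config = config
        d = config.embed_dim
        self.wq, self.bq = _linear(rng, d, d)
        self.wk, self.bk = _linear(rng, d, d)
        self.wv, self.bv = _linear(rng, d, d)
        self.wo, self.bo = _linear(rng, d, d)
        hidden = int(d * config.mlp_ratio)
        self.w1, self.b1 = _linear(rng, d, hidden)
        self.w2, self.b2 = _linear(rng, hidden, d)
        self.ln1_g = Parameter(np.ones(d, dtype=ad.DTYPE))
        self.ln1_b = Parameter(np.zeros(d, dtype=ad.DTYPE))
        self.ln2_g = Parameter(np.ones(d, dtype=ad.DTYPE))
        self.ln2_b = Parameter(np.zeros(d, dtype=ad.DTYPE))
        if config.use_positional_embedding:
            self.pos = Parameter(
                rng.normal(0, 0.02, size=(config.max_tokens, d)).astype(ad.DTYPE))
        else:
            self.pos = None

    def _attend(self, tokens: Tensor) -> Tensor:
        n, t, d = tokens.shape
        heads = self.config.n_heads
        dh = d // heads
        q = (tokens @ self.wq + self.bq).reshape(n, t, heads, dh).transpose(0, 2, 1, 3)
        k = (tokens @ self.wk + self.bk).reshape(n, t, heads, dh).transpose(0, 2, 1, 3)
        v = (tokens @ self.wv + self.bv).reshape(n, t, heads, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = ad.softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return out @ self.wo + self.bo

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.config.embed_dim:
            raise ValueError(
                f"input has {c} channels but embed_dim={self.config.embed_dim}")
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)   # (N, T, C)
        if self.pos is not None:
            if h * w > self.config.max_tokens:
                raise ValueError("token count exceeds positional table")
            tokens = tokens + self.pos[: h * w]
        a = self._attend(ad.layer_norm(tokens, self.ln1_g, self.ln1_b))
        tokens = tokens + a
        m = ad.layer_norm(tokens, self.ln2_g, self.ln2_b) @ self.w1 + self.b1
        m = m.silu() @ self.w2 + self.b2
        tokens = tokens + m
        return tokens.transpose(0, 2, 1).reshape(n, c, h, w)


class Involution(Module):
    """Involution operator with a bottleneck kernel-generation head.

    The kernel at each position is produced from the input feature vector at
    that position: channel-reduce by ``reduction_ratio`` (1x1 conv + SiLU),
    then expand to K*K*groups kernel weights (1x1 conv).  The kernel is shared
    by every channel within a group, so duplicating a channel duplicates its
    output exactly and the parameter count does not grow with channel width
    beyond the generation head.
    """

    def __init__(self, channels: int, config: InvolutionConfig,
                 rng: np.random.Generator):
        if channels % config.groups:
            raise ValueError("channels must be divisible by groups")
        self.channels = channels
        self.config = config
        hidden = max(1, channels // config.reduction_ratio)
        k, g = config.kernel_size, config.groups
        self.reduce = Conv(rng, channels, hidden, k=1, act=True)
        self.expand = Conv(rng, hidden, k * k * g, k=1, act=False)

    def forward(self, x: Tensor, kernels: Tensor | None = None) -> Tensor:
        cfg = self.config
        n, c, h, w = x.shape
        k, g, s = cfg.kernel_size, cfg.groups, cfg.stride
        if kernels is None:
            src = x if s == 1 else x[:, :, ::s, ::s]
            kernels = self.expand(self.reduce(src))
        ho, wo = kernels.shape[2], kernels.shape[3]
        kern = kernels.reshape(n, g, 1, k * k, ho, wo)
        cols = ad.unfold(x, k, stride=s, pad=k // 2)       # (N, C, K*K, Ho, Wo)
        cols = cols.reshape(n, g, c // g, k * k, ho, wo)
        return (kern * cols).sum(axis=3).reshape(n, c, ho, wo)


class CFFI(Module):
    """Channel feature fusion with involution, bridging backbone and neck.

    A 1x1 convolution reduces the top backbone map to ``width`` channels; a
    1x1 involution then aggregates spatial information on that reduced map;
    the two results are concatenated, giving ``2*width`` output channels at
    unchanged spatial size.  (At full scale the reference width is 768; the
    detector scales it by its width multiplier.)
    """

    def __init__(self, c_in: int, width: int, rng: np.random.Generator,
                 inv_config: InvolutionConfig | None = None):
        self.width = width
        self.conv = Conv(rng, c_in, width, k=1, act=True)
        self.inv = Involution(
            width, inv_config or InvolutionConfig(kernel_size=1, groups=1), rng)

    @property
    def out_channels(self) -> int:
        return 2 * self.width

    def forward(self, x: Tensor) -> Tensor:
        a = self.conv(x)
        b = self.inv(a)
        return ad.concat([a, b], axis=1)


class ASFFRescale(Module):
    """Rescale a pyramid map to a target level's grid and channel count.

    Same level: identity.  Coarser-to-finer (up): 1x1 conv to the target
    channel count, then nearest (default) or bilinear interpolation by 2x or
    4x.  Finer-to-coarser by one octave: 3x3 stride-2 conv; by two octaves:
    stride-2 max pooling followed by the 3x3 stride-2 conv.
    """

    def __init__(self, c_in: int, c_out: int, octaves: int,
                 rng: np.random.Generator, interpolation: str = "nearest"):
        if abs(octaves) > 2:
            raise ValueError("level gap beyond 2 octaves is unsupported")
        self.octaves = octaves
        self.interpolation = interpolation
        if octaves == 0:
            self.proj = None if c_in == c_out else Conv(rng, c_in, c_out, k=1)
        elif octaves > 0:   # upsample
            self.proj = Conv(rng, c_in, c_out, k=1)
        else:               # downsample
            self.proj = Conv(rng, c_in, c_out, k=3, stride=2)

    def forward(self, x: Tensor) -> Tensor:
        if self.octaves == 0:
            return self.proj(x) if self.proj else x
        if self.octaves > 0:
            y = self.proj(x)
            up = (ad.upsample_nearest if self.interpolation == "nearest"
                  else ad.upsample_bilinear)
            return up(y, 2 ** self.octaves)
        if self.octaves == -1:
            return self.proj(x)
        return self.proj(ad.maxpool2d(x, 2, stride=2))


def asff_rescale(x: FeatureMap, to_stride: int, c_out: int,
                 rng: np.random.Generator | None = None,
                 interpolation: str = "nearest") -> FeatureMap:
    """Functional one-shot rescale between pyramid levels (fresh parameters)."""
    rng = rng or np.random.default_rng(0)
    octaves = int(np.log2(x.stride / to_stride))
    block = ASFFRescale(x.shape[1], c_out, octaves, rng, interpolation)
    return FeatureMap(values=block(x.values), stride=to_stride)


class ASFFHead(Module):
    """Adaptively spatial feature fusion onto one target level.

    The three rescaled maps are concatenated and passed through a 1x1 control
    convolution producing three logit maps (lambda); a per-position softmax
    across the three sources yields alpha/beta/gamma in [0, 1] summing to 1,
    and the output is the per-position weighted sum of the rescaled maps.
    """

    def __init__(self, channels: list[int], strides: list[int],
                 target_index: int, rng: np.random.Generator,
                 interpolation: str = "nearest"):
        self.target_index = target_index
        c_out = channels[target_index]
        t_stride = strides[target_index]
        self.rescalers = [
            ASFFRescale(c, c_out, int(np.log2(s / t_stride)), rng, interpolation)
            for c, s in zip(channels, strides)
        ]
        self.control = Conv(rng, 3 * c_out, 3, k=1, act=False)

    def fusion_weights(self, rescaled: list[Tensor]) -> Tensor:
        """(N, 3, H, W) softmax weights from the control head."""
        logits = self.control(ad.concat(rescaled, axis=1))
        return ad.softmax(logits, axis=1)

    def forward(self, maps: list[Tensor],
                return_weights: bool = False):
        rescaled = [resc(m) for resc, m in zip(self.rescalers, maps)]
        weights = self.fusion_weights(rescaled)
        fused = asff_fuse(rescaled, weights)
        return (fused, weights) if return_weights else fused


def asff_fuse(rescaled: list[Tensor], weights: Tensor) -> Tensor:
    """Weighted per-position sum of three same-shape maps.

    ``weights``: (N, 3, H, W), expected non-negative with unit sum over the
    source axis (the softmax of the control logits).
    """
    if len(rescaled) != 3:
        raise ValueError("asff_fuse expects exactly three source maps")
    shape = rescaled[0].shape
    for m in rescaled[1:]:
        if m.shape != shape:
            raise ValueError(f"shape mismatch in ASFF fusion: {m.shape} vs {shape}")
    out = None
    for i, m in enumerate(rescaled):
        term = m * weights[:, i:i + 1]
        out = term if out is None else out + term
    return out
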