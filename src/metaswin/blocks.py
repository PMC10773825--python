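"""Token mixers and building blocks for the hierarchical segmentation encoder.

The central operator here is the parameter-free average-pooling token
mixer: each voxel's feature vector is replaced by the mean over its
centered K x K x K spatial neighborhood (borders average in-bounds
neighbors only).  It stands in for windowed multi-head self-attention
inside an otherwise conventional transformer block (norm -> token mixer
-> residual, norm -> feed-forward -> residual).  The windowed-attention
mixer is also provided as the reference baseline, together with
squeeze-and-excitation (SE) channel recalibration, patch embedding and
patch merging.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, avg_pool3d_same, layer_norm
from .nn import Linear, Module, Parameter, trunc_normal


# ---------------------------------------------------------------------------
# domain types

@dataclass
class FeatureMap:
    """Channels-first dense 3D feature tensor, shape (channels, D, H, W)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError(f"FeatureMap expects (C, D, H, W), got shape {self.values.shape}")
        if min(self.values.shape) < 1:
            raise ValueError(f"empty extent in FeatureMap shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMap values must be finite")

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_extent(self) -> tuple[int, int, int]:
        return self.values.shape[1:]


@dataclass
class PoolingSpec:
    """Neighborhood-averaging token mixer configuration.

    The kernel must be odd so the window is centered on each voxel.  The
    operator introduces no trainable parameters.
    """

    kernel: int = 3
    subtract_identity: bool = False

    def __post_init__(self):
        if self.kernel < 1 or self.kernel % 2 != 1:
            raise ValueError(f"pooling kernel must be a positive odd integer, got {self.kernel}")


@dataclass
class SEConfig:
    channels: int
    reduction_ratio: int = 4

    def __post_init__(self):
        if self.channels % self.reduction_ratio or self.channels // self.reduction_ratio < 1:
            raise ValueError(
                f"reduction ratio {self.reduction_ratio} must divide channels {self.channels} "
                "with a bottleneck width of at least 1"
            )

    @property
    def bottleneck(self) -> int:
        return self.channels // self.reduction_ratio


def _as_array(x) -> tuple[np.ndarray, bool]:
    if isinstance(x, FeatureMap):
        return x.values, True
    return np.asarray(x), False


# ---------------------------------------------------------------------------
# pure operators

def average_pool_mixer(x, spec: PoolingSpec | None = None):
    """Stride-1, exclude-padded K^3 neighborhood mean; zero parameters.

    Accepts a :class:`FeatureMap` or a (C, D, H, W) array and returns the
    same kind.  With ``spec.subtract_identity`` the input is subtracted
    from the pooled field (the residual-branch convention of pooling
    token mixers).
    """
    spec = spec or PoolingSpec()
    arr, wrap = _as_array(x)
    if arr.ndim != 4 or min(arr.shape) < 1:
        raise ValueError(f"expected a non-empty (C, D, H, W) array, got shape {arr.shape}")
    t = avg_pool3d_same(Tensor(arr[None].astype(np.float64)), spec.kernel)
    out = t.data[0]
    if spec.subtract_identity:
        out = out - arr
    out = out.astype(arr.dtype) if np.issubdtype(arr.dtype, np.floating) else out
    return FeatureMap(out) if wrap else out


def se_recalibrate(x, cfg: SEConfig, weights):
    """Squeeze-and-excitation: spatial mean -> bottleneck -> gates -> scale.

    ``weights`` is ``(w1, b1, w2, b2)`` for the two fully connected
    layers (``w1``: (bottleneck, channels), ``w2``: (channels,
    bottleneck)).  Gates pass through a logistic function, so they lie
    strictly in (0, 1) and the output magnitude never exceeds the input
    per channel.
    """
    arr, wrap = _as_array(x)
    if arr.shape[0] != cfg.channels:
        raise ValueError(f"channel mismatch: input has {arr.shape[0]}, config expects {cfg.channels}")
    w1, b1, w2, b2 = (np.asarray(w, dtype=np.float64) for w in weights)
    if w1.shape != (cfg.bottleneck, cfg.channels) or w2.shape != (cfg.channels, cfg.bottleneck):
        raise ValueError("SE weight shapes do not match the configuration")
    desc = arr.reshape(cfg.channels, -1).mean(axis=1)
    hidden = np.maximum(w1 @ desc + b1, 0.0)
    gates = 1.0 / (1.0 + np.exp(-(w2 @ hidden + b2)))
    out = arr * gates.reshape(-1, 1, 1, 1)
    return FeatureMap(out) if wrap else out


# ---------------------------------------------------------------------------
# network modules

class Mlp(Module):
    """Two-layer position-wise feed-forward with GELU."""

    def __init__(self, dim: int, mlp_ratio: float, rng: np.random.Generator):
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.fc2 = Linear(hidden, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


def _rel_pos_index(window: tuple[int, int, int], table_window: int) -> np.ndarray:
    """Pairwise relative-position indices into the full-table layout."""
    coords = np.array(list(itertools.product(*(range(w) for w in window))))  # (n, 3)
    rel = coords[:, None, :] - coords[None, :, :]  # (n, n, 3)
    span = 2 * table_window - 1
    rel = rel + (table_window - 1)
    return (rel[..., 0] * span * span + rel[..., 1] * span + rel[..., 2]).astype(np.intp)


class WindowAttention(Module):
    """Multi-head self-attention inside a local window, with a learned
    relative-position bias shared across windows."""

    def __init__(self, dim: int, heads: int, window: int, qkv_bias: bool = True,
                 rng: np.random.Generator | None = None):
        if dim % heads:
            raise ValueError(f"dim {dim} must be divisible by heads {heads}")
        rng = rng or np.random.default_rng(0)
        self.dim, self.heads, self.window = dim, heads, window
        self.scale = (dim // heads) ** -0.5
        self.qkv = Linear(dim, 3 * dim, bias=qkv_bias, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        span = 2 * window - 1
        self.relative_position_bias_table = Parameter(trunc_normal(rng, (span ** 3, heads)))

    def forward(self, tokens: Tensor, window: tuple[int, int, int],
                mask: np.ndarray | None = None, n_batch: int = 1) -> Tensor:
        b, n, c = tokens.shape
        h = self.heads
        qkv = self.qkv(tokens).reshape(b, n, 3, h, c // h).transpose((2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q * self.scale) @ k.transpose((0, 1, 3, 2))  # (b, h, n, n)
        idx = _rel_pos_index(window, self.window)
        bias = self.relative_position_bias_table[idx.reshape(-1)]
        attn = attn + bias.reshape(n, n, h).transpose((2, 0, 1)).reshape(1, h, n, n)
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(n_batch, nw, h, n, n) + Tensor(mask[None, :, None].astype(tokens.dtype))
            attn = attn.reshape(b, h, n, n)
        out = attn.softmax(-1) @ v  # (b, h, n, dh)
        out = out.transpose((0, 2, 1, 3)).reshape(b, n, c)
        return self.proj(out)


class PoolingMixer(Module):
    """Average-pooling token mixer used inside transformer-style blocks.

    The pooling itself has no trainable parameters.  When the mixer
    replaces a windowed-attention module inside a pre-built network, the
    attention module's output projection and relative-position bias
    table can be retained (``proj_dim`` / ``position_bias``); the bias
    table then remains registered but takes no part in the pooling math.
    """

    def __init__(self, spec: PoolingSpec | None = None, proj_dim: int | None = None,
                 position_bias: tuple[int, int] | None = None,
                 rng: np.random.Generator | None = None):
        self.spec = spec or PoolingSpec()
        self.proj = Linear(proj_dim, proj_dim, rng=rng) if proj_dim else None
        if position_bias is not None:
            window, heads = position_bias
            rng = rng or np.random.default_rng(0)
            self.relative_position_bias_table = Parameter(
                trunc_normal(rng, ((2 * window - 1) ** 3, heads)))

    def forward(self, x: Tensor) -> Tensor:  # x: (N, C, D, H, W)
        y = avg_pool3d_same(x, self.spec.kernel)
        if self.spec.subtract_identity:
            y = y - x
        if self.proj is not None:
            y = self.proj(y.transpose((0, 2, 3, 4, 1))).transpose((0, 4, 1, 2, 3))
        return y


def _shift_regions(extent: int, window: int, shift: int) -> np.ndarray:
    """Per-axis region labels for shifted-window attention masking."""
    ids = np.zeros(extent, dtype=np.int64)
    if shift:
        ids[extent - window:] = 1
        ids[extent - shift:] = 2
    return ids


class MetaSwinBlock(Module):
    """Transformer-style block: norm -> token mixer -> residual, then
    norm -> feed-forward -> residual.

    ``mixer`` selects pooling (full-field neighborhood averaging, no
    window partitioning) or windowed self-attention (with optional
    cyclic shift).  Feature maps are (N, C, D, H, W); spatial extents are
    preserved.
    """

    def __init__(self, dim: int, mixer: str = "pooling", heads: int = 3, window: int = 7,
                 shifted: bool = False, mlp_ratio: float = 4.0,
                 pool_spec: PoolingSpec | None = None,
                 keep_attention_projection: bool = False,
                 keep_position_bias: bool = False,
                 rng: np.random.Generator | None = None):
        if mixer not in ("pooling", "attention"):
            raise ValueError(f"unknown mixer {mixer!r}")
        rng = rng or np.random.default_rng(0)
        self.dim, self.mixer_kind, self.window, self.shifted = dim, mixer, window, shifted
        self.norm1 = _ChannelLayerNorm(dim)
        if mixer == "attention":
            self.mixer = WindowAttention(dim, heads, window, rng=rng)
        else:
            self.mixer = PoolingMixer(
                pool_spec, proj_dim=dim if keep_attention_projection else None,
                position_bias=(window, heads) if keep_position_bias else None, rng=rng)
        self.norm2 = _ChannelLayerNorm(dim)
        self.mlp = Mlp(dim, mlp_ratio, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.dim:
            raise ValueError(f"channel mismatch: input has {x.shape[1]}, block expects {self.dim}")
        h = self.norm1(x)
        if self.mixer_kind == "attention":
            h = self._windowed_attention(h)
        else:
            h = self.mixer(h)
        x = x + h
        h = self.mlp(self.norm2(x).transpose((0, 2, 3, 4, 1)))
        return x + h.transpose((0, 4, 1, 2, 3))

    # -- attention geometry --------------------------------------------------
    def _windowed_attention(self, x: Tensor) -> Tensor:
        n, c, d0, h0, w0 = x.shape
        ws = tuple(min(self.window, e) for e in (d0, h0, w0))
        shift = tuple(w // 2 if (self.shifted and e > w) else 0
                      for w, e in zip(ws, (d0, h0, w0)))
        pads = tuple((-e) % w for e, w in zip((d0, h0, w0), ws))
        padded = tuple(e + p for e, p in zip((d0, h0, w0), pads))
        if any(pads):
            x = x.pad(((0, 0), (0, 0)) + tuple((0, p) for p in pads))
        if any(shift):
            x = x.roll(tuple(-s for s in shift), (2, 3, 4))
        # region ids in original coordinates, rolled with the features;
        # padded voxels get an off-grid label so they never mix with real ones
        need_mask = any(shift) or any(pads)
        mask = None
        if need_mask:
            ids = np.zeros(padded, dtype=np.int64)
            for ax, (e, w, s, p) in enumerate(zip(padded, ws, shift, pads)):
                axis_ids = _shift_regions(e, w, s)
                if p:
                    axis_ids[e - p:] = 3  # off-grid marker for padded voxels
                shape = [1, 1, 1]
                shape[ax] = e
                ids = ids * 4 + axis_ids.reshape(shape)
            ids = np.roll(ids, tuple(-s for s in shift), axis=(0, 1, 2))
            wins = self._partition_np(ids[None, None].astype(np.float64), padded, ws)[..., 0]
            mask = np.where(wins[:, :, None] == wins[:, None, :], 0.0, -1e4)
        tokens = self._partition(x, padded, ws)  # (N * nW, n_tok, C)
        out = self.mixer(tokens, ws, mask=mask, n_batch=n)
        out = self._unpartition(out, padded, ws, n)
        if any(shift):
            out = out.roll(shift, (2, 3, 4))
        if any(pads):
            out = out[:, :, :d0, :h0, :w0]
        return out

    @staticmethod
    def _partition(x: Tensor, extents, ws) -> Tensor:
        n, c = x.shape[:2]
        gd, gh, gw = (e // w for e, w in zip(extents, ws))
        x = x.reshape(n, c, gd, ws[0], gh, ws[1], gw, ws[2])
        x = x.transpose((0, 2, 4, 6, 3, 5, 7, 1))
        return x.reshape(n * gd * gh * gw, ws[0] * ws[1] * ws[2], c)

    @staticmethod
    def _partition_np(arr: np.ndarray, extents, ws) -> np.ndarray:
        n, c = arr.shape[:2]
        gd, gh, gw = (e // w for e, w in zip(extents, ws))
        arr = arr.reshape(n, c, gd, ws[0], gh, ws[1], gw, ws[2])
        arr = arr.transpose(0, 2, 4, 6, 3, 5, 7, 1)
        return arr.reshape(n * gd * gh * gw, ws[0] * ws[1] * ws[2], c)

    @staticmethod
    def _unpartition(tokens: Tensor, extents, ws, n: int) -> Tensor:
        gd, gh, gw = (e // w for e, w in zip(extents, ws))
        c = tokens.shape[-1]
        x = tokens.reshape(n, gd, gh, gw, ws[0], ws[1], ws[2], c)
        x = x.transpose((0, 7, 1, 4, 2, 5, 3, 6))
        return x.reshape(n, c, *extents)


class _ChannelLayerNorm(Module):
    """Layer normalization over the channel axis of (N, C, D, H, W) maps."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias, axis=1, eps=self.eps)


class SEBlock(Module):
    """Channel recalibration: squeeze (global spatial mean), two biased
    fully connected layers around a rectifier, logistic gates in (0, 1),
    channel-wise rescaling."""

    def __init__(self, channels: int, reduction: int = 4, rng: np.random.Generator | None = None):
        cfg = SEConfig(channels, reduction)
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(channels, cfg.bottleneck, rng=rng)
        self.fc2 = Linear(cfg.bottleneck, channels, rng=rng)
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"channel mismatch: input has {x.shape[1]}, SE expects {self.channels}")
        desc = x.mean(axis=(2, 3, 4))  # (N, C)
        gates = self.fc2(self.fc1(desc).relu()).sigmoid()
        return x * gates.reshape(x.shape[0], x.shape[1], 1, 1, 1)


class PatchEmbed(Module):
    """Strided linear embedding: 2x2x2 patches -> C channels, extents halved."""

    def __init__(self, in_channels: int, embed_dim: int, rng: np.random.Generator | None = None):
        from .nn import Conv3d
        self.proj = Conv3d(in_channels, embed_dim, kernel=2, stride=2, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if any(e % 2 for e in x.shape[2:]):
            raise ValueError(f"patch embedding requires even spatial extents, got {x.shape[2:]}")
        return self.proj(x)


class PatchMerging(Module):
    """Downsampling between stages: concatenate each 2x2x2 neighborhood
    (8C channels), normalize, and project linearly to 2C.  Extents are
    padded to even if needed, then halved."""

    def __init__(self, dim: int, rng: np.random.Generator | None = None):
        from .nn import LayerNorm
        self.norm = LayerNorm(8 * dim)
        self.reduction = Linear(8 * dim, 2 * dim, bias=False, rng=rng)
        self.dim = dim

    def forward(self, x: Tensor) -> Tensor:
        n, c, d, h, w = x.shape
        pads = tuple(e % 2 for e in (d, h, w))
        if any(pads):
            x = x.pad(((0, 0), (0, 0)) + tuple((0, p) for p in pads))
            d, h, w = x.shape[2:]
        x = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        x = x.transpose((0, 2, 4, 6, 3, 5, 7, 1))  # (N, D/2, H/2, W/2, 2, 2, 2, C)
        x = x.reshape(n, d // 2, h // 2, w // 2, 8 * c)
        x = self.reduction(self.norm(x))
        return x.transpose((0, 4, 1, 2, 3))
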