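"""Assembly of the four network variants and parameter accounting.

The U-shaped network pairs a hierarchical transformer-style encoder
(patch embedding, four stages of token-mixer blocks with patch merging
between stages: channel widths C, 2C, 4C, 8C and a 16C bottleneck) with
a convolutional residual decoder connected by skip connections at every
resolution.  Four variants are built from one configuration grid:

* ``mixer="attention"`` — the windowed self-attention baseline,
* ``mixer="pooling"``  — the parameter-free average-pooling token mixer,
* each optionally with squeeze-and-excitation (SE) recalibration after
  every encoder convolutional block and every decoder block.

Because trainable-parameter totals are an exact, hardware-independent
fingerprint of an architecture, this module also ships the published
reference totals for the four variants and a checksum harness that
compares a built network against them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor, concatenate, instance_norm, layer_norm
from .blocks import MetaSwinBlock, PatchEmbed, PatchMerging, PoolingSpec, SEBlock
from .nn import Conv3d, ConvTranspose3dUp2, Module


@dataclass
class ModelConfig:
    """The architectural genotype from which a network is built.

    ``feature_size`` is the stage-1 embedding width C; stages use C, 2C,
    4C, 8C with a 16C bottleneck.  ``pooling_depths`` lets the pooling
    variant run fewer blocks per stage than the attention baseline;
    ``pooling_keeps_attention_budget`` keeps the attention module's
    output projection and position-bias table in the pooling blocks,
    which is the composition the published parameter totals correspond
    to (set it False for a strictly parameter-free mixer).
    """

    feature_size: int = 48
    in_channels: int = 4
    out_channels: int = 3
    mixer: str = "attention"
    use_se: bool = False
    depths: tuple[int, ...] = (2, 2, 2, 2)
    heads: tuple[int, ...] = (3, 6, 12, 24)
    window: int = 7
    pool_kernel: int = 3
    subtract_identity: bool = False
    mlp_ratio: float = 4.0
    se_reduction: int = 4
    roi: tuple[int, int, int] = (128, 128, 128)
    pooling_depths: tuple[int, ...] | None = None
    pooling_keeps_attention_budget: bool = True

    def __post_init__(self):
        if self.mixer not in ("attention", "pooling"):
            raise ValueError(f"mixer must be 'attention' or 'pooling', got {self.mixer!r}")
        if len(self.depths) != 4 or len(self.heads) != 4:
            raise ValueError("exactly four stages are required")
        if self.mixer == "attention":
            for s, h in enumerate(self.heads):
                if (self.feature_size * 2 ** s) % h:
                    raise ValueError(
                        f"stage {s + 1} width {self.feature_size * 2 ** s} "
                        f"not divisible by {h} heads")
        if any(r % 32 for r in self.roi):
            raise ValueError(f"roi extents must be divisible by 32, got {self.roi}")
        if self.use_se and (self.feature_size % self.se_reduction):
            raise ValueError("se_reduction must divide feature_size")

    @property
    def stage_widths(self) -> tuple[int, int, int, int]:
        c = self.feature_size
        return (c, 2 * c, 4 * c, 8 * c)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for k in ("depths", "heads", "roi", "pooling_depths"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# convolutional sub-blocks (residual, instance-normalized, leaky ReLU)

class UnetResBlock(Module):
    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.conv1 = Conv3d(in_channels, out_channels, 3, padding=1, rng=rng)
        self.conv2 = Conv3d(out_channels, out_channels, 3, padding=1, rng=rng)
        self.downsample = in_channels != out_channels
        if self.downsample:
            self.conv3 = Conv3d(in_channels, out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = instance_norm(self.conv1(x)).leaky_relu()
        y = instance_norm(self.conv2(y))
        residual = instance_norm(self.conv3(x)) if self.downsample else x
        return (y + residual).leaky_relu()


class UnetrUpBlock(Module):
    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.transp = ConvTranspose3dUp2(in_channels, out_channels, rng=rng)
        self.block = UnetResBlock(2 * out_channels, out_channels, rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        return self.block(concatenate([self.transp(x), skip], axis=1))


class _Stage(Module):
    def __init__(self, blocks: list[MetaSwinBlock], merge: PatchMerging):
        self.blocks = blocks
        self.merge = merge


class SwinBackbone(Module):
    """Patch embedding plus four token-mixer stages with patch merging.

    Returns the five hierarchical feature maps (after a parameter-free
    per-token normalization): C at 1/2 resolution through 16C at 1/32.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c = cfg.feature_size
        self.patch_embed = PatchEmbed(cfg.in_channels, c, rng=rng)
        depths = cfg.depths
        if cfg.mixer == "pooling" and cfg.pooling_depths is not None:
            depths = cfg.pooling_depths
        self.stages = []
        pool_spec = PoolingSpec(cfg.pool_kernel, cfg.subtract_identity)
        for s in range(4):
            dim = c * 2 ** s
            blocks = [
                MetaSwinBlock(
                    dim, mixer=cfg.mixer, heads=cfg.heads[s], window=cfg.window,
                    shifted=(b % 2 == 1), mlp_ratio=cfg.mlp_ratio, pool_spec=pool_spec,
                    keep_attention_projection=cfg.pooling_keeps_attention_budget,
                    keep_position_bias=cfg.pooling_keeps_attention_budget,
                    rng=rng)
                for b in range(depths[s])
            ]
            self.stages.append(_Stage(blocks, PatchMerging(dim, rng=rng)))

    def forward(self, x: Tensor) -> list[Tensor]:
        cur = self.patch_embed(x)
        hidden = [layer_norm(cur, None, None, axis=1)]
        for stage in self.stages:
            for blk in stage.blocks:
                cur = blk(cur)
            cur = stage.merge(cur)
            hidden.append(layer_norm(cur, None, None, axis=1))
        return hidden


class SegmentationNetwork(Module):
    """The full U-shaped encoder--decoder network."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = cfg.feature_size
        self.cfg = cfg
        self.backbone = SwinBackbone(cfg, rng)
        self.encoder1 = UnetResBlock(cfg.in_channels, c, rng)
        self.encoder2 = UnetResBlock(c, c, rng)
        self.encoder3 = UnetResBlock(2 * c, 2 * c, rng)
        self.encoder4 = UnetResBlock(4 * c, 4 * c, rng)
        self.bottleneck = UnetResBlock(16 * c, 16 * c, rng)
        self.decoder5 = UnetrUpBlock(16 * c, 8 * c, rng)
        self.decoder4 = UnetrUpBlock(8 * c, 4 * c, rng)
        self.decoder3 = UnetrUpBlock(4 * c, 2 * c, rng)
        self.decoder2 = UnetrUpBlock(2 * c, c, rng)
        self.decoder1 = UnetrUpBlock(c, c, rng)
        self.head = Conv3d(c, cfg.out_channels, 1, bias=True, rng=rng)
        if cfg.use_se:
            r = cfg.se_reduction
            self.se_encoder = [SEBlock(ch, r, rng) for ch in (c, c, 2 * c, 4 * c, 16 * c)]
            self.se_decoder = [SEBlock(ch, r, rng) for ch in (8 * c, 4 * c, 2 * c, c, c)]

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        if x.ndim == 4:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} input channels, got {x.shape[1]}")
        if any(e % 32 for e in x.shape[2:]):
            raise ValueError(f"spatial extents must be divisible by 32, got {x.shape[2:]}")
        se_e = self.se_encoder if cfg.use_se else [None] * 5
        se_d = self.se_decoder if cfg.use_se else [None] * 5

        def gate(t, se):
            return se(t) if se is not None else t

        h = self.backbone(x)
        enc0 = gate(self.encoder1(x), se_e[0])
        enc1 = gate(self.encoder2(h[0]), se_e[1])
        enc2 = gate(self.encoder3(h[1]), se_e[2])
        enc3 = gate(self.encoder4(h[2]), se_e[3])
        bott = gate(self.bottleneck(h[4]), se_e[4])
        d = gate(self.decoder5(bott, h[3]), se_d[0])
        d = gate(self.decoder4(d, enc3), se_d[1])
        d = gate(self.decoder3(d, enc2), se_d[2])
        d = gate(self.decoder2(d, enc1), se_d[3])
        d = gate(self.decoder1(d, enc0), se_d[4])
        return self.head(d)


def build_network(cfg: ModelConfig, seed: int = 0) -> SegmentationNetwork:
    """Deterministically build a network from its configuration."""
    return SegmentationNetwork(cfg, seed=seed)


# ---------------------------------------------------------------------------
# parameter accounting

@dataclass
class ParameterReport:
    """Per-component trainable-parameter tally for a built network."""

    components: dict[str, int]
    total: int
    config: ModelConfig | None = None

    def to_json(self) -> str:
        d = {"components": self.components, "total": self.total}
        if self.config is not None:
            d["config"] = asdict(self.config)
        return json.dumps(d, indent=1)

    def to_tsv(self) -> str:
        lines = ["component\tparameters"]
        lines += [f"{k}\t{v}" for k, v in self.components.items()]
        lines.append(f"total\t{self.total}")
        return "\n".join(lines)


def count_parameters(net: SegmentationNetwork) -> ParameterReport:
    """Exact integer tally of trainable parameters, grouped by component."""
    groups: dict[str, int] = {}
    for name, p in net.named_parameters():
        top = name.split(".", 1)[0]
        if top == "backbone":
            sub = name.split(".")
            if sub[1] == "patch_embed":
                top = "patch_embed"
            else:
                top = f"stage{int(sub[2]) + 1}"
        groups[top] = groups.get(top, 0) + int(p.size)
    total = sum(groups.values())
    assert total == net.num_parameters()
    return ParameterReport(components=groups, total=total, config=net.cfg)


#: Published total parameter counts for the four variants.  Keys are
#: (mixer, use_se, feature_size, in_channels, out_channels).
REFERENCE_COUNTS: dict[tuple[str, bool, int, int, int], int] = {
    # multi-modal MRI configuration (4 input channels, 3 region channels)
    ("attention", False, 48, 4, 3): 62_191_941,
    ("attention", True, 48, 4, 3): 62_613_669,
    ("pooling", False, 48, 4, 3): 61_012_581,
    ("pooling", True, 48, 4, 3): 61_434_309,
    # abdominal CT configuration (1 input channel, 14 classes)
    ("attention", False, 24, 1, 14): 15_703_304,
    ("attention", False, 36, 1, 14): 35_072_996,
    ("attention", False, 48, 1, 14): 62_187_296,
    ("attention", False, 60, 1, 14): 97_046_204,
    ("attention", False, 72, 1, 14): 139_649_720,
    ("attention", False, 84, 1, 14): 189_997_844,
    ("attention", True, 24, 1, 14): 15_809_336,
    ("attention", True, 36, 1, 14): 35_310_668,
    ("attention", True, 48, 1, 14): 62_609_024,
    ("attention", True, 60, 1, 14): 97_704_404,
    ("attention", True, 72, 1, 14): 140_596_808,
    ("attention", True, 84, 1, 14): 191_286_236,
    ("pooling", False, 24, 1, 14): 15_407_384,
    ("pooling", False, 36, 1, 14): 34_408_796,
    ("pooling", False, 48, 1, 14): 61_007_936,
    ("pooling", False, 60, 1, 14): 95_204_804,
    ("pooling", False, 72, 1, 14): 136_999_400,
    ("pooling", False, 84, 1, 14): 186_391_724,
    ("pooling", True, 24, 1, 14): 15_513_416,
    ("pooling", True, 36, 1, 14): 34_646_468,
    ("pooling", True, 48, 1, 14): 61_429_664,
    ("pooling", True, 60, 1, 14): 95_863_004,
    ("pooling", True, 72, 1, 14): 137_946_488,
    ("pooling", True, 84, 1, 14): 187_680_116,
}

#: Internal-consistency deltas implied by pairs of reference totals.
REFERENCE_DELTAS = {
    "se_delta_c24": 106_032,
    "se_delta_c48": 421_728,
    "mixer_delta_c48": 1_179_360,
    "channel_delta_c48": 4_645,
}


def reference_key(cfg: ModelConfig) -> tuple[str, bool, int, int, int]:
    return (cfg.mixer, cfg.use_se, cfg.feature_size, cfg.in_channels, cfg.out_channels)


def architecture_checksum(reports: list[ParameterReport]) -> dict:
    """Compare parameter reports against the published reference totals.

    Returns a machine-readable summary with one entry per report (pass,
    fail, or skipped when no reference exists) plus any internal
    consistency deltas computable from the supplied reports.
    """
    entries = []
    by_key: dict[tuple, int] = {}
    for rep in reports:
        if rep.config is None:
            entries.append({"config": None, "status": "skipped",
                            "reason": "report carries no configuration"})
            continue
        key = reference_key(rep.config)
        by_key[key] = rep.total
        expected = REFERENCE_COUNTS.get(key)
        if expected is None:
            entries.append({"config": list(key), "total": rep.total, "status": "skipped",
                            "reason": "no reference total for this configuration"})
        else:
            entries.append({"config": list(key), "total": rep.total, "expected": expected,
                            "status": "pass" if rep.total == expected else "fail"})
    deltas = {}

    def pair(name, ka, kb, expected):
        if ka in by_key and kb in by_key:
            actual = by_key[ka] - by_key[kb]
            deltas[name] = {"actual": actual, "expected": expected,
                            "status": "pass" if actual == expected else "fail"}

    for c, tag in ((24, "se_delta_c24"), (48, "se_delta_c48")):
        for mixer in ("attention", "pooling"):
            pair(f"{tag}_{mixer}", (mixer, True, c, 1, 14), (mixer, False, c, 1, 14),
                 REFERENCE_DELTAS[tag])
    pair("mixer_delta_c48", ("attention", False, 48, 1, 14), ("pooling", False, 48, 1, 14),
         REFERENCE_DELTAS["mixer_delta_c48"])
    pair("channel_delta_c48", ("attention", False, 48, 4, 3), ("attention", False, 48, 1, 14),
         REFERENCE_DELTAS["channel_delta_c48"])
    checked = [e for e in entries if e["status"] != "skipped"]
    ok = all(e["status"] == "pass" for e in checked) and \
        all(d["status"] == "pass" for d in deltas.values())
    return {"entries": entries, "deltas": deltas, "all_pass": bool(ok and checked)}


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(net: SegmentationNetwork, path):
    state = {f"param:{k}": v for k, v in net.state_dict().items()}
    np.savez_compressed(path, config=np.frombuffer(net.cfg.to_json().encode(), dtype=np.uint8),
                        **state)


def load_checkpoint(path) -> SegmentationNetwork:
    with np.load(path) as data:
        cfg = ModelConfig.from_json(bytes(data["config"]).decode())
        net = build_network(cfg)
        net.load_state_dict({k[len("param:"):]: data[k] for k in data.files
                             if k.startswith("param:")})
    return net
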