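"""Architecture builders: modified 2D U-Net and region-specific 3D V-Nets.

2D network
----------
A U-Net whose per-level convolutional block is replaced by two *residual*
sub-blocks.  Inside each sub-block the convolution is depthwise-separable
and evaluated at four dilation rates in parallel (atrous spatial pyramid);
the four branches are concatenated and fused by a pointwise (1x1)
convolution, batch-normalised, added to the block input and passed through
ReLU.  Downsampling is 2x2 max pooling, upsampling is nearest-neighbour
followed by a pointwise channel reduction and skip concatenation.  Filters
double per level.  The final layer is a 1x1 convolution with a sigmoid, so
outputs are per-pixel tumor probabilities.  Native input size is
448 x 512 with 2 channels (PET SUV, CT HU), but the network is fully
convolutional and accepts any size divisible by ``2**(depth-1)``.

3D network
----------
A V-Net-style encoder/decoder per anatomical region.  Four encoder stages
(16, 32, 64, 128 filters by default): the first works at full resolution
and the next three each start with a stride-2 convolution, so the input
cube edge must be divisible by 8.  Three decoder stages mirror them with
2x nearest upsampling, skip concatenation and residual 3x3x3 convolutions
(ReLU activations).  Region-specific patch edges: head-neck 32, chest 64,
abdomen-pelvis 96.  Output is a single-channel sigmoid probability cube of
the input shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .anatomy import Region
from .nn.tensor import Tensor, concat

__all__ = [
    "NetConfig2D", "NetConfig3D", "build_unet2d", "build_vnet3d",
    "UNet2D", "VNet3D", "receptive_field_1d",
    "save_checkpoint", "load_checkpoint",
]

DEFAULT_PATCH_EDGES = {Region.HEAD_NECK: 32, Region.CHEST: 64,
                       Region.ABDOMEN_PELVIS: 96}


@dataclass(frozen=True)
class NetConfig2D:
    depth: int = 6
    base_filters: int = 8
    dilation_rates: tuple[int, int, int, int] = (1, 2, 4, 8)
    kernel: int = 3
    in_channels: int = 2
    out_channels: int = 1
    merge: str = "concat"   # "concat" (1x1 fuse) or "add"
    seed: int = 0

    def validate(self) -> None:
        if len(self.dilation_rates) != 4:
            raise ValueError("exactly 4 dilation rates are required")
        if list(self.dilation_rates) != sorted(set(self.dilation_rates)) or \
                len(set(self.dilation_rates)) != 4:
            raise ValueError("dilation rates must be strictly increasing")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.merge not in ("concat", "add"):
            raise ValueError(f"unknown merge mode {self.merge!r}")


@dataclass(frozen=True)
class NetConfig3D:
    down_filters: tuple[int, ...] = (16, 32, 64, 128)
    n_up_blocks: int = 3
    kernel: int = 3
    patch_edges: dict = field(default_factory=lambda: dict(DEFAULT_PATCH_EDGES))
    in_channels: int = 2
    out_channels: int = 1
    seed: int = 0

    @property
    def n_downsamplings(self) -> int:
        # stage 1 runs at full resolution; each later stage halves once
        return len(self.down_filters) - 1

    def validate(self) -> None:
        if len(self.down_filters) != 4:
            raise ValueError("four encoder stages are required")
        if any(b >= a for a, b in zip(self.down_filters[1:], self.down_filters)):
            raise ValueError("down_filters must be strictly increasing")
        for region, edge in self.patch_edges.items():
            div = 2 ** self.n_downsamplings
            if edge % div:
                raise ValueError(
                    f"patch edge {edge} for {region} not divisible by {div}")


def receptive_field_1d(kernel: int, rates: tuple[int, ...]) -> int:
    """Receptive field (one axis) of a stack of dilated convs, one per rate."""
    return 1 + sum((kernel - 1) * r for r in rates)


# ---------------------------------------------------------------------------
# 2D U-Net
# ---------------------------------------------------------------------------

class DilatedSepBlock(nn.Module):
    """Residual sub-block: parallel dilated depthwise convs, fused pointwise."""

    def __init__(self, channels: int, cfg: NetConfig2D, rng):
        super().__init__()
        self.merge = cfg.merge
        self.branches = nn.ModuleList([
            nn.DepthwiseConv2d(channels, cfg.kernel, dilation=r, rng=rng)
            for r in cfg.dilation_rates])
        fuse_in = channels * 4 if cfg.merge == "concat" else channels
        self.fuse = nn.Conv2d(fuse_in, channels, kernel=1, rng=rng)
        self.bn = nn.BatchNorm(channels)

    def forward(self, x: Tensor) -> Tensor:
        outs = [b(x) for b in self.branches]
        if self.merge == "concat":
            merged = concat(outs, axis=1)
        else:
            merged = outs[0]
            for o in outs[1:]:
                merged = merged + o
        y = self.bn(self.fuse(merged))
        return (y + x).relu()


class UNetLevel(nn.Module):
    def __init__(self, cin: int, cout: int, cfg: NetConfig2D, rng):
        super().__init__()
        self.entry = nn.Conv2d(cin, cout, kernel=1, rng=rng)
        self.block1 = DilatedSepBlock(cout, cfg, rng)
        self.block2 = DilatedSepBlock(cout, cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(self.entry(x)))


class UNet2D(nn.Module):
    def __init__(self, cfg: NetConfig2D):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        filters = [cfg.base_filters * 2 ** i for i in range(cfg.depth)]
        self.encoder = nn.ModuleList()
        cin = cfg.in_channels
        for f in filters:
            self.encoder.append(UNetLevel(cin, f, cfg, rng))
            cin = f
        self.decoder = nn.ModuleList()
        self.reducers = nn.ModuleList()
        for f_deep, f_skip in zip(filters[:0:-1], filters[-2::-1]):
            self.reducers.append(nn.Conv2d(f_deep, f_skip, kernel=1, rng=rng))
            self.decoder.append(UNetLevel(2 * f_skip, f_skip, cfg, rng))
        self.head = nn.Conv2d(filters[0], cfg.out_channels, kernel=1, rng=rng)
        # small head init: initial logits near 0 (output ~0.5 everywhere),
        # keeping the sigmoid unsaturated at the start of training
        self.head.weight.data *= 0.02

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for i, level in enumerate(self.encoder):
            x = level(x)
            if i < len(self.encoder) - 1:
                skips.append(x)
                x = nn.maxpool2d(x)
        for reducer, level, skip in zip(self.reducers, self.decoder,
                                        reversed(skips)):
            x = reducer(nn.upsample_nearest(x))
            x = level(concat([x, skip], axis=1))
        return self.head(x).sigmoid()

    @property
    def pad_multiple(self) -> int:
        """Spatial dims must divide by this (one pooling per encoder level)."""
        return 2 ** (self.cfg.depth - 1)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Inference on a float array (N, C, H, W) -> (N, 1, H, W)."""
        self.eval()
        out = self.forward(Tensor(np.ascontiguousarray(batch, np.float32)))
        return out.data


def build_unet2d(cfg: NetConfig2D = NetConfig2D()) -> UNet2D:
    return UNet2D(cfg)


# ---------------------------------------------------------------------------
# 3D V-Net
# ---------------------------------------------------------------------------

class VNetStage(nn.Module):
    """Residual 3x3x3 conv stage (one conv + BN + residual ReLU)."""

    def __init__(self, channels: int, kernel: int, rng):
        super().__init__()
        self.conv = nn.Conv3d(channels, channels, kernel, rng=rng)
        self.bn = nn.BatchNorm(channels)

    def forward(self, x: Tensor) -> Tensor:
        return (self.bn(self.conv(x)) + x).relu()


class VNet3D(nn.Module):
    def __init__(self, region: Region, cfg: NetConfig3D):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.region = Region(region)
        self.patch_edge = int(cfg.patch_edges[self.region])
        div = 2 ** cfg.n_downsamplings
        if self.patch_edge % div:
            raise ValueError(
                f"patch edge {self.patch_edge} not divisible by {div}")
        rng = np.random.default_rng(cfg.seed + int(self.region))
        f = cfg.down_filters
        self.stem = nn.Conv3d(cfg.in_channels, f[0], cfg.kernel, rng=rng)
        self.enc_stages = nn.ModuleList([VNetStage(c, cfg.kernel, rng) for c in f])
        self.downs = nn.ModuleList([
            nn.Conv3d(f[i], f[i + 1], cfg.kernel, stride=2, rng=rng)
            for i in range(len(f) - 1)])
        self.ups = nn.ModuleList()
        self.dec_stages = nn.ModuleList()
        for i in range(cfg.n_up_blocks):
            deep, skip = f[-1 - i], f[-2 - i]
            self.ups.append(nn.Conv3d(deep, skip, kernel=1, rng=rng))
            self.dec_stages.append(nn.Sequential([
                nn.Conv3d(2 * skip, skip, kernel=1, rng=rng),
                VNetStage(skip, cfg.kernel, rng),
            ]))
        self.head = nn.Conv3d(f[0], cfg.out_channels, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        skips = []
        for i, stage in enumerate(self.enc_stages):
            x = stage(x)
            if i < len(self.enc_stages) - 1:
                skips.append(x)
                x = self.downs[i](x)
        for up, dec, skip in zip(self.ups, self.dec_stages, reversed(skips)):
            x = up(nn.upsample_nearest(x))
            x = dec(concat([x, skip], axis=1))
        return self.head(x).sigmoid()

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Inference on a float array (N, C, D, H, W) -> (N, 1, D, H, W)."""
        self.eval()
        out = self.forward(Tensor(np.ascontiguousarray(batch, np.float32)))
        return out.data


def build_vnet3d(region: Region | str, cfg: NetConfig3D = NetConfig3D()) -> VNet3D:
    if isinstance(region, str):
        region = Region[region]
    return VNet3D(region, cfg)


# ---------------------------------------------------------------------------
# Checkpoints (.npz weights + .json config sidecar)
# ---------------------------------------------------------------------------

def save_checkpoint(model: nn.Module, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    meta: dict = {"class": type(model).__name__}
    if isinstance(model, UNet2D):
        meta["config"] = asdict(model.cfg)
    elif isinstance(model, VNet3D):
        cfg = asdict(model.cfg)
        cfg["patch_edges"] = {Region(k).name: v
                              for k, v in model.cfg.patch_edges.items()}
        meta["config"] = cfg
        meta["region"] = model.region.name
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path):
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    state = dict(np.load(path if path.suffix else path.with_suffix(".npz")))
    cfg = meta["config"]
    if meta["class"] == "UNet2D":
        model: nn.Module = UNet2D(NetConfig2D(**{
            **cfg, "dilation_rates": tuple(cfg["dilation_rates"])}))
    elif meta["class"] == "VNet3D":
        cfg = dict(cfg)
        cfg["down_filters"] = tuple(cfg["down_filters"])
        cfg["patch_edges"] = {Region[k]: v for k, v in cfg["patch_edges"].items()}
        model = VNet3D(Region[meta["region"]], NetConfig3D(**cfg))
    else:
        raise ValueError(f"unknown checkpoint class {meta['class']!r}")
    model.load_state_dict(state)
    return model
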