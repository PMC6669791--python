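"""Network builders: the BibNet and the baseline 3-level valid-convolution U-Net.

BibNet is a fully convolutional "bib"-shaped grid of residual blocks: a
U-Net-like encoder column, a lateral residual row on every resolution
level fed by the same-level encoder output and by strided/transposed
projections from the adjacent levels, and a decoder column joining the
lateral rows bottom-up.  All 3x3x3 convolutions are padded, so the output
spatial shape equals the input spatial shape; pooling is a 2x2x2 stride-2
convolution and upsampling a stride-2 transpose convolution, and the
filter width doubles at every level.

Each convolutional block is (dropout -> 3x3x3 conv -> PReLU -> batch norm),
and a residual block is two such blocks plus an additive skip (a 1x1x1
projection when the channel count changes).

The exact per-level block counts are pinned by two printed properties of
the reference instance: ~7.5 million trainable parameters, and a receptive
field of 484 voxels per axis for neurons in the deepest encoder layer.
The default configuration below satisfies both: with the encoder residual
blocks (3, 3, 3, 4, 4) the receptive field is

    1 + 2 * sum_l c_l 2^l + (2^(L-1) - 1) = 1 + 2*234 + 15 = 484

(c_l = 3x3x3 convolutions on the encoder path at level l), and the lateral
rows (1, 1, 1, 1, 2) with decoder blocks (1, 1, 1, 1) bring the parameter
count to ~7.51 million.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Module, Tensor, count_parameters

__all__ = [
    "BibNetConfig",
    "UNetConfig",
    "BibNet",
    "UNet3",
    "build_bibnet",
    "build_unet3",
    "default_bibnet_config",
    "reduced_bibnet_config",
    "count_parameters",
    "receptive_field",
    "unet3_output_shape",
    "UNET3_SHRINK",
    "UNET3_MIN_INPUT",
]

DEFAULT_ORGANS = ("left_breast", "right_breast", "heart")


class ConfigError(ValueError):
    """Raised for structurally invalid network configurations."""


@dataclass(frozen=True)
class BibNetConfig:
    n_levels: int = 5
    base_filters: int = 8
    growth_factor: int = 2
    enc_blocks: tuple[int, ...] = (3, 3, 3, 4, 4)
    lat_blocks: tuple[int, ...] = (1, 1, 1, 1, 2)
    dec_blocks: tuple[int, ...] = (1, 1, 1, 1)
    dropout_rate: float = 0.5
    in_channels: int = 1
    out_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 2:
            raise ConfigError("n_levels must be >= 2")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.growth_factor < 1:
            raise ConfigError("growth_factor must be >= 1")
        if self.out_channels < 1:
            raise ConfigError("out_channels must be >= 1")
        if len(self.enc_blocks) != self.n_levels or len(self.lat_blocks) != self.n_levels:
            raise ConfigError("enc_blocks and lat_blocks need one entry per level")
        if len(self.dec_blocks) != self.n_levels - 1:
            raise ConfigError("dec_blocks needs one entry per level except the deepest")
        if any(b < 1 for b in self.enc_blocks + self.lat_blocks + self.dec_blocks):
            raise ConfigError("block counts must be >= 1")

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(self.base_filters * self.growth_factor ** l for l in range(self.n_levels))


def default_bibnet_config(out_channels: int = 3, seed: int = 0) -> BibNetConfig:
    """The reference BibNet instance (~7.5 M parameters, 484^3 receptive field)."""
    return BibNetConfig(out_channels=out_channels, seed=seed)


def reduced_bibnet_config(out_channels: int = 3, seed: int = 0,
                          base_filters: int = 8) -> BibNetConfig:
    """A 2-level, narrow BibNet that trains in minutes on one CPU core."""
    return BibNetConfig(
        n_levels=2,
        base_filters=base_filters,
        enc_blocks=(2, 2),
        lat_blocks=(1, 1),
        dec_blocks=(1,),
        dropout_rate=0.0,
        out_channels=out_channels,
        seed=seed,
    )


@dataclass(frozen=True)
class UNetConfig:
    """Fixed 3-level valid-convolution U-Net of the baseline.

    Encoder filters 32/32, 64/128, 256/256; decoder 128/128 then 64/64;
    3x3x3 unpadded convolutions, 2x2x2 max pooling, nearest-neighbour
    upsampling, cropped skip concatenations.
    """

    enc_filters: tuple[tuple[int, int], ...] = ((32, 32), (64, 128), (256, 256))
    dec_filters: tuple[int, ...] = (128, 64)
    in_channels: int = 1
    out_channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if len(self.enc_filters) != 3 or len(self.dec_filters) != 2:
            raise ConfigError("the baseline U-Net has a fixed 3-level topology")


# Each axis shrinks by 40 voxels through the valid-convolution chain and
# admissible inputs are multiples of 4 (two pooling stages).
UNET3_SHRINK = 40
UNET3_MIN_INPUT = 44


def unet3_output_shape(input_shape: tuple[int, int, int]) -> tuple[int, int, int]:
    """Valid-convolution shape arithmetic for the baseline U-Net.

    Per axis: two 3^3 convolutions (-2 each), pool (/2), two convolutions,
    pool, two convolutions, upsample (x2), two convolutions, upsample, two
    convolutions -> n - 40, admissible when n % 4 == 0 and n >= 44.
    Raises :class:`ValueError` naming the minimum admissible size otherwise.
    """
    out = []
    for n in input_shape:
        if n % 4 != 0 or n < UNET3_MIN_INPUT:
            raise ValueError(
                f"input extent {n} inadmissible for the valid-convolution U-Net: "
                f"needs n % 4 == 0 and n >= {UNET3_MIN_INPUT}"
            )
        out.append(n - UNET3_SHRINK)
    return tuple(out)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

class ConvBlock(Module):
    """dropout -> 3x3x3 padded conv -> PReLU -> batch norm."""

    def __init__(self, c_in, c_out, dropout, *, rng):
        super().__init__()
        self.drop = nn.Dropout(dropout)
        self.conv = nn.Conv3d(c_in, c_out, kernel=3, stride=1, padding=1, rng=rng)
        self.act = nn.PReLU(c_out)
        self.norm = nn.BatchNorm3d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.act(self.conv(self.drop(x))))


class ResBlock(Module):
    """Two convolutional blocks with an additive skip connection."""

    def __init__(self, c_in, c_out, dropout, *, rng):
        super().__init__()
        self.block1 = ConvBlock(c_in, c_out, dropout, rng=rng)
        self.block2 = ConvBlock(c_out, c_out, dropout, rng=rng)
        if c_in != c_out:
            self.proj = nn.Conv3d(c_in, c_out, kernel=1, rng=rng)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.block2(self.block1(x))
        skip = x if self.proj is None else self.proj(x)
        return nn.add(y, skip)


class ResChain(Module):
    def __init__(self, n, c_in, c_out, dropout, *, rng):
        super().__init__()
        blocks = [ResBlock(c_in, c_out, dropout, rng=rng)]
        blocks += [ResBlock(c_out, c_out, dropout, rng=rng) for _ in range(n - 1)]
        self.chain = nn.Sequential(*blocks)

    def forward(self, x: Tensor) -> Tensor:
        return self.chain(x)


# ---------------------------------------------------------------------------
# BibNet
# ---------------------------------------------------------------------------

class BibNet(Module):
    """Full-image residual multi-resolution segmentation network.

    Output spatial shape equals input spatial shape.  Inputs whose extents
    are not divisible by ``2**(n_levels-1)`` are symmetrically zero-padded
    internally and the output cropped back.
    """

    def __init__(self, config: BibNetConfig, output_names: tuple[str, ...] | None = None):
        super().__init__()
        self.config = config
        if output_names is None:
            output_names = (
                DEFAULT_ORGANS if config.out_channels == 3
                else tuple(f"organ_{i}" for i in range(config.out_channels))
            )
        if len(output_names) != config.out_channels:
            raise ConfigError("output_names must match out_channels")
        self.output_names = tuple(output_names)
        L = config.n_levels
        w = config.widths
        rng = np.random.default_rng(config.seed)
        d = config.dropout_rate

        self.encoders = nn.Sequential(*[
            ResChain(config.enc_blocks[l], config.in_channels if l == 0 else w[l],
                     w[l], d, rng=rng)
            for l in range(L)
        ])
        self.downs = nn.Sequential(*[
            nn.Conv3d(w[l - 1], w[l], kernel=2, stride=2, rng=rng) for l in range(1, L)
        ])
        self.lat_down = nn.Sequential(*[
            nn.Conv3d(w[l - 1], w[l], kernel=2, stride=2, rng=rng) for l in range(1, L)
        ])
        self.lat_up = nn.Sequential(*[
            nn.ConvTranspose3d(w[l + 1], w[l], rng=rng) for l in range(L - 1)
        ])
        self.laterals = nn.Sequential(*[
            ResChain(config.lat_blocks[l], w[l], w[l], d, rng=rng) for l in range(L)
        ])
        self.ups = nn.Sequential(*[
            nn.ConvTranspose3d(w[l + 1], w[l], rng=rng) for l in range(L - 1)
        ])
        self.decoders = nn.Sequential(*[
            ResChain(config.dec_blocks[l], 2 * w[l], w[l], d, rng=rng)
            for l in range(L - 1)
        ])
        self.head = nn.Conv3d(w[0], config.out_channels, kernel=1, rng=rng)
        self.seed_dropout(config.seed)

    def seed_dropout(self, seed: int) -> None:
        streams = np.random.SeedSequence(seed).spawn(
            sum(1 for m in self.modules() if isinstance(m, nn.Dropout))
        )
        i = 0
        for m in self.modules():
            if isinstance(m, nn.Dropout):
                m.seed(np.random.default_rng(streams[i]))
                i += 1

    def forward(self, x: Tensor) -> Tensor:
        L = self.config.n_levels
        div = 2 ** (L - 1)
        spatial = x.shape[2:]
        pads = tuple(
            ((div - s % div) % div // 2, ((div - s % div) % div + 1) // 2) for s in spatial
        )
        padded = any(lo or hi for lo, hi in pads)
        if padded:
            x = nn.pad_spatial(x, pads)

        enc = []
        h = x
        for l in range(L):
            if l > 0:
                h = self.downs.layers[l - 1](h)
            h = self.encoders.layers[l](h)
            enc.append(h)

        lat = []
        for l in range(L):
            h = enc[l]
            if l > 0:
                h = nn.add(h, self.lat_down.layers[l - 1](enc[l - 1]))
            if l < L - 1:
                h = nn.add(h, self.lat_up.layers[l](enc[l + 1]))
            lat.append(self.laterals.layers[l](h))

        h = lat[L - 1]
        for l in range(L - 2, -1, -1):
            up = self.ups.layers[l](h)
            h = self.decoders.layers[l](nn.concat([lat[l], up], axis=1))

        out = nn.sigmoid(self.head(h))
        if padded:
            out = nn.crop_spatial(out, pads)
        return out


def build_bibnet(config: BibNetConfig,
                 output_names: tuple[str, ...] | None = None) -> BibNet:
    """Instantiate a BibNet with seeded He-uniform weights."""
    return BibNet(config, output_names)


def receptive_field(config: BibNetConfig) -> tuple[int, int, int]:
    """Receptive field of a neuron in the deepest encoder layer.

    Composes per-layer (kernel, stride) contributions along the encoder
    path: a kernel-k layer seen at cumulative input stride S widens the
    field by (k-1)*S, and a stride-s layer multiplies S by s afterwards.
    """
    rf, stride = 1, 1
    for l in range(config.n_levels):
        if l > 0:
            rf += (2 - 1) * stride  # 2x2x2 stride-2 pooling convolution
            stride *= 2
        rf += config.enc_blocks[l] * 2 * (3 - 1) * stride  # two 3^3 convs per block
    return (rf, rf, rf)


# ---------------------------------------------------------------------------
# Baseline U-Net
# ---------------------------------------------------------------------------

class _CropConcat(Module):
    """Centre-crop the skip tensor to the decoder tensor and concatenate."""

    def forward(self, skip: Tensor, x: Tensor) -> Tensor:
        crops = []
        for a in range(3):
            excess = skip.shape[2 + a] - x.shape[2 + a]
            crops.append((excess // 2, excess - excess // 2))
        return nn.concat([nn.crop_spatial(skip, tuple(crops)), x], axis=1)


class UNet3(Module):
    """3-level valid-convolution U-Net (patch-in, smaller-patch-out)."""

    def __init__(self, config: UNetConfig, output_names: tuple[str, ...] | None = None):
        super().__init__()
        self.config = config
        self.output_names = tuple(
            output_names
            if output_names is not None
            else (f"organ_{i}" for i in range(config.out_channels))
        )
        rng = np.random.default_rng(config.seed)

        def vconv(ci, co):
            return nn.Sequential(nn.Conv3d(ci, co, kernel=3, rng=rng), nn.ReLU())

        (f00, f01), (f10, f11), (f20, f21) = config.enc_filters
        d1, d0 = config.dec_filters
        self.enc0 = nn.Sequential(vconv(config.in_channels, f00), vconv(f00, f01))
        self.enc1 = nn.Sequential(vconv(f01, f10), vconv(f10, f11))
        self.bottom = nn.Sequential(vconv(f11, f20), vconv(f20, f21))
        self.pool = nn.MaxPool3d()
        self.up = nn.Upsample3d()
        self.merge = _CropConcat()
        self.dec1 = nn.Sequential(vconv(f21 + f11, d1), vconv(d1, d1))
        self.dec0 = nn.Sequential(vconv(d1 + f01, d0), vconv(d0, d0))
        self.head = nn.Conv3d(d0, config.out_channels, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        for a, n in enumerate(x.shape[2:]):
            if n % 4 != 0 or n < UNET3_MIN_INPUT:
                raise ValueError(
                    f"axis {a} extent {n} inadmissible: the valid-convolution "
                    f"chain needs n % 4 == 0 and n >= {UNET3_MIN_INPUT}"
                )
        e0 = self.enc0(x)
        e1 = self.enc1(self.pool(e0))
        b = self.bottom(self.pool(e1))
        d1 = self.dec1(self.merge(e1, self.up(b)))
        d0 = self.dec0(self.merge(e0, self.up(d1)))
        return nn.sigmoid(self.head(d0))


def build_unet3(config: UNetConfig | None = None,
                output_names: tuple[str, ...] | None = None) -> UNet3:
    return UNet3(config or UNetConfig(), output_names)


# ---------------------------------------------------------------------------
# Checkpointing: weights as .npz (flat name -> array mapping mirroring the
# module tree) plus a JSON sidecar holding the configuration.
# ---------------------------------------------------------------------------

def save_model(net: BibNet | UNet3, prefix: str) -> None:
    import dataclasses
    import json
    from pathlib import Path

    prefix = str(prefix)
    net.save(prefix + ".npz")
    meta = {
        "kind": "bibnet" if isinstance(net, BibNet) else "unet3",
        "config": dataclasses.asdict(net.config),
        "output_names": list(net.output_names),
    }
    Path(prefix + ".json").write_text(json.dumps(meta, indent=1))


def load_model(prefix: str) -> BibNet | UNet3:
    import json
    from pathlib import Path

    prefix = str(prefix)
    meta = json.loads(Path(prefix + ".json").read_text())
    cfg_dict = meta["config"]
    for key in ("enc_blocks", "lat_blocks", "dec_blocks", "dec_filters"):
        if key in cfg_dict:
            cfg_dict[key] = tuple(cfg_dict[key])
    if "enc_filters" in cfg_dict:
        cfg_dict["enc_filters"] = tuple(tuple(t) for t in cfg_dict["enc_filters"])
    names = tuple(meta["output_names"])
    if meta["kind"] == "bibnet":
        net: BibNet | UNet3 = BibNet(BibNetConfig(**cfg_dict), names)
    else:
        net = UNet3(UNetConfig(**cfg_dict), names)
    net.load(prefix + ".npz")
    net.eval()
    return net
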