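"""Residual 3D U-Net for left-atrium segmentation.

Depth-3 encoder/decoder. Feature widths double along the encoder
(base -> 8*base, defaults 32 -> 256) and halve along the decoder; each
stage is a residual block of two sub-units. A convolutional sub-unit is
a strided 3x3x3 convolution -> instance norm -> PReLU followed by two
further convolution + instance-norm layers, all inside the residual
branch, with the identity shortcut added on top (projected by a 1x1x1
convolution when channels or resolution change). An up-convolutional
sub-unit is a kernel-2 stride-2 transposed convolution -> convolution ->
instance norm -> PReLU, with a nearest-upsample + 1x1x1 projection
shortcut. Skip connections concatenate encoder features into the
decoder; the head is a 1x1x1 convolution with a sigmoid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .imaging_io import BinaryMask, ImageVolume, IntensityState

__all__ = [
    "ResUNetConfig",
    "ResidualSubunitSpec",
    "ConvResidualSubunit",
    "UpResidualSubunit",
    "ResUNet3D",
    "build_model",
    "init_weights",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ResUNetConfig:
    depth: int = 3
    base_features: int = 32
    max_features: int = 256
    subunits_per_block: int = 2
    kernel: int = 3
    downsample_stride: int = 2
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_features * 2 ** self.depth != self.max_features:
            raise ValueError(
                "max_features must equal base_features * 2**depth "
                f"(got {self.base_features} * 2**{self.depth} != {self.max_features})")

    def feature_widths(self) -> tuple[int, ...]:
        """Stage widths encoder -> bottleneck -> decoder, e.g. (32,64,128,256,128,64,32)."""
        enc = [self.base_features * 2 ** i for i in range(self.depth)]
        return tuple(enc + [self.max_features] + enc[::-1])


@dataclass
class ResidualSubunitSpec:
    kind: str                 # "convolutional" | "upconvolutional"
    stride: int = 1

    @property
    def K(self) -> int:
        # layers carrying weights in the residual branch, per kind
        return 2 if self.kind == "convolutional" else 1

    def __post_init__(self):
        if self.kind not in ("convolutional", "upconvolutional"):
            raise ValueError(f"unknown sub-unit kind {self.kind!r}")


class ConvResidualSubunit(nn.Module):
    """x_{l+1} = h(x_l) + F(x_l); h identity when shape-preserving."""

    def __init__(self, cin, cout, stride=1, kernel=3, rng=None):
        self.conv1 = nn.Conv3d(cin, cout, kernel, stride=stride, rng=rng)
        self.norm1 = nn.InstanceNorm3d(cout)
        self.act = nn.PReLU(cout)
        self.conv2 = nn.Conv3d(cout, cout, kernel, rng=rng)
        self.norm2 = nn.InstanceNorm3d(cout)
        self.conv3 = nn.Conv3d(cout, cout, kernel, rng=rng)
        self.norm3 = nn.InstanceNorm3d(cout)
        self.identity_shortcut = (cin == cout and stride == 1)
        if not self.identity_shortcut:
            self.proj = nn.Conv3d(cin, cout, kernel=1, stride=stride, pad=0, rng=rng)

    def residual_branch(self, x):
        y = self.act(self.norm1(self.conv1(x)))
        y = self.norm2(self.conv2(y))
        y = self.norm3(self.conv3(y))
        return y

    def forward(self, x):
        h = x if self.identity_shortcut else self.proj(x)
        return h + self.residual_branch(x)


class UpResidualSubunit(nn.Module):
    """Transposed-conv sub-unit; shortcut is nearest upsample + 1x1x1 projection."""

    def __init__(self, cin, cout, stride=2, kernel=3, rng=None):
        self.stride = stride
        self.upconv = nn.ConvTranspose3d(cin, cout, stride=stride, rng=rng)
        self.conv = nn.Conv3d(cout, cout, kernel, rng=rng)
        self.norm = nn.InstanceNorm3d(cout)
        self.act = nn.PReLU(cout)
        self.proj = nn.Conv3d(cin, cout, kernel=1, pad=0, rng=rng)

    def residual_branch(self, x):
        return self.act(self.norm(self.conv(self.upconv(x))))

    def forward(self, x):
        h = self.proj(nn.upsample_nearest(x, self.stride))
        return h + self.residual_branch(x)


class _ConvBlock(nn.Module):
    """Residual block of two convolutional sub-units (first may stride)."""

    def __init__(self, cin, cout, stride, kernel, rng):
        self.sub1 = ConvResidualSubunit(cin, cout, stride=stride, kernel=kernel, rng=rng)
        self.sub2 = ConvResidualSubunit(cout, cout, kernel=kernel, rng=rng)

    def forward(self, x):
        return self.sub2(self.sub1(x))


class _UpBlock(nn.Module):
    """Residual block of an up-convolutional plus a convolutional sub-unit."""

    def __init__(self, cin, cout, stride, kernel, rng):
        self.sub1 = UpResidualSubunit(cin, cout, stride=stride, kernel=kernel, rng=rng)
        self.sub2 = ConvResidualSubunit(cout, cout, kernel=kernel, rng=rng)

    def forward(self, x):
        return self.sub2(self.sub1(x))


class ResUNet3D(nn.Module):
    def __init__(self, cfg: ResUNetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.seed = seed
        k, s = cfg.kernel, cfg.downsample_stride
        widths = cfg.feature_widths()
        enc_w = widths[:cfg.depth]           # e.g. (32, 64, 128)
        bottom_w = widths[cfg.depth]         # 256

        self.encoders = []
        cin = cfg.in_channels
        for w in enc_w:
            self.encoders.append(_ConvBlock(cin, w, stride=s, kernel=k, rng=rng))
            cin = w
        self.bottleneck = _ConvBlock(cin, bottom_w, stride=1, kernel=k, rng=rng)

        self.decoders = []
        cin = bottom_w
        for i in range(cfg.depth - 1, -1, -1):
            skip_w = enc_w[i]
            out_w = enc_w[i]
            self.decoders.append(_UpBlock(cin + skip_w, out_w, stride=s,
                                          kernel=k, rng=rng))
            cin = out_w
        self.head = nn.Conv3d(cin, cfg.out_channels, kernel=1, pad=0, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        cfg = self.cfg
        div = cfg.downsample_stride ** cfg.depth
        if any(d % div for d in x.shape[1:]):
            raise ValueError(
                f"spatial shape {x.shape[1:]} not divisible by {div}")
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
        x = self.bottleneck(x)
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = dec(nn.concat([x, skip], axis=0))
        return nn.sigmoid(self.head(x))

    def predict(self, voxels: np.ndarray) -> np.ndarray:
        """Forward pass without gradient tracking; returns probabilities.

        A 3D input yields a 3D probability field (single output channel).
        """
        x = nn.Tensor(voxels[None] if voxels.ndim == 3 else voxels)
        prob = self.forward(x).data
        return prob[0] if self.cfg.out_channels == 1 else prob


def build_model(cfg: ResUNetConfig | None = None, seed: int = 0) -> ResUNet3D:
    return ResUNet3D(cfg or ResUNetConfig(), seed=seed)


def init_weights(network: ResUNet3D, seed: int) -> ResUNet3D:
    """Re-draw all convolution weights (Kaiming) from a fresh seeded stream."""
    fresh = ResUNet3D(network.cfg, seed=seed)
    network.load_state_dict(fresh.state_dict())
    network.seed = seed
    return network


def predict_mask(network: ResUNet3D, vol: ImageVolume,
                 threshold: float = 0.5) -> BinaryMask:
    """Threshold the sigmoid output; the mask inherits the volume geometry."""
    if vol.intensity_state is not IntensityState.NORMALIZED:
        raise ValueError("predict_mask expects a normalized volume")
    prob = network.predict(np.asarray(vol.voxels, dtype=np.float64))
    return BinaryMask(voxels=prob > threshold, spacing=vol.spacing,
                      affine=vol.affine)


def save_checkpoint(network: ResUNet3D, path) -> None:
    """Native .npz weights plus a JSON sidecar with config and seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **network.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"config": asdict(network.cfg),
                                   "seed": network.seed}, indent=2))


def load_checkpoint(path) -> ResUNet3D:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    net = ResUNet3D(ResUNetConfig(**sidecar["config"]), seed=sidecar["seed"])
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
        net.load_state_dict({k: z[k] for k in z.files})
    return net
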