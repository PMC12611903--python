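"""3D encoder-decoder segmentation network with channel/spatial attention.

The network is a five-level (configurable) U-shaped encoder-decoder over a
fixed-size ROI.  Each level is an *attentional block*: two convolutional
sublayers (depthwise-separable by default) with instance normalization and
rectifier, refined by a channel attention module (CAM) and then a spatial
attention module (SAM), each applied as a Hadamard product:

    V_c(F) = sigmoid( MLP(AvgPool(F)) + MLP(MaxPool(F)) )       (per channel)
    V_s(F) = sigmoid( conv([ChanAvg(F) ; ChanMax(F)]) )         (per voxel)
    block(F) = V_s(F1) ⊙ F1,  F1 = V_c(F) ⊙ F

The shared MLP is two affine maps (W0 then W1) with a rectifier between and
a bottleneck of ``channels / mlp_reduction``.  Downsampling is factor-2 max
pooling; the decoder mirrors the encoder with transposed-convolution (or
nearest-neighbor) upsampling and skip concatenation.  The head reduces to
two channels followed by tanh, polarizing lesion against normal tissue; the
predicted mask is the per-voxel argmax with ties broken to background.

``use_attention=False`` ablates both attention modules (the block reduces to
its convolutional path); ``use_depthwise=False`` swaps the separable
convolutions for standard ones, giving a strictly larger parameter count.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .io_formats import BinaryMask3D, MultimodalStack
from .nn import Module, Tensor, concat


@dataclass
class NetworkConfig:
    in_channels: int
    base_width: int = 8
    levels: int = 5
    mlp_reduction: int = 8
    sam_kernel: int = 7
    use_attention: bool = True
    use_depthwise: bool = True
    upsample: str = "transposed"  # or "nearest"
    seed: int = 0

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_width < 2:
            raise ValueError("base_width must be >= 2")
        if self.base_width % self.mlp_reduction != 0:
            raise ValueError("mlp_reduction must divide base_width")
        if self.sam_kernel % 2 != 1:
            raise ValueError("sam_kernel must be odd")
        if self.upsample not in ("transposed", "nearest"):
            raise ValueError("upsample must be 'transposed' or 'nearest'")


class ChannelAttention(Module):
    """CAM: dual global pooling through a shared bottleneck MLP."""

    def __init__(self, rng, channels: int, reduction: int, nd: int = 3):
        self.nd = nd
        hidden = max(1, channels // reduction)
        self.w0 = nn.Linear(rng, channels, hidden, bias=False)
        self.w1 = nn.Linear(rng, hidden, channels, bias=False)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.w1(self.w0(v).relu())

    def __call__(self, f: Tensor) -> Tensor:
        """Channel weights in (0,1), shaped (N, C, 1, ..., 1)."""
        n, c = f.shape[:2]
        flat = f.reshape(n, c, -1)
        avg = flat.mean(axis=2)
        mx = flat.amax(axis=2)
        v = (self._mlp(avg) + self._mlp(mx)).sigmoid()
        return v.reshape((n, c) + (1,) * self.nd)


class SpatialAttention(Module):
    """SAM: channel mean/max pooled map through one k^nd convolution."""

    def __init__(self, rng, kernel: int, nd: int = 3):
        self.nd = nd
        self.conv = nn.Conv(rng, 2, 1, kernel, nd, bias=True)

    def __call__(self, f: Tensor) -> Tensor:
        """Spatial weights in (0,1), shaped (N, 1, *spatial)."""
        avg = f.mean(axis=1, keepdims=True)
        n = f.shape[0]
        mx = f.amax(axis=1).reshape((n, 1) + f.shape[2:])
        return self.conv(concat([avg, mx], axis=1)).sigmoid()


def channel_attention(f: Tensor, cam: ChannelAttention) -> Tensor:
    return cam(f)


def spatial_attention(f: Tensor, sam: SpatialAttention) -> Tensor:
    return sam(f)


class AttentionalBlock(Module):
    """Two conv sublayers (+IN+ReLU) refined by CAM then SAM."""

    def __init__(self, rng, c_in: int, c_out: int, cfg: NetworkConfig,
                 nd: int = 3):
        conv_cls = (nn.DepthwiseSeparableConv if cfg.use_depthwise
                    else nn.Conv)
        self.conv1 = conv_cls(rng, c_in, c_out, 3, nd)
        self.norm1 = nn.InstanceNorm(c_out, nd)
        self.conv2 = conv_cls(rng, c_out, c_out, 3, nd)
        self.norm2 = nn.InstanceNorm(c_out, nd)
        self.use_attention = cfg.use_attention
        if cfg.use_attention:
            self.cam = ChannelAttention(rng, c_out, cfg.mlp_reduction, nd)
            self.sam = SpatialAttention(rng, cfg.sam_kernel, nd)

    def __call__(self, x: Tensor) -> Tensor:
        f = self.norm1(self.conv1(x)).relu()
        f = self.norm2(self.conv2(f)).relu()
        if self.use_attention:
            f1 = f * self.cam(f)
            f = f1 * self.sam(f1)
        return f


def attentional_block(f: Tensor, block: AttentionalBlock) -> Tensor:
    return block(f)


def depthwise_separable_params(kernel: int, c_in: int, c_out: int,
                               with_bias: bool = False,
                               nd: int = 3) -> tuple[int, int]:
    """(standard, separable) learnable-parameter counts of one conv layer."""
    if min(kernel, c_in, c_out) < 1:
        raise ValueError("kernel and channel counts must be positive")
    kk = kernel ** nd
    standard = kk * c_in * c_out + (c_out if with_bias else 0)
    separable = kk * c_in + c_in * c_out + (c_in + c_out if with_bias else 0)
    return standard, separable


class AttnSegNet3D(Module):
    """The full ROI segmentation network (see module docstring)."""

    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        nd = 3
        widths = [cfg.base_width * 2 ** i for i in range(cfg.levels)]
        self.enc = []
        c_prev = cfg.in_channels
        for w in widths:
            self.enc.append(AttentionalBlock(rng, c_prev, w, cfg, nd))
            c_prev = w
        self.ups = []
        self.dec = []
        for i in range(cfg.levels - 2, -1, -1):
            w = widths[i]
            if cfg.upsample == "transposed":
                self.ups.append(nn.ConvTranspose2(rng, widths[i + 1], w, nd))
            else:
                self.ups.append(nn.Conv(rng, widths[i + 1], w, 1, nd))
            self.dec.append(AttentionalBlock(rng, 2 * w, w, cfg, nd))
        self.head = nn.Conv(rng, widths[0], 2, 1, nd)

    def _check_size(self, spatial: tuple[int, ...]) -> None:
        div = 2 ** (self.cfg.levels - 1)
        bad = [s for s in spatial if s % div]
        if bad:
            raise ValueError(
                f"input spatial size {spatial} not divisible by 2^(levels-1)={div}")

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, C, D, H, W) -> (N, 2, D, H, W), values in (-1, 1)."""
        self._check_size(x.shape[2:])
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block(h)
            if i < len(self.enc) - 1:
                skips.append(h)
                h = nn.maxpool2_nd(h, 3)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            if self.cfg.upsample == "transposed":
                h = up(h)
            else:
                h = up(nn.upsample_nearest2_nd(h, 3))
            h = block(concat([h, skip], axis=1))
        return self.head(h).tanh()


def build_network(cfg: NetworkConfig,
                  roi_size: int | None = None) -> AttnSegNet3D:
    """Construct the segmenter; validates ROI divisibility when given."""
    net = AttnSegNet3D(cfg)
    if roi_size is not None:
        net._check_size((roi_size,) * 3)
    return net


def predict_mask(model: AttnSegNet3D, cropped_stack,
                 spacing_mm=(1.0, 1.0, 1.0)) -> BinaryMask3D:
    """Argmax over the two polarity channels; ties go to background."""
    if isinstance(cropped_stack, MultimodalStack):
        spacing_mm = cropped_stack.spacing_mm
        x = cropped_stack.as_array()
    else:
        x = np.asarray(cropped_stack, dtype=np.float32)
    if x.shape[0] != model.cfg.in_channels:
        raise ValueError(
            f"stack has {x.shape[0]} channels, model expects "
            f"{model.cfg.in_channels}")
    y = model(Tensor(x[None])).data[0]
    fg = y[1] > y[0]
    return BinaryMask3D(fg.astype(np.uint8), spacing_mm)


def save_model(path, model: AttnSegNet3D) -> None:
    nn.save_checkpoint(path, model, asdict(model.cfg))


def load_model(path) -> AttnSegNet3D:
    config, state = nn.load_checkpoint(path)
    net = AttnSegNet3D(NetworkConfig(**config))
    net.load_state_dict(state)
    return net
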