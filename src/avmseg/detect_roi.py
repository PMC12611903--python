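"""Detection stage: slice-wise coarse localization and ROI geometry.

A 2D U-Net runs independently on every axial slice of the multimodal stack
and the thresholded slices are restacked into a coarse 3D mask.  The mass
center of that mask anchors a fixed-size cubic ROI (128 voxels per side at
clinical resolution; configurable) whose geometry — start, size, source
shape and any symmetric padding — is recorded in an :class:`ROIBox` so that
ROI-space predictions map back to the full grid exactly.

Conventions: 0-based voxel indices, half-open boxes [start, start+size),
mass center rounded half-up per axis.  When the coarse mask is empty the
caller should fall back to the grid center (see :func:`fallback_center`);
inference must not abort on a missed detection.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .io_formats import BinaryMask3D, MultimodalStack
from .nn import Module, Tensor, concat

DEFAULT_ROI_SIZE = 128
DEFAULT_THRESHOLD = 0.5


@dataclass
class ROIBox:
    """Geometry of a cubic crop, exactly invertible via :func:`map_back`.

    ``start`` indexes the (possibly padded) grid; ``pad_before``/``pad_after``
    record symmetric zero padding applied when the source grid is smaller
    than the ROI.
    """

    start: tuple[int, int, int]
    size: tuple[int, int, int]
    source_shape: tuple[int, int, int]
    pad_before: tuple[int, int, int] = (0, 0, 0)
    pad_after: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        padded = self.padded_shape
        for s, z, p in zip(self.start, self.size, padded):
            if s < 0 or s + z > p:
                raise ValueError(
                    f"box [start={self.start}, size={self.size}) exceeds "
                    f"padded grid {padded}")

    @property
    def padded_shape(self) -> tuple[int, int, int]:
        return tuple(s + b + a for s, b, a in
                     zip(self.source_shape, self.pad_before, self.pad_after))


@dataclass
class CoarseMask:
    mask: BinaryMask3D
    per_slice_scores: np.ndarray | None = None

    def is_empty(self) -> bool:
        return self.mask.is_empty()


# ---------------------------------------------------------------------------
# 2D detection U-Net
# ---------------------------------------------------------------------------

@dataclass
class DetectorConfig:
    in_channels: int
    base_width: int = 8
    levels: int = 4
    seed: int = 0


class _ConvBlock2D(Module):
    def __init__(self, rng, c_in, c_out):
        self.conv1 = nn.Conv(rng, c_in, c_out, 3, 2)
        self.norm1 = nn.InstanceNorm(c_out, 2)
        self.conv2 = nn.Conv(rng, c_out, c_out, 3, 2)
        self.norm2 = nn.InstanceNorm(c_out, 2)

    def __call__(self, x):
        h = self.norm1(self.conv1(x)).relu()
        return self.norm2(self.conv2(h)).relu()


class UNet2D(Module):
    """Standard 4-level 2D U-Net emitting per-pixel foreground probability."""

    def __init__(self, cfg: DetectorConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        widths = [cfg.base_width * 2 ** i for i in range(cfg.levels)]
        self.enc = []
        c_prev = cfg.in_channels
        for w in widths:
            self.enc.append(_ConvBlock2D(rng, c_prev, w))
            c_prev = w
        self.ups = []
        self.dec = []
        for i in range(cfg.levels - 2, -1, -1):
            self.ups.append(nn.ConvTranspose2(rng, widths[i + 1], widths[i], 2))
            self.dec.append(_ConvBlock2D(rng, 2 * widths[i], widths[i]))
        self.head = nn.Conv(rng, widths[0], 1, 1, 2)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, C, H, W) -> probabilities (N, 1, H, W)."""
        div = 2 ** (self.cfg.levels - 1)
        if any(s % div for s in x.shape[2:]):
            raise ValueError(
                f"slice size {x.shape[2:]} not divisible by {div}")
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block(h)
            if i < len(self.enc) - 1:
                skips.append(h)
                h = nn.maxpool2_nd(h, 2)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            h = block(concat([up(h), skip], axis=1))
        return self.head(h).sigmoid()


def save_detector(path, model: UNet2D) -> None:
    nn.save_checkpoint(path, model, asdict(model.cfg))


def load_detector(path) -> UNet2D:
    config, state = nn.load_checkpoint(path)
    net = UNet2D(DetectorConfig(**config))
    net.load_state_dict(state)
    return net


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def detect_coarse(stack, detector: UNet2D,
                  threshold: float = DEFAULT_THRESHOLD) -> CoarseMask:
    """Run the 2D detector on every axial slice and restack to 3D.

    May legitimately return an empty mask; the caller decides the fallback.
    """
    if isinstance(stack, MultimodalStack):
        x = stack.as_array()
        spacing = stack.spacing_mm
    else:
        x = np.asarray(stack, dtype=np.float32)
        spacing = (1.0, 1.0, 1.0)
    if x.shape[0] != detector.cfg.in_channels:
        raise ValueError(
            f"stack has {x.shape[0]} channels, detector expects "
            f"{detector.cfg.in_channels}")
    # slices along axis 0 of the volume become the batch axis
    slices = np.moveaxis(x, 1, 0)  # (n_slices, C, H, W)
    probs = detector(Tensor(slices)).data[:, 0]  # (n_slices, H, W)
    mask3d = (probs >= threshold).astype(np.uint8)
    scores = mask3d.reshape(mask3d.shape[0], -1).mean(axis=1)
    return CoarseMask(BinaryMask3D(mask3d, spacing), per_slice_scores=scores)


def mass_center(mask) -> tuple[int, int, int]:
    """Arithmetic mean of foreground voxel indices, rounded half-up."""
    m = mask.voxels if isinstance(mask, BinaryMask3D) else np.asarray(mask)
    idx = np.argwhere(m)
    if len(idx) == 0:
        raise ValueError("mass center of an empty mask is undefined")
    mean = idx.mean(axis=0)
    return tuple(int(v) for v in np.floor(mean + 0.5))


def fallback_center(shape) -> tuple[int, int, int]:
    """Grid center, used when the coarse detection comes back empty."""
    return tuple(int(s) // 2 for s in shape)


def _box_for(center, size, source_shape) -> ROIBox:
    size3 = (size,) * 3 if np.isscalar(size) else tuple(int(s) for s in size)
    pad_b, pad_a = [], []
    for z, s in zip(size3, source_shape):
        short = max(0, z - s)
        pad_b.append(short // 2)
        pad_a.append(short - short // 2)
    padded = [s + b + a for s, b, a in zip(source_shape, pad_b, pad_a)]
    start = []
    for c, z, p, b in zip(center, size3, padded, pad_b):
        st = int(c) + b - z // 2
        start.append(int(np.clip(st, 0, p - z)))
    return ROIBox(tuple(start), size3, tuple(source_shape),
                  tuple(pad_b), tuple(pad_a))


def crop_volume(volume: np.ndarray, box: ROIBox) -> np.ndarray:
    """Crop one 3D volume (or a (C, ...) stack of them) to the box."""
    v = np.asarray(volume)
    spatial = v.shape[-3:]
    if spatial != box.source_shape:
        raise ValueError(f"volume shape {spatial} != box source {box.source_shape}")
    pads = [(b, a) for b, a in zip(box.pad_before, box.pad_after)]
    if v.ndim == 4:
        pads = [(0, 0)] + pads
    if any(p != (0, 0) for p in pads):
        v = np.pad(v, pads)
    sl = tuple(slice(s, s + z) for s, z in zip(box.start, box.size))
    if v.ndim == 4:
        sl = (slice(None),) + sl
    return v[sl]


def crop_roi(stack, center, size: int = DEFAULT_ROI_SIZE):
    """Crop the multimodal stack to a cubic ROI centered at `center`.

    Returns (cropped, ROIBox).  The box start is center - size//2, clamped
    inside the (zero-padded, if necessary) grid.
    """
    if isinstance(stack, MultimodalStack):
        arr = stack.as_array()
        box = _box_for(center, size, arr.shape[1:])
        cropped = crop_volume(arr, box)
        out = MultimodalStack(
            {n: cropped[i] for i, n in enumerate(stack.channel_names)},
            stack.spacing_mm, stack.origin, case_id=stack.case_id)
        return out, box
    arr = np.asarray(stack)
    box = _box_for(center, size, arr.shape[-3:])
    return crop_volume(arr, box), box


def map_back(roi_mask, box: ROIBox) -> BinaryMask3D:
    """Paste an ROI-frame mask back onto the full grid."""
    m = roi_mask.voxels if isinstance(roi_mask, BinaryMask3D) \
        else np.asarray(roi_mask)
    spacing = roi_mask.spacing_mm if isinstance(roi_mask, BinaryMask3D) \
        else (1.0, 1.0, 1.0)
    if m.shape != box.size:
        raise ValueError(f"ROI mask shape {m.shape} != box size {box.size}")
    full = np.zeros(box.padded_shape, dtype=np.uint8)
    sl = tuple(slice(s, s + z) for s, z in zip(box.start, box.size))
    full[sl] = m
    unpad = tuple(slice(b, b + s) for b, s in
                  zip(box.pad_before, box.source_shape))
    return BinaryMask3D(full[unpad], spacing)
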