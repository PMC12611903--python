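"""Volumetric image I/O and grid-consistency checking.

Volumes are exchanged as NIfTI files via nibabel.  On read, every volume is
reoriented to the closest RAS+ canonical orientation so that voxel-index
arithmetic (mass centers, ROI boxes) is convention-stable regardless of how
the file was stored.  Images are float32, masks uint8 with values {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

GEOM_ATOL_MM = 1e-6


@dataclass
class BinaryMask3D:
    """A {0,1} label volume on a known voxel grid."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.voxels)
        uniq = np.unique(v)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(
                f"mask is not binary: found values {uniq[:10].tolist()}")
        self.voxels = v.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not self.voxels.any()


@dataclass
class MultimodalStack:
    """Ordered, co-registered named channels on one voxel grid."""

    channels: dict[str, np.ndarray]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    case_id: str = ""

    def __post_init__(self):
        if not self.channels:
            raise ValueError("a stack needs at least one channel")
        shapes = {name: np.asarray(v).shape for name, v in self.channels.items()}
        first = next(iter(shapes.values()))
        bad = [n for n, s in shapes.items() if s != first]
        if bad:
            raise ValueError(f"channel shape mismatch: {bad} differ from {first}")
        self.channels = {n: np.asarray(v, dtype=np.float32)
                         for n, v in self.channels.items()}
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def as_array(self) -> np.ndarray:
        """(C, X, Y, Z) float32 array in channel order."""
        return np.stack(list(self.channels.values()), axis=0)


# ---------------------------------------------------------------------------
# NIfTI read / write
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_volume(volume: np.ndarray, path, spacing_mm=(1, 1, 1),
                 origin=(0, 0, 0)) -> None:
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={vol.ndim}")
    dtype = np.uint8 if vol.dtype == np.uint8 else np.float32
    img = nib.Nifti1Image(vol.astype(dtype), _affine(spacing_mm, origin))
    img.header.set_zooms(tuple(float(s) for s in spacing_mm))
    nib.save(img, str(path))


def read_volume(path):
    """Read a 3D volume; returns (array, spacing_mm, origin) in RAS+."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"cannot parse volume file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D payload, got shape {data.shape}")
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return data, spacing, origin


def read_mask(path) -> BinaryMask3D:
    data, spacing, origin = read_volume(path)
    return BinaryMask3D(data, spacing, origin)  # validates {0,1}


def write_mask(mask: BinaryMask3D, path) -> None:
    write_volume(mask.voxels.astype(np.uint8), path, mask.spacing_mm,
                 mask.origin)


def assemble_stack(channel_paths: dict[str, str | Path],
                   case_id: str = "") -> MultimodalStack:
    """Load named channel files and verify they share one voxel grid."""
    if not channel_paths:
        raise ValueError("need at least one channel path")
    loaded = {}
    geom = {}
    for name, p in channel_paths.items():
        data, spacing, origin = read_volume(p)
        loaded[name] = data
        geom[name] = (data.shape, spacing, origin)
    ref_name = next(iter(geom))
    ref_shape, ref_sp, ref_or = geom[ref_name]
    bad = []
    for name, (shape, sp, org) in geom.items():
        if (shape != ref_shape
                or not np.allclose(sp, ref_sp, atol=GEOM_ATOL_MM)
                or not np.allclose(org, ref_or, atol=GEOM_ATOL_MM)):
            bad.append(name)
    if bad:
        raise ValueError(
            f"channels not on a common grid (reference '{ref_name}'): {bad}")
    return MultimodalStack(loaded, ref_sp, ref_or, case_id=case_id)


# ---------------------------------------------------------------------------
# Dataset manifests
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.csv"


def write_manifest(rows: list[dict], out_dir) -> Path:
    """rows: one dict per case with case_id, split, and per-file columns."""
    out = Path(out_dir) / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "case_id" not in df.columns or "split" not in df.columns:
        raise ValueError("manifest must have case_id and split columns")
    return df
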