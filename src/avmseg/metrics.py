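"""Geometric evaluation of segmentations.

Overlap metrics come from voxel confusion counts:

    DSC  = 2TP / (2TP + FP + FN)
    Sens = TP / (TP + FN)
    F2   = 5TP / (5TP + 4FP + FN)

Distance metrics are computed between mask *surfaces* (foreground voxels
with at least one six-connected background neighbor, grid edge counting as
background), with voxel-center coordinates in millimetres:

    h(A,B)   = max_{a in A} min_{b in B} ||a - b||     (directed Hausdorff)
    HD(A,B)  = max(h(A,B), h(B,A))
    MSD(A,B) = (h(A,B) + h(B,A)) / 2

Note on MSD: the definition above — the mean of the two *directed Hausdorff
maxima* — is what this evaluation suite reports under that name.  It is not
the conventional average surface distance (the mean of all point-to-surface
distances); that quantity is available separately as
:func:`average_surface_distance` to avoid conflation.

WMT quantifies how differently two competing target contours take up a
white-matter tract: the absolute difference of the tract-voxel proportion
inside each contour.  The normalizer is the contour volume by default
(``normalizer="target"``); dividing by the tract volume instead is exposed
as ``normalizer="tract"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_formats import BinaryMask3D

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SurfaceSet:
    """Physical (mm) coordinates of a mask's boundary voxel centers."""

    points: np.ndarray  # (n, 3) float64

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) == 0:
            raise ValueError("surface set is empty")


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask3D):
        return mask.voxels.astype(bool)
    return np.asarray(mask).astype(bool)


def confusion_counts(a, b) -> ConfusionCounts:
    """Voxel-wise confusion of prediction `a` against ground truth `b`."""
    av, bv = _as_bool(a), _as_bool(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    tp = int(np.count_nonzero(av & bv))
    fp = int(np.count_nonzero(av & ~bv))
    fn = int(np.count_nonzero(~av & bv))
    tn = av.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float, c: ConfusionCounts) -> float:
    if den == 0:
        # both masks empty: perfect (vacuous) agreement by convention
        return 1.0
    return num / den


def dsc(c: ConfusionCounts) -> float:
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, c)


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        return 1.0 if c.fp == 0 else 0.0
    return c.tp / (c.tp + c.fn)


def f2(c: ConfusionCounts) -> float:
    return _ratio(5 * c.tp, 5 * c.tp + 4 * c.fp + c.fn, c)


# ---------------------------------------------------------------------------
# Surface distances
# ---------------------------------------------------------------------------

def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 six-connected background neighbor (the
    grid edge counts as background)."""
    eroded = ndimage.binary_erosion(mask, structure=_SIX_CONN, border_value=0)
    return mask & ~eroded


def surface_points(mask, spacing_mm=(1.0, 1.0, 1.0)) -> SurfaceSet:
    m = _as_bool(mask)
    if isinstance(mask, BinaryMask3D):
        spacing_mm = mask.spacing_mm
    if not m.any():
        raise ValueError("cannot extract the surface of an empty mask")
    idx = np.argwhere(_surface_voxels(m))
    return SurfaceSet(idx * np.asarray(spacing_mm, dtype=np.float64))


def directed_hausdorff(a: SurfaceSet, b: SurfaceSet) -> float:
    """h(A,B) = max over A of the distance to the nearest point of B, mm."""
    d, _ = cKDTree(b.points).query(a.points, k=1)
    return float(d.max())


def hausdorff(a: SurfaceSet, b: SurfaceSet) -> float:
    return max(directed_hausdorff(a, b), directed_hausdorff(b, a))


def mean_surface_distance(a: SurfaceSet, b: SurfaceSet) -> float:
    """Mean of the two directed Hausdorff maxima (see module docstring)."""
    return 0.5 * (directed_hausdorff(a, b) + directed_hausdorff(b, a))


def average_surface_distance(a: SurfaceSet, b: SurfaceSet) -> float:
    """Conventional symmetric average surface distance (all-point mean)."""
    dab, _ = cKDTree(b.points).query(a.points, k=1)
    dba, _ = cKDTree(a.points).query(b.points, k=1)
    return float(np.concatenate([dab, dba]).mean())


# ---------------------------------------------------------------------------
# Tract-protection statistic
# ---------------------------------------------------------------------------

def wmt(a, b, wm, normalizer: str = "target") -> float:
    """Absolute difference of the tract-voxel proportion inside contours
    `a` and `b`.

    normalizer="target": |A∩WM|/|A| vs |B∩WM|/|B| (default).
    normalizer="tract":  |A∩WM|/|WM| vs |B∩WM|/|WM|.
    """
    av, bv, wv = _as_bool(a), _as_bool(b), _as_bool(wm)
    if not (av.shape == bv.shape == wv.shape):
        raise ValueError("mask shapes must match")
    na, nb = av.sum(), bv.sum()
    if na == 0 or nb == 0:
        raise ValueError("WMT is undefined for an empty contour")
    if normalizer == "target":
        pa = (av & wv).sum() / na
        pb = (bv & wv).sum() / nb
    elif normalizer == "tract":
        nw = wv.sum()
        if nw == 0:
            return 0.0
        pa = (av & wv).sum() / nw
        pb = (bv & wv).sum() / nw
    else:
        raise ValueError("normalizer must be 'target' or 'tract'")
    return float(abs(pa - pb))


# ---------------------------------------------------------------------------
# Per-case / per-dataset evaluation
# ---------------------------------------------------------------------------

@dataclass
class CaseMetrics:
    dsc: float
    sensitivity: float
    f2: float
    hd_mm: float
    msd_mm: float
    wmt: float
    empty_prediction: bool = False

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc, "sensitivity": self.sensitivity, "f2": self.f2,
            "hd_mm": self.hd_mm, "msd_mm": self.msd_mm, "wmt": self.wmt,
            "empty_prediction": self.empty_prediction,
        }


def evaluate_case(pred, truth, wm=None,
                  spacing_mm=(1.0, 1.0, 1.0)) -> CaseMetrics:
    """All geometric metrics for one (prediction, ground truth) pair.

    An empty prediction gives overlap metrics of 0 and undefined (NaN)
    distance metrics, flagged via ``empty_prediction``.
    """
    pv, tv = _as_bool(pred), _as_bool(truth)
    if isinstance(pred, BinaryMask3D):
        spacing_mm = pred.spacing_mm
    c = confusion_counts(pv, tv)
    if not pv.any():
        both_empty = not tv.any()
        val = 1.0 if both_empty else 0.0
        return CaseMetrics(val, val, val, np.nan, np.nan, np.nan,
                           empty_prediction=True)
    if not tv.any():
        # a nonempty prediction against an empty truth: zero overlap,
        # distances undefined
        return CaseMetrics(0.0, 0.0, 0.0, np.nan, np.nan, np.nan)
    sa = surface_points(pv, spacing_mm)
    sb = surface_points(tv, spacing_mm)
    hab = directed_hausdorff(sa, sb)
    hba = directed_hausdorff(sb, sa)
    w = wmt(pv, tv, wm) if wm is not None else np.nan
    return CaseMetrics(dsc(c), sensitivity(c), f2(c),
                       max(hab, hba), 0.5 * (hab + hba), w)


def summarize(records: list[CaseMetrics],
              case_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-case table plus a mean ± SD summary row (sample SD, ddof=1)."""
    if case_ids is None:
        case_ids = [f"case_{i:04d}" for i in range(len(records))]
    df = pd.DataFrame([r.as_dict() for r in records])
    df.insert(0, "case_id", case_ids)
    cols = ["dsc", "sensitivity", "f2", "hd_mm", "msd_mm", "wmt"]
    mean = df[cols].mean()
    sd = df[cols].std(ddof=1) if len(df) > 1 else df[cols].std(ddof=0)
    summary = {"case_id": "mean±SD", "empty_prediction": df.empty_prediction.any()}
    summary.update({c: mean[c] for c in cols})
    out = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    out.attrs["sd"] = {c: float(sd[c]) for c in cols}
    return out
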