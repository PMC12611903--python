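"""Synthetic multimodal neurovascular phantoms.

Each phantom case emulates the structures the segmentation pipeline needs to
see: a bright, compact, irregular "nidus" (the radiosurgical target) that is
most conspicuous in the MRA-like channel, diffuse perilesional signal in the
T2-like channel, a mildly hyperdense lesion in the CT-like channel, a curved
tubular white-matter "tract" passing within a few voxels of the nidus, and
optionally a smooth dose peak concentrated on the nidus.

Geometry
--------
The nidus is an ellipsoid whose radius is modulated by a smooth low-order
random function of direction (amplitude = ``nidus_irregularity``); at zero
irregularity its voxel volume is the analytic ellipsoid volume, which keeps
the generator checkable in closed form.  The tract is a tube of radius
``tract_radius_vox`` swept along a quadratic Bezier curve whose closest
approach is aimed just inside ``tract_margin_vox`` of the nidus surface, so
the pair exercises the tract-protection statistic without overlapping.

These phantoms are deliberately simple: they have no vascular tree, no
anatomy outside the lesion, and stationary Gaussian noise.  They are meant
to make the pipeline testable end to end, not to simulate MR/CT physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .dose import DoseGrid
from .io_formats import (BinaryMask3D, MultimodalStack, write_manifest,
                         write_mask, write_volume)


class GeometryError(ValueError):
    """Requested phantom geometry cannot fit in the grid."""


DEFAULT_CONTRASTS = {
    # channel -> (background mean, nidus/foreground mean), arbitrary units
    "ct": (40.0, 55.0),
    "mra": (20.0, 100.0),
    "t2": (30.0, 65.0),
}
DEFAULT_NOISE = {"ct": 3.0, "mra": 5.0, "t2": 4.0}


@dataclass
class PhantomParams:
    """Generator configuration; defaults define the standard study phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nidus_radius_range_vox: tuple[float, float] = (5.0, 9.0)
    nidus_irregularity: float = 0.3
    tract_radius_vox: float = 2.0
    tract_margin_vox: float = 2.0
    channel_contrasts: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRASTS))
    noise_sigma: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE))
    include_tract_channel: bool = True
    dose_prescription_gy: float | None = 20.0
    dose_falloff_sigma_vox: float = 2.0
    seed: int = 0

    def __post_init__(self):
        gs = tuple(int(s) for s in self.grid_shape)
        if any(s < 32 for s in gs):
            raise ValueError("grid_shape entries must be >= 32")
        self.grid_shape = gs
        rmin, rmax = self.nidus_radius_range_vox
        limit = min(gs) / 4
        for r in (rmin, rmax, self.tract_radius_vox):
            if not 0 < r < limit:
                raise ValueError(
                    f"radius {r} must be in (0, min(grid)/4 = {limit})")
        if rmin > rmax:
            raise ValueError("nidus radius range must be (min, max)")
        if not 0 <= self.nidus_irregularity <= 1:
            raise ValueError("nidus_irregularity must be in [0, 1]")
        if self.tract_margin_vox < 0:
            raise ValueError("tract_margin_vox must be >= 0")
        if any(s < 0 for s in self.noise_sigma.values()):
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PhantomCase:
    stack: MultimodalStack
    nidus_mask: BinaryMask3D
    tract_mask: BinaryMask3D
    dose: DoseGrid | None
    params: PhantomParams
    case_id: str
    tract_nidus_gap_vox: float = np.nan


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _orthobasis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _bump_field(rng: np.random.Generator, n_terms: int = 6):
    """Smooth zero-ish-mean function of direction, normalized to [-1, 1]."""
    dirs = np.stack([_random_unit(rng) for _ in range(n_terms)])
    coef = rng.normal(size=n_terms)

    def f(u: np.ndarray) -> np.ndarray:
        # u: (..., 3) unit vectors
        proj = u @ dirs.T                     # (..., n_terms)
        raw = (proj ** 2 - 1.0 / 3.0) @ coef  # degree-2 terms, mean ~ 0
        scale = np.abs(coef).sum() * (2.0 / 3.0)
        return raw / max(scale, 1e-12)
    return f


def _nidus_mask(params: PhantomParams, rng: np.random.Generator):
    """Returns (mask bool array, center, radius_of(u) callable)."""
    gs = np.array(params.grid_shape, dtype=float)
    rmin, rmax = params.nidus_radius_range_vox
    semi = rng.uniform(rmin, rmax, size=3)
    eps = params.nidus_irregularity
    rmax_eff = semi.max() * (1 + eps)
    margin = rmax_eff + params.tract_radius_vox + params.tract_margin_vox + 2.0
    if np.any(2 * margin >= gs):
        raise GeometryError(
            "nidus + tract cannot fit with requested margin: required interior "
            f"clearance {margin:.1f} vox exceeds half the grid {gs / 2}")
    center = rng.uniform(margin, gs - margin)

    bump = _bump_field(rng)

    idx = np.indices(params.grid_shape, dtype=float)
    rel = idx - center.reshape(3, 1, 1, 1)
    dist = np.sqrt((rel ** 2).sum(axis=0))
    with np.errstate(invalid="ignore"):
        u = np.where(dist[None] > 0, rel / np.maximum(dist[None], 1e-12), 0.0)
    # directional radius of the perturbed ellipsoid
    u_flat = np.moveaxis(u, 0, -1)
    r_ell = 1.0 / np.sqrt(((u_flat / semi) ** 2).sum(axis=-1) + 1e-30)
    radius = r_ell * (1.0 + eps * bump(u_flat))
    mask = dist <= radius

    def radius_of(direction: np.ndarray) -> float:
        d = direction / np.linalg.norm(direction)
        r_e = 1.0 / np.sqrt(((d / semi) ** 2).sum())
        return float(r_e * (1.0 + eps * bump(d[None])[0]))

    return mask, center, radius_of


def _tract_mask(params: PhantomParams, rng: np.random.Generator,
                center: np.ndarray, radius_of) -> np.ndarray:
    gs = np.array(params.grid_shape, dtype=float)
    u = _random_unit(rng)
    # aim the continuous closest approach halfway into the allowed margin so
    # the voxelized surface gap stays <= tract_margin_vox
    gap_target = 0.5 * params.tract_margin_vox
    d_center = radius_of(u) + params.tract_radius_vox + gap_target
    p_near = center + u * d_center
    if np.any(p_near < 1) or np.any(p_near > gs - 2):
        raise GeometryError("tract closest-approach point falls outside grid")
    e1, e2 = _orthobasis(u)
    half_len = 0.45 * float(gs.min())
    bow = rng.uniform(0.15, 0.35) * half_len
    ends = [p_near - half_len * e1 + bow * e2,
            p_near + half_len * e1 + bow * e2]
    ctrl = 2.0 * p_near - 0.5 * (ends[0] + ends[1])  # Bezier hits p_near at t=.5
    t = np.linspace(0.0, 1.0, 400)[:, None]
    curve = ((1 - t) ** 2 * ends[0] + 2 * t * (1 - t) * ctrl + t ** 2 * ends[1])

    lo = np.maximum(np.floor(curve.min(axis=0) - params.tract_radius_vox - 1),
                    0).astype(int)
    hi = np.minimum(np.ceil(curve.max(axis=0) + params.tract_radius_vox + 1),
                    gs).astype(int)
    mask = np.zeros(params.grid_shape, dtype=bool)
    if np.any(hi <= lo):
        raise GeometryError("tract lies entirely outside the grid")
    sub = np.indices(tuple(hi - lo)).reshape(3, -1).T + lo
    tree = cKDTree(curve)
    d, _ = tree.query(sub, k=1)
    inside = d <= params.tract_radius_vox
    mask[tuple(sub[inside].T)] = True
    return mask


def surface_gap_vox(a: np.ndarray, b: np.ndarray) -> float:
    """Min voxel-center distance between the surfaces of two binary volumes."""
    from .metrics import _surface_voxels
    sa = np.argwhere(_surface_voxels(a.astype(bool)))
    sb = np.argwhere(_surface_voxels(b.astype(bool)))
    if len(sa) == 0 or len(sb) == 0:
        return float("nan")
    d, _ = cKDTree(sb).query(sa, k=1)
    return float(d.min())


def dose_for_target(target, prescription_gy: float,
                    falloff_sigma_vox: float = 2.0,
                    spacing_mm=(1.0, 1.0, 1.0)) -> DoseGrid:
    """Synthetic conformal 'plan': prescription dose on the 1-voxel-dilated
    target with Gaussian falloff outside, normalized so the peak equals the
    prescription.  A stand-in for beam-level planning, good enough to give
    DVH endpoints nontrivial structure."""
    tv = target.voxels.astype(bool) if isinstance(target, BinaryMask3D) \
        else np.asarray(target).astype(bool)
    if not tv.any():
        raise ValueError("cannot build a dose grid for an empty target")
    dilated = ndimage.binary_dilation(tv, iterations=1)
    g = ndimage.gaussian_filter(dilated.astype(np.float64), falloff_sigma_vox)
    return DoseGrid(prescription_gy * g / g.max(), spacing_mm)


# ---------------------------------------------------------------------------
# Case and dataset generation
# ---------------------------------------------------------------------------

def generate_case(params: PhantomParams, case_id: str = "case_0000") -> PhantomCase:
    """Generate one phantom case; deterministic for a fixed ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    nidus, center, radius_of = _nidus_mask(params, rng)
    tract = _tract_mask(params, rng, center, radius_of)
    tract &= ~nidus  # the tract skirts the nidus; it never overlaps it
    if not tract.any():
        raise GeometryError("tract mask is empty after clipping to the grid")

    soft_nidus = ndimage.gaussian_filter(nidus.astype(np.float32), 0.5)
    halo = ndimage.gaussian_filter(
        ndimage.binary_dilation(nidus, iterations=3).astype(np.float32), 2.0)

    channels: dict[str, np.ndarray] = {}
    for name, (bg, fg) in params.channel_contrasts.items():
        if name == "t2":
            img = bg + (fg - bg) * halo
        elif name == "mra":
            img = bg + (fg - bg) * soft_nidus
        else:
            img = bg + (fg - bg) * soft_nidus * 0.9 + 2.0 * halo
        sigma = params.noise_sigma.get(name, 0.0)
        if sigma > 0:
            img = img + rng.normal(0.0, sigma, size=img.shape)
        channels[name] = img.astype(np.float32)
    if params.include_tract_channel:
        channels["tract"] = tract.astype(np.float32)

    dose = None
    if params.dose_prescription_gy is not None:
        dose = dose_for_target(nidus, params.dose_prescription_gy,
                               params.dose_falloff_sigma_vox,
                               params.spacing_mm)

    stack = MultimodalStack(channels, params.spacing_mm, case_id=case_id)
    return PhantomCase(
        stack=stack,
        nidus_mask=BinaryMask3D(nidus.astype(np.uint8), params.spacing_mm),
        tract_mask=BinaryMask3D(tract.astype(np.uint8), params.spacing_mm),
        dose=dose,
        params=params,
        case_id=case_id,
        tract_nidus_gap_vox=surface_gap_vox(tract, nidus),
    )


def generate_dataset(n_cases: int, split_ratio: float, seed: int,
                     params_template: PhantomParams | None = None
                     ) -> tuple[list[PhantomCase], list[PhantomCase]]:
    """Generate a reproducible train/test phantom dataset.

    The split is round-to-nearest on the training side (n=191, ratio=0.8
    gives the conventional 153:38 partition); per-case seeds are derived
    deterministically from the master seed.
    """
    if not 0 < split_ratio < 1:
        raise ValueError("split_ratio must be in (0, 1)")
    if n_cases < 2:
        raise ValueError("need at least 2 cases for a nonempty split")
    n_train = int(np.floor(n_cases * split_ratio + 0.5))
    n_test = n_cases - n_train
    if n_train < 1 or n_test < 1:
        raise ValueError(
            f"split {n_train}:{n_test} leaves an empty partition")
    template = params_template or PhantomParams()
    seeds = np.random.SeedSequence(seed).generate_state(n_cases) % (2 ** 31)
    cases = [
        generate_case(replace(template, seed=int(s)), case_id=f"case_{i:04d}")
        for i, s in enumerate(seeds)
    ]
    return cases[:n_train], cases[n_train:]


def write_dataset(train: list[PhantomCase], test: list[PhantomCase],
                  out_dir) -> Path:
    """Write every case as NIfTI files plus a CSV manifest; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for split, cases in (("train", train), ("test", test)):
        for case in cases:
            row: dict = {"case_id": case.case_id, "split": split}
            cdir = out / case.case_id
            cdir.mkdir(exist_ok=True)
            sp = case.stack.spacing_mm
            for name, vol in case.stack.channels.items():
                p = cdir / f"{name}.nii.gz"
                write_volume(vol, p, sp)
                row[f"channel_{name}"] = str(p)
            p = cdir / "nidus.nii.gz"
            write_mask(case.nidus_mask, p)
            row["nidus"] = str(p)
            p = cdir / "tract.nii.gz"
            write_mask(case.tract_mask, p)
            row["tract"] = str(p)
            if case.dose is not None:
                p = cdir / "dose.nii.gz"
                write_volume(case.dose.dose, p, sp)
                row["dose"] = str(p)
            rows.append(row)
    return write_manifest(rows, out)
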