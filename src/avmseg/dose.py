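"""Dosimetric-endpoint evaluation: DVH curves, Dq percentile doses, VxGy,
prescription-isodose conformity, and endpoint-series concordance.

Conventions
-----------
* Dq ("dose to q% of the volume") follows the higher-rank sorted-voxel rule
  without interpolation: the largest dose level that at least q% of the
  structure's voxels receive.
* CI = PIV/TV and nCI = (PIV*TV)/TV_PIV**2 (Paddick-style inverse), the
  standard CyberKnife-planning definitions, where PIV is the prescription
  isodose volume, TV the target volume and TV_PIV their intersection.
* VxGy is returned as a fraction in [0, 1]; the CLI reports percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import BinaryMask3D


@dataclass
class DoseGrid:
    """Absorbed dose in Gy per voxel on a known grid."""

    dose: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        d = np.asarray(self.dose, dtype=np.float64)
        if not np.isfinite(d).all():
            raise ValueError("dose grid contains non-finite values")
        if (d < 0).any():
            raise ValueError("dose must be non-negative")
        self.dose = d
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self):
        return self.dose.shape


@dataclass
class DVHEndpoints:
    dmean: float
    dmax: float
    d99: float
    d95: float
    v_at: dict[float, float] = field(default_factory=dict)
    coverage_pct: float | None = None
    ci: float | None = None
    nci: float | None = None
    nci_defined: bool = True


def _mask_doses(dose: DoseGrid, mask: BinaryMask3D) -> np.ndarray:
    if dose.shape != mask.shape:
        raise ValueError(f"dose {dose.shape} vs mask {mask.shape} shape mismatch")
    if mask.is_empty():
        raise ValueError("mask is empty; DVH quantities are undefined")
    return dose.dose[mask.voxels.astype(bool)]


def dvh_curve(dose: DoseGrid, mask: BinaryMask3D,
              n_bins: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative DVH: fraction of the structure receiving >= each level.

    Returns (levels_gy, fractions); levels run from 0 to just above Dmax so
    the curve starts at 1.0 and ends at 0.0.
    """
    d = _mask_doses(dose, mask)
    dmax = float(d.max())
    top = dmax * (1.0 + 1e-6) + 1e-9
    levels = np.linspace(0.0, top, n_bins + 1)
    # fraction receiving >= level; searchsorted on the sorted dose array
    ds = np.sort(d)
    frac = 1.0 - np.searchsorted(ds, levels, side="left") / d.size
    return levels, frac


def v_at_dose(dose: DoseGrid, mask: BinaryMask3D, level: float) -> float:
    """Fraction of structure voxels receiving at least `level` Gy."""
    if level < 0:
        raise ValueError("dose level must be >= 0")
    d = _mask_doses(dose, mask)
    return float(np.mean(d >= level))


def dose_percentile(dose: DoseGrid, mask: BinaryMask3D, q: float) -> float:
    """Dq: the largest dose level received by at least q% of the structure."""
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    d = np.sort(_mask_doses(dose, mask))[::-1]  # descending
    k = int(np.ceil(q / 100.0 * d.size))
    return float(d[k - 1])


def dvh_endpoints(dose: DoseGrid, mask: BinaryMask3D,
                  v_levels: tuple[float, ...] = (1.0,)) -> DVHEndpoints:
    d = _mask_doses(dose, mask)
    return DVHEndpoints(
        dmean=float(d.mean()),
        dmax=float(d.max()),
        d99=dose_percentile(dose, mask, 99),
        d95=dose_percentile(dose, mask, 95),
        v_at={lv: v_at_dose(dose, mask, lv) for lv in v_levels},
    )


def conformity(dose: DoseGrid, target: BinaryMask3D,
               prescription: float) -> tuple[float, float, float | None]:
    """(coverage %, CI, nCI) of the prescription isodose against the target.

    nCI is None (undefined) when the prescription isodose misses the target
    entirely.
    """
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    if target.is_empty():
        raise ValueError("target mask is empty")
    if dose.shape != target.shape:
        raise ValueError("dose/target shape mismatch")
    piv = dose.dose >= prescription
    tv = target.voxels.astype(bool)
    n_piv = int(piv.sum())
    n_tv = int(tv.sum())
    n_both = int((piv & tv).sum())
    coverage = 100.0 * n_both / n_tv
    ci = n_piv / n_tv
    nci = (n_piv * n_tv) / n_both ** 2 if n_both > 0 else None
    return coverage, ci, nci


def r_squared(x, y) -> float:
    """Coefficient of determination of the OLS fit of y on x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D series")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; regression undefined")
    if np.ptp(y) == 0:
        return 0.0  # a constant response carries no explainable variance
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2)
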