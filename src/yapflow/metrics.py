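"""Image-quantification statistics on arrays and masks.

These are the measurement formulas used on the microscopy data, applied
here to synthetic stacks: the YAP nuclear/cytoplasmic intensity ratio
(mean intensities after mean-projection), chromatin compaction as the
coefficient of variation of the DAPI signal inside the nucleus mask,
actin-cap total intensity as the mean of a maximum-intensity projection
over the apical planes above the nucleus within the nuclear footprint,
and ordinary least-squares regression of per-cell YR on cap intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import CellPopulationSample, SyntheticImageStack

__all__ = [
    "IntensityStats",
    "yr_from_intensities",
    "normalize_to_control",
    "chromatin_cv",
    "cap_total_intensity",
    "regress_population",
    "RegressionResult",
]


@dataclass(frozen=True)
class IntensityStats:
    mean: float
    std: float
    cv: float
    n_voxels: int


def yr_from_intensities(nuc_mean: float, cyto_mean: float) -> float:
    """YR = mean nuclear intensity / mean cytoplasmic intensity."""
    if cyto_mean <= 0:
        raise ValueError("cytoplasmic mean intensity must be positive")
    return nuc_mean / cyto_mean


def normalize_to_control(values, control_mean: float):
    """values / control_mean (static-control normalization)."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return np.asarray(values, dtype=float) / control_mean


def chromatin_cv(voxels, mask) -> IntensityStats:
    """Coefficient of variation σ/µ of in-mask intensities (population σ)."""
    voxels = np.asarray(voxels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if voxels.shape != mask.shape:
        raise ValueError("voxels and mask must share a shape")
    vals = voxels[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError("mean intensity must be positive")
    std = float(vals.std(ddof=0))
    return IntensityStats(mean=mean, std=std, cv=std / mean, n_voxels=int(vals.size))


def cap_total_intensity(stack: SyntheticImageStack | np.ndarray,
                        nucleus_mask=None,
                        apical_range: tuple[int, int] | None = None) -> float:
    """Cap intensity: apical max-projection, mean inside the nuclear footprint.

    ``apical_range`` is a half-open (start, stop) z interval that must lie
    strictly above the top nucleus slice.
    """
    if isinstance(stack, SyntheticImageStack):
        voxels = stack.voxels
        nucleus_mask = stack.nucleus_mask if nucleus_mask is None else nucleus_mask
        apical_range = stack.apical_range if apical_range is None else apical_range
    else:
        voxels = np.asarray(stack, dtype=float)
    mask = np.asarray(nucleus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    lo, hi = apical_range
    top = int(np.max(np.nonzero(mask.any(axis=(1, 2)))[0]))
    if lo <= top:
        raise ValueError("apical range overlaps the nucleus slices")
    if hi <= lo or hi > voxels.shape[0]:
        raise ValueError("invalid apical range")
    projection = voxels[lo:hi].max(axis=0)
    footprint = mask.any(axis=0)
    return float(projection[footprint].mean())


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def regress_population(sample: CellPopulationSample) -> RegressionResult:
    """OLS of per-cell YR on cap intensity with a two-sided slope test."""
    if sample.n < 3:
        raise ValueError("need at least three cells")
    x = np.asarray(sample.cap_intensity, dtype=float)
    y = np.asarray(sample.yr, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("cap intensity has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r=float(res.rvalue), p=float(res.pvalue), n=sample.n)
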