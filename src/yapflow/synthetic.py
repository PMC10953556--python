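"""Synthetic inputs for the flow-mechanotransduction analysis.

Everything the downstream modules consume can be generated here with the
statistical structure the experiments exhibit:

* shear-stress waveforms — steady (unidirectional, USS) or sinusoidal
  (oscillatory, OSS, zero mean), with the optional time-compression device
  used for oscillatory runs (a 86 400 s schedule compressed 10^4-fold onto
  8.64 s);
* actin-cap volume-fraction and nuclear-stiffness time courses of the
  saturating-exponential family — strong cap growth and ~+30% stiffening
  under USS, slight cap growth and ~-10% softening under OSS;
* single-cell populations with a negative YAP-ratio vs cap-intensity
  relationship;
* DAPI-like nucleus image stacks with controllable chromatin heterogeneity
  (speckle amplitude), for exercising the image metrics.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FlowWaveform",
    "TimeCourse",
    "CellPopulationSample",
    "SyntheticImageStack",
    "make_flow_waveform",
    "make_cap_timecourse",
    "make_stiffness_timecourse",
    "make_cell_population",
    "make_nucleus_stack",
    "CAP_PRESETS",
    "STIFFNESS_PRESETS",
]

#: Preset (plateau, time constant s) for the actin-cap volume-fraction course.
#: Free calibration constants standing in for the immunofluorescence fits.
CAP_PRESETS: dict[str, dict[str, float]] = {
    "USS12": {"plateau": 0.30, "time_constant": 14400.0},
    "USS4": {"plateau": 0.18, "time_constant": 28800.0},
    "OSS": {"plateau": 0.08, "time_constant": 14400.0},
}

#: Preset (baseline kPa, plateau kPa, time constant s) for nuclear stiffness:
#: USS stiffens +30% over baseline, OSS softens -10%.
STIFFNESS_PRESETS: dict[str, dict[str, float]] = {
    "USS12": {"baseline": 1.0, "plateau": 1.30, "time_constant": 14400.0},
    "USS4": {"baseline": 1.0, "plateau": 1.20, "time_constant": 28800.0},
    "OSS": {"baseline": 1.0, "plateau": 0.90, "time_constant": 14400.0},
}


@dataclass
class FlowWaveform:
    """Sampled wall shear stress τ(t) in dyn cm^-2.

    ``compression`` >= 1 condenses a slow schedule: the sampled schedule
    spans ``duration / compression`` seconds and one schedule second stands
    for ``compression`` seconds of the modelled process.  The oscillation
    frequency applies on the (condensed) schedule clock.
    """

    kind: str
    magnitude: float
    duration: float
    dt: float
    frequency: float | None = None
    compression: float = 1.0
    times: np.ndarray = field(default=None, repr=False)
    tau: np.ndarray = field(default=None, repr=False)

    @property
    def schedule_duration(self) -> float:
        return self.duration / self.compression

    def tau_at(self, t: float) -> float:
        """Shear stress at schedule time t (s)."""
        if self.kind == "steady":
            return self.magnitude
        return self.magnitude * np.sin(2.0 * np.pi * self.frequency * t)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "tau_dyn_cm2": self.tau}).to_csv(
            path, index=False
        )


def make_flow_waveform(
    kind: str,
    magnitude: float,
    duration: float,
    dt: float,
    frequency: float | None = None,
    compression: float = 1.0,
) -> FlowWaveform:
    """Build a sampled shear-stress waveform.

    ``kind`` is ``"steady"`` (τ constant) or ``"oscillatory"``
    (τ = magnitude·sin(2π·frequency·t), zero mean over whole periods);
    ``frequency`` is required for oscillatory waveforms.
    """
    if kind not in ("steady", "oscillatory"):
        raise ValueError(f"unknown waveform kind {kind!r}")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if compression < 1:
        raise ValueError("compression must be >= 1")
    if kind == "oscillatory" and (frequency is None or frequency <= 0):
        raise ValueError("oscillatory waveform requires a positive frequency")
    wf = FlowWaveform(
        kind=kind, magnitude=magnitude, duration=duration, dt=dt,
        frequency=frequency, compression=compression,
    )
    n = int(round(wf.schedule_duration / dt))
    wf.times = np.arange(n + 1) * dt
    wf.tau = np.array([wf.tau_at(t) for t in wf.times])
    return wf


@dataclass
class TimeCourse:
    """A prescribed model input v(t): cap volume fraction or E_nuc (kPa).

    ``params`` records the generating (baseline, plateau, time_constant).
    """

    times: np.ndarray
    values: np.ndarray
    condition: str = "custom"
    kind: str = "generic"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def at(self, t) -> float:
        """Linear interpolation, clamped at the ends."""
        return float(np.interp(t, self.times, self.values))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, condition="custom", kind="generic") -> "TimeCourse":
        df = pd.read_csv(path)
        return cls(times=df["time_s"].to_numpy(), values=df["value"].to_numpy(),
                   condition=condition, kind=kind)


def _sample_times(duration: float, n_points: int) -> np.ndarray:
    return np.linspace(0.0, duration, n_points)


def make_cap_timecourse(
    condition: str = "USS12",
    plateau: float | None = None,
    time_constant: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration: float = 86400.0,
    n_points: int = 200,
) -> TimeCourse:
    """Actin-cap volume fraction ρ_cap(t) = plateau·(1 − exp(−t/τc)).

    Presets: USS12 saturates at a high plateau; OSS grows only slightly.
    Optional additive Gaussian noise is clipped back into [0, 1].
    """
    preset = CAP_PRESETS.get(condition, {})
    plateau = preset.get("plateau", 0.2) if plateau is None else plateau
    time_constant = (
        preset.get("time_constant", 14400.0) if time_constant is None else time_constant
    )
    if not 0.0 <= plateau <= 1.0:
        raise ValueError("plateau must lie in [0, 1]")
    if time_constant <= 0:
        raise ValueError("time_constant must be positive")
    t = _sample_times(duration, n_points)
    v = plateau * (1.0 - np.exp(-t / time_constant))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    v = np.clip(v, 0.0, 1.0)
    return TimeCourse(
        times=t, values=v, condition=condition, kind="cap_volume_fraction",
        params={"baseline": 0.0, "plateau": plateau, "time_constant": time_constant},
    )


def make_stiffness_timecourse(
    condition: str = "USS12",
    baseline: float | None = None,
    plateau: float | None = None,
    time_constant: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration: float = 86400.0,
    n_points: int = 200,
) -> TimeCourse:
    """Nuclear Young's modulus E_nuc(t) relaxing from baseline to plateau.

    USS presets stiffen (plateau > baseline), the OSS preset softens.
    """
    preset = STIFFNESS_PRESETS.get(condition, {})
    baseline = preset.get("baseline", 1.0) if baseline is None else baseline
    plateau = preset.get("plateau", 1.0) if plateau is None else plateau
    time_constant = (
        preset.get("time_constant", 14400.0) if time_constant is None else time_constant
    )
    if baseline <= 0 or plateau <= 0:
        raise ValueError("moduli must be positive")
    if time_constant <= 0:
        raise ValueError("time_constant must be positive")
    t = _sample_times(duration, n_points)
    v = plateau + (baseline - plateau) * np.exp(-t / time_constant)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    v = np.maximum(v, 1e-9)
    return TimeCourse(
        times=t, values=v, condition=condition, kind="nuclear_stiffness_kPa",
        params={"baseline": baseline, "plateau": plateau,
                "time_constant": time_constant},
    )


@dataclass
class CellPopulationSample:
    """Per-cell actin-cap intensity (a.u.) and YAP nuclear/cytoplasmic ratio."""

    n: int
    cap_intensity: np.ndarray
    yr: np.ndarray
    condition: str = "USS12"
    seed: int = 0

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "cell_id": np.arange(self.n),
            "cap_intensity": self.cap_intensity,
            "yr": self.yr,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition="custom") -> "CellPopulationSample":
        df = pd.read_csv(path)
        return cls(n=len(df), cap_intensity=df["cap_intensity"].to_numpy(),
                   yr=df["yr"].to_numpy(), condition=condition)


def make_cell_population(
    n: int = 80,
    intercept: float = 1.2,
    slope: float = -0.35,
    noise_sd: float = 0.08,
    seed: int = 0,
    condition: str = "USS12",
) -> CellPopulationSample:
    """Cells on a line yr = intercept + slope·cap + noise.

    Cap intensity is uniform on [0, 2] a.u.; the default preset has a
    negative slope (cells with stronger caps show a lower YAP ratio).
    YR values are floored at a small positive number.
    """
    if n < 2:
        raise ValueError("need at least two cells")
    rng = np.random.default_rng(seed)
    cap = rng.uniform(0.0, 2.0, size=n)
    yr = intercept + slope * cap
    if noise_sd > 0:
        yr = yr + rng.normal(0.0, noise_sd, size=n)
    yr = np.maximum(yr, 1e-6)
    return CellPopulationSample(n=n, cap_intensity=cap, yr=yr,
                                condition=condition, seed=seed)


@dataclass
class SyntheticImageStack:
    """A DAPI-like nucleus stack plus mask (synthetic stand-in for confocal data).

    ``apical_range`` is the (start, stop) z-index interval just above the
    nucleus, where an actin-cap signal would be measured.
    """

    voxels: np.ndarray
    nucleus_mask: np.ndarray
    z_spacing: float
    apical_range: tuple[int, int]
    compaction: float = 0.0
    voxel_size: float = 0.5

    def to_tiff(self, path, mask_path=None) -> None:
        tifffile.imwrite(path, self.voxels.astype(np.float32))
        if mask_path is not None:
            tifffile.imwrite(mask_path, self.nucleus_mask.astype(np.uint8))


def make_nucleus_stack(
    semi_axes: tuple[float, float, float] = (8.0, 6.0, 5.0),
    compaction: float = 0.0,
    seed: int = 0,
    voxel_size: float = 0.5,
    apical_planes: int = 4,
    cap_intensity: float = 0.0,
    base_intensity: float = 100.0,
) -> SyntheticImageStack:
    """Ellipsoidal nucleus with compaction-controlled intensity speckle.

    ``semi_axes`` = (x, y, z) semi-axes in µm.  In-mask intensity is
    base·(1 + compaction·N(0,1)) clipped at zero, so the chromatin CV grows
    with ``compaction`` (CV = 0 exactly at compaction 0).  ``apical_planes``
    slices above the nucleus carry a uniform ``cap_intensity``.
    """
    ax, ay, az = (float(a) for a in semi_axes)
    if min(ax, ay, az) <= 0:
        raise ValueError("semi-axes must be positive")
    if compaction < 0:
        raise ValueError("compaction must be >= 0")
    rng = np.random.default_rng(seed)
    nx = int(np.ceil(ax / voxel_size)) + 2
    ny = int(np.ceil(ay / voxel_size)) + 2
    nz = int(np.ceil(az / voxel_size)) + 2
    z = (np.arange(-nz, nz + 1) + 0.5)[:, None, None] * voxel_size
    y = (np.arange(-ny, ny + 1) + 0.5)[None, :, None] * voxel_size
    x = (np.arange(-nx, nx + 1) + 0.5)[None, None, :] * voxel_size
    mask = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 <= 1.0
    # pad z above the nucleus for the apical planes
    pad = np.zeros((apical_planes,) + mask.shape[1:], dtype=bool)
    mask = np.concatenate([mask, pad], axis=0)
    voxels = np.zeros(mask.shape, dtype=float)
    n_in = int(mask.sum())
    intensities = base_intensity * (1.0 + compaction * rng.standard_normal(n_in))
    voxels[mask] = np.maximum(intensities, 0.0)
    top = int(np.max(np.nonzero(mask.any(axis=(1, 2)))[0]))
    apical = (top + 1, top + 1 + apical_planes)
    if cap_intensity:
        voxels[apical[0]:apical[1]] = cap_intensity
    return SyntheticImageStack(
        voxels=voxels, nucleus_mask=mask, z_spacing=voxel_size,
        apical_range=apical, compaction=compaction, voxel_size=voxel_size,
    )
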