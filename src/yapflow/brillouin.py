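"""Brillouin-shift to elastic-modulus conversion and time-course fitting.

Brillouin microscopy measures the frequency shift :math:`\\nu_B` of light
inelastically scattered by spontaneous acoustic phonons.  The shift relates
quadratically to the high-frequency longitudinal modulus

.. math:: M' = \\frac{\\rho_{nuc}\\,\\lambda^2\\,\\nu_B^2}{4 n^2}

with nucleus mass density ``rho_nuc``, incident wavelength ``wavelength`` and
refractive index ``refractive_index``.  The quasi-static Young's modulus *E*
is then obtained from the empirical log-log relation

.. math:: \\log_{10} M' = a_B \\log_{10} E + b_B

The log base and units are a convention of this package (base 10, *E* in kPa,
*M'* in Pa): nucleus-scale shifts of 4-8 GHz map to GPa-range longitudinal
moduli and kPa-range Young's moduli, the physiological regime.

This module also fits the saturating-exponential time-course family

.. math:: v(t) = p + (b - p)\\,e^{-t/\\tau_c}

used to turn measured nuclear-stiffness (and actin-cap) series into the
prescribed model inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BrillouinParams",
    "ShiftSeries",
    "TimeCourseFit",
    "shift_to_longitudinal",
    "longitudinal_to_young",
    "young_to_longitudinal",
    "fit_loglog",
    "fit_timecourse",
    "saturating_exponential",
    "convert_series",
]

GHZ = 1.0e9


@dataclass(frozen=True)
class BrillouinParams:
    """Physical constants and calibration coefficients of the conversion.

    Defaults: nucleus density 1350 kg m^-3, 532 nm incident light,
    nuclear refractive index 1.38, and log-log coefficients
    a_B = 0.081, b_B = 9.37 (E in kPa, M' in Pa, base-10 logs).
    """

    rho_nuc: float = 1350.0
    wavelength: float = 532e-9
    refractive_index: float = 1.38
    a_B: float = 0.081
    b_B: float = 9.37
    log_base: float = 10.0

    def __post_init__(self) -> None:
        for name in ("rho_nuc", "wavelength", "refractive_index", "log_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ShiftSeries:
    """A time series of nuclear Brillouin shifts (GHz).

    Each shift is conventionally the mean over several positions sampled
    uniformly inside one nucleus.
    """

    times: np.ndarray
    nu_B: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.nu_B = np.asarray(self.nu_B, dtype=float)
        if self.times.shape != self.nu_B.shape:
            raise ValueError("times and nu_B must have the same shape")
        if np.any(self.nu_B <= 0):
            raise ValueError("Brillouin shifts must be positive")

    @classmethod
    def from_csv(cls, path) -> "ShiftSeries":
        df = pd.read_csv(path)
        return cls(times=df["time_s"].to_numpy(), nu_B=df["nu_B_GHz"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "nu_B_GHz": self.nu_B}).to_csv(
            path, index=False
        )


def shift_to_longitudinal(nu_B_GHz, params: BrillouinParams | None = None):
    """Longitudinal modulus M' (Pa) from a Brillouin shift in GHz."""
    params = params or BrillouinParams()
    nu = np.asarray(nu_B_GHz, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("Brillouin shift must be positive")
    nu_hz = nu * GHZ
    m = params.rho_nuc * params.wavelength**2 * nu_hz**2 / (
        4.0 * params.refractive_index**2
    )
    return m if m.ndim else float(m)


def longitudinal_to_young(M_prime_Pa, params: BrillouinParams | None = None):
    """Young's modulus E (kPa) from the longitudinal modulus (Pa)."""
    params = params or BrillouinParams()
    m = np.asarray(M_prime_Pa, dtype=float)
    if np.any(m <= 0):
        raise ValueError("longitudinal modulus must be positive")
    log = np.log(m) / math.log(params.log_base)
    e = params.log_base ** ((log - params.b_B) / params.a_B)
    return e if e.ndim else float(e)


def young_to_longitudinal(E_kPa, params: BrillouinParams | None = None):
    """Inverse of :func:`longitudinal_to_young` (E in kPa -> M' in Pa)."""
    params = params or BrillouinParams()
    e = np.asarray(E_kPa, dtype=float)
    if np.any(e <= 0):
        raise ValueError("Young's modulus must be positive")
    log_e = np.log(e) / math.log(params.log_base)
    m = params.log_base ** (params.a_B * log_e + params.b_B)
    return m if m.ndim else float(m)


def fit_loglog(E_kPa, M_prime_Pa, log_base: float = 10.0) -> tuple[float, float]:
    """Ordinary least squares of log M' on log E.

    Returns the estimated (a_B, b_B).  Requires at least two strictly
    positive pairs with non-degenerate E values.
    """
    e = np.asarray(E_kPa, dtype=float)
    m = np.asarray(M_prime_Pa, dtype=float)
    if e.size < 2 or m.size != e.size:
        raise ValueError("need at least two (E, M') pairs")
    if np.any(e <= 0) or np.any(m <= 0):
        raise ValueError("moduli must be positive")
    x = np.log(e) / math.log(log_base)
    y = np.log(m) / math.log(log_base)
    if np.ptp(x) == 0:
        raise ValueError("E values are degenerate; slope unidentifiable")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def saturating_exponential(t, baseline, plateau, time_constant):
    """v(t) = plateau + (baseline - plateau) * exp(-t / time_constant)."""
    t = np.asarray(t, dtype=float)
    return plateau + (baseline - plateau) * np.exp(-t / time_constant)


@dataclass
class TimeCourseFit:
    baseline: float
    plateau: float
    time_constant: float
    residual: float
    identifiable: bool = True
    covariance: np.ndarray | None = field(default=None, repr=False)


def fit_timecourse(times, values) -> TimeCourseFit:
    """Nonlinear least-squares fit of the saturating-exponential family.

    A constant series is degenerate: the fit returns plateau == baseline and
    flags the time constant as unidentifiable instead of failing.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    span = float(np.ptp(v))
    if span == 0.0 or span < 1e-12 * max(1.0, abs(float(np.mean(v)))):
        mean = float(np.mean(v))
        return TimeCourseFit(mean, mean, float("nan"), 0.0, identifiable=False)
    p0 = (float(v[0]), float(v[-1]), max(float(t[-1]) / 3.0, 1e-9))
    popt, pcov = curve_fit(
        saturating_exponential, t, v, p0=p0, maxfev=20000,
        bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
    )
    resid = float(np.sqrt(np.mean((saturating_exponential(t, *popt) - v) ** 2)))
    return TimeCourseFit(
        baseline=float(popt[0]), plateau=float(popt[1]),
        time_constant=float(popt[2]), residual=resid, covariance=pcov,
    )


def convert_series(series: ShiftSeries, params: BrillouinParams | None = None) -> pd.DataFrame:
    """Convert a shift series to (time_s, M_prime_Pa, E_kPa)."""
    params = params or BrillouinParams()
    m = shift_to_longitudinal(series.nu_B, params)
    e = longitudinal_to_young(m, params)
    return pd.DataFrame({"time_s": series.times, "M_prime_Pa": m, "E_kPa": e})
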