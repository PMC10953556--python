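"""Fiber stresses and the reduced-order nuclear force balance.

Cytoskeletal stress combines a passive elastic part and a myosin-driven
active part, σ = K_F·ε + σ_M, for both conventional (basal) fibers and the
perinuclear actin cap.  The full 3D finite-element force balance is
replaced by a lumped nuclear-shell balance with explicit monotonicity
guarantees that encode the mechanistic claims:

* a shielding weight w(ρ_cap) = ρ_cap/(ρ_cap + w_half) ∈ [0, 1), increasing
  in the cap volume fraction, splits the fiber load — the cap concentrates
  stress onto its LINC footprint (σ_LINC grows with ρ_cap) while shielding
  the rest of the nuclear membrane from the dispersed conventional-fiber
  pull (σ_NM decreases with ρ_cap);
* the nuclear-membrane equivalent strain divides the membrane stress by the
  nuclear modulus plus a cap-stiffness term,
  ε_NM = σ_NM/(E_nuc + k_shield·ρ_cap·K_F,cap), so both nuclear stiffening
  and a stiffer cap suppress deformation.

An optional direct apical flow loading σ_flow lets wall shear stress reach
the membrane through the cell body (attenuated by the same shielding
weight); it carries the oscillation of an oscillatory waveform into ε_NM.
Transmission is weaker for reversed flow (the cell profile is polarized
with the flow), so the strain oscillates at the waveform fundamental.

A coarse axisymmetric Laplace solve provides the conventional-fiber
direction field (diffusion potential of F-actin from the basal surface
toward the nuclear membrane) and its alignment order parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "CellGeometry",
    "MechanicsParams",
    "MechanicsState",
    "FiberState",
    "fiber_stress",
    "cf_volume_fraction_target",
    "step_cf_volume_fraction",
    "cf_volume_fraction_analytic",
    "fiber_orientation_field",
    "OrientationField",
    "anisotropy_coefficient",
    "shielding_weight",
    "nuclear_stress_balance",
    "basal_traction",
    "geometric_projection_factor",
]


@dataclass(frozen=True)
class CellGeometry:
    """Cell and nucleus geometry (µm).

    The cytoplasm height profile is Gaussian, h(r) = A·exp(-r²/2w²); the
    nucleus is an ellipsoid (in-plane semi-axes, total height) sitting just
    above the basal plane.
    """

    gaussian_amplitude: float = 5.0
    gaussian_width: float = 12.0
    nucleus_semi_major: float = 7.0
    nucleus_semi_minor: float = 5.0
    nucleus_height: float = 3.0
    basal_gap: float = 0.3

    def __post_init__(self) -> None:
        for name in ("gaussian_amplitude", "gaussian_width",
                     "nucleus_semi_major", "nucleus_semi_minor",
                     "nucleus_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        top = self.basal_gap + self.nucleus_height
        if top >= self.height_at(0.0):
            raise ValueError("nucleus does not fit inside the cell profile")
        if self.height_at(self.nucleus_semi_major) <= self.basal_gap + self.nucleus_height / 2:
            raise ValueError("nucleus does not fit inside the cell profile")

    def height_at(self, r: float) -> float:
        return self.gaussian_amplitude * math.exp(
            -(r * r) / (2.0 * self.gaussian_width**2)
        )


def geometric_projection_factor(geometry: CellGeometry) -> float:
    """Lumped projection of fiber stress onto the nuclear membrane.

    Ratio of the nucleus equatorial cross-section to its surface area
    (Thomsen approximation), a dimensionless O(0.1) factor standing in for
    the membrane-area-weighted projection of the finite-element model.
    """
    a = geometry.nucleus_semi_major
    b = geometry.nucleus_semi_minor
    c = geometry.nucleus_height / 2.0
    p = 1.6075
    surface = 4.0 * math.pi * (
        ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    ) ** (1.0 / p)
    return math.pi * a * b / surface


@dataclass(frozen=True)
class MechanicsParams:
    """Stiffnesses (kPa), stress coefficients, and lumped-balance closures.

    All invented closure constants of the reduced-order balance
    (w_half, linc_area_fraction, k_shield, chi_strain, c_flow) live here.
    """

    K_F_cf: float = 10.0          # passive conventional-fiber stiffness, kPa
    K_F_cap: float = 20.0         # passive actin-cap stiffness, kPa
    k_sigma_myo: float = 2.0      # contractile stress per µM active myosin, kPa/µM
    cap_prestress: float = 1.5    # cap contractile prestress, kPa
    k_myo_cap: float = 0.5        # cap stress sensitivity to active myosin, kPa/µM
    w_half: float = 0.3           # cap fraction at half shielding
    linc_area_fraction: float = 0.1
    k_shield: float = 0.1         # cap-stiffness contribution to strain denominator
    c1: float = 0.3               # ρ_cf target per µM F-actin
    rho_max: float = 0.4
    tau_rho: float = 3000.0       # ρ_cf relaxation time, s
    chi_strain: float = 0.3       # fiber strain per unit nuclear-membrane strain
    k_traction: float = 2.0       # basal traction per unit ρ_cf·σ_cf
    c_flow: float = 0.008         # direct flow loading, kPa per dyn cm^-2
    flow_reverse_efficiency: float = 0.3
    p_max: float = 0.6            # asymptotic fiber polarization under flow
    tau_align: float = 14400.0    # polarization time constant, s

    def __post_init__(self) -> None:
        if self.K_F_cf <= 0 or self.K_F_cap <= 0:
            raise ValueError("fiber stiffnesses must be positive")
        if not 0 <= self.flow_reverse_efficiency <= 1:
            raise ValueError("flow_reverse_efficiency must lie in [0, 1]")


@dataclass
class FiberState:
    """Volume fractions, stiffnesses and stresses of both fiber families."""

    rho_cf: float = 0.0
    rho_cap: float = 0.0
    K_F_cf: float = 10.0
    K_F_cap: float = 20.0
    sigma_M_cf: float = 0.0
    sigma_M_cap: float = 0.0
    epsilon_cf: float = 0.0
    orientation_order: float = 0.0


@dataclass
class MechanicsState:
    """Stress read-outs of one quasi-static balance evaluation (kPa)."""

    sigma_cf: float
    sigma_cap: float
    sigma_NM_mean: float
    sigma_LINC: float
    epsilon_NM_eq: float
    traction: float
    E_nuc: float


def fiber_stress(epsilon: float, myosin_active: float, K_F: float,
                 params: MechanicsParams) -> float:
    """σ = K_F·ε + σ_M with σ_M linear in activated myosin (kPa)."""
    if K_F <= 0:
        raise ValueError("fiber stiffness must be positive")
    if myosin_active < 0:
        raise ValueError("active myosin must be non-negative")
    return K_F * epsilon + params.k_sigma_myo * myosin_active


def cf_volume_fraction_target(C_F_actin: float, params: MechanicsParams) -> float:
    """First-order map: target ρ_cf = clip(c1·[F-actin], 0, ρ_max)."""
    if C_F_actin < 0:
        raise ValueError("F-actin concentration must be non-negative")
    return float(np.clip(params.c1 * C_F_actin, 0.0, params.rho_max))


def step_cf_volume_fraction(current_rho: float, C_F_actin: float, dt: float,
                            params: MechanicsParams) -> float:
    """Relax ρ_cf toward its F-actin-set target with time constant τ_ρ.

    Uses the exact exponential update, so arbitrary dt is stable and the
    closed-form solution is reproduced to round-off.
    """
    target = cf_volume_fraction_target(C_F_actin, params)
    decay = math.exp(-dt / params.tau_rho)
    return target + (current_rho - target) * decay


def cf_volume_fraction_analytic(rho0: float, target: float, t: float,
                                params: MechanicsParams) -> float:
    """Closed form ρ(t) = target + (ρ0 − target)·exp(−t/τ_ρ)."""
    return target + (rho0 - target) * math.exp(-t / params.tau_rho)


def anisotropy_coefficient(sigma_parallel: float, sigma_perpendicular: float) -> float:
    """Stress anisotropy: σ_parallel-to-flow / σ_perpendicular-to-flow."""
    if sigma_perpendicular <= 0:
        raise ValueError("perpendicular stress must be positive")
    return sigma_parallel / sigma_perpendicular


def shielding_weight(rho_cap: float, params: MechanicsParams) -> float:
    """w(ρ_cap) = ρ_cap/(ρ_cap + w_half) ∈ [0, 1), increasing."""
    if rho_cap < 0:
        raise ValueError("cap volume fraction must be non-negative")
    return rho_cap / (rho_cap + params.w_half)


def nuclear_stress_balance(
    sigma_cf: float,
    rho_cf: float,
    sigma_cap: float,
    rho_cap: float,
    K_F_cap: float,
    E_nuc: float,
    params: MechanicsParams,
    geometry: CellGeometry | None = None,
    sigma_flow: float = 0.0,
) -> MechanicsState:
    """Reduced-order nuclear-shell balance.

    σ_LINC  = w·σ_cap·ρ_cap / linc_area_fraction
    σ_NM    = (1−w)·(g_geom·ρ_cf·σ_cf + σ_flow)
    ε_NM,eq = σ_NM / (E_nuc + k_shield·ρ_cap·K_F,cap)

    Guaranteed partial-derivative signs: ∂σ_LINC/∂ρ_cap ≥ 0,
    ∂σ_NM/∂ρ_cap ≤ 0, ∂ε_NM/∂E_nuc < 0, ∂ε_NM/∂K_F,cap ≤ 0.
    """
    if E_nuc <= 0:
        raise ValueError("nuclear modulus must be positive")
    for name, v in (("sigma_cf", sigma_cf), ("rho_cf", rho_cf),
                    ("sigma_cap", sigma_cap), ("rho_cap", rho_cap),
                    ("K_F_cap", K_F_cap), ("sigma_flow", sigma_flow)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    g = geometric_projection_factor(geometry or CellGeometry())
    w = shielding_weight(rho_cap, params)
    sigma_linc = w * sigma_cap * rho_cap / params.linc_area_fraction
    sigma_nm = (1.0 - w) * (g * rho_cf * sigma_cf + sigma_flow)
    eps = sigma_nm / (E_nuc + params.k_shield * rho_cap * K_F_cap)
    return MechanicsState(
        sigma_cf=sigma_cf, sigma_cap=sigma_cap, sigma_NM_mean=sigma_nm,
        sigma_LINC=sigma_linc, epsilon_NM_eq=eps,
        traction=basal_traction(sigma_cf, rho_cf, params), E_nuc=E_nuc,
    )


def basal_traction(sigma_cf: float, rho_cf: float,
                   params: MechanicsParams) -> float:
    """Basal traction stress carried at focal adhesions: k_t·ρ_cf·σ_cf (kPa)."""
    if sigma_cf < 0 or rho_cf < 0:
        raise ValueError("inputs must be non-negative")
    return params.k_traction * rho_cf * sigma_cf


def direct_flow_stress(tau: float, params: MechanicsParams) -> float:
    """Apical flow loading transmitted toward the nucleus (kPa).

    Direction-asymmetric: reversed flow (τ < 0) transmits with reduced
    efficiency because the cell profile is polarized with the flow.
    """
    if tau >= 0:
        return params.c_flow * tau
    return params.c_flow * params.flow_reverse_efficiency * (-tau)


# ---------------------------------------------------------------------------
# fiber orientation: axisymmetric diffusion potential


@dataclass
class OrientationField:
    """Direction field of conventional fibers on an axisymmetric (r, z) grid."""

    r: np.ndarray
    z: np.ndarray
    potential: np.ndarray       # masked: NaN outside the cytoplasmic domain
    direction: np.ndarray       # (nz, nr, 2) unit vectors (dr, dz), NaN outside
    orientation_order: float
    domain: np.ndarray          # boolean cytoplasm mask


def _domain_masks(geometry: CellGeometry, nr: int, nz: int):
    r_max = 3.0 * geometry.gaussian_width
    z_max = geometry.gaussian_amplitude
    r = np.linspace(0.0, r_max, nr)
    z = np.linspace(0.0, z_max, nz)
    rr, zz = np.meshgrid(r, z)
    height = geometry.gaussian_amplitude * np.exp(-(rr**2) / (2 * geometry.gaussian_width**2))
    cell = zz <= height
    zc = geometry.basal_gap + geometry.nucleus_height / 2.0
    nucleus = ((rr / geometry.nucleus_semi_major) ** 2
               + ((zz - zc) / (geometry.nucleus_height / 2.0)) ** 2) <= 1.0
    return r, z, cell, nucleus


def fiber_orientation_field(geometry: CellGeometry,
                            grid_resolution: int = 64) -> OrientationField:
    """Solve the axisymmetric diffusion potential of F-actin.

    Laplace's equation in cylindrical coordinates on the cytoplasmic domain,
    with the basal surface (z = 0) as source (φ = 1) and the nuclear
    membrane as sink (φ = 0); zero-flux elsewhere.  Fiber directions are
    the normalized descending gradients; the nematic order parameter
    S = |⟨e^{2iθ}⟩| summarizes their alignment.
    """
    nr = nz = int(grid_resolution)
    r, z, cell, nucleus = _domain_masks(geometry, nr, nz)
    across = int(np.count_nonzero(
        (np.abs(r) <= geometry.nucleus_semi_major)))
    if across < 4 or int(np.count_nonzero(
            (z >= geometry.basal_gap)
            & (z <= geometry.basal_gap + geometry.nucleus_height))) < 4:
        raise ValueError("grid too coarse to resolve the nucleus (need >= 4 cells)")
    free = cell & ~nucleus
    free[0, :] = False          # basal Dirichlet row
    idx = -np.ones(free.shape, dtype=int)
    idx[free] = np.arange(int(free.sum()))
    n = int(free.sum())
    dr = r[1] - r[0]
    dz = z[1] - z[0]
    rows, cols, vals = [], [], []
    b = np.zeros(n)

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    nz_, nr_ = free.shape
    for (iz, ir) in zip(*np.nonzero(free)):
        k = idx[iz, ir]
        diag = 0.0
        # radial neighbours with cylindrical 1/r term; mirror at the axis
        for dir_, jr in ((-1, ir - 1), (+1, ir + 1)):
            if ir == 0:
                # axis: symmetric neighbour; Laplacian -> 2·(φ1 − φ0)·2/dr²
                continue
            coef = 1.0 / dr**2 + dir_ / (2.0 * r[ir] * dr)
            if 0 <= jr < nr_ and (free[iz, jr] or nucleus[iz, jr] or iz == 0):
                if free[iz, jr]:
                    add(k, idx[iz, jr], coef)
                    diag -= coef
                elif nucleus[iz, jr]:
                    diag -= coef            # Dirichlet 0
                else:
                    pass
            elif 0 <= jr < nr_ and cell[iz, jr] and iz == 0:
                pass
            else:
                # outside the cell: zero-flux (mirror) — omit both terms
                pass
        if ir == 0:
            jr = 1
            coef = 4.0 / dr**2
            if free[iz, jr]:
                add(k, idx[iz, jr], coef)
                diag -= coef
            elif nucleus[iz, jr]:
                diag -= coef
        # vertical neighbours
        for jz in (iz - 1, iz + 1):
            coef = 1.0 / dz**2
            if 0 <= jz < nz_:
                if free[jz, ir]:
                    add(k, idx[jz, ir], coef)
                    diag -= coef
                elif nucleus[jz, ir]:
                    diag -= coef
                elif jz == 0 and cell[jz, ir]:
                    diag -= coef
                    b[k] -= coef * 1.0      # basal Dirichlet φ = 1
                else:
                    pass                     # outside: zero-flux
        add(k, k, diag)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    phi_free = spla.spsolve(A, b)
    phi = np.full(free.shape, np.nan)
    phi[free] = phi_free
    phi[0, :][cell[0, :]] = 1.0
    phi[nucleus] = 0.0
    # gradient on the filled field (NaN-safe via masked differences)
    filled = np.where(np.isnan(phi), 0.0, phi)
    gz, gr = np.gradient(filled, dz, dr)
    direction = np.full(phi.shape + (2,), np.nan)
    mag = np.hypot(gr, gz)
    ok = free & (mag > 0)
    # descending gradient: from the basal source toward the nuclear sink
    direction[ok, 0] = -gr[ok] / mag[ok]
    direction[ok, 1] = -gz[ok] / mag[ok]
    theta = np.arctan2(direction[ok, 1], direction[ok, 0])
    order = float(np.abs(np.exp(2j * theta).mean())) if theta.size else 0.0
    return OrientationField(r=r, z=z, potential=phi, direction=direction,
                            orientation_order=order, domain=free)
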