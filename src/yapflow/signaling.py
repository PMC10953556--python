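"""RhoA-centered mechanochemical signalling network.

Flow shear stress τ activates RhoA at the plasma membrane through a Hill
term R_max,ρ·τ/(τ+a) acting on the inactive pool; stress borne by basal
fibers at focal adhesions phosphorylates FAK, and the FAK phosphorylation
flux feeds an additive RhoA activation source.  Active RhoA is exchanged
from the membrane into the cytoplasm, where it drives the canonical
cascade: RhoA→ROCK and RhoA→mDia; ROCK→LIMK→Cofilin phosphorylation
(inactivation of the severing activity); mDia polymerises G-actin into
F-actin while active (unphosphorylated) Cofilin severs it; ROCK activates
myosin.

The spatial reaction-diffusion problem is reduced to well-mixed
compartments (membrane / cytoplasm / basal focal adhesions) with
first-order exchange; the contract is the qualitative trajectory shape,
not spatial fields.  Every activation/deactivation is written as a paired
flux between a conserved pool's states, so actin, myosin, FAK, Cofilin,
RhoA, ROCK, mDia and LIMK totals are preserved exactly by the integrator
(classical RK4 preserves linear invariants).

A key emergent feature: the unphosphorylated FAK pool depletes slowly
(dephosphorylation ≪ phosphorylation) under sustained load, so the
FAK-driven RhoA source decays over hours even while basal pFAK
accumulates — this is what gives RhoA (and everything downstream) its
interior maximum under prolonged unidirectional flow.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "SignalingParams",
    "SignalingState",
    "rhoa_activation_rate",
    "fak_phosphorylation_rate",
    "step_signaling",
    "steady_state",
    "rhs",
    "SPECIES",
    "COMPARTMENTS",
]

#: state-vector ordering used by the fast stepping path
SPECIES = (
    "rhoa_inactive", "rhoa_active_mem", "rhoa_active_cyto",
    "rock_active", "mdia_active", "limk_active",
    "cofilin_p", "cofilin", "f_actin", "g_actin",
    "myosin_active", "myosin", "fak_p", "fak",
)

COMPARTMENTS = {
    "rhoa_inactive": "cytoplasm", "rhoa_active_mem": "membrane",
    "rhoa_active_cyto": "cytoplasm", "rock_active": "cytoplasm",
    "mdia_active": "cytoplasm", "limk_active": "cytoplasm",
    "cofilin_p": "cytoplasm", "cofilin": "cytoplasm",
    "f_actin": "cytoplasm", "g_actin": "cytoplasm",
    "myosin_active": "cytoplasm", "myosin": "cytoplasm",
    "fak_p": "basal", "fak": "basal",
}


@dataclass(frozen=True)
class SignalingParams:
    """Rate constants (s^-1, or s^-1 per µM for bimolecular steps) and pools (µM).

    The published reaction tables are not reproduced here; these defaults
    are free constants calibrated once to the documented trajectory shapes
    (fast fiber build-up over ~10 min, RhoA decline over hours through
    FAK-pool depletion) and every one is overridable.
    """

    # flow sensing (Hill) and FAK feedback
    R_max_rho: float = 1.5e-3   # maximal flow-driven RhoA activation rate
    a: float = 6.0              # half-activation shear stress, dyn cm^-2
    k_rho_basal: float = 1.0e-3  # constitutive (flow-independent) activation
    k_rho_fak: float = 0.06     # RhoA activation per unit FAK phospho-drive
    k_rho_deact: float = 8.0e-3
    k_ex: float = 0.02          # membrane -> cytoplasm RhoA transfer
    k_fak: float = 2.0e-4       # FAK phosphorylation scale
    sigma_fak_half: float = 20.0  # half-saturation focal-adhesion stress, kPa
    k_fak_dephos: float = 1.0e-5  # slow: pFAK accumulates over a day
    # cascade
    k_rock_on: float = 6.0e-3
    k_rock_off: float = 2.0e-3
    k_mdia_on: float = 5.0e-3
    k_mdia_off: float = 2.0e-3
    k_limk_on: float = 4.0e-3
    k_limk_off: float = 2.0e-3
    k_cof_phos: float = 3.0e-3
    k_cof_dephos: float = 1.0e-3
    k_poly: float = 4.0e-3
    k_depoly: float = 2.5e-3
    k_myo_on: float = 4.0e-3
    k_myo_off: float = 2.0e-3
    # conserved pools, µM
    rho_total: float = 1.0
    rock_total: float = 1.0
    mdia_total: float = 1.0
    limk_total: float = 1.0
    cofilin_total: float = 1.0
    actin_total: float = 1.0
    myosin_total: float = 1.0
    fak_total: float = 1.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name.endswith("_total") and value <= 0:
                raise ValueError(f"{name} must be positive")
            if value < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SignalingState:
    """Concentrations (µM) of the network species; see COMPARTMENTS."""

    rhoa_inactive: float
    rhoa_active_mem: float
    rhoa_active_cyto: float
    rock_active: float
    mdia_active: float
    limk_active: float
    cofilin_p: float
    cofilin: float
    f_actin: float
    g_actin: float
    myosin_active: float
    myosin: float
    fak_p: float
    fak: float

    @property
    def rhoa_active(self) -> float:
        return self.rhoa_active_mem + self.rhoa_active_cyto

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "SignalingState":
        return cls(**{s: float(v) for s, v in zip(SPECIES, x)})

    def check_invariants(self, params: SignalingParams, tol: float = 1e-6) -> None:
        """Raise if conservation or non-negativity is violated beyond tol."""
        x = self.as_array()
        if np.any(x < -tol):
            raise ValueError("negative concentration beyond tolerance")
        pools = {
            "rho": (self.rhoa_inactive + self.rhoa_active, params.rho_total),
            "cofilin": (self.cofilin + self.cofilin_p, params.cofilin_total),
            "actin": (self.f_actin + self.g_actin, params.actin_total),
            "myosin": (self.myosin + self.myosin_active, params.myosin_total),
            "fak": (self.fak + self.fak_p, params.fak_total),
        }
        for name, (total, expected) in pools.items():
            if abs(total - expected) > tol * max(expected, 1.0):
                raise ValueError(f"{name} pool drifted beyond tolerance")


def rhoa_activation_rate(tau: float, C_rho_inactive: float,
                         params: SignalingParams) -> float:
    """Flow-driven RhoA activation rate, µM/s: R_max,ρ · τ/(τ+a) · C_inactive."""
    if tau < 0:
        raise ValueError("shear stress must be non-negative")
    if C_rho_inactive < 0:
        raise ValueError("concentration must be non-negative")
    if tau == 0.0:
        return 0.0
    return params.R_max_rho * tau / (tau + params.a) * C_rho_inactive


def fak_phosphorylation_rate(sigma_fa: float, C_fak: float,
                             params: SignalingParams) -> float:
    """FAK phosphorylation flux, µM/s: saturating in focal-adhesion stress.

    rate = k_fak · σ/(σ + σ_half) · [FAK]; exponent-1 Hill dependence.
    """
    if sigma_fa < 0:
        raise ValueError("focal-adhesion stress must be non-negative")
    if C_fak < 0:
        raise ValueError("concentration must be non-negative")
    return params.k_fak * sigma_fa / (sigma_fa + params.sigma_fak_half) * C_fak


def _rhs_tuple(x, tau, sigma_fa, p: SignalingParams):
    """Network right-hand side on a plain tuple (fast path).

    Written as paired fluxes so every conserved pool's derivative sums to
    zero exactly.
    """
    (I, Am, Ac, rock, mdia, limk, cofp, cof, f, g, myo_a, myo,
     fakp, fak) = x
    h = sigma_fa / (sigma_fa + p.sigma_fak_half) if sigma_fa > 0 else 0.0
    flow = p.R_max_rho * tau / (tau + p.a) if tau > 0 else 0.0
    act = (p.k_rho_basal + flow + p.k_rho_fak * h * (fak / p.fak_total)) * I
    ex = p.k_ex * Am
    de_m = p.k_rho_deact * Am
    de_c = p.k_rho_deact * Ac
    rock_on = p.k_rock_on * Ac * (p.rock_total - rock)
    rock_off = p.k_rock_off * rock
    mdia_on = p.k_mdia_on * Ac * (p.mdia_total - mdia)
    mdia_off = p.k_mdia_off * mdia
    limk_on = p.k_limk_on * rock * (p.limk_total - limk)
    limk_off = p.k_limk_off * limk
    cof_ph = p.k_cof_phos * limk * cof
    cof_de = p.k_cof_dephos * cofp
    poly = p.k_poly * mdia * g
    sever = p.k_depoly * cof * f
    myo_on = p.k_myo_on * rock * myo
    myo_off = p.k_myo_off * myo_a
    fak_ph = p.k_fak * h * fak
    fak_de = p.k_fak_dephos * fakp
    return (
        -act + de_m + de_c,          # rhoa_inactive
        act - ex - de_m,             # rhoa_active_mem
        ex - de_c,                   # rhoa_active_cyto
        rock_on - rock_off,
        mdia_on - mdia_off,
        limk_on - limk_off,
        cof_ph - cof_de,             # cofilin_p
        cof_de - cof_ph,             # cofilin
        poly - sever,                # f_actin
        sever - poly,                # g_actin
        myo_on - myo_off,            # myosin_active
        myo_off - myo_on,            # myosin
        fak_ph - fak_de,             # fak_p
        fak_de - fak_ph,             # fak
    )


def rhs(state: SignalingState, tau: float, sigma_fa: float,
        params: SignalingParams) -> np.ndarray:
    """Time derivative of the state (µM/s) at shear stress τ and FA stress σ."""
    return np.array(_rhs_tuple(tuple(state.as_array()), tau, sigma_fa, params))


def _rk4_tuple(x, tau, sigma_fa, dt, p):
    k1 = _rhs_tuple(x, tau, sigma_fa, p)
    x2 = tuple(xi + 0.5 * dt * ki for xi, ki in zip(x, k1))
    k2 = _rhs_tuple(x2, tau, sigma_fa, p)
    x3 = tuple(xi + 0.5 * dt * ki for xi, ki in zip(x, k2))
    k3 = _rhs_tuple(x3, tau, sigma_fa, p)
    x4 = tuple(xi + dt * ki for xi, ki in zip(x, k3))
    k4 = _rhs_tuple(x4, tau, sigma_fa, p)
    sixth = dt / 6.0
    return tuple(
        xi + sixth * (a + 2.0 * b + 2.0 * c + d)
        for xi, a, b, c, d in zip(x, k1, k2, k3, k4)
    )


def step_signaling(state: SignalingState, tau_t: float, sigma_fa_t: float,
                   dt: float, params: SignalingParams) -> SignalingState:
    """Advance the network one RK4 step of length dt (s).

    Inputs are held constant over the step (the flow waveform and mechanics
    are updated by the caller between steps).  Conservation is exact up to
    floating-point round-off.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tau_t < 0 or sigma_fa_t < 0:
        raise ValueError("tau and sigma_fa must be non-negative")
    x = _rk4_tuple(tuple(state.as_array()), tau_t, sigma_fa_t, dt, params)
    return SignalingState.from_array(x)


def steady_state(params: SignalingParams, tau: float,
                 sigma_fa: float = 0.0) -> SignalingState:
    """Closed-form root of the network right-hand side.

    The cascade is a feed-forward chain given (τ, σ_fa), so the fixed point
    solves sequentially: FAK balance, RhoA three-state balance, then each
    activation/deactivation pair.  Used to initialise every scenario.
    """
    if tau < 0 or sigma_fa < 0:
        raise ValueError("tau and sigma_fa must be non-negative")
    p = params
    h = sigma_fa / (sigma_fa + p.sigma_fak_half) if sigma_fa > 0 else 0.0
    denom = p.k_fak_dephos + p.k_fak * h
    fak_frac = 1.0 if denom == 0 else p.k_fak_dephos / denom
    fak = p.fak_total * fak_frac
    fak_p = p.fak_total - fak
    flow = p.R_max_rho * tau / (tau + p.a) if tau > 0 else 0.0
    r = p.k_rho_basal + flow + p.k_rho_fak * h * fak_frac
    kd, kex = p.k_rho_deact, p.k_ex
    gain_m = r / (kex + kd)
    gain_c = gain_m * kex / kd
    I = p.rho_total / (1.0 + gain_m + gain_c)
    Am, Ac = gain_m * I, gain_c * I
    def _bal(on, drive, off, total):
        num = on * drive
        return total * num / (num + off) if (num + off) > 0 else 0.0
    rock = _bal(p.k_rock_on, Ac, p.k_rock_off, p.rock_total)
    mdia = _bal(p.k_mdia_on, Ac, p.k_mdia_off, p.mdia_total)
    limk = _bal(p.k_limk_on, rock, p.k_limk_off, p.limk_total)
    cofp = _bal(p.k_cof_phos, limk, p.k_cof_dephos, p.cofilin_total)
    cof = p.cofilin_total - cofp
    # F-actin balance: k_poly·mdia·G = k_depoly·cof·F
    on, off = p.k_poly * mdia, p.k_depoly * cof
    f = p.actin_total * on / (on + off) if (on + off) > 0 else 0.0
    g = p.actin_total - f
    myo_a = _bal(p.k_myo_on, rock, p.k_myo_off, p.myosin_total)
    myo = p.myosin_total - myo_a
    state = SignalingState(
        rhoa_inactive=I, rhoa_active_mem=Am, rhoa_active_cyto=Ac,
        rock_active=rock, mdia_active=mdia, limk_active=limk,
        cofilin_p=cofp, cofilin=cof, f_actin=f, g_actin=g,
        myosin_active=myo_a, myosin=myo, fak_p=fak_p, fak=fak,
    )
    res = float(np.linalg.norm(rhs(state, tau, sigma_fa, params)))
    if res > 1e-10:
        raise RuntimeError(f"steady state did not converge; residual {res:.3e}")
    return state
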