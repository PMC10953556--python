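"""YAP phosphorylation and strain-gated nucleocytoplasmic shuttling.

Cytoplasmic YAP exists phosphorylated (pYAP, retained) or dephosphorylated
(transport-competent).  Dephosphorylation is driven by the cytoskeleton —
its rate is proportional to the product of F-actin and active-myosin
concentrations — while re-phosphorylation is first order.  Dephosphorylated
YAP is imported into the nucleus at a rate gated by the nuclear-membrane
equivalent strain through a Hill function (nuclear-pore stretch) and
exported at a first-order rate:

    d pYAP/dt    = k_phos·YAP_cyto − k_dephos·[F-actin]·[myosin*]·pYAP
    d YAP_cyto/dt = −(above) − k_in(ε)·YAP_cyto + k_out·YAP_nuc / vol_ratio
    d YAP_nuc/dt  = vol_ratio·k_in(ε)·YAP_cyto − k_out·YAP_nuc
    k_in(ε)      = k_in0 + k_in_max·εⁿ/(εⁿ + ε_halfⁿ)

``vol_ratio`` is the cytoplasm-to-nucleus volume ratio; the conserved
(volume-weighted) total is pYAP + YAP_cyto + YAP_nuc/vol_ratio, and at
constant inputs the steady nuclear/cytoplasmic ratio is
vol_ratio·k_in/k_out.

The read-outs mirror the image quantification: YR (nuclear over total
cytoplasmic intensity) and the pYAP fraction of total YAP.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "YapParams",
    "YapState",
    "dephos_rate",
    "import_rate",
    "step_yap",
    "yr",
    "pyap_fraction",
    "normalize_to_control",
]


@dataclass(frozen=True)
class YapParams:
    """Transport and (de)phosphorylation coefficients.

    Rates are free calibration constants chosen so YAP shuttling relaxes
    over ~1-2 h: fast enough to track the strain history within a day,
    slow enough that the oscillatory-flow run is still approaching its
    plateau.  ``hill_n`` and ``eps_half`` position the import gate inside
    the strain range the mechanics module produces.
    """

    k_dephos: float = 8.0e-4    # s^-1 per (µM F-actin · µM myosin*)
    k_phos: float = 5.0e-5      # s^-1
    k_in0: float = 5.0e-6       # basal import, s^-1
    k_in_max: float = 6.0e-5    # strain-gated import increment, s^-1
    eps_half: float = 0.1      # half-activation equivalent strain
    hill_n: float = 2.0
    k_out: float = 6.0e-5       # first-order export, s^-1
    vol_ratio: float = 3.0      # cytoplasm/nucleus volume ratio

    def __post_init__(self) -> None:
        for name in ("k_dephos", "k_phos", "k_in0", "k_in_max", "k_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.eps_half <= 0 or self.vol_ratio <= 0:
            raise ValueError("eps_half and vol_ratio must be positive")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")


@dataclass
class YapState:
    """Concentrations (µM): phospho-YAP and transport-competent YAP pools."""

    pYAP_cyto: float
    YAP_cyto: float
    YAP_nuc: float

    def total(self, params: YapParams) -> float:
        """Conserved volume-weighted total (per cytoplasmic volume)."""
        return self.pYAP_cyto + self.YAP_cyto + self.YAP_nuc / params.vol_ratio


def dephos_rate(C_F_actin: float, C_myosin_active: float, pYAP: float,
                params: YapParams) -> float:
    """Dephosphorylation flux k_dephos·[F]·[M*]·pYAP (µM/s)."""
    if min(C_F_actin, C_myosin_active, pYAP) < 0:
        raise ValueError("inputs must be non-negative")
    return params.k_dephos * C_F_actin * C_myosin_active * pYAP


def import_rate(epsilon_NM_eq: float, params: YapParams) -> float:
    """Strain-gated import rate k_in0 + k_in_max·εⁿ/(εⁿ+ε_halfⁿ) (s^-1)."""
    if epsilon_NM_eq < 0:
        raise ValueError("equivalent strain must be non-negative")
    if epsilon_NM_eq == 0.0:
        return params.k_in0
    en = epsilon_NM_eq ** params.hill_n
    return params.k_in0 + params.k_in_max * en / (en + params.eps_half ** params.hill_n)


def _rhs(p, c, n, C_F, C_M, k_in, prm: YapParams, chemistry: bool):
    if chemistry:
        deph = prm.k_dephos * C_F * C_M * p
        phos = prm.k_phos * c
    else:
        deph = phos = 0.0
    imp = k_in * c
    exp_ = prm.k_out * n
    return (
        phos - deph,
        deph - phos - imp + exp_ / prm.vol_ratio,
        prm.vol_ratio * imp - exp_,
    )


def step_yap(state: YapState, C_F_actin: float, C_myosin_active: float,
             epsilon_NM_eq: float, dt: float, params: YapParams,
             k_in_override: float | None = None,
             chemistry: bool = True) -> YapState:
    """Advance the three-pool YAP system one RK4 step of length dt (s).

    ``k_in_override`` fixes the import rate (used by the chemical-only
    scenario); ``chemistry=False`` freezes the (de)phosphorylation fluxes
    (mechanical-only scenario).  The volume-weighted total is conserved
    exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    k_in = import_rate(epsilon_NM_eq, params) if k_in_override is None else k_in_override
    x = (state.pYAP_cyto, state.YAP_cyto, state.YAP_nuc)
    args = (C_F_actin, C_myosin_active, k_in, params, chemistry)
    k1 = _rhs(*x, *args)
    x2 = tuple(v + 0.5 * dt * k for v, k in zip(x, k1))
    k2 = _rhs(*x2, *args)
    x3 = tuple(v + 0.5 * dt * k for v, k in zip(x, k2))
    k3 = _rhs(*x3, *args)
    x4 = tuple(v + dt * k for v, k in zip(x, k3))
    k4 = _rhs(*x4, *args)
    new = tuple(
        v + dt / 6.0 * (a + 2 * b + 2 * c_ + d)
        for v, a, b, c_, d in zip(x, k1, k2, k3, k4)
    )
    return YapState(*new)


def yap_steady_state(total: float, C_F_actin: float, C_myosin_active: float,
                     epsilon_NM_eq: float, params: YapParams) -> YapState:
    """Closed-form fixed point at constant inputs.

    Yn/Yc = vol_ratio·k_in/k_out and pYAP/Yc = k_phos/(k_dephos·[F]·[M*]);
    ``total`` is the conserved volume-weighted total.
    """
    k_in = import_rate(epsilon_NM_eq, params)
    ratio_n = params.vol_ratio * k_in / params.k_out
    drive = params.k_dephos * C_F_actin * C_myosin_active
    ratio_p = params.k_phos / drive if drive > 0 else 0.0
    yc = total / (1.0 + ratio_p + ratio_n / params.vol_ratio)
    return YapState(pYAP_cyto=ratio_p * yc, YAP_cyto=yc, YAP_nuc=ratio_n * yc)


def yr(state: YapState) -> float:
    """YAP nuclear-to-cytoplasmic ratio YR = Yn / (pYAP + Yc)."""
    cyto = state.pYAP_cyto + state.YAP_cyto
    if cyto <= 0:
        raise ValueError("cytoplasmic YAP signal is zero")
    return state.YAP_nuc / cyto


def pyap_fraction(state: YapState, params: YapParams | None = None) -> float:
    """Phosphorylated fraction of total YAP (volume-weighted when params given)."""
    if params is not None:
        total = state.total(params)
    else:
        total = state.pYAP_cyto + state.YAP_cyto + state.YAP_nuc
    if total <= 0:
        raise ValueError("total YAP is zero")
    return state.pYAP_cyto / total


def normalize_to_control(values, control_mean: float):
    """Divide read-outs by a static-control mean (the standard normalization)."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    try:
        return [v / control_mean for v in values]
    except TypeError:
        return values / control_mean
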