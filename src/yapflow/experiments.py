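"""Scenario presets and the coupled flow→signalling→mechanics→YAP loop.

A scenario couples the modules quasi-statically at each step:

1. evaluate the shear-stress waveform τ(t) (the signalling network senses
   the magnitude |τ|; the direct apical loading keeps the sign),
2. advance the RhoA network one step with the focal-adhesion stress fed
   back from the previous step's conventional-fiber stress,
3. update the conventional-fiber volume fraction (first-order relaxation
   toward its F-actin target) and the flow-alignment polarization,
4. evaluate both fiber stresses and re-solve the lumped nuclear balance
   with the prescribed actin-cap volume fraction and nuclear modulus
   time courses,
5. advance YAP transport with the resulting nuclear-membrane strain.

Fiber strain is taken from the previous step's nuclear-membrane strain
(lagged coupling; the loop gain is < 1 so the lag error is O(dt)).

Oscillatory runs use the condensed-schedule device: the slow inputs and
slow kinetics advance with an effective step dt·compression while the
waveform oscillates on the condensed clock, so a 86 400 s process is
simulated as an 8.64 s schedule (compression 10⁴) that resolves the
oscillation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mechanics as mech
from . import signaling as sig
from . import yap as yapmod
from .synthetic import (
    CAP_PRESETS,
    STIFFNESS_PRESETS,
    FlowWaveform,
    TimeCourse,
    make_cap_timecourse,
    make_flow_waveform,
    make_stiffness_timecourse,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "preset",
    "PRESET_NAMES",
    "run_scenario",
    "cap_stiffness_sweep",
    "tidy_signaling_table",
    "dominant_frequency",
    "trend_slope",
]


@dataclass
class ScenarioConfig:
    """Full specification of one in-silico flow experiment."""

    name: str = "USS12"
    waveform_kind: str = "steady"
    magnitude: float = 12.0           # dyn cm^-2
    frequency: float | None = None    # Hz, oscillatory only
    duration: float = 86400.0         # modelled (real) seconds
    dt: float = 1.0                   # schedule step, s
    compression: float = 1.0
    seed: int = 0
    cap_condition: str = "USS12"
    stiffness_condition: str = "USS12"
    cap_enabled: bool = True          # ACs+/-
    stiffening_enabled: bool = True   # Stiff+/-
    cap_plateau_factor: float = 1.0   # LatB-style cap suppression
    sigma_M_factor: float = 1.0       # LatB-style contractility reduction
    K_F_cap: float | None = None      # override of the cap passive stiffness
    chemical_only: bool = False       # import fixed at the basal rate
    mechanical_only: bool = False     # (de)phosphorylation frozen
    yap_total: float = 1.0            # conserved volume-weighted total, µM
    record_every: int | None = None   # defaults to ~1-min sampling
    signaling_overrides: dict = field(default_factory=dict)
    mechanics_overrides: dict = field(default_factory=dict)
    yap_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("duration and dt must be positive")
        if self.dt >= self.duration / self.compression:
            raise ValueError("dt must be smaller than the schedule duration")
        if self.waveform_kind == "oscillatory" and not self.frequency:
            raise ValueError("oscillatory scenario requires a frequency")

    def build_waveform(self) -> FlowWaveform:
        return make_flow_waveform(
            kind=self.waveform_kind, magnitude=self.magnitude,
            duration=self.duration, dt=self.dt, frequency=self.frequency,
            compression=self.compression,
        )

    def build_cap_course(self) -> TimeCourse:
        if not self.cap_enabled:
            t = np.linspace(0.0, self.duration, 8)
            return TimeCourse(times=t, values=np.zeros_like(t),
                              condition="none", kind="cap_volume_fraction",
                              params={"plateau": 0.0})
        base = CAP_PRESETS[self.cap_condition]
        return make_cap_timecourse(
            condition=self.cap_condition,
            plateau=base["plateau"] * self.cap_plateau_factor,
            time_constant=base["time_constant"],
            duration=self.duration, seed=self.seed,
        )

    def build_stiffness_course(self) -> TimeCourse:
        base = STIFFNESS_PRESETS[self.stiffness_condition]
        if not self.stiffening_enabled:
            t = np.linspace(0.0, self.duration, 8)
            return TimeCourse(times=t, values=np.full_like(t, base["baseline"]),
                              condition="frozen", kind="nuclear_stiffness_kPa",
                              params={"baseline": base["baseline"],
                                      "plateau": base["baseline"]})
        return make_stiffness_timecourse(
            condition=self.stiffness_condition,
            duration=self.duration, seed=self.seed,
        )


PRESET_NAMES = (
    "USS12", "USS4_72h", "OSS", "OSS_enforced",
    "ACs+Stiff+", "ACs+Stiff-", "ACs-Stiff+", "ACs-Stiff-",
    "LatB30", "LatB60", "cap_stiffness_sweep",
    "chemical_only", "mechanical_only", "static_control",
)


def preset(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Named scenario presets reproducing the in-silico experiments.

    Quadrant presets toggle actin-cap formation (ACs±) and nuclear
    stiffening (Stiff±).  LatB presets suppress the cap plateau (30 nM
    mildly, 60 nM strongly) while reducing the conventional-fiber
    contractile stress by <9% and <36% respectively, matching the
    ablation-calibrated dose effects.  chemical_only pins import to the
    basal rate (mechanosensing suppressed); mechanical_only freezes the
    phospho-chemistry.
    """
    base = dict(name=name, seed=seed)
    uss = dict(waveform_kind="steady", magnitude=12.0, duration=86400.0,
               dt=1.0, cap_condition="USS12", stiffness_condition="USS12")
    oss = dict(waveform_kind="oscillatory", magnitude=12.0, frequency=1.0,
               duration=86400.0, dt=0.005, compression=1.0e4,
               cap_condition="OSS", stiffness_condition="OSS")
    table: dict[str, dict] = {
        "USS12": uss,
        "ACs+Stiff+": uss,
        "ACs+Stiff-": {**uss, "stiffening_enabled": False},
        "ACs-Stiff+": {**uss, "cap_enabled": False},
        "ACs-Stiff-": {**uss, "cap_enabled": False, "stiffening_enabled": False},
        "USS4_72h": dict(waveform_kind="steady", magnitude=4.0,
                         duration=259200.0, dt=2.0,
                         cap_condition="USS4", stiffness_condition="USS4"),
        "OSS": oss,
        "OSS_enforced": {**oss, "cap_condition": "USS12",
                         "stiffness_condition": "USS12"},
        "LatB30": {**uss, "cap_plateau_factor": 0.5, "sigma_M_factor": 0.95},
        "LatB60": {**uss, "cap_plateau_factor": 0.15, "sigma_M_factor": 0.70},
        "cap_stiffness_sweep": uss,
        "chemical_only": {**uss, "chemical_only": True},
        "mechanical_only": {**uss, "mechanical_only": True},
        "static_control": dict(waveform_kind="steady", magnitude=0.0,
                               duration=86400.0, dt=5.0,
                               cap_enabled=False, stiffening_enabled=False),
    }
    if name not in table:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(table)}")
    cfg = {**table[name], **base, **overrides}
    return ScenarioConfig(**cfg)


@dataclass
class ScenarioResult:
    """Time-indexed trajectory table plus summary statistics."""

    config: ScenarioConfig
    table: pd.DataFrame
    summary: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "trajectory.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(provenance_dict(self.config), fh, sort_keys=True)


def provenance_dict(config: ScenarioConfig) -> dict:
    """Serializable record of the config and every effective default."""
    sp = replace(sig.SignalingParams(), **config.signaling_overrides)
    mp = replace(mech.MechanicsParams(), **config.mechanics_overrides)
    yp = replace(yapmod.YapParams(), **config.yap_overrides)
    return {
        "scenario": dataclasses.asdict(config),
        "signaling_params": dataclasses.asdict(sp),
        "mechanics_params": dataclasses.asdict(mp),
        "yap_params": dataclasses.asdict(yp),
    }


def _baseline_fixed_point(sp, mp, yp, geometry, rho_cap0, E0, sigma_M_factor,
                          K_F_cap, yap_total, tau0=0.0):
    """Self-consistent no-flow (or constant-τ) state of the coupled system."""
    eps_cf = 0.0
    state = sig.steady_state(sp, tau0, 0.0)
    for _ in range(200):
        Ma = state.myosin_active
        sigma_cf = mp.K_F_cf * eps_cf + mp.k_sigma_myo * Ma * sigma_M_factor
        rho_cf = mech.cf_volume_fraction_target(state.f_actin, mp)
        ms = mech.nuclear_stress_balance(
            sigma_cf, rho_cf,
            mp.cap_prestress + mp.k_myo_cap * Ma, rho_cap0, K_F_cap, E0, mp,
            geometry=geometry,
            sigma_flow=mech.direct_flow_stress(tau0, mp))
        new_eps_cf = mp.chi_strain * ms.epsilon_NM_eq
        new_state = sig.steady_state(sp, tau0, sigma_cf)
        delta = abs(new_eps_cf - eps_cf) + abs(
            new_state.myosin_active - state.myosin_active)
        eps_cf, state = new_eps_cf, new_state
        if delta < 1e-14:
            break
    ystate = yapmod.yap_steady_state(yap_total, state.f_actin,
                                     state.myosin_active,
                                     ms.epsilon_NM_eq, yp)
    return state, ms, eps_cf, ystate


def run_scenario(config: ScenarioConfig, outdir=None,
                 geometry: mech.CellGeometry | None = None) -> ScenarioResult:
    """Run the coupled loop for one scenario; deterministic per config+seed."""
    sp = replace(sig.SignalingParams(), **config.signaling_overrides)
    mp = replace(mech.MechanicsParams(), **config.mechanics_overrides)
    yp = replace(yapmod.YapParams(), **config.yap_overrides)
    geometry = geometry or mech.CellGeometry()
    waveform = config.build_waveform()
    cap_course = config.build_cap_course()
    stiff_course = config.build_stiffness_course()
    K_F_cap = mp.K_F_cap if config.K_F_cap is None else config.K_F_cap

    dt = config.dt
    dt_eff = dt * config.compression
    n_steps = int(round(config.duration / config.compression / dt))
    every = config.record_every
    if every is None:
        every = max(1, int(round(10.0 / dt_eff))) if config.compression == 1 else 1

    rho_cap0 = cap_course.at(0.0)
    E0 = stiff_course.at(0.0)
    state, ms0, eps_cf, ystate = _baseline_fixed_point(
        sp, mp, yp, geometry, rho_cap0, E0, config.sigma_M_factor, K_F_cap,
        config.yap_total)
    k_in_override = yp.k_in0 if config.chemical_only else None
    chemistry = not config.mechanical_only

    x = tuple(state.as_array())
    rho_cf = mech.cf_volume_fraction_target(state.f_actin, mp)
    sigma_cf = ms0.sigma_cf
    polar = 0.0
    g = mech.geometric_projection_factor(geometry)
    rows = []

    def record(step, t_eff, tau, xs, msx, ys, polar):
        (I, Am, Ac, rock, mdia, limk, cofp, cof, f, g_a, myo_a, myo,
         fakp, fak) = xs
        coeff = mech.anisotropy_coefficient(
            msx.sigma_cf * (1 + polar), msx.sigma_cf * (1 - 0.5 * polar)
        ) if msx.sigma_cf > 0 else 1.0
        rows.append((
            t_eff, tau, Am + Ac, Ac, rock, mdia, limk, cofp, f, myo_a,
            fakp, msx.sigma_cf, msx.sigma_cap, msx.sigma_LINC,
            msx.sigma_NM_mean, msx.epsilon_NM_eq, msx.traction, msx.E_nuc,
            ys.pYAP_cyto, ys.YAP_cyto, ys.YAP_nuc,
            yapmod.yr(ys), yapmod.pyap_fraction(ys, yp), coeff,
            f + g_a, myo_a + myo, fakp + fak, ys.total(yp),
        ))

    record(0, 0.0, waveform.tau_at(0.0), x, ms0, ystate, polar)
    decay_align = math.exp(-dt_eff / mp.tau_align)
    for step in range(1, n_steps + 1):
        t_sched = step * dt
        t_eff = t_sched * config.compression
        tau_signed = float(waveform.tau_at(t_sched))
        tau_mag = abs(tau_signed)
        # 2. signalling with lagged focal-adhesion stress
        x = sig._rk4_tuple(x, tau_mag, sigma_cf, dt_eff, sp)
        f_actin, myo_a = x[8], x[10]
        # 3. fiber fraction and polarization
        rho_cf = mech.step_cf_volume_fraction(rho_cf, f_actin, dt_eff, mp)
        p_target = mp.p_max * tau_mag / (tau_mag + sp.a) if tau_mag > 0 else 0.0
        polar = p_target + (polar - p_target) * decay_align
        # 4. stresses and nuclear balance (prescribed cap and modulus)
        sigma_cf = mp.K_F_cf * eps_cf + mp.k_sigma_myo * myo_a * config.sigma_M_factor
        sigma_cap = mp.cap_prestress + mp.k_myo_cap * myo_a
        rho_cap = cap_course.at(t_eff)
        E_nuc = stiff_course.at(t_eff)
        msx = mech.nuclear_stress_balance(
            sigma_cf, rho_cf, sigma_cap, rho_cap, K_F_cap, E_nuc, mp,
            geometry=geometry,
            sigma_flow=mech.direct_flow_stress(tau_signed, mp))
        eps_cf = mp.chi_strain * msx.epsilon_NM_eq
        # 5. YAP transport
        ystate = yapmod.step_yap(
            ystate, f_actin, myo_a, msx.epsilon_NM_eq, dt_eff, yp,
            k_in_override=k_in_override, chemistry=chemistry)
        if step % every == 0 or step == n_steps:
            record(step, t_eff, tau_signed, x, msx, ystate, polar)

    columns = [
        "time_s", "tau_dyn_cm2", "rhoa_active", "rhoa_active_cyto",
        "rock_active", "mdia_active", "limk_active", "cofilin_p", "f_actin",
        "myosin_active", "fak_p", "sigma_cf_kPa", "sigma_cap_kPa",
        "sigma_LINC_kPa", "sigma_NM_mean_kPa", "epsilon_NM_eq",
        "traction_kPa", "E_nuc_kPa", "pYAP_uM", "YAP_cyto_uM", "YAP_nuc_uM",
        "YR", "pYAP_fraction", "anisotropy_coefficient",
        "actin_total", "myosin_total", "fak_total", "yap_total",
    ]
    table = pd.DataFrame(rows, columns=columns)
    summary = _summarize(table, config)
    result = ScenarioResult(config=config, table=table, summary=summary)
    if outdir is not None:
        result.write(outdir)
    return result


def _summarize(table: pd.DataFrame, config: ScenarioConfig) -> dict:
    yr_series = table["YR"].to_numpy()
    t = table["time_s"].to_numpy()
    i_peak = int(np.argmax(yr_series))
    drift = {
        pool: float(abs(table[pool].iloc[-1] - table[pool].iloc[0])
                    / max(abs(table[pool].iloc[0]), 1e-300))
        for pool in ("actin_total", "myosin_total", "fak_total", "yap_total")
    }
    return {
        "scenario": config.name,
        "yr_baseline": float(yr_series[0]),
        "yr_peak": float(yr_series[i_peak]),
        "yr_peak_time_s": float(t[i_peak]),
        "yr_final": float(yr_series[-1]),
        "yr_final_over_peak": float(yr_series[-1] / yr_series[i_peak]),
        "pyap_fraction_final": float(table["pYAP_fraction"].iloc[-1]),
        "epsilon_NM_final": float(table["epsilon_NM_eq"].iloc[-1]),
        "yr_trend_slope_per_s": trend_slope(t, yr_series),
        "conservation_drift": drift,
    }


def tidy_signaling_table(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format signalling trajectory (time_s, species, compartment,
    concentration_uM) from a scenario table."""
    from .signaling import COMPARTMENTS

    cols = [c for c in table.columns if c in COMPARTMENTS or c == "rhoa_active"]
    records = []
    for col in cols:
        comp = COMPARTMENTS.get(col, "membrane+cytoplasm")
        for t, v in zip(table["time_s"], table[col]):
            records.append((t, col, comp, v))
    return pd.DataFrame(records, columns=["time_s", "species", "compartment",
                                          "concentration_uM"])


def trend_slope(t, values) -> float:
    """OLS slope of a read-out against modelled time (per second)."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(values, dtype=float)
    return float(np.polyfit(t - t.mean(), v, 1)[0])


def dominant_frequency(times, values) -> float:
    """Dominant non-zero frequency (Hz) of a detrended, uniformly sampled series."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    dt = float(np.mean(np.diff(t)))
    detrended = v - np.polyval(np.polyfit(t, v, 1), t)
    spec = np.abs(np.fft.rfft(detrended * np.hanning(v.size)))
    freqs = np.fft.rfftfreq(v.size, dt)
    spec[0] = 0.0
    return float(freqs[int(np.argmax(spec))])


def cap_stiffness_sweep(config: ScenarioConfig,
                        K_F_cap_values) -> pd.DataFrame:
    """Re-run the scenario varying only the cap passive stiffness.

    The cap contractile stress is untouched (it is a separate prestress
    parameter), so the sweep isolates the stiffness-shielding role of the
    cap.  Returns YR at the end of the run per stiffness value.
    """
    values = list(K_F_cap_values)
    if not values:
        raise ValueError("empty stiffness sweep")
    rows = []
    for k in values:
        res = run_scenario(replace(config, K_F_cap=float(k)))
        rows.append({"K_F_cap_kPa": float(k),
                     "yr_final": res.summary["yr_final"],
                     "yr_peak": res.summary["yr_peak"]})
    return pd.DataFrame(rows)
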