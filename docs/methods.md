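# Methods

This note records the model structure, the reasoning behind the default
parameters, what the synthetic data do and do not emulate, and the numerical
choices. Everything quantitative stated here is computed by the test suite
or the scenario runner; nothing is asserted beyond what the code reproduces.

## Scope and reduction strategy

The physical system is a single endothelial cell (later, a monolayer) under
wall shear stress: flow sensing at the membrane, a RhoA-centered signalling
cascade, actomyosin mechanics, nuclear deformation, and strain-gated YAP
shuttling. The reference formulation of this pathway is a 3D finite-element
multiphysics model; `yapflow` deliberately replaces the spatial problem with
a reduced-order surrogate whose contract is the *shape* of the trajectories
and the *signs* of the mechanistic couplings, not spatial fields:

* reaction–diffusion → well-mixed compartments (membrane, cytoplasm, basal
  focal adhesions) with first-order exchange;
* the nuclear force balance → a lumped shell balance with explicit
  monotonicity guarantees (below);
* the channel flow solve → the wall shear stress taken directly as input.

Two structures are *prescribed*, not emergent, mirroring how the study
treats them: the actin-cap volume fraction ρ_cap(t) and the nuclear Young's
modulus E_nuc(t) enter as time courses fitted from (here: synthetic)
measurements. The cap formation mechanism is explicitly out of scope.

## Signalling network

Species (µM): RhoA (inactive / active-membrane / active-cytoplasm), ROCK,
mDia, LIMK, phospho- and active cofilin, F/G-actin, myosin (active/total),
FAK (phospho/unphospho). Every reaction is an activation/deactivation pair
within a conserved pool, so actin, myosin, FAK, cofilin, RhoA, ROCK, mDia
and LIMK totals are exact invariants of the dynamics.

RhoA activation has three sources: a constitutive basal rate (static cells
have stress fibers and traction), the flow Hill term R_max,ρ·τ/(τ+a), and a
FAK-feedback term proportional to the instantaneous FAK phosphorylation
drive h(σ_FA)·[FAK]/FAK_total. The FAK term is the clock of the slow
dynamics: phosphorylation is fast relative to dephosphorylation
(k_fak_dephos = 1e-5 s⁻¹), so under sustained load the unphosphorylated
pool depletes over ~6–8 h. The RhoA source therefore rises at flow onset
(σ_FA jumps) and then decays below its pre-flow value — producing the
interior maximum of RhoA, and downstream of it mDia, phospho-cofilin,
F-actin and active myosin, while basal pFAK accumulates monotonically.

The published reaction tables for this pathway are not reproduced here; all
rate constants are free calibration constants chosen once by time-scale
analysis against the documented trajectory shapes — RhoA/ROCK/myosin
relaxation of minutes (k ≈ 2–8×10⁻³ s⁻¹), fiber build-up over ~10 min,
FAK-pool depletion over hours — and then frozen. Every constant is a field
of `SignalingParams` and user-overridable. Whether the FAK term enters RhoA
activation additively or multiplicatively is not constrained by the
qualitative contract; the additive form was chosen for its clean
conservation structure.

## Mechanics closures

All invented closure constants live in `MechanicsParams`:

* shielding weight w(ρ_cap) = ρ_cap/(ρ_cap + w_half), w_half = 0.3;
* σ_LINC = w·σ_cap·ρ_cap/a_LINC with LINC area fraction a_LINC = 0.1;
* σ_NM = (1−w)·(g·ρ_cf·σ_cf + σ_flow), with g the ratio of the nuclear
  equatorial cross-section to its surface area (≈ 0.44 for the default
  7×5×1.5 µm half-height ellipsoid) — a lumped stand-in for the
  membrane-area-weighted projection of the finite-element model;
* ε_NM = σ_NM/(E_nuc + k_shield·ρ_cap·K_F,cap), k_shield = 0.1.

These guarantee ∂σ_LINC/∂ρ_cap ≥ 0, ∂σ_NM/∂ρ_cap ≤ 0, ∂ε_NM/∂E_nuc < 0 and
∂ε_NM/∂K_F,cap ≤ 0 by construction (verified by finite differences on a
parameter grid in the tests).

σ_flow = c_flow·τ is a direct apical loading term: shear drag transmitted
through the cell body to the nuclear envelope, attenuated by the same
shielding weight. It is what carries the waveform frequency into ε_NM under
oscillatory flow — the slow chemistry cannot. Transmission is weaker for
reversed flow (efficiency 0.3), because the flow-polarized cell profile
presents different geometry upstream and downstream; this asymmetry makes
the strain oscillate at the waveform fundamental rather than at the
rectified double frequency. c_flow = 0.008 kPa/(dyn cm⁻²) was set so that
under OSS the sustained direct loading (plus softening and the small cap)
keeps the nuclear strain at or above its static value — the condition for
sustained YAP import — while under USS it is quickly outweighed by the
cap terms.

The cap's contractile stress is a prestress plus a weak myosin sensitivity
(σ_cap = 1.5 + 0.5·[myosin*] kPa), deliberately independent of the cap's
passive stiffness K_F,cap so that the stiffness sweep varies shielding
alone ("maintaining its contractile stress"). Fiber strain is fed back as
ε_cf = χ·ε_NM with χ = 0.3 from the previous step (lagged coupling; the
loop gain (1−w)·g·ρ_cf·K_F·χ/E ≈ 0.2 keeps the fixed point stable and the
lag error O(dt)).

The conventional-fiber direction field solves Laplace's equation on an
axisymmetric (r, z) grid — basal surface as source, nuclear membrane as
sink, zero-flux on the free surface — by sparse finite differences;
directions are descending normalized gradients and alignment is summarized
by the nematic order parameter S = |⟨e^{2iθ}⟩|. Staircase Dirichlet
boundaries limit the solver to first-order accuracy; at the default 48–96
grids successive refinements agree to ≈1% RMS on the unit-range potential.

## YAP transport

The three pools (pYAP, cytoplasmic YAP, nuclear YAP) follow the equations
in the `yap` module docstring; the conserved quantity is the
volume-weighted total pYAP + Y_c + Y_n/vol_ratio with vol_ratio = 3 the
cytoplasm-to-nucleus volume ratio, and the constant-input fixed point obeys
Y_n/Y_c = vol_ratio·k_in/k_out exactly. The import gate (Hill exponent 2,
ε_half = 0.1) is positioned inside the strain range the mechanics produces:
static baseline ε ≈ 0.067 sits on the rising flank, early-USS strain
(≈ 0.15–0.19) near saturation, late-USS strain (≈ 0.02–0.05) on the foot.
Import/export rates (k_in up to 6.5×10⁻⁵ s⁻¹, k_out = 6×10⁻⁵ s⁻¹) give a
shuttling relaxation time of ~1–2 h, fast enough that YR peaks 1–6 h after
flow onset and visibly declines by 24 h, slow enough that the OSS run is
still rising toward its plateau at the end of the day.

Two decomposition scenarios isolate the regulation arms. *Chemical-only*
suppresses mechanosensitive transport: the import rate is pinned at the
basal (strain-independent) k_in0, so from flow onset YAP exports
monotonically to a low plateau set by k_in0/k_out, modulated only by the
phospho-chemistry. (Freezing import at its t = 0 value — which includes
the baseline strain contribution — would instead leave YAP at its fixed
point and could not produce the rapid monotone export this scenario is
meant to exhibit; pinning at the basal rate is the faithful reading of
"suppressing the mechanosensitive aspect".) *Mechanical-only* freezes the
(de)phosphorylation fluxes; the biphasic YR shape survives, showing it is
mechanically driven.

## Scenario coupling and integration

Each step of `run_scenario`: waveform → signalling (RK4) → fiber fraction
and polarization → stresses and nuclear balance → YAP (RK4). The signalling
and YAP integrators are fixed-step classical RK4 on conservative pairwise
fluxes: all default rates put the systems far from the stability limit at
the operating steps (1 s for USS runs, 50 s effective for OSS), RK4
preserves the linear conservation laws to machine round-off (the measured
drift over a simulated day is <1e-13 relative), and steady states are
obtained in closed form by sequential solution of the feed-forward chain
rather than by time-stepping, so every scenario starts at a genuine coupled
fixed point (a static control stays exactly flat). A stiff implicit scheme
was considered and rejected: it would buy nothing at these rate constants
and would trade away the exact conservation.

Oscillatory runs use the condensed-schedule device: a 86 400 s process is
mapped onto an 8.64 s schedule (compression 10⁴). Slow dynamics advance
with the effective step dt·compression while the waveform oscillates on the
condensed clock at 1 Hz, so the oscillation is resolved (dt = 0.005 s, 200
samples per period) without resolving 86 400 real oscillation periods.

Default problem sizes: 86 400 steps of 1 s for a 24-h USS run (~6 s of
wall time), 1 728 steps for the condensed OSS run, trajectories sampled
every 10 s of modelled time.

## Synthetic data

The generators emulate the statistical structure of the study's
measurements, not their microscopy physics:

* cap and stiffness courses are saturating exponentials
  (plateau·(1−e^{−t/τ}), τ = 4 h) — the measured courses are monotone and
  saturating, but their true functional form and fitted values are not
  published; the presets (USS12 cap plateau 0.30, OSS 0.08; USS stiffening
  +30%, OSS softening −10%) are free calibration constants;
* per-cell populations place YR on a line in cap intensity (default slope
  −0.35 over a uniform [0, 2] a.u. cap range) with additive Gaussian noise —
  only the sign and significance of the correlation are meaningful;
* DAPI-like stacks are ellipsoidal masks with Gaussian intensity speckle
  whose amplitude (`compaction`) controls the chromatin CV; no PSF, shot
  noise, or segmentation error is modelled.

Consequently, a passing suite demonstrates that the *pipeline* (generators →
model → metrics) reproduces the documented phenotypes under these idealised
inputs; it says nothing about fitting real image data.

## Vertex monolayer

Energy: E = Σ_c [K_A/2 (A−A0)² + Γ/2 P² + s_c·f·|r_b−r_a|] + Σ_e Λℓ with
K_A = 1, A0 = 1, Γ = 0.04, Λ = 0.02, f = 0.15 in preferred-cell-size units —
the canonical vertex energy family plus one contractile fiber element per
cell along the flow (x) axis, anchored at the cell's extreme-x vertices
(ties broken toward smaller y, so on the unjittered lattice the anchor
forces of adjacent cells cancel and the perfect tiling is an exact
equilibrium). Relaxation is L-BFGS with the analytic gradient, boundary
vertices pinned, topology fixed (no T1 transitions — the experiments are
quasi-static and short).

Ablation severs the target cell's fiber (tension → 0 across a cut line
perpendicular to the fiber) in a tissue where every cell carries the same
dimensionless stress s; the recoil opening ellipse is spanned by the cut
line and the distance the severed anchors spring apart, and the recoil
angle is their ratio. With no stored tension nothing is released and the
angle is zero; over s ∈ [0.2, 1] the angle grows linearly (R² > 0.99 on the
default 64-cell mesh), so the inverse map from measured recoil angles to
tissue stress is well-defined on the calibrated range. The tissue-wide s is
essential: the post-ablation equilibrium of a single released cell in an
unstressed tissue would not depend on its own pre-cut tension.

Capped cells lose 70% of their conventional-fiber tension per unit cap
strength — cap assembly draws on the conventional-fiber actin pool — and
their nuclear-strain proxy (cell-shape anisotropy) is reduced by the same
shielding law as the single-cell model. This orthogonal disorder in the
elongation director is what nucleates the ±1/2 nematic defects detected by
winding numbers on the dual-lattice plaquettes (three-cell triples around
interior vertices, nematic mod-π wrapping; plaquettes touching
boundary-clamped cells are excluded as pinning artifacts, and nearly
isotropic cells — regular polygons have isotropic second moments — are
assigned a reference director so an undeformed tiling is defect-free
rather than noise-dominated).

## Brillouin conversion

The shift→modulus conversion is exact arithmetic; the only convention
choice is the log base and units of the empirical log-log relation, which
the source of the coefficients leaves implicit. Base 10 with M′ in Pa and
E in kPa is the unique natural combination under which nucleus-scale shifts
(4–8 GHz → M′ ≈ 1–5 GPa) map to kPa-scale Young's moduli, the physiological
range; both coefficients and the base are configurable. The hydrogel
cross-validation of the log-log relation is represented by the OLS
round-trip test (no hydrogel data are shipped).

## Degenerate inputs and tolerances

Constant time series are flagged unidentifiable by the course fitter rather
than failing; zero cytoplasmic YAP, empty masks, zero perpendicular stress,
non-positive moduli and out-of-range fractions raise `ValueError`.
Relaxation declares non-convergence above a free-gradient norm of 1e-6;
steady-state solvers verify their residual (<1e-10) before returning.
Conservation is checked row-wise on every scenario table at 1e-6 relative.

## Known limitations

* No spatial fields: sub-cellular gradients, nuclear shape change, and the
  finite-element-grade stress maps are outside the surrogate's contract.
* ρ_cap(t) and E_nuc(t) are inputs, not predictions; all preset magnitudes
  are placeholders for unpublished fits.
* The Hippo kinase cascade, AMOT binding and transcriptional output are
  lumped into the single phosphorylation reaction.
* The vertex model is 2D, without division, motility or T1 rearrangements;
  its defect statistics are qualitative.
* Rate constants are calibrated to qualitative trajectory shapes; absolute
  concentrations and times should not be read quantitatively.
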