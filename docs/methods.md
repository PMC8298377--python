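# Methods

## Model structure and assumptions

The tissue is a constrained mixture of two load-bearing constituents: a
single family of collagen fibers (reference density `ρ_0^c`, initially
80% of the mass) and an isotropic non-collagenous matrix (`ρ_0^m`,
constant in time). Both experience the same total deformation gradient
`F`; only collagen carries inelastic parts, `F = F_e^c F_r^c F_p^c`. The
two inelastic gradients are exactly unimodular fiber-aligned stretches, so
any volume change is elastic and, through the penalty below, attributable
to growth alone. Fiber directions are mapped and renormalized through the
chain, which makes the scalar stretches multiplicative:
`λ = λ_e λ_r λ_p`. With the fiber frames generated by these unimodular
stretches all intermediate directions coincide with the reference
direction, and the anisotropic invariant reduces to
`I_e^c = (a·C a)/(λ_p λ_r)²`.

Key modeling assumptions, inherited from the class of homogenized
constrained-mixture growth models this package implements:

* spatial mass density is (nearly) constant — growth is incompressible, so
  `det F` must follow `ρ_0(t)/ρ_0(0)`; this is enforced by a quadratic
  penalty, not exactly;
* the matrix is purely elastic and isochoric in its energy; volume changes
  cost no matrix energy, so growth happens against the penalty and the
  collagen anisotropy only;
* damage is plastic-like (permanent stretch), not stiffness degradation;
  the damage variable `d` controls the *biological* response, while the
  mechanical softening comes from the plastic stretch reducing `λ_e`;
* species (MMP, GF) are local scalars — no diffusion, no mechano-feedback
  on their production.

## Parameters

Mechanical and biological constants (SI units; 1 year = 3.1536e7 s):

| symbol | meaning | default (biaxial) |
|---|---|---|
| μ | matrix stiffness per unit mass | 115 J/kg |
| k1, k2 | collagen exponential law | 2.0 J/kg, 3.2 |
| κ | growth penalty | 1e7 J/kg |
| ρ_0(0) | initial reference density | 1050 kg/m³ |
| φ_c(0) | collagen mass fraction | 0.8 |
| λ_pre | deposition pre-stretch | 1.062 |
| k_rem | remodeling gain | 0.8/year |
| m_p, λ̄_p | damage slope and threshold | 2.5, 1.3 |
| M0, G0 | homeostatic MMP/GF | 5.6e-5, 3.5e-5 kg/m³ |
| m1, m2 | MMP production/decay | 4e-11 kg/(m³ s), 1e-6 /s |
| g1, g2 | GF production/decay | 1e-4 /s, 4.63e-5 /s |
| t_decay | accumulated-MMP memory | 0.5 year |
| kd1, kd2 | damaged-collagen removal | 1e-4 kg/(m³ s), 10 |
| ki1, ki2 | intact-collagen deposition | 2e-4 kg/(m³ s), 2 |

The species-study preset uses ki1 = 1e-4; the indentation preset uses
k1 = 10 J/kg, κ = 1e8 J/kg, m_p = 4.5, λ̄_p = 1.1, g1 = 2e-4,
g2 = 6.94e-5. One parameter table lists the MMP production constant with
density units; the rate equation requires kg/(m³ s), which is used
throughout. All presets are overridable from a flat YAML file
(`tissueheal.params.load_config`).

## Time integration and numerical choices

Everything is backward Euler. The plastic update is the exact solution of
its implicit equation (linear in the end-of-step plastic stretch because
the damage increment depends only on the known maximum stretch), clamped so
`λ_e ≥ 1` and monotone. The remodeling update is a safeguarded scalar
Newton (tolerance 1e-12 relative, bisection fallback) on a strictly
monotone residual. The species step eliminates the damaged pool and solves
a monotone scalar equation for M by safeguarded Newton — a naive
fixed-point iteration diverges for steps above a few days — after which the
accumulator, GF and intact pool follow, each implicit in its own variable.
The damaged pool is clamped at zero and degradation stops there. At the
healing onset the 0/0 time average in the accumulated-MMP signal is defined
by its right limit, `M(t*) − M0`.

Phases are staggered: prestretch (remodeling only, closed-form steady
state `λ_r = λ/(λ_p λ_pre)` by default), damage (60 s; damage/plastic
updates at 0.25 s steps; remodeling left active, its effect over 60 s is
O(1e-5) and a switch can disable it), healing (one year at 0.1-day steps
by default; halving the step changes the one-year collagen density by
< 0.5%). The transition at t\* splits the collagen density into damaged
and intact pools in proportion to d\*.

Stresses are analytic (`S = 2∂Ψ/∂C` at frozen internal state, hand-coded
3×3 algebra in the hot path); a central-finite-difference fallback on the
energy exists for testing only. The consistent tangent finite-differences
the *bounded* collagen + matrix response through the full internal update
(so internal-variable sensitivity is included) and adds the exact analytic
tangent of the very stiff volumetric term — differencing that term would
bury the soft structural modes under κ-scaled round-off.

## Mixed finite elements and the global solver

The H1-P0 element carries trilinear displacements and an element-constant
dilatation/pressure pair; stationarity of the three-field functional gives
`θ_e = ⟨J⟩_e` (ρ_0-weighted) and `p_e = κ(θ_e − ⟨ρ_0/ρ_0(0)⟩_e)`, which
are condensed so the global Newton iteration is displacement-only, with a
rank-one per-element coupling term. 2×2×2 Gauss quadrature. The
quarter-plate meshes are generated programmatically; for the indentation
test the in-plane element sizes shrink geometrically (ratio 0.7) toward
the loaded corner. The surface pressure is a dead load in the reference
configuration (a follower variant was considered unnecessary at these
rotations); its cone profile vanishes at the 1 cm radius inferred from the
load definition.

The penalty stiffness (κρ_0 ≈ 1e10–1e11 Pa against tissue stiffness
~2e4 Pa) makes plain Newton fragile: nearly isochoric soft modes have tiny
linearized stiffness but quartic energy walls, so full steps overshoot
violently. The solver therefore combines (i) Levenberg–Marquardt damped
Newton with a backtracking line search, (ii) stagnation acceptance at the
round-off floor of the penalty (only below 1e-6 relative residual), and
(iii) continuation in κ: if the damped iteration fails, the step is solved
with the penalty scaled down to 1e-4 κ and ramped back up with warm starts
— each intermediate problem is well conditioned and converges quadratically
in 3–5 iterations. Load steps bisect up to four times on top of that.
Internal variables are committed only after global convergence (nested
local/global iteration). The per-Gauss-point kernels are vectorized over
the whole mesh; their agreement with the scalar material driver is asserted
in the test suite, and the single-element solution matches the
material-point driver to ~1e-8 relative.

## What the studies emulate — and what they do not

The study runners generate all inputs programmatically: the biaxial
protocol (quarter sample 6×3×0.225 mm, fibers along x, prestretch
1.34/1.25, two stretch cycles to 1.83 and 1.93 in four 15-s ramps — the
waveform shape is a package choice, only the maxima and the 60 s duration
are fixed by the protocol), the species study (damage treated as a
prescribed constant at a material point), and the indentation test
(quarter plate 6×6×1.2 cm, prestretch applied by essential boundary
conditions and then swapped for the equivalent nodal tractions, triangular
pressure ramp peaking at 36 kPa at 30 s, removed by 60 s). Probe points
for the indentation strains sit on the x-face, y-face and top center;
their coordinates are arguments, not constants. These synthetic inputs
contain no measurement noise, no geometric variability and a single fiber
family, so passing tests demonstrate internal consistency of the coupled
model, not agreement with any particular tissue.

Default problem sizes are chosen for desk-scale runs: the biaxial studies
use the single element they physically need; the indentation test defaults
to the full 22×22×8 mesh in the CLI but is exercised at 8×8×4 (with 2.5 s
damage and 30-day healing steps) in the test suite, where only sign
patterns and orderings — not magnitudes — are meaningful.

## Design decisions on open points

* The damage law read literally returns 0 once d = 1; it is implemented as
  `d = min(1, m_p⟨λ_max − λ̄_p⟩)` held monotone, consistent with
  irreversibility and the stated range.
* The collagen energy uses the full anisotropic invariant; only the matrix
  energy is isochoric.
* The deposition law admits negative rates for G < G0; the dynamics never
  produce that regime, so it is left unclamped with a runtime warning.
* During healing, remodeling and the biology are formally one implicit
  system, but the biology does not depend on the deformation and the
  remodeling does not depend on the species, so the sequential solve is
  the exact coupled solution.
* The element-level dilatation/pressure pair is condensed rather than kept
  as a ninth node; the two are mathematically equivalent.

## Known limitations

* With the boundary conditions of the biaxial healing study (in-plane
  stretches held, thickness free) the model *identically* predicts the
  same percent thickness increase in both held configurations:
  the unimodular inelastic parts leave `J` purely elastic, the penalty
  pins `J` to `ρ_0(t)/ρ_0(0)` to ~1e-5, and the thickness ratio equals the
  `J` ratio — so the thickness gain is the net relative mass gain,
  configuration-independent. With the biaxial parameter table as printed
  (ki1 = 2e-4) the one-year mass gain is ≈ 115%, which is what the
  package reports for both configurations. Reported reference values of
  44.01% and 35.5% for the two configurations are not reachable — nor
  mutually consistent — under this formulation and parameter set; the two
  corresponding tests are left failing deliberately rather than tuned.
* No species diffusion, single fiber family, no mechano-feedback on
  production rates, dead (non-follower) surface pressure, and the damage
  phase assumes the biological state is strictly frozen.
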