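# tissueheal

Coupled chemo-mechano-biological modeling of damage-induced healing and
growth in soft collagenous tissues.

When a soft tissue is overstretched, collagen molecules fail by interstrand
delamination — one strand of the triple helix slides irreversibly against
the other two. `tissueheal` models this molecular damage as fiber-direction
plasticity at the continuum scale, lets the accumulated damage trigger a
biochemical cascade (matrix metalloproteinases degrade the damaged
collagen, growth factors deposit new collagen), and converts the net change
of collagen mass into volumetric tissue growth under a near-incompressibility
constraint. The package is aimed at computational biomechanics researchers
studying wound healing, scarring and growth & remodeling, who want a small,
fully inspectable Python implementation of the coupled problem — from the
constitutive point level up to a mixed finite-element solver.

## Model

The deformation gradient is split multiplicatively for the collagen fibers,

    F = F_e^c F_r^c F_p^c ,          F = F_e^m  (matrix),

with unimodular fiber-aligned inelastic parts
`F_i = λ_i a⊗a + λ_i^(-1/2)(I − a⊗a)`: `λ_p` is the permanent (damage)
stretch, `λ_r` the remodeling stretch exchanging stretched for freshly
deposited collagen. The mixture free energy per unit reference volume is

    Ψ = ρ_0^c W^c(I_e^c) + ρ_0^m W^m(Ī_1) + ρ_0 W^L(J),

with an exponential tension-only fiber law
`W^c = k1/(2k2) (exp(k2⟨I_e^c − 1⟩²) − 1)`, an isochoric Neo-Hookean matrix
`W^m = μ/2 (Ī_1 − 3)`, and a growth penalty
`W^L = κ/2 (J − ρ_0/ρ_0(0))²` that forces the volume to follow the evolving
reference density (incompressible growth). Stresses are `S = 2∂Ψ/∂C` at
frozen internal state; `σ = J⁻¹ F S Fᵀ`.

Damage evolves from the maximum collagen stretch
`λ_max = max_τ λ(τ)/λ_r` as `d = min(1, m_p⟨λ_max − λ̄_p⟩)` with plastic
flow `λ̇_p = d λ̇_max/λ_e` (active while `λ_e > 1`); remodeling follows
`λ̇_r = k_rem (λ_e − λ_pre)/(λ_pre − 1)`. During healing, the species obey

    Ṁ = m1 ρ^cd/ρ^c* − m2 (M − M0),
    Ġ = g1 I_M − g2 (G − G0),         I_M = (ī_M − M0) e^(−Δt/t_decay),
    ρ̇^cd = kd1 (e^(−kd2 (M−M0)/M0) − 1)   (M > M0),
    ρ̇^ci = ki1 (1 − e^(−ki2 (G−G0)/G0)),

all integrated by backward Euler. A three-field (u, θ, p) Hu–Washizu H1-P0
hexahedral element (trilinear displacements, element-constant dilatation and
pressure, condensed) carries the model onto meshes; the Gauss-point
internal variables advance in a staggered prestretch → damage → healing
sequence.

## Worked example

`python examples/biaxial_damage_and_healing.py` runs the biaxial tension
test on a single mixed element and prints

```
damage phase:
  max collagen stretch, cycle 1: 1.4503   (tissue stretch 1.83 over the remodeling stretch)
  max collagen stretch, cycle 2: 1.5296
  damage at t* = 60 s:           0.5740   (linear law m_p (lambda_max - 1.3))
healing phase (one year, held prestretched):
  thickness increase:            114.56 %
  final volume ratio J:          2.1456   vs growth target 2.1456
  growth-constraint error e(kappa): 7.64e-09
  final elastic collagen stretch:  1.0620   (remodeled back to the pre-stretch 1.062)
```

The collagen stretches are the tissue stretch maxima divided by the
remodeling stretch `1.34/1.062` set up during prestretch; the damage is the
linear law evaluated at the second-cycle maximum; the healed thickness
tracks the net deposited collagen mass exactly because the growth penalty
(`κ = 1e7 J/kg`) pins `J` to `ρ_0/ρ_0(0)` to ~1e-8. Other capabilities are
demonstrated in `examples/species_response.py` (the biochemical cascade for
fixed damage), `examples/constitutive_point.py` (one deformation state
through the mixture energy) and `examples/indentation_scaled.py` (spatially
heterogeneous healing of an indented plate).

A thin CLI wraps the same runners: `tissueheal species|sensitivity|biaxial|indent`.

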