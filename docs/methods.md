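# Methods

## Model

The package implements the standard continuum theory of lipid monolayers
with splay, tilt, and saddle-splay elasticity.  A membrane is two
monolayers joined at a mid-plane surface R_mp; each monolayer carries a
unit director field n̂ (tails → heads) and its dividing plane lies at
R± = R_mp + δ n̂ with tail length δ = δ₀√(1+t²).  On the dividing plane,

* tilt: t = n̂/(n̂·N) − N, with N the dividing-plane unit normal;
* splay J̃ = tr(∇n̂) and saddle splay K̃ = det(∇n̂), the trace and
  determinant of the director-gradient tensor in the surface basis — in
  the tilt-free limit these are c₁+c₂ and c₁c₂ of the dividing plane;
* energy density u = ½κ_m J̃² − κ_m J̃ J_sm + κ̄_m K̃ + ½κ_t t² + γ_m,
  integrated over both dividing planes of every element.

Sign conventions: the monolayer normal points from tails to heads; a
sphere with outward directors has J̃ = +2/R; J_sm < 0 describes
cone-shaped (inverted-phase-forming) lipids.  These conventions reproduce
the closed-form prefusion energies exactly (sphere:
16πκ_m(1−δ₀J_sm) + 8πκ̄_m, independent of radius; cylinder:
2πκ_m R L/(R²−δ₀²); plane: 0), which the test suite uses as quadrature
oracles.

Stretching enters the total energy once per monolayer *accounting unit* as
½K_m(A−A₀)²/A₀, whose derivative is the tension γ_m = K_m(A−A₀)/A₀.  The
γ_m density in u is used only when evaluating local stress for the pore
barrier; integrating it over the area as well would double-count the
stretching energy.

### Parameters

| symbol | meaning | default | unit |
|--------|---------|---------|------|
| κ_m    | monolayer bending rigidity | 10 | k_BT |
| χ      | κ̄_m/κ_m saddle-splay ratio | −0.5 | – |
| l      | tilt decay length √(κ_m/κ_t) | 1.2 | nm |
| J_sm   | mean lipid intrinsic curvature | −0.22 | nm⁻¹ |
| δ₀     | undeformed tail length | 1.5 | nm |
| K_m    | stretching modulus | 80 | mN/m |
| λ      | pore rim line tension | 15 | pN |

k_BT = 4.114 pN·nm (298 K).  The defaults are the mid-range values of the
experimental literature for phospholipid monolayers; κ_m scales all
energies linearly, J_sm is the composition lever (−0.1 nm⁻¹ for pure
DOPC, −0.28 nm⁻¹ for cholesterol-rich plasma membranes).

## Configurations and boundary conditions

Supported pairings: flat-flat, sphere-sphere, sphere-flat (axisymmetric)
and cylinder-flat (quarter-turn symmetric).  Each fusion site consists of
a diaphragm element (absent for the stalk, ρ_D = 0), one near-site element
per membrane, and analytic far fields.  The fusion-site size ρ_size is
*defined* as the radius where tilt vanishes and the bending matches the
surrounding compartment, so the far field is the exact sphere / cylinder /
plane, entering the energy in closed form (sphere caps, planes) or by
analytic quadrature (cylinder footprint); ρ_size itself is a free DOF.

* **Stalk centre**: the two mid-planes meet on the axis at a fixed 90°
  angle (hydrophobic-void avoidance).  The merged proximal leaflets share
  one director there — horizontal for up-down symmetric pairings — which
  makes their dividing surfaces tile the hourglass neck; distal directors
  are axial so the distal dividing surfaces cap the axis smoothly.
* **Diaphragm rim** (three-way junction): mid-plane positions coincide;
  rim angles φ_up, φ_down are free; the lipid director *and the tilt* are
  continuous across the junction.  Director continuity is imposed by
  shared junction DOFs; tilt continuity — equivalent to tangent-continuity
  of each monolayer's dividing surface across the junction — is imposed as
  a stiff quadratic penalty on the tilt mismatch integrated along the
  junction ring (μ = 100 k_BT/nm; converged solutions satisfy the
  constraint to |Δt| ≲ 0.01 and the penalty energy itself is ≲ 0.1 k_BT,
  independent of μ).  This constraint is load-bearing: without it the
  junction line tension is spuriously negative and the diaphragm has no
  equilibrium radius.
* **Fusion-site edge**: mid-plane height free; slope and curvature clamped
  to the compartment's; directors equal the surface normal *and rotate
  with it* (first-order tilt continuity), so both tilt and splay join the
  far field continuously.

Lipid accounting follows the distinct exchange time scales: the proximal
leaflets merge into one unit at stalk formation (fast lateral flow), the
distal leaflets remain separate units (no flip-flop on the stalk/pore time
scale).  Regimes: `reservoir` (all units tension-free), `before_flipflop`
(units keep prefusion relaxed areas; closed units accumulate stretching),
`after_flipflop` (stretching relaxed to zero).  Units touching a flat or
tubular membrane are connected to effectively infinite reservoirs and
never carry stretching.  Closed spherical compartments conserve their
enclosed mid-plane volume: the far-field radius is re-solved (Brent's
method, relative tolerance 10⁻¹⁰) at every energy evaluation.

## Numerical realization

* Fields: mid-plane height and director angles are Chebyshev-basis
  polynomials of order M = 8 in the scaled radial coordinate; quarter-turn
  elements add order-4 cos 2φ (sin 2φ for the azimuthal director
  component) mode profiles on top of the analytic cylinder background.
  Boundary conditions are linear constraints; free parameters live in the
  constraint null space, and the particular solution is the lowest-degree
  Hermite interpolant (a minimum-coefficient-norm particular solution
  oscillates and was found to destabilize trial geometries).
* Quadrature: Gauss–Legendre, 32 radial points (axisymmetric), 22 radial
  × 16 azimuthal (quarter-turn).  Refining quadrature does not change a
  converged state's energy (< 10⁻³ k_BT); raising M from 8 to 12 moves
  converged flat-flat barriers by ~2 k_BT.
* Offset construction: δ = δ₀√(1+t²) is implicit (t lives on the dividing
  plane built with δ).  It is resolved by one explicit correction — tilt
  evaluated on the δ₀-offset surface, offset rebuilt once with the
  resulting δ field, smoothed onto a degree-6 polynomial and saturated
  smoothly at 1.6 δ₀.  An open-ended fixed point is unstable at the stalk
  waist, where the two mirror halves of the merged proximal dividing
  surface meet at a corner and the normal direction swings by ~90°.
  Equilibrium tilts stay below the saturation (|t| ≲ 1.2), so the cap is
  inactive at solutions; it only tames strongly deformed trial shapes.
* Feasibility: nearly folded offsets (director approaching the dividing
  plane) are discouraged by a smooth barrier rather than hard errors, so
  the optimizer sees a differentiable landscape; truly degenerate
  geometries raise errors that the driver converts into graded penalties.
* Minimization: L-BFGS-B over all polynomial free coefficients and scalar
  boundary DOFs jointly, with forward-difference gradients (step 10⁻⁶),
  multi-start from seeded Gaussian perturbations of a heuristic initial
  shape (staged: short exploration of every start, full polish of the two
  best).  A plain backtracking gradient-descent method is available
  (`method="gradient_descent"`) and is used in the tests that check
  monotone descent.  Diaphragm solves run a continuation: shape relaxation
  at a short ladder of pinned rim radii, then release.  Asymmetric pairings
  (sphere-flat) are warm-started by composing the two corresponding
  symmetric solutions; quarter-turn problems are warm-started from the
  axisymmetric flat-flat solution, with the cylinder's azimuthal structure
  carried by the analytic background.  With these schemes the minima are
  seed-independent (identical to < 0.1 k_BT across seeds).
* Fusion-site locality: ρ_size is capped at 12 nm (≈ 10 tilt decay
  lengths; diaphragm annuli at 8 nm width).  The quadratic functional
  admits an unphysical large-scale relaxation channel — a wide,
  weakly-bent skirt around the fusion site that harvests the J_sm
  cross-term through the 4δ₀K̃ coupling of the two offset dividing planes —
  which real fusion sites do not exhibit; the cap excludes it while
  leaving the converged local shapes unconstrained (equilibrium ρ_size
  ≈ 8–10 nm, interior to the bound, for all axisymmetric cases).

## Pore energetics

The stress map σ(ρ,φ) = u₊ + u₋ − 2u₀ is evaluated on the two diaphragm
leaflets of the converged state (including each unit's current tension);
u₀ is the mean monolayer density of the surrounding compartment membranes
in the hemifused state, including their tension (zero for flat/tubular
reservoirs).  U_pore(ρ) integrates the stress released by a central pore
of radius ρ against the rim cost 2πρλ on a 400-point radial grid (the
diaphragm shape is frozen during pore growth — pore-size fluctuations are
fast compared to shape relaxation); the barrier is the profile maximum,
refined by quadratic interpolation, and is flagged `rim_limited` when it
sits at the diaphragm rim rather than in the interior.  For elliptical
(quarter-turn) diaphragms the radius grid extends to the minor semi-axis.
Constant-σ maps reproduce the closed forms ρ_c = λ/σ, E_pore = πλ²/σ to
10⁻⁶ relative, which the tests assert.

## What the solver reproduces, and known limitations

With the reference parameter set the solver reproduces the qualitative
phenomenology of hemifusion energetics: E_stalk is linear in J_sm
(R² > 0.99, slope ≈ 365 k_BT·nm), decreases monotonically with
compartment curvature (the reductions at R_c = 20 nm are ≈ 38 k_BT for
vesicle-vesicle, ≈ 20 k_BT for vesicle-flat and ≈ 9 k_BT for tubule-flat
fusion); the pore barrier grows steeply toward strongly negative J_sm
(≈ 76 k_BT at J_sm = −0.3 nm⁻¹, λ = 15 pN); and the relaxed diaphragm
radius (≈ 3 nm) is nearly geometry-independent across pairings.  The
microvillus scenario (tubule radius 38 → 70 nm) raises the stalk barrier
by ≈ 2.2 k_BT, i.e. an ≈ 10-fold Arrhenius slow-down.

Absolute stalk/diaphragm energies, however, depend on how the singular
90°-corner core at the stalk waist / junction ring is regularized, which
this class of theories does not specify; across published continuum
solvers the flat-flat stalk energy at comparable parameters spans tens of
k_BT.  This implementation's converged absolute barriers sit ≈ 25 k_BT
below the higher published values at every J_sm while all *differences*
(curvature effects, regime effects, rate ratios) are insensitive to the
core treatment.  Known limitations: graph-chart mid-planes (no overhangs
beyond ~60° slopes), truncated cos 2φ anisotropy for cylinder-flat sites,
no hydration/van-der-Waals/undulation forces, no alternative pathways
(elongated stalk, leaky fusion), and no absolute pore-opening times (the
Arrhenius prefactor is unknown; only rate ratios are reported).
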