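# hemifusion

A continuum elastic solver for the intermediates of lipid membrane fusion.
It computes equilibrium shapes and energies of the **hemifusion stalk** and
the **hemifusion diaphragm** formed between flat, spherical, and cylindrical
membrane compartments, and the **fusion-pore formation energy barrier** on
the diaphragm — the two dominant barriers that set the speed of biological
fusion events (synaptic vesicle release, enveloped-virus entry, cell-cell
fusion at microvilli).

## Who this is for

Membrane biophysicists who want desk-scale, reproducible estimates of how
compartment geometry (vesicle radius, tubule radius) and lipid composition
(spontaneous curvature) shift the stalk and pore barriers, without running
coarse-grained molecular dynamics.

## The model

Each lipid monolayer is described by the quadratic tilt–splay energy
density evaluated on its dividing plane:

    u = ½ κ_m J̃² − κ_m J̃ J_sm + κ̄_m K̃ + ½ κ_t t² + γ_m

where J̃ and K̃ are the splay (trace) and saddle splay (determinant) of the
director-gradient tensor, t is the lipid tilt, J_sm the mole-fraction
averaged intrinsic curvature of the mixture, κ̄_m = χ κ_m the saddle-splay
modulus, κ_t = κ_m / l² the tilt modulus (l is the tilt decay length), and
γ_m the monolayer tension from lateral stretching, γ_m = K_m (A−A₀)/A₀.
The dividing plane sits at R_mp + δ n̂ with tail length δ = δ₀ √(1+t²).

A fusion site is decomposed into membrane elements (the diaphragm, the two
near-site membranes, and analytic far fields); the mid-plane position and
the two leaflet director fields of each element are polynomial expansions
whose coefficients — together with scalar boundary DOFs (fusion-site sizes,
compartment separation, rim radius ρ_D, rim angles) — are optimized by
multi-start quasi-Newton descent under the boundary conditions of the
intermediate (90° mid-plane angle at the stalk centre; director and tilt
continuity at the three-way diaphragm junction; tilt-free matching to the
compartments at the fusion-site edge; fixed enclosed volume and fixed
leaflet lipid numbers where the compartments are closed).

Barriers are reported relative to the closed-form prefusion energies
(16πκ_m(1−δ₀J_sm) + 8πκ̄_m for a sphere, 2πκ_m R L/(R²−δ₀²) for a
cylinder, 0 for a plane).  On the converged diaphragm, the stress map
σ(ρ,φ) = u₊ + u₋ − 2u₀ drives pore opening against the rim line tension λ:

    U_pore(ρ) = 2πρλ − ∫∫ σ ρ' dρ' dφ,   E_pore = max U_pore.

Pore-opening rates obey an Arrhenius law, so barrier differences translate
into rate ratios exp(ΔE/k_BT).

Units: lengths in nm, energies in k_BT (k_BT = 4.114 pN·nm); inputs accept
"80 mN/m" and "15 pN" style strings.

## Worked example

```python
from hemifusion import (CompartmentSpec, MaterialParams, MinimizerOptions,
                        stalk_energy)

flat = CompartmentSpec(kind="flat")
vesicle = CompartmentSpec(kind="sphere", R_c=20.0)
lipids = MaterialParams(kappa_m=10.0, chi=-0.5, l=1.2, J_sm=-0.22,
                        delta0=1.5)
opts = MinimizerOptions(n_starts=4, seed=0)

r_ff = stalk_energy(flat, flat, lipids, regime="reservoir", options=opts)
r_ss = stalk_energy(vesicle, vesicle, lipids, regime="reservoir",
                    options=opts)
print(f"E_stalk flat-flat      : {r_ff.barrier:6.1f} kBT")
print(f"E_stalk vesicle-vesicle: {r_ss.barrier:6.1f} kBT")
print(f"curvature effect       : {r_ss.barrier - r_ff.barrier:+6.1f} kBT")
```

prints

```
E_stalk flat-flat      :   57.7 kBT
E_stalk vesicle-vesicle:   19.5 kBT
curvature effect       :  -38.1 kBT
```

i.e. bringing two 20-nm vesicles together instead of two planar membranes
lowers the first fusion barrier by several tens of k_BT — high curvature
strongly promotes stalk formation, the physical reason why small synaptic
vesicles start fusing faster than larger ones.

There is also a thin CLI over the same library:

```
hemifusion stalk --config run.yaml --out results/
hemifusion sweep --config sweep.yaml
```

with YAML configs holding the pairing, material parameters (with units),
constraint regime and minimizer options; results are written as JSON
summaries plus CSV shape/stress exports.

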