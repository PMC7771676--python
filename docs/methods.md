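# Methods

## Physical model and assumptions

CSF in a pial perivascular space is treated as an incompressible
Newtonian fluid in the Stokes regime. The justification is dimensional:
with gap half-width h ≈ 20 μm, peak velocities of order 10²–10³ μm/s,
ρ = 10³ kg/m³ and μ = 0.697×10⁻³ Pa·s, the Reynolds number ρUh/μ stays
below 0.01 and the Womersley number h√(2πfρ/μ) below ≈ 0.2 at cardiac
frequencies, so nonlinear convection and (largely) transient inertia are
negligible. The PVS is an open (non-porous) annular compartment: the
inner boundary is the arterial wall, which moves as prescribed; the outer
boundary is rigid and impermeable (no-slip); inlet and outlets carry
traction (pressure) conditions. Wall motion is one-way coupled — the
fluid does not push back on the artery.

The wall forcing combines

1. a travelling diameter pulsation: the relative diameter change δ(s)
   over one cardiac cycle propagates at wave speed c as
   A(X,t) = −0.5 δ(t − ‖X−X0‖/c) R_PVS along the boundary normal. The
   amplitude scale is the *average* PVS width R_PVS rather than the local
   radius; this keeps the displacement field uniform in magnitude along
   tapering vessels and is implemented verbatim. With the fluid-outward
   normal pointing into the artery, δ > 0 moves the wall into the PVS, so
   systole expels fluid through both ends;
2. optionally, a rigid pulsatile translation B(X,t) r, synchronous with
   δ, of peak amplitude γ (default 6 μm) that vanishes at the pivot X_c
   and reverses beyond it. The direction r is only constrained to be
   normal to the X0–X_c axis (a one-parameter family in 3D); the default
   picks the global axis least aligned with that axis, projected and
   normalized, and is configurable.

Systemic pressure effects enter as traction values: static gradients
(presets 0.01, 0.52, 1.46 and 12 mmHg/m for the third circulation,
respiration, the cardiac cycle, and an infusion upper bound), a
sinusoidal gradient a sin(2π(ft+θ)) with phase shift θ, or a Windkessel
outlet C dp/dt = Q − p/R (defaults C = 1.798 μL/mmHg,
R = 1.097 mmHg/(μL/min); a 1000× lower compliance variant represents a
single-PVS-scale downstream compartment). Static and pulsatile gradients
are converted to outlet pressures weighted by the centerline branch
lengths so the average gradient along every inlet→outlet path is
identical; the inlet is gauged to zero (only pressure differences are
physical).

## Numerical formulation

**3D solver.** Taylor–Hood elements: continuous piecewise-quadratic
velocity, piecewise-linear pressure, an inf-sup stable pair; geometry is
isoparametric quadratic, so edge midside nodes placed on curved walls
represent circular cross-sections to third order. Time discretization is
first-order implicit Euler on the moving mesh: at each step the wall
displacement is evaluated on the *reference* wall, extended into the
volume by a componentwise Laplace solve (Dirichlet on both walls, natural
on end faces — the constant-coefficient extension operator lives on the
reference mesh and is factorized once), the mesh is moved, the discrete
mesh velocity w = (dᵏ − dᵏ⁻¹)/Δt is formed, and the saddle-point system

    ρ/Δt (v, φ) + μ(∇v, ∇φ) − ρ(∇·(w⊗v), φ) − (p, ∇·φ) + (q, ∇·v)
      = ρ/Δt (vᵏ⁻¹, φ)_{Ω_{t^{k-1}}} + (−p̃ n, φ)_Γ

is solved by sparse direct LU. The ALE advection correction enters with a
minus sign (the chain rule for the time derivative on a moving frame); a
non-conservative variant −ρ((w·∇)v, φ) is available behind a flag — at
these amplitudes the term is O(10⁻³) relative and the choice is
unobservable, which the global mass-balance monitor confirms. The
previous-step momentum term is integrated over the previous domain.
Quadrature is a conical-product Gauss–Jacobi rule exact to degree 5.

Degenerate cases: inverted cells after mesh motion raise a geometry error
suggesting a smaller step or amplitude; shell meshes that are locally one
cell thick can produce pressure vertices whose entire velocity patch is
Dirichlet — their indeterminate multiplier is pinned to zero (rows and
columns are structurally empty) and any local mass defect is visible in
the reported residual.

**Reduced model.** The idealized annulus uses a quasi-static lubrication
closure: ∂a/∂t + ∂Q/∂z = 0 with Q = −(πK/8μ) ∂p/∂z and the annular
conductance K(R₁, R₂) = R₂⁴ − R₁⁴ − (R₂²−R₁²)²/ln(R₂/R₁), discretized
with vertex-centred finite volumes on the axial mesh (10 L + 1 vertices
at the default 0.1 mm mesh size), implicit in time with the
backward-difference area rate as source. Discrete mass conservation is
exact by construction (residual ~10⁻¹²). The conductance uses the
instantaneous wall radius by default (geometrically nonlinear); a
frozen-at-rest mode linearizes the model fully — including the v_avg
normalization — and is what makes the superposition test exact. An
explicit unsteady inertia correction (ρ/a) ∂Q/∂t is available behind a
flag, default off, consistent with the small Womersley number. End
conditions: prescribed pressures (default) or a symmetry (zero-flux) far
end, which models an infinitely long cylinder when L is a multiple of the
wavelength.

**Tie-breaks and conventions.** Net-flow velocity is the slope between
the per-cycle maxima of the particle position x(t) in the two last
complete cycles, (x₂ − x₁)·f, with windows aligned to the end of the
record and ties broken by the earliest time. The tracked particle uses
the into-the-domain velocity at the inlet, so steady downstream transport
is positive. Reynolds and Womersley numbers use the gap *half*-width as
the characteristic length — the only choice consistent with the regime
bounds quoted above at the velocities the models produce. Pressure
gradient statistics are volume-weighted over quadrature points.
1 mmHg = 133.322 Pa throughout.

## Synthetic inputs and what they do (not) show

The measured arterial waveform and the image-based bifurcation surface
are external inputs. The shipped surrogates reproduce their summary
characteristics: the cardiac surrogate is an asymmetric C¹ pulse (fast
systolic upstroke over 20 % of the cycle, slow decay) with diastolic
baseline zero and half-amplitude 0.7 % (peak-to-peak diameter change
1.4 %); the sine surrogate is a single harmonic of the same
half-amplitude. The synthetic Y-bifurcation is parametric (defaults:
parent diameter 40 μm, daughters 36/32 μm, branch lengths 0.5/0.45/0.5 mm,
PVS width 0.9 × local diameter, spherical junction fillet of the parent
radius at X_c — the fillet is a meshing necessity, not a physiological
claim). Tests passing on these surrogates verify the *mechanics*
(conservation, convergence, scaling laws, cross-model agreement); exact
velocity magnitudes from in vivo recordings additionally depend on the
measured waveform shape and vessel geometry, which users can supply as a
CSV waveform and an STL surface + centerline. Surrogate-driven runs do
land in the experimentally reported few-hundred-μm/s oscillation and
few-μm/s peristaltic net-flow ranges.

The bifurcation/import mesher is a body-fitted lattice method (background
cube lattice split into tetrahedra, vertices near the implicit inner/outer
tube-union surfaces snapped onto them, outside cells discarded, largest
connected component kept). Its boundary is faithful to O(lattice
spacing); generated straight annuli instead use a structured curved mesh
whose volume and areas match closed forms to ~10⁻⁵.

## Verification suite and problem sizes

The test suite runs on deliberately small problems chosen so each check
is sharp at its tolerance: steady annular Poiseuille against the closed
form (reduced ≤0.1 %, 3D ≤2 % on a 4 320-cell curved annulus — measured
0.06 %); global mass balance below 1 % of peak flux on a 1 152-cell
travelling-wave run; exact zero-forcing fixed points; exact superposition
in the frozen-conductance reduced model; monotone growth of the
peak-to-peak inlet velocity with length for L ∈ {1, 5, 10, 50} mm at
λ = 100 mm; net flow < 1 μm/s for L ≤ 10 mm with zero end-pressure
difference; 1D-vs-3D peak-flow agreement within 10 % (measured < 0.1 %);
time-step halving and mesh refinement changing peak velocity by ≤2 % and
≤5 % respectively; and a miniature synthetic bifurcation whose velocity
trace oscillates at the forcing frequency. These sizes are the package's
own verification choices; production runs simply use finer lattices,
longer branches and Δt = 1 ms.

## Known limitations

Circular annular cross-sections only (elliptic or eccentric PVS would
raise velocities); no porous-media resistance inside the PVS; prescribed
wall motion (no fluid–structure interaction); no nonlinear convection;
sparse direct solves limit practical problem size to ~10⁵ velocity
unknowns per step; the lattice mesher's ragged boundary makes its surface
areas accurate only to first order in the lattice spacing.
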