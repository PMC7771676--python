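# pvsflow

Computational models of cerebrospinal-fluid (CSF) flow in perivascular
spaces (PVS) — the thin annular, CSF-filled compartments that surround
cerebral arteries on the brain's pial surface. Flow in these spaces is a
central ingredient of glymphatic clearance theories, and the mechanisms
behind the experimentally observed oscillatory and net transport of
microspheres (arterial wall pulsation, rigid vessel motion, systemic
pressure gradients) are still debated. `pvsflow` is aimed at researchers in
brain fluid mechanics who want to simulate and dissect these driving
mechanisms at mouse scale.

## Models

**3D moving-domain Stokes.** CSF is an incompressible Newtonian fluid
(ρ = 10³ kg/m³, μ = 0.697×10⁻³ Pa·s) at low Reynolds (Re < 0.01) and
Womersley (α < 0.2) numbers, governed by the time-dependent Stokes
equations on a deforming domain Ω_t:

    ρ ∂v/∂t − μ ∇²v + ∇p = 0,    ∇·v = 0   in Ω_t,

solved in Arbitrary Lagrangian–Eulerian (ALE) form with Taylor–Hood
(P2/P1) tetrahedral finite elements, implicit Euler in time, and a
harmonic extension of the prescribed wall displacement that moves the
mesh. The inner (arterial) wall moves with

    d|_Λ(X, t) = A(X, t) n + B(X, t) r,
    A(X, t) = −0.5 · δ(t − ‖X − X0‖/c) · R_PVS,

a travelling diameter pulsation δ (relative diameter change over one
cardiac cycle, wave speed c = 1 m/s, average PVS width
R_PVS = 4.4×10⁻² mm) plus an optional rigid vessel motion of peak
amplitude γ pivoting about a point X_c near the bifurcation,

    B(X, t) = γ (‖X_c−X0‖ − ‖X−X0‖)/‖X_c−X0‖ · δ(t)/(δ_max − δ_min).

Inlet/outlets carry traction (pressure) conditions: zero, static or
sinusoidal gradients weighted by branch length so every inlet→outlet path
sees the same average gradient, or a lumped Windkessel impedance
C dp/dt = Q − p/R representing the downstream CSF compartment.

**Reduced axisymmetric model.** For idealized annular PVS (inner/outer
radii 20/60 μm), a quasi-static lubrication reduction
∂a/∂t + ∂Q/∂z = 0 with the annular Poiseuille conductance
K = R₂⁴ − R₁⁴ − (R₂²−R₁²)²/ln(R₂/R₁) reproduces the length-sweep
experiments in milliseconds and serves as an independent cross-check of
the 3D solver (they agree to well under 10 % on matched straight annuli).

**Outputs.** Per-boundary flow rates Q(t) = ∫_Γ v·n ds, average normal
velocities v_avg = Q/A, the tracked particle position
x(t) = ∫₀ᵗ v_avg dτ, and the net-flow velocity (slope between the
per-cycle peaks of x over the two last cycles), plus peak pressure,
pressure-gradient statistics and Reynolds/Womersley numbers.

Geometries: 1D idealized annuli, structured curved 3D annuli, a
parametric synthetic arterial Y-bifurcation at mouse scale (PVS width =
0.9 × local arterial diameter, giving widths of 28–42 μm around arteries
of 32–46 μm), and PVS extrusion around an imported artery surface (STL)
with a supplied centerline.

## Worked example

Run the idealized length-sweep model from the command line:

```sh
pvsflow fixtures fixtures                 # default waveforms + configs
pvsflow run fixtures/model_G.yaml -o run_G
```

which prints (idealized annulus, L = 1 mm, 10 Hz cardiac-like pulsation
with 0.7 % half-amplitude, zero end-pressure difference):

```json
{
  "mass_residual": 8.654713040637925e-12,
  "model_id": "G",
  "net_flow_velocity_um_s": 6.702860905954955e-05,
  "p2p_amplitude_um_s": 190.2093709234842,
  "peak_pressure_Pa": 0.1966262144252746,
  "peak_v_avg_um_s": 152.0595118699375,
  "reynolds": 0.004363257155521879,
  "solver": "reduced_axisym",
  "womersley": 0.18989063237826964
}
```

The wall pulsation alone drives a strong oscillation of the average
normal velocity at the inlet (peak-to-peak 190 μm/s) but essentially no
net drift (7×10⁻⁵ μm/s): a 1-mm PVS is far shorter than the 100-mm
arterial pulse wavelength, so the oscillation is almost perfectly
reversible. The Reynolds number 0.0044 confirms the Stokes regime; mass
is conserved to round-off. Sweeping the domain length,

```sh
pvsflow sweep fixtures/model_G.yaml -p L -v 1,5,10,50,100 -o sweep.csv
```

shows the velocity amplitude growing with length up to the wavelength
(190 → 4593 μm/s between 1 and 50 mm) and peristaltic net flow appearing
only for wavelength-scale domains (4.2 μm/s at 50 mm, 7.7 μm/s at
100 mm; below 0.3 μm/s for L ≤ 10 mm). In the library, the same run is
three calls: `make_idealized_annulus` → `solve_reduced` →
`FlowRecord.net_flow_velocity()`; 3D runs use
`make_synthetic_bifurcation`/`make_annulus_mesh_3d` with `run_cycles`.

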