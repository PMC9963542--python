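# Methods

`acoustolbm` simulates the lateral migration of a single microparticle in a
straight microchannel under a one-dimensional standing surface acoustic wave
(SSAW), using a two-dimensional lattice-Boltzmann fluid coupled to a
Lagrangian marker ring through an immersed-boundary (IB) kernel.  This note
records the model, its assumptions, the numerical choices that were genuinely
open, and what the synthetic scenarios do and do not establish.

## Fluid model

The fluid is a D2Q9 BGK lattice-Boltzmann solver: nine discrete populations
`f_i` per node relax toward a second-order Maxwellian equilibrium at rate
`1/τ` and stream to nearest neighbours each step.  Density and momentum are
the zeroth and first moments of `f_i`; kinematic viscosity follows from the
relaxation time as `ν = c_s²(τ − 1/2)` with `c_s² = 1/3` and unit lattice
spacing and time step.  The solver targets the incompressible low-Mach regime;
every configuration keeps the lattice Mach number below 0.1 and `τ > 0.5`.
Body forces enter through the Shan–Chen velocity shift: the equilibrium is
evaluated at `u + τF/ρ`, which injects exactly `F` of momentum per node per
step.  A state update is one fused collide-and-stream pass (numba-jitted when
numba is importable, with an equivalent vectorized numpy fallback; a
regression test keeps both paths within rounding of each other).

Physical and lattice frames are linked by three base conversion factors
(length, density, kinematic viscosity); time, velocity, force and
energy-density factors follow by dimensional analysis, and dynamic similarity
is enforced by matching the Reynolds number, which is invariant under this
construction.  The stock mapping is a 160 µm channel on 80 nodes (2 µm per
cell), water density 1027 kg/m³ at lattice density 1, and ν = 10⁻⁶ m²/s at
lattice viscosity 0.0167 (τ = 0.5501), giving 66.8 ns per step.  The acoustic
energy density converts with the pressure factor (force per area).

## Boundary conditions

* **Half-way (link) bounce-back** for straight no-slip walls: the reflected
  population returns to the node it left with reversed direction, placing the
  wall half a cell outside the outermost fluid row.  Exactly mass-conserving
  and second-order accurate; used for the channel scenarios.
* **Zou–He moment reconstruction** for on-node walls: the wall density is
  rebuilt from the known populations and the three unknowns are set so the
  node's moments equal (ρ_wall, u_wall) exactly, for both moving and
  stationary walls.  Used for the lid-driven cavity.  Corner nodes reflect
  all their unknown populations bounce-back style, which keeps them
  mass-neutral; assigning corners a neighbour's density instead leaks mass at
  ≈4·10⁻⁶ of the total per step.
* A **velocity-corrected moving bounce-back lid** is available as the
  alternative cavity treatment.  It conserves mass exactly, but a fully
  bounce-back-walled box retains the known neutrally stable staggered
  (checkerboard) invariants of bounce-back, which a driven lid pumps slowly:
  at Re = 100 on 50² the spurious mode becomes visible after ~2·10⁴ steps.
  The reconstruction walls damp it, so they are the cavity default; the cost
  is a slow mass leak (~10⁻⁷ of the total per step), which is why the exact
  conservation property is demonstrated on closed bounce-back channels
  instead.
* **Open-flow handlers** for the drag benchmark: an exact-flux Zou–He
  velocity inlet with a smooth cubic start-up ramp, a Zou–He constant-density
  outlet, and specular free-slip walls.  An equilibrium-pinned inlet is also
  provided but is soft — its realized influx sags when the interior
  pressurizes (we measured 20–45% flux deficits, which silently deflate any
  drag coefficient normalized by the nominal speed).

## Immersed boundary coupling

The particle (or cylinder) boundary is a closed ring of Lagrangian markers,
spaced ~0.65 cells apart, coupled to the grid by the compact hat kernel
`δ(x) = max(0, 1 − |x|)` applied as a 2D tensor product: marker forces are
spread to the ≤4 surrounding nodes, and marker velocities are interpolated
back with the same weights, so the total spread force equals the total marker
force exactly (the kernel is a partition of unity) and the markers advect
with the local fluid (explicit Euler, one lattice step).

**Constraint scheme.**  The classical choice is a penalty spring tethering
each marker to its reference position.  In this compressible, low-viscosity
setting that scheme is structurally unstable: the marker-position integrator
plus the spring forms an undamped oscillator against the fluid, and its m = 0
radial ("breathing") component couples to the weakly damped acoustic field —
a harmonic decomposition shows the breathing amplitude growing from 10⁻⁶ to
O(1) lattice units within a few thousand steps at any tested stiffness
(0.005–0.1, with and without velocity damping).  The package therefore uses
proportional velocity constraints, which are contractive:

* **Mobile particle:** `F_i = −γ(v_i − v̄) + F_ext/N` with γ = 1, where `v_i`
  is the interpolated fluid velocity at marker i and `v̄` its ring mean.  The
  first term cancels the ring's deformation rate each step and sums to zero,
  so the particle remains force-free apart from the external (acoustic,
  optional gravity–buoyancy) load, which is shared equally over the markers.
  Measured shape deviation stays below 0.1% of the radius over 4·10⁴ steps,
  and with the sound off the lateral drift is ~3·10⁻⁵ cells over the same
  span.  The membrane is massless: particle density and compressibility act
  on the dynamics only through the acoustic contrast factor.  A Hooke
  penalty term remains available through the `stiffness` knob (default 0).
* **Fixed obstacle:** markers stay pinned and the interpolated velocity is
  cancelled directly, `F_i = −v_i` (unit gain; the one-step kernel response
  per unit force is ≈0.5–0.96, so the loop contracts).  The summed constraint
  force, sign-reversed, is the hydrodynamic force on the obstacle; its x
  component is the drag entering `C_d = F_drag / (½ρDu²)`.
* Markers of the drag cylinder are placed on a circle retracted 0.3 cells
  inside the nominal radius, because the hat kernel's effective no-slip
  surface sits about that far outside the marker ring.  The retraction was
  calibrated once against the confined-channel cylinder benchmark of
  Schäfer & Turek (2D-1, Re = 20, reference C_d = 5.5795): D = 10 markers
  without retraction give 6.34, with retraction the free-cylinder deviations
  drop to a few percent.

## Acoustic radiation force

A particle with radius much smaller than the wavelength in a 1D standing wave
feels the time-averaged radiation force

    F_A(y) = −(2π V_p E_ac / λ) Φ sin(4π (y − φ₀)/λ),
    Φ = (5ρ_p − 2ρ_f)/(2ρ_p + ρ_f) − β_p/β_f,

with `V_p = (4/3)πr³`, `E_ac` the acoustic energy density and Φ the acoustic
contrast factor.  Positions `y = φ₀ + kλ/2` are stable pressure nodes for
Φ > 0; the antinodes midway between them attract Φ < 0 particles.  The phase
offset `φ₀` makes the node layout explicit in configuration: a
half-wavelength channel with `φ₀ = λ/4` has its single node at mid-width
(the centred-focusing case), and a full-wavelength channel with the same
relative offset has two nodes at W/4 and 3W/4 with the antinode at the
centre (the two-node case).  `E_ac` may also be given as `aV²` from the
transducer voltage.  Water compressibility defaults to 4.5·10⁻¹⁰ Pa⁻¹.
Acoustic streaming and secondary (inter-particle) radiation forces are not
modelled; the force acts on the particle centroid and is applied through the
IB markers, so the acoustic field does not perturb the fluid except through
the particle.

The force is evaluated at the instantaneous centroid every step, converted to
lattice units through the force factor, and shared equally over the markers.

## Scenarios and problem sizes

All sizes below are the package's own choices, made once and recorded here.

* **Plane Poiseuille** (validation): 40-cell channel (the axial extent is
  irrelevant for this x-invariant flow, so tests use 4 columns), τ = 1,
  driven by the uniform body force equivalent to −dP/dx for fully developed
  flow; run to a 10⁻⁹ velocity-stationarity tolerance and compared with the
  analytic parabola (L2 error ≈ 0.03%; refinement 40 → 80 cells reduces it).
* **Lid-driven cavity** (validation): 50×50 nodes, Re = 100 on the lid speed
  (0.1) and cavity span, reconstruction walls; the centreline u-profile is
  interpolated to the 17 literature sample heights (129²-grid reference of
  Ghia, Ghia & Shin, shipped as a CSV fixture) — RMS deviation ≈ 0.4% of the
  lid speed.
* **Cylinder drag** (validation): free-slip lateral walls at blockage ≤ 0.04,
  exact-flux inlet, pressure outlet, drag from the direct-forcing reaction
  averaged over 2000-step windows (the open box rings acoustically with
  period ~2Nx/c_s; the smooth 6000-step inlet ramp keeps the ringing small).
  Geometry is chosen per Reynolds number: D = 10 in a 400×250 box for
  Re ≥ 0.5, and D = 3 for creeping flow, where the drag force depends on the
  diameter only through the Oseen logarithm but the walls must sit several
  Oseen lengths `ν/U` away (walls at 1.25 ν/U inflate the drag ~60% over the
  unbounded correlation; at ~4 ν/U the excess is ~12%).  The reference curve
  is the Clift–Grace–Weber low-Re correlation, shipped as a CSV fixture and
  interpolated log-log.  Measured deviations: +12% (Re = 0.1), ≈+10%
  (Re = 1), +4% (Re = 10), all of one sign because residual confinement and
  finite resolution both push the drag up.
* **SSAW focusing** (the study itself): 160 µm channel on 80 lateral nodes
  with 24 periodic axial nodes (the axial flow is x-invariant, so a short
  box is exact and cheap); the axial Poiseuille profile is initialized
  analytically and sustained by its matching body force at Re = 0.70.  The
  default particle is 10 µm polystyrene (ρ = 1050 kg/m³,
  β = 2.49·10⁻¹⁰ Pa⁻¹); iron oxide and PMMA are stocked for the contrast
  sweep.  The transducer proportionality constant that would map the
  experimental drive voltage to an energy density is not available, so
  `E_ac` defaults to 150 J/m³ — a strong-but-physical SSAW drive calibrated
  once so the default particle settles well inside the 3·10⁵-step budget
  (≈3.3 ms of physical time per 5·10⁴ steps).  The steady-state position is
  independent of `E_ac`; only the transient scales with it.

**Settling criterion.**  The particle counts as settled when, over a trailing
5000-step window (sampled every 100 steps), (a) its lateral position stays
within 0.5 µm of the window median, and (b) that median lies within the same
tolerance of a stable node.  Condition (b) matters because stationarity alone
also fires for a particle that merely moves slowly (e.g. a small particle far
from the node, or sound off).  The run stops early once both conditions hold
with a 10× stricter stationarity bound, so the reported steady position has
converged well inside the ±1 µm comparison band; the settle time reported is
the onset of the criterion at its nominal tolerance.

## What the synthetic scenarios do and do not show

The generator reproduces the study conditions: unit mapping, channel and
particle geometry, fluid properties, Re = 0.70 axial flow, and the two node
layouts.  Passing tests establish internal consistency of the solver (exact
conservation identities, kernel exactness, analytic channel flow), agreement
with independent literature references for the cavity and cylinder, and the
qualitative physics of acoustophoresis: release-position-independent focusing
at the node, nearest-node selection in the two-node layout, and transients
ordered by r³ and by contrast factor.  They do not validate against the
experimental trajectories themselves (the drive energy density is unknown and
the curves are not tabulated), do not include acoustic streaming, particle
inertia, wall lubrication corrections, particle–particle interactions, or 3D
effects, and a single calibrated `E_ac` stands in for the voltage map.

## Numerical edge cases and failure policy

Non-positive or non-finite density aborts the run with the step index rather
than clamping.  A membrane whose kernel support leaves the domain raises an
out-of-domain error; a focusing particle whose markers reach a wall raises a
wall-contact error carrying the trajectory up to that point.  Configuration
validation names the offending key; a lattice viscosity implying τ ≤ 0.5 is a
stability error.  The simulator contains no random number generation, so
every run is bit-reproducible from its configuration, and every output file
embeds the configuration echo needed to rerun it.
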