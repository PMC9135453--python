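# Methods

`cytorod` simulates assemblies of rigid cytoskeletal filaments (microtubule
proxies) driven by two-headed crosslinking motors in the overdamped regime.
The two design pillars are (i) a four-state crosslinker kinetic Monte Carlo
whose rates descend from a free-energy landscape, so the passive limit obeys
detailed balance, and (ii) a linearized implicit-Euler timestep in which
steric exclusion enters as complementarity constraints and motor tethers as
bilateral spring constraints, both resolved in a single convex quadratic
program per step.  This removes the stiff-spring and hard-potential step-size
restrictions of explicit schemes.

## Filament model

A filament is a rigid spherocylinder: center `x` (µm), unit quaternion `θ`
(scalar-first; the director `p̂` is the reference axis (0,0,1) rotated by
`θ`), length `L` and diameter `D`.  The minus end sits at `x − (L/2)p̂`.
Arc coordinates `s ∈ [−L/2, +L/2]` parametrize the centerline, minus end at
`−L/2`.  Units everywhere: µm, pN, s, pN·µm; `kBT = 4.141e-3` pN·µm (300 K).

Drag uses standard slender-body coefficients,

    ζ∥ = 2πηL / ln(2L/D),   ζ⊥ = 2 ζ∥,   ζrot = πηL³ / (3 ln(2L/D)),

with solvent viscosity η = 0.01 pN·s·µm⁻² by default (cytoplasm-like; the
stiffness example below uses the aqueous value).  The mobility matrix is
block diagonal per filament; the axial spin of a spherocylinder is a null
mode and is projected out of the angular velocity.  Orientation updates use
the quaternion exponential map of `h·ω` followed by renormalization.

## Crosslinking motors

A motor is a Hookean tether (stiffness `κ_xl`, rest length `ℓ0`) with two
binding heads, A and B, and four states U, SA, SB, D.  The tether spans the
filament *surfaces*: for attachment points `P1`, `P2` on the two centerlines,
`ℓf = |P1 − P2| − (r_i + r_j)`, clamped at zero.  With this convention two
filaments crosslinked by a relaxed motor sit at centerline separation
`ℓ0 + D`, which is the length scale read off minus-end pair correlations in
motor-condensed networks (first peak at `D`, second at `D + ℓ0`).  The tether
energy is `E(ℓ) = ½ κ_xl (ℓf − ℓ0)²`.

Transition rates per head:

* U→S: `ko_S · (3 ε Ka / 4π rc³) · Σ_i L_in,i(x)`, with `L_in,i` the
  centerline arclength of filament `i` inside the capture sphere of radius
  `rc` about the head; the binding site is drawn uniformly over the captured
  arclength.  These transitions carry no tether deformation energy.
* S→U: `ko_S`.
* S→D: `ko_D · ε Ke · Σ_j ∫ ds exp[−(1−λ) β E(ℓf(s))]`, integrated with a
  fixed 256-node midpoint rule per candidate filament, restricted to arcs
  with `βE ≤ 20` (truncation error < 1e-8 relative); the binding site is
  drawn from the discretized density by inverse transform.
* D→S: `ko_D · exp[+λ β E(ℓf)]`.

`β` appears in the D→S exponent for dimensional consistency, and the caption
constraint that the S⇌D equilibrium constant reduce to the Boltzmann factor
then holds exactly: the ratio of binding density to unbinding rate is
`ε Ke exp(−βE)` for every energy-partition factor `λ ∈ [0,1]`.

Events are sampled per head as frozen-rate Poisson processes,
`P(fire in h) = 1 − exp(−R(0)h)` (first-order in `h`), at most one transition
per head per step; if both heads of one crosslinker fire, one event is kept
uniformly at random.  Transitions move only along U⇌S⇌D.  Unbound motors
diffuse isotropically with configurable diffusivity `diff_u` (default
1 µm²/s) and reflect from impermeable walls.  Singly bound heads sit at their
attachment point and the tether carries no force.  Bound active heads step
toward their preferred end with the linear force-velocity law

    v_F = vm · max(0, min(1, 1 + F_proj/F_stall)),

`F_proj > 0` assisting.  Singly bound active heads step at `vm`.  A head
reaching its target end pauses (clamps), detaches, or wraps onto the
opposite end, per species (wrap is only meaningful for a filament spanning
a full periodic cell while axis-aligned; no shipped scenario uses it).
Species may declare a tension-only ("slack") tether: the stalk buckles
rather than pushes, so energy and force vanish on the compression side and
slack bonds drop out of the constraint set for that step.  The gliding
kinesin-1 uses this (a symmetric spring lets compressed bonds destabilize
the transported filament); crosslinker species keep the symmetric spring,
whose compression push is part of the published physics.
A force-dependent-binding hook (replace `E` by the tether force in the S⇌D
exponents) exists as a config switch but is off by default and unvalidated.

## Constraint-based timestep

Each step runs three tasks: (1) motor diffusion and stepping, (2) the kMC
sweep, (3) filament motion.  For (3), collisions with surface separation
below a buffer (default `0.3·D`) and all doubly bound tethers define the
constraint set.  Writing `D` for the sparse matrix mapping constraint force
magnitudes γ to equal-and-opposite wrenches `±(n̂, r×n̂)`, the linearized
implicit step is the convex QP

    min ½ γᵀ(DᵀMD + diag(0, K⁻¹/h))γ + qᵀγ,   γ_u ≥ 0,
    q = [Φu/h + DuᵀM Fnc ;  (Φb − Φb0)/h + DbᵀM Fnc],

whose KKT conditions are exactly the discrete complementarity
`0 ≤ Φu^{k+1} ⟂ γu ≥ 0` and spring law `K(Φb^{k+1} − Φb0) = −γb` on the
linearized next-step gaps.  `K⁻¹ → 0` (rigid joints) keeps the problem
convex.  Brownian forcing enters `Fnc` as a random wrench with covariance
`2 kBT M⁻¹/h` (body frame, anisotropic translation plus transverse rotation,
Euler-Maruyama), so collisions resist thermal overlap within the same solve;
free-filament translational/rotational diffusion then satisfies the Einstein
relations, which is how the scheme is validated (no claim of pathwise
equivalence with any particular reference discretization).

The solver is Barzilai-Borwein projected gradient descent: projection clamps
only the collision block; BB1/BB2 step sizes alternate after a conservative
first step `1e-4/‖M‖est`; the stopping rule is a projected-gradient ∞-norm
below `1e-6·max(1, ‖q‖∞)` (configurable).  Three numerical refinements keep
iteration counts manageable without changing the minimizer or the stopping
rule: Jacobi (diagonal) rescaling of the iteration, warm starting from the
previous step's γ with new tethers initialized at their local Hookean value
`−κ(ℓf − ℓ0)`, and an exact active-set/Cholesky path for small problems
(≲500 constraints).  Purely bilateral problems with finite stiffness are an
unconstrained SPD system and are solved directly.

Contact geometry is the exact segment-segment closest point (Lumelsky-style
clamping); exactly parallel overlapping pairs use the midpoint of the overlap
interval as a deterministic symmetric tie-break.  Periodic images are
resolved by minimum image on center-center displacements before the narrow
phase; neighbor search uses periodic kd-trees (ghost images for the
x-periodic cylinder), equivalent to cell lists with cell size ≥ L + D +
buffer.  Walls (sphere, spherical shell, cylinder) enter as one-sided
unilateral constraints on the endcap spheres — exact for these convex
geometries.

### Timestep guidance and overlap control

The default `h = 1e-4` s is stable far beyond the stiff-spring explicit
limit: for 10 crosslinkers of `κ = 100` pN/µm bridging 1 µm filaments with
combined drag `4πηL/ln(2L/D) = 0.003` pN·s/µm, the tether relaxation time is
`1/λ = 3e-6` s, and the implicit step reproduces the closed-form recurrence
`(ℓ−ℓ0) → (ℓ−ℓ0)/(1 + hλ)` to 1e-10 at `hλ ≈ 30-10³`, where forward Euler
diverges.  What `h` cannot exceed is the *collision detection* scale: a
contact constraint exists only once a gap drops below the buffer, so a
filament can penetrate a neighbor by roughly its one-step free displacement
before being caught.  At `h = 1e-4` a thermal 0.5 µm filament's endcap moves
~10-20 nm per step; dense thermal packings therefore show transient overlaps
of that magnitude (bounded, not amplified — the implicit solve removes them
in O(1) steps).  Dense + Brownian scenarios (packing ≳ 0.3) therefore use
`h = 1e-5`, matching the practice for the published dense confined runs;
dilute or athermal runs keep `h = 1e-4`.

## Motor parameter sets (reconstructions)

The per-species tables of the original study are not reproduced here; the
shipped presets are literature-typical reconstructions and are editable:

| species | vm (µm/s) | Fstall (pN) | κ_xl (pN/µm) | ℓ0 (µm) | direction | ends |
|---|---|---|---|---|---|---|
| kinesin1 | 1.0 | 5 | 100 | 0.053 | plus,plus | detach |
| xctk2 | 0.046 | 1 | 100 | 0.053 | minus (one motile end) | pause |
| aster_motor | 0.1 | 5 | 100 | 0.053 | minus,minus | pause |
| dynein | 1.0 | 1.25 | 100 | 0.053 | minus,minus | detach |

All species use `ko_S = ko_D = 1 s⁻¹`, `ε = 400 µm⁻¹`, `Ka = 1e-3 µm³`,
`Ke = 2`, `λ = 0.5`, `rc = 0.1` µm, `diff_u = 1` µm²/s.  Notes: the
kinesin-1 walking speed 1 µm/s is the one experimentally constrained value in
the gliding benchmark; XCTK2 is a kinesin-14 with one motile motor end and a
passive microtubule-binding tail, hence `active = (True, False)` — modeling
it with two walking heads makes antiparallel gels slide at ~2·vm instead of
the observed sub-vm straining velocity — and kinesin-14s accumulate at and
pause on minus ends (their aster-forming role), hence `end_behavior = pause`;
the aster motor's `vm = 0.1` µm/s
follows from the stated mean end-arrival time `τ_walk = L/vm ≈ 5 s` for
0.5 µm filaments.  `Ka`/`Ke` conventions make all rates s⁻¹ with `ε` a linear
site density; their absolute values set bound fractions (here: heavily
crosslinked regimes) and are reconstructions, not measurements.

## Scenario generators and problem sizes

All scenarios are generated programmatically from (parameters, seed); there
are no external data files.  The gliding assay anchors motor head A at
uniform random positions on an immobile, non-bindable substrate rod with a
periodic track so the carpet is unbounded; the cargo starts one tether rest
length above the substrate surface.  The nematic tube and confined cylinder
insert axial rods by rejection sampling (overlap-free by construction); the
isotropic bulk and spherical shell resolve residual overlaps with a short
athermal constraint-only relaxation (an overlap disappears in O(1) implicit
steps).

Desk-scale sizes used by the test suite and `scripts/acceptance.py` (chosen
for a single CPU; physical parameters unchanged):

* gliding assay: 1 filament (L = 1 µm), 100 motors, 10 s — the published
  configuration.
* antiparallel tube: 20 filaments × 8 motors/filament at 30% volume
  fraction (x-period 1.2 µm), 11 s with 10 s velocity averaging, athermal
  filaments (the crosslinked gel is kinetically caged; the sliding velocity
  is motor-set, matching the athermal treatment of the published
  nematic-bundle sliding measurement); the test suite uses 16 filaments.
  Published runs: 3000 filaments, 10-30 motors/filament — within that
  study's range Vx was reported insensitive to motor count, which the suite
  re-checks at reduced scale (and confirms: 8-20 motors/filament and
  thermal vs athermal all give the same Vx here).
* bulk aster: 100 filaments / 200 motors in a 1.75 µm periodic box (the
  published number density), Brownian on, 9.5 s, pair correlations over the
  final 3 s; the test suite uses 120 filaments in 1.86 µm for 10 s.
  Published: 40,000/80,000 in 10 µm for 35 s.
* shell and confined cylinder: smoke-scale analogues asserting invariants
  (confinement integrity, order-parameter ranges), not printed numbers.

What the generators do **not** emulate: filament flexibility, dynamic
instability, hydrodynamic coupling between filaments, motor-motor steric
exclusion.  Passing tests therefore validate the rigid-filament,
local-drag model class, not those effects.

## Measurement protocols

* Local nematic order: `S_local = √(3/2 Q:Q)` with `Q = ⟨p̂p̂⟩ − δ/3`
  averaged over a filament plus its directly crosslinked neighbors.
* Axial order profile: windowed average of `½(3cos²θ − 1)` with weights
  equal to the centerline arclength inside the window (the window weight is
  not fully specified in the source; arclength overlap is this package's
  choice).  Empty windows report NaN, not zero.
* Minus-end RDF: minimum-image pair histogram, ideal-gas normalized, 2 nm
  bins; peak radii located on a 3-bin smoothed curve within physically
  distinct windows (contact region 18-45 nm, crosslink region 55-110 nm).
* Virial stress: `σ = (1/V) Σ f ⊗ d` per constraint, with `f = γn̂` on the
  first body and `d` the minimum-image branch vector between application
  points — closest centerline points for collisions (sign-safe under
  overlap), attachment points for tethers.  Pushed-apart overlaps give
  extensile `Π_col > 0`; stretched tethers contractile `Π_xl < 0`;
  `Π = ⅓ Tr σ`.
* Straining velocity: virtual sampling planes orthogonal to x, five square
  0.2 µm windows per plane (center + half-window compass offsets);
  per window `Px` is the mean director x-component of crossing filaments,
  `V±x` the mean unwrapped x-velocity of +x/−x movers over the averaging
  interval (10 s, matching the photobleaching protocol), `Vx = V+x − V−x`;
  windows missing either mover group are dropped.
* Polarity divergence: central-difference divergence of the windowed mean
  director field, non-dimensionalized by filament length.

## Known limitations

* The kMC is first-order in `h`: occupancy statistics carry O(R·h) bias;
  the detailed-balance suite sizes `h` so this bias is far below its
  statistical resolution at 10⁶ events.
* Contact resolution lags by one step (see timestep guidance); deep
  overlaps of near-parallel rods at too-large `h` make the closest-point
  normal ill-conditioned.
* The Brownian rotation update omits higher-order drift corrections; it is
  validated against the Einstein relations, not against a specific
  reference discretization.
* BBPGD iteration counts grow on heavily crosslinked dense networks
  (hundreds per step); the per-run log records iterations and residuals.
* At 16-40 filaments the antiparallel nematic slides at ~0.8·vm
  (37-40 nm/s for vm = 46 nm/s), insensitive to motor density and to
  thermal motion; the published sub-vm collective braking (~26 nm/s at
  3000 filaments) does not emerge at these system sizes.
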