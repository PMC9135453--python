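"""Deterministic, seedable generators of the study's initial conditions.

Every generator is a pure function of its parameters and a seed.  The motor
parameter sets below are reconstructions assembled from literature-typical
single-molecule values (walking speeds, stall forces, tether stiffness and
rest lengths of kinesin-1-, XCTK2/kinesin-14- and dynein-like motors); they
are shipped as editable defaults, not as measured fits.

Scenarios:

* gliding assay — one microtubule transported over a carpet of
  surface-anchored motors (mixed active/inactive), the classic motility
  benchmark.  The surface is modeled as an immobile filament-like substrate
  so anchored heads reuse the standard attachment bookkeeping; the track is
  periodic along x so the carpet is effectively unbounded.
* antiparallel nematic tube — densely packed (≈30% volume fraction) ±x
  filaments in an x-periodic cylinder with crosslinking motors, the
  self-straining network geometry.
* bulk isotropic suspension — uniform isotropic filaments plus unbound
  end-pausing minus-end motors in a periodic box; condenses into asters.
* spherical shell / confined cylinder — confined analogues (polarity
  sorting, polarity-sorted bilayers vs bottle-brushes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boundaries import Boundary, CylinderX, PeriodicBox, SphericalShell, make_boundary
from .geometry import ConfigurationError, FilamentSet, KBT_ROOM
from .kinetics import SA, MotorParams, MotorPopulation, U
from .state import SystemState

# ----------------------------------------------------------------------------
# Motor species (reconstructed parameter sets; see docs/methods.md)
# ----------------------------------------------------------------------------

SPECIES: dict[str, MotorParams] = {
    # plus-end-directed transporter; free velocity 1 µm/s (the one
    # experimentally constrained value in the gliding benchmark)
    "kinesin1": MotorParams(
        name="kinesin1", kappa=100.0, ell0=0.053, vm=1.0, fstall=5.0,
        ko_s=1.0, ko_d=1.0, ka=1.0e-3, ke=2.0, lam=0.5, rc=0.1, eps=400.0,
        diff_u=1.0, direction=(1, 1), end_behavior="detach",
        slack_tether=True,
    ),
    # minus-end-directed kinesin-14-family crosslinker (XCTK2/NCD-like):
    # one motile motor end walking at 46 nm/s plus one passive
    # microtubule-binding tail (head B crosslinks but does not step)
    "xctk2": MotorParams(
        name="xctk2", kappa=100.0, ell0=0.053, vm=0.046, fstall=1.0,
        ko_s=1.0, ko_d=1.0, ka=1.0e-3, ke=2.0, lam=0.5, rc=0.1, eps=400.0,
        diff_u=1.0, direction=(-1, -1), active=(True, False),
        end_behavior="pause",
    ),
    # minus-end-directed, end-pausing aster former; vm = L/τ_walk ≈ 0.1 µm/s
    # for 0.5 µm filaments
    "aster_motor": MotorParams(
        name="aster_motor", kappa=100.0, ell0=0.053, vm=0.1, fstall=5.0,
        ko_s=1.0, ko_d=1.0, ka=1.0e-3, ke=2.0, lam=0.5, rc=0.1, eps=400.0,
        diff_u=1.0, direction=(-1, -1), end_behavior="pause",
    ),
    # processive minus-end-directed transporter that detaches at the end
    "dynein": MotorParams(
        name="dynein", kappa=100.0, ell0=0.053, vm=1.0, fstall=1.25,
        ko_s=1.0, ko_d=1.0, ka=1.0e-3, ke=2.0, lam=0.5, rc=0.1, eps=400.0,
        diff_u=1.0, direction=(-1, -1), end_behavior="detach",
    ),
}


def get_species(spec) -> MotorParams:
    """Species name, mapping of overrides, or a MotorParams instance."""
    if isinstance(spec, MotorParams):
        return spec
    if isinstance(spec, str):
        if spec not in SPECIES:
            raise ConfigurationError(
                f"unknown motor species '{spec}' (known: {sorted(SPECIES)})"
            )
        return SPECIES[spec]
    if isinstance(spec, dict):
        base = SPECIES[spec["species"]] if "species" in spec else MotorParams()
        over = {k: v for k, v in spec.items() if k != "species"}
        if "direction" in over:
            over["direction"] = tuple(over["direction"])
        if "active" in over:
            over["active"] = tuple(over["active"])
        return base.with_(**over)
    raise ConfigurationError("motor spec must be a species name, mapping, or MotorParams")


@dataclass
class ScenarioSpec:
    """Resolved scenario description (bookkeeping for configs and logs)."""

    name: str
    boundary: Boundary
    n_filaments: int
    filament_length: float
    filament_diameter: float
    n_motors: int
    motor: MotorParams
    seed: int


# ----------------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------------

def quat_from_director(u: np.ndarray) -> np.ndarray:
    """Quaternion rotating the reference axis (0,0,1) onto unit vector u."""
    u = np.asarray(u, dtype=float)
    z = np.array([0.0, 0.0, 1.0])
    c = float(u @ z)
    if c < -1.0 + 1e-12:
        return np.array([0.0, 1.0, 0.0, 0.0])  # 180° about x
    axis = np.cross(z, u)
    q = np.concatenate([[1.0 + c], axis])
    return q / np.linalg.norm(q)


def random_unit_vectors(rng, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def max_overlap(state: SystemState) -> float:
    """Largest surface overlap depth (µm); 0 when fully non-overlapping."""
    from .constraints import collect_collisions

    uni = collect_collisions(state, buffer=0.0)
    if uni.n == 0:
        return 0.0
    return float(max(0.0, -np.min(uni.phi)))


def relax_overlaps(state: SystemState, h: float = 1e-4, max_steps: int = 2000, tol: float = None) -> int:
    """Athermal, motor-free constraint relaxation of initial overlaps.

    The implicit complementarity step removes a detected overlap in O(1)
    steps; returns the number of steps taken."""
    from .constraints import assemble_qp, bbpgd_solve, collect_collisions, constraint_forces
    from .geometry import advance_configuration, mobility_apply

    if tol is None:
        tol = 1e-3 * float(np.min(state.filaments.diameters))
    for step in range(max_steps):
        uni = collect_collisions(state)
        if uni.n == 0 or np.min(uni.phi) > -tol:
            return step
        from .constraints import ConstraintBlock

        qp = assemble_qp(state, uni, ConstraintBlock.empty(bilateral=True), None, h)
        gamma, _ = bbpgd_solve(qp)
        U6 = mobility_apply(state.filaments, constraint_forces(qp, gamma))
        advance_configuration(state.filaments, U6, h, state.boundary)
    raise ConfigurationError(
        f"overlap relaxation did not converge in {max_steps} steps "
        f"(residual overlap {max_overlap(state):.2e} µm)"
    )


def _uniform_points(rng, boundary: Boundary, n: int, margin: float = 0.0) -> np.ndarray:
    if isinstance(boundary, PeriodicBox):
        return rng.random((n, 3)) * boundary.lengths
    if isinstance(boundary, CylinderX):
        R = 0.5 * boundary.diameter - margin
        x = rng.random(n) * boundary.period
        r = R * np.sqrt(rng.random(n))
        th = rng.random(n) * 2 * np.pi
        return np.stack([x, r * np.cos(th), r * np.sin(th)], axis=1)
    if isinstance(boundary, SphericalShell):
        lo, hi = boundary.r_in + margin, boundary.r_out - margin
        u = random_unit_vectors(rng, n)
        r = (lo**3 + rng.random(n) * (hi**3 - lo**3)) ** (1.0 / 3.0)
        return u * r[:, None]
    raise ConfigurationError(f"cannot draw uniform points in boundary '{boundary.kind}'")


# ----------------------------------------------------------------------------
# Scenario generators
# ----------------------------------------------------------------------------

def gen_gliding_assay(
    n_motors: int = 100,
    n_active: int = 100,
    length: float = 1.0,
    diameter: float = 0.025,
    track_period: float = 1.0,
    track_width: float = 0.12,
    n_tracks: int = 1,
    substrate_diameter: float = 0.002,
    motor="kinesin1",
    seed: int = 0,
    eta: float = 0.01,
) -> SystemState:
    """Surface gliding assay: one microtubule over an anchored motor carpet.

    The surface is one or more immobile, non-bindable substrate rods along x;
    each motor's head A is permanently anchored at a uniform random position
    along one track period (track drawn uniformly when n_tracks > 1), head B
    binds and walks on the microtubule.  n_active of the motors walk at vm;
    the rest are inactive (vm = 0 crosslinkers).  The cargo microtubule is
    the last filament.

    The substrate rod is hairline-thin by default: it stands for the anchor
    points atop the motor stalks, not for the coverslip (which lies below
    and is never reached — tether compression pushes the cargo back long
    before contact).  A thick substrate rod at anchor height acts as a
    pivot that lets the driven cargo pole-vault off the carpet.
    """
    if not 0 <= n_active <= n_motors:
        raise ConfigurationError("need 0 <= n_active <= n_motors")
    if n_tracks < 1:
        raise ConfigurationError("need at least one anchor track")
    rng = np.random.default_rng(seed)
    params = get_species(motor)
    box = PeriodicBox(lengths=np.array([track_period, 4.0 * length, 4.0 * length]))
    y0 = 2.0 * length
    z_sub = 2.0 * length
    gap0 = params.ell0 + 0.5 * (diameter + substrate_diameter)  # rest height
    ez = np.array([1.0, 0.0, 0.0])
    if n_tracks == 1:
        ys = np.array([y0])
    else:
        ys = y0 + np.linspace(-0.5 * track_width, 0.5 * track_width, n_tracks)
    centers = [[0.5 * track_period, y, z_sub] for y in ys]
    centers.append([0.5 * track_period, y0, z_sub + gap0])
    filset = FilamentSet(
        centers=np.array(centers),
        quats=np.array([quat_from_director(ez)] * (n_tracks + 1)),
        lengths=[track_period + length + 0.2] * n_tracks + [length],
        diameters=[substrate_diameter] * n_tracks + [diameter],
        mobile=[False] * n_tracks + [True],
        bindable=[False] * n_tracks + [True],
        eta=eta,
    )
    pop = MotorPopulation(params, n_motors)
    pop.state[:] = SA
    pop.fil[:, 0] = rng.integers(0, n_tracks, n_motors)
    pop.arc[:, 0] = (rng.random(n_motors) - 0.5) * track_period
    pop.locked[:, 0] = True
    active = np.zeros(n_motors, dtype=bool)
    active[rng.permutation(n_motors)[:n_active]] = True
    pop.active[:, 0] = False
    pop.active[:, 1] = active
    return SystemState(filaments=filset, motors=[pop], boundary=box, rng=rng, kbt=KBT_ROOM)


def _insert_axial_rods(
    rng, n: int, boundary, length: float, diameter: float, max_tries: int = 200000
):
    """Sequential random insertion of x-aligned rods without surface overlap."""
    centers = np.empty((n, 3))
    placed = 0
    tries = 0
    while placed < n:
        tries += 1
        if tries > max_tries:
            raise ConfigurationError(
                f"packing infeasible: placed {placed}/{n} axial rods after {max_tries} tries"
            )
        c = _uniform_points(rng, boundary, 1, margin=0.5 * diameter)[0]
        if placed:
            prev = centers[:placed]
            dx = np.abs(boundary.min_image(c - prev)[:, 0])
            dyz = c[1:] - prev[:, 1:]
            dyz2 = np.einsum("ij,ij->i", dyz, dyz)
            # exact centerline distance of parallel x-aligned rods
            gap_x = np.maximum(dx - length, 0.0)
            close = gap_x * gap_x + dyz2 < diameter * diameter
            if np.any(close):
                continue
        centers[placed] = c
        placed += 1
    return centers


def gen_nematic_tube(
    n_filaments: int,
    motors_per_filament: float,
    tube_diameter: float,
    period: float,
    length: float = 0.5,
    diameter: float = 0.025,
    motor="xctk2",
    seed: int = 0,
    eta: float = 0.01,
) -> SystemState:
    """Antiparallel nematic tube: ±x filaments at high packing in an
    x-periodic cylinder, motors initially unbound and uniformly distributed.

    Polarity split is exact (|#+x − #−x| ≤ 1); insertion is rejection
    sampling so the generated state is overlap-free by construction.
    """
    rng = np.random.default_rng(seed)
    boundary = CylinderX(diameter=tube_diameter, period=period)
    centers = _insert_axial_rods(rng, n_filaments, boundary, length, diameter)
    plus = np.zeros(n_filaments, dtype=bool)
    plus[rng.permutation(n_filaments)[: (n_filaments + 1) // 2]] = True
    qplus = quat_from_director(np.array([1.0, 0.0, 0.0]))
    qminus = quat_from_director(np.array([-1.0, 0.0, 0.0]))
    quats = np.where(plus[:, None], qplus, qminus)
    filset = FilamentSet(
        centers=centers, quats=quats,
        lengths=np.full(n_filaments, length), diameters=np.full(n_filaments, diameter),
        mobile=np.ones(n_filaments, dtype=bool), bindable=np.ones(n_filaments, dtype=bool),
        eta=eta,
    )
    n_motors = int(round(motors_per_filament * n_filaments))
    pop = MotorPopulation(get_species(motor), n_motors)
    pop.state[:] = U
    pop.x = _uniform_points(rng, boundary, n_motors)
    return SystemState(filaments=filset, motors=[pop], boundary=boundary, rng=rng, kbt=KBT_ROOM)


def gen_bulk_isotropic(
    n_filaments: int,
    n_motors: int,
    box_lengths,
    length: float = 0.5,
    diameter: float = 0.025,
    motor="aster_motor",
    seed: int = 0,
    eta: float = 0.01,
    relax: bool = True,
) -> SystemState:
    """Bulk isotropic suspension in a periodic box; motors all unbound."""
    rng = np.random.default_rng(seed)
    boundary = PeriodicBox(lengths=np.asarray(box_lengths, dtype=float))
    centers = _uniform_points(rng, boundary, n_filaments)
    dirs = random_unit_vectors(rng, n_filaments)
    quats = np.array([quat_from_director(u) for u in dirs])
    filset = FilamentSet(
        centers=centers, quats=quats,
        lengths=np.full(n_filaments, length), diameters=np.full(n_filaments, diameter),
        mobile=np.ones(n_filaments, dtype=bool), bindable=np.ones(n_filaments, dtype=bool),
        eta=eta,
    )
    pop = MotorPopulation(get_species(motor), n_motors)
    pop.state[:] = U
    pop.x = _uniform_points(rng, boundary, n_motors)
    state = SystemState(filaments=filset, motors=[pop], boundary=boundary, rng=rng, kbt=KBT_ROOM)
    if relax:
        relax_overlaps(state)
    return state


def gen_spherical_shell(
    n_filaments: int,
    n_motors: int,
    r_in: float = 5.0,
    r_out: float = 5.102,
    length: float = 0.25,
    diameter: float = 0.025,
    motor="dynein",
    seed: int = 0,
    eta: float = 0.01,
    relax_steps: int = 2000,
) -> SystemState:
    """Filaments between two concentric shells, aligned along ±e_θ (meridians);
    overlaps resolved by an athermal relaxation pass before motors are added."""
    if r_out - r_in <= diameter:
        raise ConfigurationError("shell gap must exceed the filament diameter")
    rng = np.random.default_rng(seed)
    boundary = SphericalShell(r_in=r_in, r_out=r_out)
    centers = _uniform_points(rng, boundary, n_filaments, margin=0.5 * diameter)
    rhat = centers / np.linalg.norm(centers, axis=1, keepdims=True)
    # polar basis vector e_θ at each point (meridian direction)
    zax = np.array([0.0, 0.0, 1.0])
    eth = np.cross(np.cross(rhat, zax), rhat)
    nrm = np.linalg.norm(eth, axis=1, keepdims=True)
    # points at the poles get an arbitrary tangent
    bad = nrm[:, 0] < 1e-8
    eth[bad] = np.cross(rhat[bad], np.array([1.0, 0.0, 0.0]))
    nrm[bad] = np.linalg.norm(eth[bad], axis=1, keepdims=True)
    eth /= nrm
    sign = np.where(rng.random(n_filaments) < 0.5, 1.0, -1.0)
    quats = np.array([quat_from_director(s * u) for s, u in zip(sign, eth)])
    filset = FilamentSet(
        centers=centers, quats=quats,
        lengths=np.full(n_filaments, length), diameters=np.full(n_filaments, diameter),
        mobile=np.ones(n_filaments, dtype=bool), bindable=np.ones(n_filaments, dtype=bool),
        eta=eta,
    )
    state = SystemState(filaments=filset, motors=[], boundary=boundary, rng=rng, kbt=KBT_ROOM)
    relax_overlaps(state, max_steps=relax_steps)
    pop = MotorPopulation(get_species(motor), n_motors)
    pop.state[:] = U
    pop.x = _uniform_points(rng, boundary, n_motors)
    state.motors = [pop]
    return state


def gen_confined_cylinder(
    n_filaments: int,
    n_motors: int,
    cylinder_diameter: float,
    period: float,
    length: float = 0.25,
    diameter: float = 0.025,
    motor="aster_motor",
    seed: int = 0,
    eta: float = 0.01,
) -> SystemState:
    """Axially aligned ±x filaments in an impermeable x-periodic cylinder."""
    if cylinder_diameter <= diameter:
        raise ConfigurationError("cylinder diameter must exceed the filament diameter")
    rng = np.random.default_rng(seed)
    boundary = CylinderX(diameter=cylinder_diameter, period=period)
    centers = _insert_axial_rods(rng, n_filaments, boundary, length, diameter)
    plus = np.zeros(n_filaments, dtype=bool)
    plus[rng.permutation(n_filaments)[: n_filaments // 2]] = True
    qplus = quat_from_director(np.array([1.0, 0.0, 0.0]))
    qminus = quat_from_director(np.array([-1.0, 0.0, 0.0]))
    quats = np.where(plus[:, None], qplus, qminus)
    filset = FilamentSet(
        centers=centers, quats=quats,
        lengths=np.full(n_filaments, length), diameters=np.full(n_filaments, diameter),
        mobile=np.ones(n_filaments, dtype=bool), bindable=np.ones(n_filaments, dtype=bool),
        eta=eta,
    )
    pop = MotorPopulation(get_species(motor), n_motors)
    pop.state[:] = U
    pop.x = _uniform_points(rng, boundary, n_motors)
    return SystemState(filaments=filset, motors=[pop], boundary=boundary, rng=rng, kbt=KBT_ROOM)


def spherocylinder_volume(length: float, diameter: float) -> float:
    return np.pi * diameter**2 * length / 4.0 + np.pi * diameter**3 / 6.0


GENERATORS = {
    "gliding_assay": gen_gliding_assay,
    "nematic_tube": gen_nematic_tube,
    "bulk_isotropic": gen_bulk_isotropic,
    "spherical_shell": gen_spherical_shell,
    "confined_cylinder": gen_confined_cylinder,
}


def build_scenario(spec: dict, seed: int = None) -> SystemState:
    """Build a SystemState from a scenario config mapping
    (key 'name' selects the generator; remaining keys are its arguments)."""
    if "name" not in spec:
        raise ConfigurationError("scenario config needs a 'name' key")
    name = spec["name"]
    if name not in GENERATORS:
        raise ConfigurationError(
            f"unknown scenario '{name}' (known: {sorted(GENERATORS)})"
        )
    kwargs = {k: v for k, v in spec.items() if k != "name"}
    if seed is not None:
        kwargs["seed"] = seed
    gen = GENERATORS[name]
    import inspect

    valid = set(inspect.signature(gen).parameters)
    unknown = set(kwargs) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown scenario keys for '{name}': {sorted(unknown)} "
            f"(accepted: {sorted(valid)})"
        )
    return gen(**kwargs)
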