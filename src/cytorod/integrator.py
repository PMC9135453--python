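"""Timestep orchestration: Brownian forcing and the linearized implicit step.

Each step executes the three tasks in sequence:

1. motor motion — unbound motors diffuse, bound heads co-move with their
   filaments and step along them with the force-velocity law;
2. motor binding/unbinding — one kinetic Monte Carlo sweep;
3. filament motion — collect collision and tether constraints, assemble and
   solve the convex QP, then advance positions/orientations with
   U = M (Fu + Fb + Fnc).

Thermal motion enters as an effective non-constraint force Fnc with
covariance 2 kBT M⁻¹ / h per step (body frame, anisotropic translation +
transverse rotation), so collisions resist thermal overlap inside the same
implicit solve.  The implicit treatment of stiff tether springs removes the
explicit-Euler step-size restriction h < 2/λ (λ = N κ_xl / ζ): the scheme is
stable for h λ ≫ 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constraints import (
    assemble_qp,
    bbpgd_solve,
    collect_collisions,
    collect_tethers,
    constraint_forces,
    residuals,
)
from .geometry import KBT_ROOM, ConfigurationError, advance_configuration, mobility_apply
from .kinetics import diffuse_unbound, move_bound_heads, sample_events
from .state import SystemState


@dataclass
class StepConfig:
    """Per-step numerical parameters.

    h: timestep (s), default 1e-4.  kbt: thermal energy (pN·µm); kbt = 0 or
    brownian = False gives the athermal (deterministic) mode.
    """

    h: float = 1e-4
    kbt: float = KBT_ROOM
    brownian: bool = True
    collision_buffer: float = None     # default 0.3·max(D) inside collect_collisions
    solver_tol: float = None           # default 1e-6·max(1, ‖q‖∞)
    solver_max_iter: int = 5000
    check_residuals: bool = False

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ConfigurationError("timestep h must be positive")
        if self.kbt < 0:
            raise ConfigurationError("kbt must be non-negative")


def brownian_kick(state: SystemState, cfg: StepConfig, rng: np.random.Generator) -> np.ndarray:
    """Random non-constraint force with ⟨F Fᵀ⟩ = 2 kBT M⁻¹ / h.

    Passed through the QP's q so the constraint solve sees thermal forcing.
    The resulting free-filament displacement over one step has covariance
    2 kBT M h (Einstein relation); axial spin torque is omitted (null mode).
    """
    filset = state.filaments
    n = filset.n
    if not cfg.brownian or cfg.kbt == 0.0:
        return np.zeros(6 * n)
    p = filset.directors()
    xi = rng.standard_normal((n, 5))
    pref = np.sqrt(2.0 * cfg.kbt / cfg.h)
    # orthonormal transverse frame (e1, e2) ⟂ p
    ref = np.zeros((n, 3))
    ref[np.arange(n), np.argmin(np.abs(p), axis=1)] = 1.0
    e1 = np.empty_like(p)
    e1[:, 0] = p[:, 1] * ref[:, 2] - p[:, 2] * ref[:, 1]
    e1[:, 1] = p[:, 2] * ref[:, 0] - p[:, 0] * ref[:, 2]
    e1[:, 2] = p[:, 0] * ref[:, 1] - p[:, 1] * ref[:, 0]
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.empty_like(p)
    e2[:, 0] = p[:, 1] * e1[:, 2] - p[:, 2] * e1[:, 1]
    e2[:, 1] = p[:, 2] * e1[:, 0] - p[:, 0] * e1[:, 2]
    e2[:, 2] = p[:, 0] * e1[:, 1] - p[:, 1] * e1[:, 0]
    F = np.zeros((n, 6))
    F[:, :3] = pref * (
        np.sqrt(filset.zeta_par)[:, None] * xi[:, 0:1] * p
        + np.sqrt(filset.zeta_perp)[:, None] * (xi[:, 1:2] * e1 + xi[:, 2:3] * e2)
    )
    F[:, 3:] = pref * np.sqrt(filset.zeta_rot)[:, None] * (xi[:, 3:4] * e1 + xi[:, 4:5] * e2)
    F[~filset.mobile] = 0.0
    return F.reshape(-1)


def timestep(state: SystemState, cfg: StepConfig) -> dict:
    """Advance the system by one step h; returns per-step diagnostics."""
    rng = state.rng
    h = cfg.h

    # task 1: motor diffusion and stepping
    diffuse_unbound(state, h, rng)
    move_bound_heads(state, h)

    # task 2: binding / unbinding
    events = sample_events(state, h, rng)

    # task 3: filament dynamics
    Fnc = brownian_kick(state, cfg, rng)
    if state.external_force is not None:
        Fnc = Fnc + state.external_force
    uni = collect_collisions(state, cfg.collision_buffer)
    bil = collect_tethers(state)
    diag = {
        "time": state.time,
        "n_unilateral": uni.n,
        "n_bilateral": bil.n,
        "iterations": 0,
        "residual": 0.0,
        **events,
    }
    if uni.n + bil.n > 0:
        qp = assemble_qp(state, uni, bil, Fnc, h)
        gamma0 = _warm_start_vector(state, qp)
        gamma, info = bbpgd_solve(qp, tol=cfg.solver_tol, max_iter=cfg.solver_max_iter, gamma0=gamma0)
        state.warm_start = dict(zip(qp.uni.keys + qp.bil.keys, gamma))
        F = Fnc + constraint_forces(qp, gamma)
        diag["iterations"] = info["iterations"]
        diag["residual"] = info["residual"]
        diag["tol"] = info.get("tol", 0.0)
        diag["gamma"] = gamma
        diag["qp"] = qp
        if cfg.check_residuals:
            comp, bres = residuals(qp, gamma, Fnc)
            diag["complementarity_residual"] = comp
            diag["bilateral_residual"] = bres
    else:
        state.warm_start = {}
        F = Fnc
    U = mobility_apply(state.filaments, F)
    if not np.all(np.isfinite(U)):
        raise FloatingPointError("non-finite velocities: aborting step")
    advance_configuration(state.filaments, U, h, state.boundary)
    state.time += h
    state.step_index += 1
    return diag


def _warm_start_vector(state: SystemState, qp) -> np.ndarray:
    """Previous-step γ per persistent constraint; rows new this step start
    from 0 (contacts) or the local Hookean value −κ(ℓf−ℓ0) (tethers), which
    cancels a fresh tether's 1/h forcing term exactly."""
    prev = state.warm_start
    gamma0 = np.empty(qp.n)
    for k, key in enumerate(qp.uni.keys):
        gamma0[k] = prev.get(key, 0.0)
    if qp.nb:
        hook = -qp.bil.kappa * (qp.bil.phi - qp.bil.rest)
        for k, key in enumerate(qp.bil.keys):
            gamma0[qp.nu + k] = prev.get(key, hook[k])
    return gamma0


def run(state: SystemState, cfg: StepConfig, n_steps: int, recorders=()) -> list[dict]:
    """Run n_steps timesteps, invoking each recorder as recorder(state, diag).

    Returns the list of per-step diagnostic dicts (without the bulky gamma/qp
    entries)."""
    log = []
    for _ in range(n_steps):
        diag = timestep(state, cfg)
        for rec in recorders:
            rec(state, diag)
        log.append({k: v for k, v in diag.items() if k not in ("gamma", "qp")})
    return log
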