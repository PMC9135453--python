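"""Four-state crosslinking-motor model: stepping, binding kinetics, tethers.

A crosslinker is a Hookean spring with two binding heads (A and B) and four
states: unbound (U), singly bound through A or B (SA/SB), doubly bound (D).
Transition rates follow a free-energy landscape so that in the passive limit
(walking speed vm = 0) the bound-site distribution relaxes to the Boltzmann
distribution of the tether energy E(ℓ) = ½ κ_xl (ℓf − ℓ0)² — detailed balance:
the ratio of the doubly-binding site density to the doubly-unbinding rate is
∝ exp(−βE) independent of the energy-partition factor λ.

Rates (per head):

    U → S   :  ko_S · (3 ε Ka / 4π rc³) · Σ_i L_in,i(x)
    S → U   :  ko_S
    S → D   :  ko_D · ε Ke · Σ_j ∫ ds_j exp[−(1−λ) β E(ℓf(s))]
    D → S   :  ko_D · exp[+λ β E(ℓf)]

L_in,i(x) is the centerline arclength of filament i inside the capture sphere
of radius rc about the head position x; ε is the linear density of binding
sites.  The tether spans the filament *surfaces*: for attachment points P1,
P2 on the two centerlines, ℓf = |P1 − P2| − (r_i + r_j) clamped at zero.
(This makes the rest centerline separation of two crosslinked filaments
ℓ0 + Dfil, the scale read off from minus-end pair correlations of
motor-condensed filament networks.)

Event sampling treats each head as an inhomogeneous Poisson process frozen at
start-of-step rates: P(fire in h) = 1 − exp(−R(0) h), at most one transition
per head per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .boundaries import Boundary, point_filament_candidates
from .geometry import ConfigurationError, FilamentSet, KBT_ROOM

# crosslinker states
U, SA, SB, D = 0, 1, 2, 3
STATE_NAMES = {U: "U", SA: "SA", SB: "SB", D: "D"}

# binding-weight cutoff: sites with βE beyond this contribute < 1e-8 and are
# excluded from the S→D integral (bounded-cost integration)
ENERGY_CUTOFF_KBT = 20.0
# quadrature nodes per candidate filament for the S→D integral / site sampling
SD_QUAD_NODES = 256


@dataclass
class MotorParams:
    """Kinetic and mechanical parameters of one crosslinker/motor species.

    Units: kappa pN/µm, ell0 µm, vm µm/s, fstall pN, ko_s & ko_d 1/s,
    ka µm³, ke dimensionless (with the linear site density eps in µm⁻¹),
    rc µm, diff_u µm²/s.  direction: per head, +1 = plus-end-directed,
    −1 = minus-end-directed.  end_behavior: 'pause' clamps a head that
    reaches its target end, 'detach' releases it.
    """

    name: str = "motor"
    kappa: float = 100.0
    ell0: float = 0.05
    vm: float = 1.0
    fstall: float = 5.0
    ko_s: float = 1.0
    ko_d: float = 1.0
    ka: float = 1.0e-3
    ke: float = 2.0
    lam: float = 0.5
    rc: float = 0.2
    eps: float = 400.0
    diff_u: float = 1.0
    direction: tuple[int, int] = (1, 1)
    active: tuple[bool, bool] = (True, True)
    end_behavior: str = "detach"
    allow_same_filament: bool = False
    slack_tether: bool = False     # tension-only tether (stalk buckles, no push)
    force_dependent: bool = False  # hook: replace E(ℓ) by F(ℓ) in S⇌D rates

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.ell0 < 0:
            raise ConfigurationError("kappa and ell0 must be non-negative")
        if min(self.ko_s, self.ko_d, self.ka, self.ke, self.eps, self.rc) < 0:
            raise ConfigurationError("rates and association constants must be non-negative")
        if not 0.0 <= self.lam <= 1.0:
            raise ConfigurationError("energy partition factor lam must lie in [0, 1]")
        if any(self.active) and self.fstall <= 0:
            raise ConfigurationError("active heads require fstall > 0")
        if self.end_behavior not in ("pause", "detach", "wrap"):
            raise ConfigurationError("end_behavior must be 'pause', 'detach' or 'wrap'")
        if tuple(self.direction) not in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            raise ConfigurationError("direction entries must be ±1")

    def with_(self, **kw) -> "MotorParams":
        return replace(self, **kw)


@dataclass
class Crosslinker:
    """Single-crosslinker view (bulk data lives in MotorPopulation)."""

    id: int
    params: MotorParams
    state: int
    x: np.ndarray
    fil: tuple[int, int]
    arc: tuple[float, float]

    def bound_heads(self) -> list[int]:
        return {U: [], SA: [0], SB: [1], D: [0, 1]}[self.state]


class MotorPopulation:
    """All crosslinkers of one species, stored columnar."""

    def __init__(self, params: MotorParams, n: int):
        self.params = params
        self.state = np.full(n, U, dtype=np.int8)
        self.x = np.zeros((n, 3))
        self.fil = np.full((n, 2), -1, dtype=np.int64)
        self.arc = np.zeros((n, 2))
        self.active = np.tile(np.asarray(params.active, dtype=bool), (n, 1))
        self.locked = np.zeros((n, 2), dtype=bool)

    @property
    def n(self) -> int:
        return self.state.shape[0]

    def view(self, i: int) -> Crosslinker:
        return Crosslinker(
            id=i,
            params=self.params,
            state=int(self.state[i]),
            x=self.x[i].copy(),
            fil=(int(self.fil[i, 0]), int(self.fil[i, 1])),
            arc=(float(self.arc[i, 0]), float(self.arc[i, 1])),
        )

    def head_bound(self) -> np.ndarray:
        """(n, 2) bool: which heads are attached."""
        out = np.zeros((self.n, 2), dtype=bool)
        out[:, 0] = (self.state == SA) | (self.state == D)
        out[:, 1] = (self.state == SB) | (self.state == D)
        return out

    def check_consistency(self, filset: FilamentSet) -> None:
        bound = self.head_bound()
        if np.any(self.fil[bound] < 0):
            raise ConfigurationError("bound head without filament id")
        if np.any(self.fil[~bound] >= 0):
            raise ConfigurationError("unbound head with stale filament id")
        half = 0.5 * filset.lengths
        for hd in range(2):
            m = bound[:, hd]
            if np.any(np.abs(self.arc[m, hd]) > half[self.fil[m, hd]] + 1e-9):
                raise ConfigurationError("bound arc coordinate outside filament")

    def copy(self) -> "MotorPopulation":
        out = MotorPopulation(self.params, self.n)
        out.state = self.state.copy()
        out.x = self.x.copy()
        out.fil = self.fil.copy()
        out.arc = self.arc.copy()
        out.active = self.active.copy()
        out.locked = self.locked.copy()
        return out


# ----------------------------------------------------------------------------
# Tether mechanics
# ----------------------------------------------------------------------------

def tether_deviation(ellf, params: MotorParams):
    """Signed tether extension ℓf − ℓ0; clamped at 0 for tension-only
    (slack) tethers, whose stalk buckles instead of pushing."""
    dev = np.asarray(ellf, dtype=float) - params.ell0
    if params.slack_tether:
        dev = np.maximum(dev, 0.0)
    return dev


def tether_energy(ellf, params: MotorParams):
    """Hookean tether energy E(ℓ) = ½ κ_xl (ℓf − ℓ0)², pN·µm (zero on the
    compression side for slack tethers)."""
    ellf = np.asarray(ellf, dtype=float)
    if np.any(ellf < 0):
        raise ConfigurationError("tether length must be non-negative")
    return 0.5 * params.kappa * tether_deviation(ellf, params) ** 2


def step_velocity(fproj, params: MotorParams):
    """Linear force-velocity with stall: v_F = vm·max(0, min(1, 1 + F/Fstall)).

    fproj > 0 assists stepping (velocity saturates at vm); fproj = −Fstall
    halts the head.
    """
    if params.fstall <= 0:
        raise ConfigurationError("fstall must be positive")
    return params.vm * np.clip(1.0 + np.asarray(fproj, dtype=float) / params.fstall, 0.0, 1.0)


def _attachment_points(pop: MotorPopulation, filset: FilamentSet, idx: np.ndarray):
    """Attachment points of both heads for doubly bound crosslinkers idx."""
    p = filset.directors()
    a = np.empty((len(idx), 2, 3))
    for hd in range(2):
        f = pop.fil[idx, hd]
        a[:, hd, :] = filset.centers[f] + pop.arc[idx, hd, None] * p[f]
    return a


def tether_separation(pop: MotorPopulation, filset: FilamentSet, boundary: Boundary, idx=None):
    """Vector geometry of all (or selected) doubly bound tethers.

    Returns (idx, ellf, uhat, points) where uhat is the unit vector from head
    B's attachment point toward head A's (minimum image) and ellf the
    surface-to-surface tether length (clamped at 0).
    """
    if idx is None:
        idx = np.nonzero(pop.state == D)[0]
    idx = np.asarray(idx, dtype=int)
    if len(idx) == 0:
        return idx, np.empty(0), np.empty((0, 3)), np.empty((0, 2, 3))
    a = _attachment_points(pop, filset, idx)
    d = boundary.min_image(a[:, 0] - a[:, 1])
    dist = np.linalg.norm(d, axis=1)
    radsum = 0.5 * (
        filset.diameters[pop.fil[idx, 0]] + filset.diameters[pop.fil[idx, 1]]
    )
    ellf = np.maximum(dist - radsum, 0.0)
    uhat = np.zeros_like(d)
    ok = dist > 1e-12
    uhat[ok] = d[ok] / dist[ok, None]
    return idx, ellf, uhat, a


def tether_geometry(xl: Crosslinker, filset: FilamentSet, boundary: Boundary):
    """Spec-level single-crosslinker tether geometry: (ℓf, direction, points)."""
    if xl.state != D:
        raise ConfigurationError("tether geometry requires a doubly bound crosslinker")
    pop = MotorPopulation(xl.params, 1)
    pop.state[0] = D
    pop.fil[0] = xl.fil
    pop.arc[0] = xl.arc
    _, ellf, uhat, a = tether_separation(pop, filset, boundary)
    return float(ellf[0]), uhat[0], a[0]


# ----------------------------------------------------------------------------
# Transition rates
# ----------------------------------------------------------------------------

def _capture_intervals(points, fil_idx, pt_idx, filset: FilamentSet, reach, boundary: Boundary):
    """Arc intervals [lo, hi] of filaments fil_idx within distance `reach` of
    points[pt_idx] (centerline distance), clipped to the filament extent.
    Returns (lo, hi) with lo > hi marking empty intervals."""
    p = filset.directors()[fil_idx]
    dvec = boundary.min_image(points[pt_idx] - filset.centers[fil_idx])
    m = np.einsum("ij,ij->i", p, dvec)
    d2 = np.einsum("ij,ij->i", dvec, dvec)
    disc = m * m - d2 + reach * reach
    half = 0.5 * filset.lengths[fil_idx]
    w = np.sqrt(np.maximum(disc, 0.0))
    lo = np.maximum(m - w, -half)
    hi = np.minimum(m + w, half)
    empty = disc <= 0
    lo[empty], hi[empty] = 1.0, 0.0
    return lo, hi


def rate_U_to_S(x, filset: FilamentSet, params: MotorParams, boundary: Boundary) -> float:
    """Binding rate of one unbound head at position x (s⁻¹)."""
    x = np.asarray(x, dtype=float)
    cand = np.nonzero(filset.bindable)[0]
    if len(cand) == 0:
        return 0.0
    lo, hi = _capture_intervals(
        x[None, :], cand, np.zeros(len(cand), dtype=int), filset, params.rc, boundary
    )
    lin = np.sum(np.maximum(hi - lo, 0.0))
    return params.ko_s * 3.0 * params.eps * params.ka / (4.0 * np.pi * params.rc**3) * lin


def arclength_in_sphere(f, x, rc: float, boundary: Boundary = None) -> float:
    """Centerline arclength of spherocylinder f inside the sphere (x, rc)."""
    boundary = boundary or Boundary()
    filset = FilamentSet(
        centers=f.center[None, :], quats=f.quat[None, :], lengths=[f.length],
        diameters=[f.diameter], mobile=[f.mobile], bindable=[True],
    )
    lo, hi = _capture_intervals(
        np.asarray(x, dtype=float)[None, :], np.array([0]), np.array([0]), filset, rc, boundary
    )
    return float(max(hi[0] - lo[0], 0.0))


@dataclass
class BindingDensity:
    """Discretized S→D binding density of one singly bound head.

    nodes/weights are flattened over candidate filaments; `rate` is the total
    S→D transition rate ko_D·εKe·Σ_j ∫ w ds (s⁻¹).
    """

    rate: float
    fil: np.ndarray      # (K,) candidate filament per node
    s: np.ndarray        # (K,) arc coordinate of node
    w: np.ndarray        # (K,) unnormalized density · node width
    ds: np.ndarray       # (K,) node width

    def sample_site(self, rng) -> tuple[int, float]:
        cum = np.cumsum(self.w)
        if cum[-1] <= 0:
            raise ConfigurationError("cannot sample binding site with zero density")
        k = int(np.searchsorted(cum, rng.random() * cum[-1]))
        k = min(k, len(self.w) - 1)
        s = self.s[k] + (rng.random() - 0.5) * self.ds[k]
        return int(self.fil[k]), float(s)


def rate_S_to_D(
    head_point,
    own_fil: int,
    own_radius: float,
    filset: FilamentSet,
    params: MotorParams,
    boundary: Boundary,
    kbt: float = KBT_ROOM,
) -> BindingDensity:
    """S→D rate of a bound head at head_point attached to filament own_fil.

    Integrates the Boltzmann-weighted linear binding density
    ε Ke exp[−(1−λ) β E(ℓf(s))] over candidate filaments with a fixed
    midpoint quadrature (SD_QUAD_NODES nodes per filament), restricted to
    arcs with βE ≤ ENERGY_CUTOFF_KBT.
    """
    a = np.asarray(head_point, dtype=float)
    rates, (pi, fi, s, w, ds) = _sd_binding_batch(
        a[None, :],
        np.array([own_fil]),
        np.array([own_radius], dtype=float),
        filset, params, boundary, kbt,
    )
    return BindingDensity(rate=float(rates[0]), fil=fi, s=s, w=w, ds=ds)


def _sd_binding_batch(
    points: np.ndarray,
    own_fil: np.ndarray,
    own_radius: np.ndarray,
    filset: FilamentSet,
    params: MotorParams,
    boundary: Boundary,
    kbt: float,
):
    """Vectorized S→D rates for many singly bound heads at once.

    Returns (rates, pair_data) where pair_data = (pi, fi, s, w, ds) holds the
    flattened quadrature grid for binding-site sampling: pi indexes into
    `points`, fi is the candidate filament, s/w/ds the node arc coordinates,
    density·width weights and node widths.
    """
    points = np.atleast_2d(points)
    h = points.shape[0]
    empty = (
        np.zeros(h),
        (np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0), np.empty(0), np.empty(0)),
    )
    if h == 0 or filset.n == 0:
        return empty
    radii = 0.5 * filset.diameters
    if params.kappa > 0:
        stretch = np.sqrt(2.0 * ENERGY_CUTOFF_KBT * kbt / params.kappa)
        search = params.ell0 + stretch + np.max(own_radius) + np.max(radii) + 0.5 * np.max(filset.lengths)
        pi, fi = point_filament_candidates(points, filset, search, boundary)
    else:
        pi = np.repeat(np.arange(h), filset.n)
        fi = np.tile(np.arange(filset.n), h)
    keep = filset.bindable[fi]
    if not params.allow_same_filament:
        keep &= fi != own_fil[pi]
    pi, fi = pi[keep], fi[keep]
    if len(pi) == 0:
        return empty
    if params.kappa > 0:
        reach = params.ell0 + stretch + own_radius[pi] + radii[fi]
    else:
        reach = np.full(len(pi), 1e9)
    lo, hi = _capture_intervals(points, fi, pi, filset, reach, boundary)
    keep = hi > lo
    pi, fi, lo, hi = pi[keep], fi[keep], lo[keep], hi[keep]
    if len(pi) == 0:
        return empty
    ds = (hi - lo) / SD_QUAD_NODES
    s = lo[:, None] + (np.arange(SD_QUAD_NODES) + 0.5)[None, :] * ds[:, None]
    p = filset.directors()[fi]
    dvec = boundary.min_image(points[pi] - filset.centers[fi])
    diff = dvec[:, None, :] - s[:, :, None] * p[:, None, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    ellf = np.maximum(dist - (own_radius[pi] + radii[fi])[:, None], 0.0)
    dev = ellf - params.ell0
    if params.slack_tether:
        dev = np.maximum(dev, 0.0)
    if params.force_dependent:
        barrier = params.kappa * np.abs(dev)
    else:
        barrier = 0.5 * params.kappa * dev ** 2
    w = np.exp(-(1.0 - params.lam) * barrier / kbt) * ds[:, None]
    rates = params.ko_d * params.eps * params.ke * np.bincount(
        pi, weights=w.sum(axis=1), minlength=h
    )
    K = SD_QUAD_NODES
    pair_data = (
        np.repeat(pi, K),
        np.repeat(fi, K),
        s.reshape(-1),
        w.reshape(-1),
        np.repeat(ds, K),
    )
    return rates, pair_data


def rate_D_to_S(ellf, params: MotorParams, kbt: float = KBT_ROOM):
    """Unbinding rate of one head of a doubly bound crosslinker (s⁻¹):
    ko_D·exp[λ β E(ℓf)] (β inserted for dimensional consistency)."""
    if params.force_dependent:
        barrier = params.kappa * np.abs(tether_deviation(ellf, params))
    else:
        barrier = tether_energy(ellf, params)
    return params.ko_d * np.exp(params.lam * barrier / kbt)


# ----------------------------------------------------------------------------
# Stepping and diffusion (task 1 of the per-step sequence)
# ----------------------------------------------------------------------------

def _end_events(pop: MotorPopulation, filset: FilamentSet, head: int, moved: np.ndarray) -> None:
    """Clamp or detach heads that stepped past a filament end."""
    half = 0.5 * filset.lengths[pop.fil[moved, head]]
    s = pop.arc[moved, head]
    over = np.abs(s) > half
    if not np.any(over):
        return
    which = moved[over]
    if pop.params.end_behavior == "pause":
        pop.arc[which, head] = np.clip(pop.arc[which, head], -half[over], half[over])
        return
    if pop.params.end_behavior == "wrap":
        # filament spans a full periodic cell (sterically its own image):
        # carry the head onto the opposite end
        L = 2.0 * half[over]
        pop.arc[which, head] -= np.sign(pop.arc[which, head]) * L
        return
    # detach: place the released head's record at the end point it walked off
    endpoint_arc = np.sign(pop.arc[which, head]) * half[over]
    pop.arc[which, head] = endpoint_arc
    _release_head(pop, filset, which, head)


def _release_head(pop: MotorPopulation, filset: FilamentSet, idx: np.ndarray, head: int) -> None:
    idx = np.asarray(idx, dtype=int)
    if len(idx) == 0:
        return
    p = filset.directors()
    attach = filset.centers[pop.fil[idx, head]] + pop.arc[idx, head, None] * p[pop.fil[idx, head]]
    was_d = pop.state[idx] == D
    pop.state[idx] = np.where(
        was_d, (SB if head == 0 else SA), U
    ).astype(np.int8)
    newly_unbound = idx[~was_d]
    pop.x[newly_unbound] = attach[~was_d]
    pop.fil[idx, head] = -1
    pop.arc[idx, head] = 0.0


def move_bound_heads(state, h: float) -> None:
    """Advance bound motor heads along their filaments over one step.

    Heads co-move with their filament's rigid motion automatically (positions
    are stored as arc coordinates).  Singly bound active heads step at vm;
    doubly bound active heads step at v_F(Fproj) computed from the shared
    tether force with each head's own projection; inactive and locked heads
    do not step.  Heads reaching an end either pause (clamp) or detach.
    """
    filset = state.filaments
    for pop in state.motors:
        params = pop.params
        if params.vm != 0.0:
            p = filset.directors()
            # singly bound heads: unloaded stepping at vm
            for head, st in ((0, SA), (1, SB)):
                idx = np.nonzero((pop.state == st) & pop.active[:, head] & ~pop.locked[:, head])[0]
                if len(idx):
                    pop.arc[idx, head] += params.direction[head] * params.vm * h
                    _end_events(pop, filset, head, idx)
            # doubly bound: force-velocity with the tether force projection
            idx, ellf, uhat, _ = tether_separation(pop, filset, state.boundary)
            if len(idx):
                gam = -params.kappa * tether_deviation(ellf, params)  # <0 stretched
                for head in range(2):
                    sgn = 1.0 if head == 0 else -1.0  # uhat points B→A
                    fvec = gam[:, None] * (sgn * uhat)
                    dstep = params.direction[head] * p[pop.fil[idx, head]]
                    fproj = np.einsum("ij,ij->i", fvec, dstep)
                    vf = step_velocity(fproj, params)
                    ok = pop.active[idx, head] & ~pop.locked[idx, head]
                    move = idx[ok]
                    if len(move):
                        pop.arc[move, head] += params.direction[head] * vf[ok] * h
                        _end_events(pop, filset, head, move)
        else:
            pass  # passive crosslinkers never step


def diffuse_unbound(state, h: float, rng) -> None:
    """Isotropic Brownian point diffusion of unbound motors, reflected at
    impermeable walls (wrapped across periodic faces)."""
    for pop in state.motors:
        if pop.params.diff_u <= 0:
            continue
        idx = np.nonzero(pop.state == U)[0]
        if len(idx) == 0:
            continue
        kick = rng.standard_normal((len(idx), 3)) * np.sqrt(2.0 * pop.params.diff_u * h)
        pop.x[idx] = state.boundary.reflect(pop.x[idx] + kick)


# ----------------------------------------------------------------------------
# Kinetic Monte Carlo event sampling (task 2)
# ----------------------------------------------------------------------------

def _fire(rng, rate, h):
    """Bernoulli draw with P = 1 − exp(−R h) per entry."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ConfigurationError("negative transition rate")
    return rng.random(rate.shape) < -np.expm1(-rate * h)


def sample_events(state, h: float, rng) -> dict:
    """One kMC sweep: evaluate all head transition rates at the current
    geometry and fire each head independently with P = 1 − exp(−R h).

    Transitions move only along U ⇌ (SA, SB) ⇌ D.  If both heads of one
    crosslinker fire in the same step, one of the two events is chosen
    uniformly at random (first-order truncation keeps this O(h²) rare).
    Returns event counts for diagnostics.
    """
    filset = state.filaments
    boundary = state.boundary
    counts = {"bind_us": 0, "unbind_su": 0, "bind_sd": 0, "unbind_ds": 0}
    for pop in state.motors:
        params = pop.params
        n = pop.n
        p_dir = filset.directors()

        # ---- rates and proposed events, all evaluated before any update ----
        fire = np.zeros((n, 2), dtype=bool)
        event = np.zeros((n, 2), dtype=np.int8)  # 0 none, 1 bind, 2 unbind
        sd_density: dict[int, BindingDensity] = {}
        us_sites: dict[tuple[int, int], tuple[int, float]] = {}

        # U heads: binding
        u_idx = np.nonzero(pop.state == U)[0]
        if len(u_idx):
            cand_mask = filset.bindable
            pts = pop.x[u_idx]
            maxhalf = 0.5 * np.max(filset.lengths) if filset.n else 0.0
            pi, fi = point_filament_candidates(
                pts, filset, params.rc + maxhalf, boundary
            )
            keep = cand_mask[fi]
            pi, fi = pi[keep], fi[keep]
            lo, hi = _capture_intervals(pts, fi, pi, filset, params.rc, boundary)
            lin = np.maximum(hi - lo, 0.0)
            pos = lin > 0
            pi, fi, lo, hi, lin = pi[pos], fi[pos], lo[pos], hi[pos], lin[pos]
            lin_tot = np.bincount(pi, weights=lin, minlength=len(u_idx))
            pref = 3.0 * params.eps * params.ka / (4.0 * np.pi * params.rc**3)
            rate_us = params.ko_s * pref * lin_tot
            for head in range(2):
                can = ~pop.locked[u_idx, head]
                f = _fire(rng, rate_us, h) & can
                fire[u_idx, 0 + head] |= f
                event[u_idx[f], head] = 1
            hit = np.nonzero(fire[u_idx, 0] | fire[u_idx, 1])[0]
            for k in hit:
                sel = pi == k
                weights = lin[sel]
                cum = np.cumsum(weights)
                r = rng.random() * cum[-1]
                j = np.searchsorted(cum, r)
                s = lo[sel][j] + rng.random() * (hi[sel][j] - lo[sel][j])
                us_sites[(int(u_idx[k]), 0)] = (int(fi[sel][j]), float(s))
                us_sites[(int(u_idx[k]), 1)] = us_sites[(int(u_idx[k]), 0)]

        # S heads: bound head may unbind (ko_s); free head may doubly bind
        sa = pop.state == SA
        sb = pop.state == SB
        s_any = np.nonzero(sa | sb)[0]
        if len(s_any):
            bound_head_of = np.where(sa[s_any], 0, 1)
            # unbinding of the bound head
            unlocked = ~pop.locked[s_any, bound_head_of]
            f_un = _fire(rng, np.full(len(s_any), params.ko_s), h) & unlocked
            fire[s_any[f_un], bound_head_of[f_un]] = True
            event[s_any[f_un], bound_head_of[f_un]] = 2
            # doubly binding of the free head
            free_head_of = 1 - bound_head_of
            can_bind = ~pop.locked[s_any, free_head_of]
            if np.any(can_bind):
                sel = s_any[can_bind]
                bh = bound_head_of[can_bind]
                fh = free_head_of[can_bind]
                ownf = pop.fil[sel, bh]
                attach = filset.centers[ownf] + pop.arc[sel, bh, None] * p_dir[ownf]
                rates, (ppi, pfi, ps, pw, pds) = _sd_binding_batch(
                    attach, ownf, 0.5 * filset.diameters[ownf],
                    filset, params, boundary, state.kbt,
                )
                f_bind = _fire(rng, rates, h)
                for k in np.nonzero(f_bind)[0]:
                    i = int(sel[k])
                    fire[i, fh[k]] = True
                    event[i, fh[k]] = 1
                    m = ppi == k
                    sd_density[i] = BindingDensity(
                        rate=float(rates[k]), fil=pfi[m], s=ps[m], w=pw[m], ds=pds[m]
                    )

        # D heads: either may unbind
        d_idx, ellf, _, _ = tether_separation(pop, filset, boundary)
        if len(d_idx):
            r_off = rate_D_to_S(ellf, params, state.kbt)
            for head in range(2):
                f = _fire(rng, r_off, h) & ~pop.locked[d_idx, head]
                fire[d_idx, head] |= f
                event[d_idx[f], head] = 2

        # ---- resolve: at most one transition per crosslinker per step when
        # both heads propose conflicting events ----
        both = np.nonzero(fire[:, 0] & fire[:, 1])[0]
        for i in both:
            drop = int(rng.random() < 0.5)
            fire[i, drop] = False
            event[i, drop] = 0

        # ---- apply (unbinds batched; binds need per-event site sampling) ----
        for head in range(2):
            idx = np.nonzero(fire[:, head])[0]
            if len(idx) == 0:
                continue
            un = idx[event[idx, head] == 2]
            if len(un):
                was_d = pop.state[un] == D
                counts["unbind_ds"] += int(np.sum(was_d))
                counts["unbind_su"] += int(np.sum(~was_d))
                _release_head(pop, filset, un, head)
            for i in idx[event[idx, head] == 1]:
                if pop.state[i] == U:
                    filj, s = us_sites[(int(i), head)]
                    pop.state[i] = SA if head == 0 else SB
                    pop.fil[i, head] = filj
                    pop.arc[i, head] = s
                    counts["bind_us"] += 1
                else:
                    filj, s = sd_density[int(i)].sample_site(rng)
                    pop.state[i] = D
                    pop.fil[i, head] = filj
                    pop.arc[i, head] = s
                    counts["bind_sd"] += 1
    return counts
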