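"""Per-step convex QP coupling collision and crosslinker-spring constraints.

Collisions are unilateral complementarity constraints 0 ≤ Φu ⟂ γu ≥ 0 on the
signed surface separation Φu of filament pairs (and filament-wall contacts);
doubly bound crosslinker tethers are bilateral Hookean constraints
K(Φb − Φb0) = −γb on the tether length.  One linearized implicit-Euler step
turns both into a single convex quadratic program

    min_γ  ½ γᵀ M γ + qᵀ γ,   subject to γu ≥ 0,

with M = Dᵀ M D + diag(0, K⁻¹/h) (symmetric positive semidefinite) and
q = [Φu/h + DuᵀM Fnc ; (Φb−Φb0)/h + DbᵀM Fnc].  D maps constraint force
magnitudes to equal-and-opposite force/torque pairs on the filaments.  The QP
is solved matrix-free with Barzilai-Borwein projected gradient descent
(projection clamps only the unilateral block).  The stiff-spring limit
(K⁻¹ → 0) stays convex: springs degenerate into non-compliant joints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .boundaries import Boundary, filament_pair_candidates
from .geometry import ConfigurationError, FilamentSet, segment_pair_geometry
from .kinetics import tether_separation

DEFAULT_BUFFER_FACTOR = 0.3   # collision buffer = 0.3 · max filament diameter
DEFAULT_MAX_ITER = 5000


def _cross(a, b):
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


@dataclass
class ConstraintBlock:
    """A homogeneous batch of constraints (struct-of-arrays).

    For each constraint k: filament pair (i[k], j[k]) with j = −1 for a
    static wall; phi[k] the signed gap (collision) or tether length
    (bilateral); normal[k] the unit direction along which the gap grows when
    body i moves; point_i/point_j the application points (in body i's local
    periodic image); lever_i/lever_j the arms from each center.
    """

    i: np.ndarray
    j: np.ndarray
    phi: np.ndarray
    normal: np.ndarray
    point_i: np.ndarray
    point_j: np.ndarray
    lever_i: np.ndarray
    lever_j: np.ndarray
    kappa: np.ndarray = None        # bilateral only
    rest: np.ndarray = None         # bilateral only (Φb0)
    keys: list = field(default_factory=list)  # warm-start identities

    @property
    def n(self) -> int:
        return len(self.phi)

    @classmethod
    def empty(cls, bilateral: bool = False) -> "ConstraintBlock":
        z3 = np.empty((0, 3))
        return cls(
            i=np.empty(0, dtype=int), j=np.empty(0, dtype=int), phi=np.empty(0),
            normal=z3.copy(), point_i=z3.copy(), point_j=z3.copy(),
            lever_i=z3.copy(), lever_j=z3.copy(),
            kappa=np.empty(0) if bilateral else None,
            rest=np.empty(0) if bilateral else None,
            keys=[],
        )


def collect_collisions(state, buffer: float = None) -> ConstraintBlock:
    """All filament-filament and filament-wall contacts with gap < buffer.

    The neighbor search prunes on center distance (cell-list equivalent via a
    periodic kd-tree); the narrow phase is the exact spherocylinder
    minimal-distance geometry.
    """
    filset = state.filaments
    boundary = state.boundary
    if buffer is None:
        buffer = DEFAULT_BUFFER_FACTOR * float(np.max(filset.diameters))
    if buffer < 0:
        raise ConfigurationError("collision buffer must be non-negative")
    cutoff = float(np.max(filset.lengths)) + float(np.max(filset.diameters)) + buffer
    pairs = filament_pair_candidates(filset, cutoff, boundary)
    out = ConstraintBlock.empty()
    if len(pairs):
        ii, jj = pairs[:, 0], pairs[:, 1]
        both_static = ~(filset.mobile[ii] | filset.mobile[jj])
        ii, jj = ii[~both_static], jj[~both_static]
    if len(pairs) and len(ii):
        r = boundary.min_image(filset.centers[ii] - filset.centers[jj])
        p = filset.directors()
        h1 = 0.5 * filset.lengths[ii]
        h2 = 0.5 * filset.lengths[jj]
        dist, s1, s2, nhat = segment_pair_geometry(r, p[ii], h1, p[jj], h2)
        radsum = 0.5 * (filset.diameters[ii] + filset.diameters[jj])
        sep = dist - radsum
        keep = sep < buffer
        ii, jj, s1, s2, nhat, sep, r = ii[keep], jj[keep], s1[keep], s2[keep], nhat[keep], sep[keep], r[keep]
        h1, h2, radsum = h1[keep], h2[keep], radsum[keep]
        # application points = closest centerline points (the force is central
        # along n̂, so the ±D/2 surface offset carries no torque; centerline
        # points keep the virial branch vector along +n̂ even when surfaces
        # interpenetrate), expressed relative to body i's periodic image
        ci = filset.centers[ii]
        pt_i = ci + s1[:, None] * p[ii]
        cj_local = ci - r  # body j's center in i's image frame
        pt_j = cj_local + s2[:, None] * p[jj]
        out = ConstraintBlock(
            i=ii, j=jj, phi=sep, normal=nhat,
            point_i=pt_i, point_j=pt_j,
            lever_i=pt_i - ci, lever_j=pt_j - cj_local,
            keys=[("col", int(a), int(b)) for a, b in zip(ii, jj)],
        )
    # filament-wall contacts
    widx, wsep, wcontact, wnormal = boundary.wall_gaps(filset)
    if len(widx):
        keep = (wsep < buffer) & filset.mobile[widx]
        widx, wsep, wcontact, wnormal = widx[keep], wsep[keep], wcontact[keep], wnormal[keep]
    if len(widx):
        wall = ConstraintBlock(
            i=widx, j=np.full(len(widx), -1, dtype=int), phi=wsep, normal=wnormal,
            point_i=wcontact, point_j=wcontact,
            lever_i=wcontact - filset.centers[widx], lever_j=np.zeros((len(widx), 3)),
            keys=[("wall", int(a), k) for k, a in enumerate(widx)],
        )
        out = _concat_blocks(out, wall)
    return out


def _concat_blocks(a: ConstraintBlock, b: ConstraintBlock) -> ConstraintBlock:
    if a.n == 0:
        return b
    if b.n == 0:
        return a
    return ConstraintBlock(
        i=np.concatenate([a.i, b.i]), j=np.concatenate([a.j, b.j]),
        phi=np.concatenate([a.phi, b.phi]), normal=np.concatenate([a.normal, b.normal]),
        point_i=np.concatenate([a.point_i, b.point_i]),
        point_j=np.concatenate([a.point_j, b.point_j]),
        lever_i=np.concatenate([a.lever_i, b.lever_i]),
        lever_j=np.concatenate([a.lever_j, b.lever_j]),
        kappa=None if a.kappa is None else np.concatenate([a.kappa, b.kappa]),
        rest=None if a.rest is None else np.concatenate([a.rest, b.rest]),
        keys=a.keys + b.keys,
    )


def collect_tethers(state) -> ConstraintBlock:
    """One bilateral constraint per doubly bound crosslinker."""
    filset = state.filaments
    blocks = ConstraintBlock.empty(bilateral=True)
    for pidx, pop in enumerate(state.motors):
        idx, ellf, uhat, a = tether_separation(pop, filset, state.boundary)
        if pop.params.slack_tether and len(idx):
            # tension-only tethers: slack bonds carry no force this step
            taut = ellf > pop.params.ell0
            idx, ellf, uhat, a = idx[taut], ellf[taut], uhat[taut], a[taut]
        if len(idx) == 0:
            continue
        fi = pop.fil[idx, 0]
        fj = pop.fil[idx, 1]
        ci = filset.centers[fi]
        # head B's point in head A's periodic image frame
        d_mi = state.boundary.min_image(a[:, 0] - a[:, 1])
        pt_i = a[:, 0]
        pt_j = a[:, 0] - d_mi
        blk = ConstraintBlock(
            i=fi, j=fj, phi=ellf, normal=uhat,
            point_i=pt_i, point_j=pt_j,
            lever_i=pt_i - ci, lever_j=pt_j - (ci - state.boundary.min_image(ci - filset.centers[fj])),
            kappa=np.full(len(idx), pop.params.kappa),
            rest=np.full(len(idx), pop.params.ell0),
            keys=[("xl", pidx, int(k)) for k in idx],
        )
        blocks = _concat_blocks(blocks, blk)
    return blocks


# ----------------------------------------------------------------------------
# QP assembly
# ----------------------------------------------------------------------------

@dataclass
class QPProblem:
    """Matrix-free convex QP  min ½γᵀMγ + qᵀγ  s.t. γ[:nu] ≥ 0.

    M γ = Dᵀ M (D γ) + [0; K⁻¹ γb / h].  D is the (6N × Nc) sparse
    force-direction matrix; the mobility product uses the filament set's
    anisotropic drag blocks.
    """

    D: sp.csr_matrix
    q: np.ndarray
    nu: int
    nb: int
    h: float
    kinv: np.ndarray          # (nb,) 1/κ entries (0 = rigid joint)
    filset: FilamentSet
    uni: ConstraintBlock = None
    bil: ConstraintBlock = None

    @property
    def n(self) -> int:
        return self.nu + self.nb

    def _mob_arrays(self):
        if not hasattr(self, "_mob"):
            fs = self.filset
            p = fs.directors()
            izp = np.where(fs.mobile, 1.0 / fs.zeta_par, 0.0)
            izq = np.where(fs.mobile, 1.0 / fs.zeta_perp, 0.0)
            izr = np.where(fs.mobile, 1.0 / fs.zeta_rot, 0.0)
            self._mob = (p, izp, izq, izr)
        return self._mob

    def mobility_apply(self, F: np.ndarray) -> np.ndarray:
        p, izp, izq, izr = self._mob_arrays()
        FT = F.reshape(-1, 6)
        f, tau = FT[:, :3], FT[:, 3:]
        fp = np.einsum("ij,ij->i", f, p)
        U = np.empty_like(FT)
        U[:, :3] = (fp * izp)[:, None] * p + izq[:, None] * (f - fp[:, None] * p)
        tp = np.einsum("ij,ij->i", tau, p)
        U[:, 3:] = izr[:, None] * (tau - tp[:, None] * p)
        return U.reshape(-1)

    @property
    def DT(self):
        if not hasattr(self, "_DT"):
            self._DT = self.D.T.tocsr()
        return self._DT

    def matvec(self, gamma: np.ndarray) -> np.ndarray:
        F = self.D @ gamma
        U = self.mobility_apply(F)
        out = self.DT @ U
        if self.nb:
            out[self.nu:] += self.kinv * gamma[self.nu:] / self.h
        return out

    def diagonal(self) -> np.ndarray:
        """diag(M) per constraint (used for Jacobi rescaling of the solver)."""
        p, izp, izq, izr = self._mob_arrays()

        def body(idx, normal, lever):
            tau = _cross(lever, normal)
            npdot = np.einsum("ij,ij->i", normal, p[idx])
            tpdot = np.einsum("ij,ij->i", tau, p[idx])
            n2 = np.einsum("ij,ij->i", normal, normal)
            t2 = np.einsum("ij,ij->i", tau, tau)
            return (
                npdot**2 * izp[idx]
                + (n2 - npdot**2) * izq[idx]
                + (t2 - tpdot**2) * izr[idx]
            )

        out = np.zeros(self.n)
        off = 0
        for blk in (self.uni, self.bil):
            if blk is None or blk.n == 0:
                if blk is not None:
                    off += blk.n
                continue
            d = body(blk.i, blk.normal, blk.lever_i)
            has_j = blk.j >= 0
            if np.any(has_j):
                d[has_j] += body(blk.j[has_j], blk.normal[has_j], blk.lever_j[has_j])
            out[off : off + blk.n] = d
            off += blk.n
        if self.nb:
            out[self.nu :] += self.kinv / self.h
        return out

    def dense_matrix(self) -> np.ndarray:
        """Dense M = DᵀMD + diag(0, K⁻¹/h) (small problems / oracles)."""
        from .geometry import mobility_apply_multi

        Dd = self.D.toarray()
        M = Dd.T @ mobility_apply_multi(self.filset, Dd)
        if self.nb:
            M[self.nu :, self.nu :] += np.diag(self.kinv / self.h)
        return M


def _direction_matrix(filset: FilamentSet, blocks: list[ConstraintBlock]) -> sp.csr_matrix:
    """Sparse D with one column per constraint: ±(n̂, r×n̂) force/torque pairs."""
    n6 = 6 * filset.n
    rows, cols, vals = [], [], []
    col0 = 0
    for blk in blocks:
        if blk.n == 0:
            continue
        tq_i = _cross(blk.lever_i, blk.normal)
        base_i = 6 * blk.i
        for c in range(3):
            rows.append(base_i + c)
            vals.append(blk.normal[:, c])
            rows.append(base_i + 3 + c)
            vals.append(tq_i[:, c])
        cols.extend([np.arange(blk.n) + col0] * 6)
        has_j = blk.j >= 0
        if np.any(has_j):
            tq_j = _cross(blk.lever_j[has_j], blk.normal[has_j])
            base_j = 6 * blk.j[has_j]
            for c in range(3):
                rows.append(base_j + c)
                vals.append(-blk.normal[has_j, c])
                rows.append(base_j + 3 + c)
                vals.append(-tq_j[:, c])
            cols.extend([np.nonzero(has_j)[0] + col0] * 6)
        col0 += blk.n
    if not rows:
        return sp.csr_matrix((n6, 0))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n6, col0))


def assemble_qp(
    state, uni: ConstraintBlock, bil: ConstraintBlock, Fnc: np.ndarray, h: float
) -> QPProblem:
    """Build the per-step QP from collision and tether constraints."""
    if h <= 0:
        raise ConfigurationError("timestep must be positive")
    filset = state.filaments
    D = _direction_matrix(filset, [uni, bil])
    nu, nb = uni.n, bil.n
    q = np.empty(nu + nb)
    q[:nu] = uni.phi / h
    if nb:
        q[nu:] = (bil.phi - bil.rest) / h
        with np.errstate(divide="ignore"):
            kinv = np.where(bil.kappa > 0, 1.0 / np.where(bil.kappa > 0, bil.kappa, 1.0), 0.0)
    else:
        kinv = np.empty(0)
    if Fnc is not None and (nu + nb) > 0:
        from .geometry import mobility_apply

        q += D.T @ mobility_apply(filset, Fnc)
    return QPProblem(D=D, q=q, nu=nu, nb=nb, h=h, kinv=kinv, filset=filset, uni=uni, bil=bil)


# ----------------------------------------------------------------------------
# BBPGD solver
# ----------------------------------------------------------------------------

class ConvergenceWarning(UserWarning):
    pass


def _project(gamma: np.ndarray, nu: int) -> np.ndarray:
    out = gamma.copy()
    out[:nu] = np.maximum(out[:nu], 0.0)
    return out


def _projected_gradient_norm(gamma: np.ndarray, g: np.ndarray, nu: int) -> float:
    pg = g.copy()
    at_bound = (gamma[:nu] <= 0.0) & (g[:nu] > 0.0)
    pg_u = pg[:nu]
    pg_u[at_bound] = 0.0
    pg[:nu] = pg_u
    return float(np.max(np.abs(pg))) if len(pg) else 0.0


try:  # optional acceleration of the sparse BBPGD loop
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=True)
def _bb_loop_sparse(
    indptr, rows, vals, q, kinv_h, nu, p, izp, izq, izr, gamma, tol, max_iter, first_alpha, wnorm
):  # pragma: no cover - exercised via bbpgd_solve
    n = q.shape[0]
    nfil = p.shape[0]
    n6 = 6 * nfil
    F = np.zeros(n6)
    Uv = np.zeros(n6)
    g = np.zeros(n)
    g_new = np.zeros(n)
    gamma_new = np.zeros(n)

    def matvec(x, g_out):
        for k in range(n6):
            F[k] = 0.0
        for j in range(n):
            xj = x[j]
            if xj != 0.0:
                for k in range(indptr[j], indptr[j + 1]):
                    F[rows[k]] += vals[k] * xj
        for i in range(nfil):
            b = 6 * i
            fp = F[b] * p[i, 0] + F[b + 1] * p[i, 1] + F[b + 2] * p[i, 2]
            tp = F[b + 3] * p[i, 0] + F[b + 4] * p[i, 1] + F[b + 5] * p[i, 2]
            for c in range(3):
                Uv[b + c] = fp * p[i, c] * izp[i] + (F[b + c] - fp * p[i, c]) * izq[i]
                Uv[b + 3 + c] = (F[b + 3 + c] - tp * p[i, c]) * izr[i]
        for j in range(n):
            s = 0.0
            for k in range(indptr[j], indptr[j + 1]):
                s += vals[k] * Uv[rows[k]]
            if j >= nu:
                s += kinv_h[j - nu] * x[j]
            g_out[j] = s + q[j]

    def pgnorm(x, g_in):
        # convergence is judged on the *unscaled* projected gradient via the
        # per-row weights wnorm (Jacobi rescaling does not change the KKT test)
        r = 0.0
        for j in range(n):
            gj = g_in[j]
            if j < nu and x[j] <= 0.0 and gj > 0.0:
                gj = 0.0
            a = abs(gj) * wnorm[j]
            if a > r:
                r = a
        return r

    matvec(gamma, g)
    res = pgnorm(gamma, g)
    if res <= tol:
        return 0, res
    alpha = first_alpha
    it = 0
    while it < max_iter:
        it += 1
        moved = False
        for j in range(n):
            v = gamma[j] - alpha * g[j]
            if j < nu and v < 0.0:
                v = 0.0
            gamma_new[j] = v
            if v != gamma[j]:
                moved = True
        if not moved:
            break
        matvec(gamma_new, g_new)
        ss = 0.0
        sy = 0.0
        yy = 0.0
        for j in range(n):
            s_j = gamma_new[j] - gamma[j]
            y_j = g_new[j] - g[j]
            ss += s_j * s_j
            sy += s_j * y_j
            yy += y_j * y_j
        if sy > 1e-30:
            alpha = ss / sy if (it % 2 == 1) else sy / yy
        else:
            alpha = first_alpha
        for j in range(n):
            gamma[j] = gamma_new[j]
            g[j] = g_new[j]
        res = pgnorm(gamma, g)
        if res <= tol:
            return it, res
    return it, res


_DENSE_LIMIT = 512


def _active_set_solve(Mdense, q, nu, gamma0, max_rounds: int = 30):
    """Direct small-problem solve: guess the active contact set, solve the
    reduced SPD system, and update the set until the KKT conditions hold.
    Returns None when a reduced system is not SPD (caller falls back)."""
    from scipy.linalg import cho_factor, cho_solve

    n = len(q)
    active = np.ones(n, dtype=bool)
    active[:nu] = (gamma0[:nu] > 0) | (q[:nu] < 0)
    scale = max(1.0, float(np.max(np.abs(q))))
    for _ in range(max_rounds):
        idx = np.nonzero(active)[0]
        gamma = np.zeros(n)
        if len(idx):
            try:
                sub = cho_factor(Mdense[np.ix_(idx, idx)], lower=True)
            except np.linalg.LinAlgError:
                return None
            gamma[idx] = cho_solve(sub, -q[idx])
        g = Mdense @ gamma + q
        neg = active[:nu] & (gamma[:nu] < 0)
        push = ~active[:nu] & (g[:nu] < -1e-12 * scale)
        if not (np.any(neg) or np.any(push)):
            gamma[:nu] = np.maximum(gamma[:nu], 0.0)
            return gamma
        active[:nu] = (active[:nu] & ~neg) | push
    return None


def _bbpgd_dense(Mdense, q, nu, tol, max_iter, gamma):
    """BB projected gradient with an explicit dense matrix (small problems)."""
    g = Mdense @ gamma + q
    res = _projected_gradient_norm(gamma, g, nu)
    if res <= tol:
        return gamma, 0, res
    m_est = np.linalg.norm(Mdense, ord=np.inf)
    alpha = 1e-4 / max(m_est, 1e-30)
    it = 0
    while it < max_iter:
        it += 1
        gamma_new = _project(gamma - alpha * g, nu)
        s = gamma_new - gamma
        if not np.any(s):
            break
        g_new = Mdense @ gamma_new + q
        y = g_new - g
        sy = float(s @ y)
        if sy > 1e-30:
            alpha = float(s @ s) / sy if (it % 2 == 1) else sy / float(y @ y)
        else:
            alpha = 1e-4 / max(m_est, 1e-30)
        gamma, g = gamma_new, g_new
        res = _projected_gradient_norm(gamma, g, nu)
        if res <= tol:
            break
    return gamma, it, res


def bbpgd_solve(
    qp: QPProblem,
    tol: float = None,
    max_iter: int = DEFAULT_MAX_ITER,
    gamma0: np.ndarray = None,
):
    """Solve the constraint QP: min ½γᵀMγ + qᵀγ subject to γu ≥ 0.

    The solver is Barzilai-Borwein projected gradient descent (only the
    first nu collision entries are clamped), stopping when the ∞-norm of the
    projected gradient drops below tol (default 1e-6·max(1, ‖q‖∞)); the
    first step uses a conservative fixed step 1e-4/‖M‖est, then BB1/BB2 step
    sizes alternate.  Purely bilateral problems with finite stiffness are an
    unconstrained SPD system and are solved directly by Cholesky (the exact
    minimizer the iteration would reach).  Small problems use an explicit
    dense matrix; large ones a matrix-free sparse kernel.

    Returns (γ, info dict with iterations / residual / converged).
    """
    n = qp.n
    if n == 0:
        return np.empty(0), {"iterations": 0, "residual": 0.0, "converged": True, "tol": 0.0}
    if tol is None:
        tol = 1e-6 * max(1.0, float(np.max(np.abs(qp.q))))
    if gamma0 is None:
        gamma = np.zeros(n)
    else:
        gamma = _project(np.asarray(gamma0, dtype=float).copy(), qp.nu)

    if n <= _DENSE_LIMIT and n * n * 6 * qp.filset.n <= 4_000_000:
        Mdense = qp.dense_matrix()
        if qp.nb == 0 or np.all(qp.kinv > 0):
            sol = _active_set_solve(Mdense, qp.q, qp.nu, gamma)
            if sol is not None:
                res = _projected_gradient_norm(sol, Mdense @ sol + qp.q, qp.nu)
                if res <= max(tol, 1e-8 * np.max(np.abs(qp.q))):
                    return sol, {"iterations": 1, "residual": res, "converged": True, "tol": tol}
        gamma, it, res = _bbpgd_dense(Mdense, qp.q, qp.nu, tol, max_iter, gamma)
    elif _HAVE_NUMBA:
        # Jacobi-rescaled iteration: identical QP and stopping test, far
        # fewer BB iterations on heterogeneous constraint sets
        csc = qp.D.tocsc()
        p, izp, izq, izr = qp._mob_arrays()
        dg = np.maximum(qp.diagonal(), 1e-300)
        sqrtd = np.sqrt(dg)
        data_s = csc.data / np.repeat(sqrtd, np.diff(csc.indptr))
        q_s = qp.q / sqrtd
        kinv_h = (qp.kinv / qp.h) / dg[qp.nu :] if qp.nb else np.empty(0)
        gamma_s = gamma * sqrtd
        probe = np.random.default_rng(12345).standard_normal(n)
        mp = qp.matvec(probe / sqrtd) / sqrtd
        m_est = np.linalg.norm(mp) / np.linalg.norm(probe)
        it, res = _bb_loop_sparse(
            csc.indptr, csc.indices, data_s, q_s, kinv_h, qp.nu,
            p, izp, izq, izr, gamma_s, tol, max_iter, 1e-4 / max(m_est, 1e-30), sqrtd,
        )
        gamma = gamma_s / sqrtd
    else:
        probe = np.random.default_rng(12345).standard_normal(n)
        m_est = np.linalg.norm(qp.matvec(probe / np.linalg.norm(probe)))
        alpha = 1e-4 / max(m_est, 1e-30)
        g = qp.matvec(gamma) + qp.q
        res = _projected_gradient_norm(gamma, g, qp.nu)
        it = 0
        while res > tol and it < max_iter:
            it += 1
            gamma_new = _project(gamma - alpha * g, qp.nu)
            s = gamma_new - gamma
            if not np.any(s):
                break
            g_new = qp.matvec(gamma_new) + qp.q
            y = g_new - g
            sy = float(s @ y)
            if sy > 1e-30:
                alpha = float(s @ s) / sy if (it % 2 == 1) else sy / float(y @ y)
            else:
                alpha = 1e-4 / max(m_est, 1e-30)
            gamma, g = gamma_new, g_new
            res = _projected_gradient_norm(gamma, g, qp.nu)

    converged = res <= tol
    if not converged:
        warnings.warn(
            f"BBPGD did not converge in {max_iter} iterations (residual {res:.3e}, tol {tol:.3e})",
            ConvergenceWarning,
            stacklevel=2,
        )
    return gamma, {"iterations": it, "residual": res, "converged": converged, "tol": tol}


def constraint_forces(qp: QPProblem, gamma: np.ndarray) -> np.ndarray:
    """Map solved constraint magnitudes to the 6N force/torque vector
    F = D γ (equal and opposite per pair by construction)."""
    return qp.D @ np.asarray(gamma, dtype=float)


def residuals(qp: QPProblem, gamma: np.ndarray, Fnc: np.ndarray = None):
    """Post-solve constraint residuals on the linearized next-step gaps.

    Returns (complementarity, bilateral): max over unilateral constraints of
    min(γu, Φu + h·DᵀU), and max over bilateral rows of
    |K(Φb_lin − Φb0) + γb| (in force units).
    """
    F = constraint_forces(qp, gamma)
    if Fnc is not None:
        F = F + Fnc
    U = qp.mobility_apply(F)
    dphi = qp.D.T @ U
    comp = 0.0
    bil = 0.0
    if qp.nu:
        phi_next = qp.uni.phi + qp.h * dphi[: qp.nu]
        comp = float(np.max(np.abs(np.minimum(gamma[: qp.nu], phi_next))))
    if qp.nb:
        phi_next = qp.bil.phi + qp.h * dphi[qp.nu :]
        gb = gamma[qp.nu :]
        resid = np.where(
            qp.bil.kappa > 0,
            qp.bil.kappa * (phi_next - qp.bil.rest) + gb,
            phi_next - qp.bil.rest,
        )
        bil = float(np.max(np.abs(resid)))
    return comp, bil
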