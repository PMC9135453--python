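"""Constraint collection, QP assembly, and the BBPGD solver."""

import numpy as np
import pytest
from scipy.optimize import minimize

import cytorod as ct
from cytorod.constraints import (
    ConstraintBlock,
    _projected_gradient_norm,
    assemble_qp,
    bbpgd_solve,
    collect_collisions,
    collect_tethers,
    constraint_forces,
    residuals,
)
from cytorod.kinetics import D as STATE_D, MotorParams, MotorPopulation
from cytorod.scenarios import quat_from_director
from cytorod.state import SystemState

from conftest import make_filset, random_rod


def axial_rod(x, y, z, length=1.0, diameter=0.025, axis=(1.0, 0, 0), **kw):
    return ct.Spherocylinder(
        kw.pop("idx", 0), [x, y, z], quat_from_director(np.asarray(axis, dtype=float)),
        length, diameter, **kw,
    )


def simple_state(rods, motors=(), boundary=None, eta=0.01, seed=0):
    return SystemState(
        filaments=make_filset(rods, eta=eta),
        motors=list(motors),
        boundary=boundary or ct.Boundary(),
        rng=np.random.default_rng(seed),
    )


def spring_population(pairs_arcs, kappa=100.0, ell0=0.053, lock=True):
    pop = MotorPopulation(MotorParams(kappa=kappa, ell0=ell0, vm=0.0), len(pairs_arcs))
    for k, (i, j, si, sj) in enumerate(pairs_arcs):
        pop.state[k] = STATE_D
        pop.fil[k] = (i, j)
        pop.arc[k] = (si, sj)
    if lock:
        pop.locked[:] = True
    return pop


class TestCollectCollisions:
    def test_distant_pair_yields_nothing(self):
        st = simple_state([axial_rod(0, 0, 0), axial_rod(0, 1.0, 0, idx=1)])
        assert collect_collisions(st).n == 0

    def test_overlapping_pair_yields_one_negative_gap(self):
        st = simple_state([axial_rod(0, 0, 0), axial_rod(0, 0.02, 0, idx=1)])
        uni = collect_collisions(st)
        assert uni.n == 1
        assert uni.phi[0] < 0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        rods = [random_rod(rng, box=1.5, length=0.4, idx=k) for k in range(100)]
        st = simple_state(rods)
        buffer = 0.0075
        uni = collect_collisions(st, buffer)
        got = {(int(i), int(j)) for i, j in zip(uni.i, uni.j) if j >= 0}
        expected = set()
        for a in range(100):
            for b in range(a + 1, 100):
                sep, *_ = ct.min_distance(rods[a], rods[b])
                if sep < buffer:
                    expected.add((a, b))
        assert got == expected


class TestCollectTethers:
    def test_no_doubly_bound_no_constraints(self):
        st = simple_state([axial_rod(0, 0, 0)])
        assert collect_tethers(st).n == 0

    def test_one_doubly_bound_crosslinker(self):
        rods = [axial_rod(0, 0, 0), axial_rod(0, 0.08, 0, idx=1)]
        pop = spring_population([(0, 1, 0.1, 0.1)])
        st = simple_state(rods, [pop])
        bil = collect_tethers(st)
        assert bil.n == 1
        assert bil.phi[0] == pytest.approx(0.08 - 0.025)

    def test_count_matches_d_state_records(self, rng):
        rods = [axial_rod(0, 0, 0), axial_rod(0, 0.08, 0, idx=1)]
        pop = MotorPopulation(MotorParams(), 30)
        n_d = 0
        for k in range(30):
            r = rng.random()
            if r < 0.4:
                pop.state[k] = STATE_D
                pop.fil[k] = (0, 1)
                pop.arc[k] = tuple(rng.uniform(-0.4, 0.4, 2))
                n_d += 1
        st = simple_state(rods, [pop])
        assert collect_tethers(st).n == n_d


class TestAssembleQP:
    def test_empty_problem(self):
        st = simple_state([axial_rod(0, 0, 0)])
        qp = assemble_qp(
            st, ConstraintBlock.empty(), ConstraintBlock.empty(bilateral=True),
            np.zeros(6), 1e-4,
        )
        assert qp.n == 0

    def test_matches_dense_oracle(self):
        """M = DᵀMD + K⁻¹/h assembled independently from mobility blocks."""
        rods = [axial_rod(0, 0, 0), axial_rod(0, 0.02, 0, idx=1),
                axial_rod(0.3, 0.09, 0, idx=2)]
        pop = spring_population([(0, 2, 0.3, -0.2), (1, 2, -0.1, 0.4)])
        st = simple_state(rods, [pop])
        uni = collect_collisions(st)
        bil = collect_tethers(st)
        assert uni.n >= 1 and bil.n == 2
        h = 1e-4
        qp = assemble_qp(st, uni, bil, None, h)
        # independent dense assembly
        fs = st.filaments
        Mmob = np.zeros((18, 18))
        for k in range(18):
            e = np.zeros(18)
            e[k] = 1.0
            Mmob[:, k] = ct.mobility_apply(fs, e)
        Dd = np.zeros((18, qp.n))
        col = 0
        for blk in (uni, bil):
            for k in range(blk.n):
                n = blk.normal[k]
                Dd[6 * blk.i[k] : 6 * blk.i[k] + 3, col] = n
                Dd[6 * blk.i[k] + 3 : 6 * blk.i[k] + 6, col] = np.cross(blk.lever_i[k], n)
                if blk.j[k] >= 0:
                    Dd[6 * blk.j[k] : 6 * blk.j[k] + 3, col] = -n
                    Dd[6 * blk.j[k] + 3 : 6 * blk.j[k] + 6, col] = -np.cross(blk.lever_j[k], n)
                col += 1
        Mref = Dd.T @ Mmob @ Dd
        Mref[uni.n :, uni.n :] += np.eye(2) / (100.0 * h)
        for k in range(qp.n):
            e = np.zeros(qp.n)
            e[k] = 1.0
            assert np.allclose(qp.matvec(e), Mref[:, k], atol=1e-12)

    def test_rest_length_spring_contributes_zero_q(self):
        rods = [axial_rod(0, 0, 0), axial_rod(0, 0.053 + 0.025, 0, idx=1)]
        pop = spring_population([(0, 1, 0.2, 0.2)])
        st = simple_state(rods, [pop])
        bil = collect_tethers(st)
        qp = assemble_qp(st, ConstraintBlock.empty(), bil, None, 1e-4)
        assert qp.q[0] == pytest.approx(0.0, abs=1e-10)


class MockQP:
    """Synthetic QP with an explicit SPSD matrix (oracle comparisons)."""

    def __init__(self, M, q, nu):
        self.M = M
        self.q = q
        self.nu = nu
        self.nb = len(q) - nu
        self.kinv = np.ones(self.nb)
        self.h = 1.0

        class _FS:
            n = 1

        self.filset = _FS()

    @property
    def n(self):
        return len(self.q)

    def matvec(self, x):
        return self.M @ x

    def dense_matrix(self):
        return self.M.copy()


class TestBBPGD:
    def test_nonnegative_q_pure_unilateral_gives_zero(self, rng):
        A = rng.standard_normal((8, 5))
        M = A @ A.T + 0.1 * np.eye(8)
        q = np.abs(rng.standard_normal(8))
        gamma, info = bbpgd_solve(MockQP(M, q, nu=8))
        assert np.allclose(gamma, 0.0)
        assert info["converged"]

    def test_scalar_unilateral_closed_form(self):
        m, phi, h = 2.5, 0.03, 1e-3
        gamma, _ = bbpgd_solve(MockQP(np.array([[m]]), np.array([-phi / h]), nu=1))
        assert gamma[0] == pytest.approx(phi / (h * m), rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_spsd_matches_reference_qp_solver(self, seed):
        rng = np.random.default_rng(seed)
        n, nu = 20, 12
        A = rng.standard_normal((n, n - 4))
        M = A @ A.T + 1e-3 * np.eye(n)
        q = rng.standard_normal(n) * 3
        gamma, info = bbpgd_solve(MockQP(M, q, nu), tol=1e-12)

        def obj(x):
            return 0.5 * x @ M @ x + q @ x, M @ x + q

        bounds = [(0, None)] * nu + [(None, None)] * (n - nu)
        ref = minimize(obj, np.zeros(n), jac=True, bounds=bounds,
                       method="L-BFGS-B", options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 2000})
        f_got = 0.5 * gamma @ M @ gamma + q @ gamma
        assert f_got <= ref.fun + 1e-8 * max(1, abs(ref.fun))
        assert abs(f_got - ref.fun) <= 1e-8 * max(1.0, abs(ref.fun))

    def test_nonconvergence_warns(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((30, 30))
        M = A @ A.T
        q = rng.standard_normal(30) * 100
        import cytorod.constraints as C

        old = (C._DENSE_LIMIT, C._HAVE_NUMBA)
        C._DENSE_LIMIT, C._HAVE_NUMBA = 0, False  # force the generic iterative path
        try:
            with pytest.warns(ct.constraints.ConvergenceWarning):
                bbpgd_solve(MockQP(M, q, nu=0), tol=1e-14, max_iter=2)
        finally:
            C._DENSE_LIMIT, C._HAVE_NUMBA = old

    def test_sparse_kernel_agrees_with_dense_path(self):
        """The matrix-free kernel and the dense small-problem path solve the
        same physical QP to the same stopping rule."""
        rng = np.random.default_rng(9)
        rods = [random_rod(rng, box=0.4, length=0.3, idx=k) for k in range(12)]
        pairs = [(i, j, rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1))
                 for i in range(12) for j in range(i + 1, 12) if rng.random() < 0.4]
        pop = spring_population(pairs)
        st = simple_state(rods, [pop])
        uni = collect_collisions(st, buffer=0.05)
        bil = collect_tethers(st)
        qp = assemble_qp(st, uni, bil, None, 1e-4)
        tol = 1e-10 * max(1.0, np.max(np.abs(qp.q)))
        g_dense, _ = bbpgd_solve(qp, tol=tol)
        import cytorod.constraints as C

        old = C._DENSE_LIMIT
        C._DENSE_LIMIT = 0  # force the sparse path
        try:
            g_sparse, _ = bbpgd_solve(qp, tol=tol)
        finally:
            C._DENSE_LIMIT = old

        def f(x):
            return 0.5 * x @ qp.matvec(x) + qp.q @ x

        assert f(g_sparse) == pytest.approx(f(g_dense), abs=1e-8 * max(1, abs(f(g_dense))))


class TestConstraintForces:
    def _contact_qp(self):
        st = simple_state([axial_rod(0, 0, 0), axial_rod(0, 0.02, 0, idx=1)])
        uni = collect_collisions(st)
        return st, assemble_qp(st, uni, ConstraintBlock.empty(bilateral=True), None, 1e-4)

    def test_zero_gamma_zero_forces(self):
        _, qp = self._contact_qp()
        assert np.all(constraint_forces(qp, np.zeros(qp.n)) == 0)

    def test_action_reaction_single_contact(self):
        _, qp = self._contact_qp()
        F = constraint_forces(qp, np.ones(qp.n)).reshape(2, 6)
        assert np.allclose(F[0, :3], qp.uni.normal[0])
        assert np.allclose(F[1, :3], -qp.uni.normal[0])

    def test_internal_forces_sum_to_zero(self, rng):
        rods = [random_rod(rng, box=0.5, length=0.4, idx=k) for k in range(20)]
        pairs = [(i, (i + 3) % 20, 0.1, -0.1) for i in range(20)]
        pop = spring_population(pairs)
        st = simple_state(rods, [pop])
        uni = collect_collisions(st, buffer=0.1)
        bil = collect_tethers(st)
        qp = assemble_qp(st, uni, bil, None, 1e-4)
        gamma = rng.standard_normal(qp.n)
        F = constraint_forces(qp, gamma).reshape(20, 6)
        assert np.allclose(F[:, :3].sum(axis=0), 0.0, atol=1e-10)
        # total torque about the origin: Σ (τ_i + x_i × f_i) = 0 in free space
        tq = F[:, 3:] + np.cross(st.filaments.centers, F[:, :3])
        assert np.allclose(tq.sum(axis=0), 0.0, atol=1e-10)


class TestImplicitSpring:
    def _two_rod_spring(self, n_springs=1, kappa=100.0, gap_excess=0.05, eta=0.01):
        ell0 = 0.053
        dist = 0.025 + ell0 + gap_excess
        rods = [axial_rod(0, 0, 0), axial_rod(0, dist, 0, idx=1)]
        arcs = np.linspace(-0.4, 0.4, n_springs)
        pop = spring_population([(0, 1, a, a) for a in arcs], kappa=kappa, ell0=ell0)
        return simple_state(rods, [pop], eta=eta), pop

    @pytest.mark.parametrize("hk_ratio", [1.0, 10.0, 1e3])
    def test_relaxation_matches_implicit_recurrence(self, hk_ratio):
        """ℓ − ℓ0 contracts by 1/(1 + h N κ (2/ζ⊥)) per step, stable even for
        h κ/ζ⊥ ≫ 1 where explicit Euler diverges."""
        st, pop = self._two_rod_spring(n_springs=10)
        zperp = st.filaments.zeta_perp[0]
        kappa = 100.0
        h = hk_ratio * zperp / kappa  # h κ / ζ⊥ = hk_ratio
        lam = 10 * kappa * 2 / zperp
        cfg = ct.StepConfig(h=h, brownian=False)
        from cytorod.kinetics import tether_separation

        gaps = []
        for _ in range(6):
            ct.timestep(st, cfg)
            _, ellf, _, _ = tether_separation(pop, st.filaments, st.boundary)
            gaps.append(ellf.mean())
        fac = 1.0 / (1.0 + h * lam)
        pred = 0.053 + 0.05 * fac ** np.arange(1, 7)
        assert np.allclose(gaps, pred, atol=1e-10)

    def test_rigid_joint_limit_restores_rest_length(self):
        """κ⁻¹ → 0 (rigid joint): one linearized step drives ℓf to ℓ0."""
        st, pop = self._two_rod_spring(gap_excess=0.004)
        pop.params = pop.params.with_(kappa=0.0)  # kinv = 0 in the QP
        cfg = ct.StepConfig(h=1e-4, brownian=False)
        ct.timestep(st, cfg)
        from cytorod.kinetics import tether_separation

        _, ellf, _, _ = tether_separation(pop, st.filaments, st.boundary)
        assert ellf[0] == pytest.approx(0.053, abs=5e-5)  # linearization error only


class TestResiduals:
    def test_overlapping_rods_separate_with_small_residuals(self):
        st = simple_state([axial_rod(0, 0, 0), axial_rod(0, 0.02, 0, idx=1)])
        cfg = ct.StepConfig(h=1e-4, brownian=False, check_residuals=True)
        d = ct.timestep(st, cfg)
        tol = 1e-6 * max(1.0, abs(d["residual"]) + 1e3)
        assert d["complementarity_residual"] <= 1e-4
        sep, *_ = ct.min_distance(st.filaments.view(0), st.filaments.view(1))
        assert sep > -1e-6  # overlap resolved to linearization tolerance

    def test_dense_packing_overlap_control(self):
        """Dense thermal rod packing: overlaps stay bounded by the one-step
        free-flight displacement (no potential-style blow-up), forces finite.

        Contacts are only seeded once a gap drops below the buffer, so a
        thermally kicked rod can penetrate by up to roughly its one-step free
        displacement (~0.01-0.02 µm here) before the constraint exists; the
        implicit solve then removes the overlap instead of amplifying it."""
        from cytorod.scenarios import max_overlap

        st = ct.gen_nematic_tube(30, 0, 0.165, 1.2, seed=5)
        dfil = float(st.filaments.diameters[0])
        # dense + thermal runs use h = 1e-5 so the one-step free flight stays
        # below the contact buffer (the dilute default is h = 1e-4)
        cfg = ct.StepConfig(h=1e-5, brownian=True)
        samples = []
        for k in range(3000):
            ct.timestep(st, cfg)
            if k % 50 == 0:
                samples.append(max_overlap(st))
        assert np.median(samples) < 0.3 * dfil  # typical: below the buffer
        assert max(samples) < 0.8 * dfil        # spikes: bounded, no blow-up
        assert np.all(np.isfinite(st.filaments.centers))
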