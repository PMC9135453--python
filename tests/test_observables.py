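"""Order parameters, RDF, virial stress, straining-velocity protocol."""

import numpy as np
import pytest

import cytorod as ct
from cytorod.boundaries import PeriodicBox
from cytorod.io import Trajectory
from cytorod.kinetics import D as STATE_D, MotorParams, MotorPopulation
from cytorod.observables import (
    axial_order_profile,
    local_nematic_order,
    nematic_order_of_directors,
    plane_straining_velocity,
    polarity_divergence,
    polarity_field,
    rdf_minus_ends,
    rdf_peaks,
    virial_stress,
)
from cytorod.scenarios import quat_from_director
from cytorod.state import SystemState

from conftest import make_filset


def rods_along(axes, centers=None, length=0.5, diameter=0.025):
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    if centers is None:
        centers = [[k * 1.0, 0, 0] for k in range(len(axes))]
    return make_filset(
        [
            ct.Spherocylinder(k, c, quat_from_director(a / np.linalg.norm(a)),
                              length, diameter)
            for k, (c, a) in enumerate(zip(centers, axes))
        ]
    )


def link(pop_idx, pairs):
    pop = MotorPopulation(MotorParams(), len(pairs))
    for k, (i, j) in enumerate(pairs):
        pop.state[k] = STATE_D
        pop.fil[k] = (i, j)
    return pop


class TestLocalNematicOrder:
    def test_identical_directors_give_unity(self):
        fs = rods_along([[0, 0, 1]] * 4)
        pop = link(0, [(0, 1), (1, 2), (2, 3), (0, 3)])
        st = SystemState(filaments=fs, motors=[pop], rng=np.random.default_rng(0))
        s, nd = local_nematic_order(st)
        assert np.allclose(s, 1.0, atol=1e-12)
        assert nd[0] == 3  # self + two crosslinked partners

    def test_isolated_filament_self_average(self):
        fs = rods_along([[1, 1, 0]])
        st = SystemState(filaments=fs, rng=np.random.default_rng(0))
        s, nd = local_nematic_order(st)
        assert s[0] == pytest.approx(1.0)
        assert nd[0] == 1

    def test_isotropic_neighborhood_vanishes(self):
        rng = np.random.default_rng(11)
        p = rng.standard_normal((10_000, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        assert nematic_order_of_directors(p) < 0.05  # O(N^-1/2) residual

    def test_bounds(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.standard_normal((30, 3))
            p /= np.linalg.norm(p, axis=1, keepdims=True)
            s = nematic_order_of_directors(p)
            assert -1e-12 <= s <= 1.0 + 1e-12


class TestAxialOrderProfile:
    def test_axis_aligned_filaments_give_one(self):
        fs = rods_along([[1, 0, 0]] * 5, centers=[[0.1 * k, 0, 0] for k in range(5)])
        edges = np.linspace(-0.5, 1.0, 7)
        _, prof, _ = axial_order_profile(fs, edges)
        filled = ~np.isnan(prof)
        assert np.allclose(prof[filled], 1.0)

    def test_perpendicular_filaments_give_minus_half(self):
        fs = rods_along([[0, 1, 0], [0, 0, 1]], centers=[[0.2, 0, 0], [0.3, 0, 0]])
        edges = np.array([0.0, 0.5])
        _, prof, _ = axial_order_profile(fs, edges)
        assert prof[0] == pytest.approx(-0.5)

    def test_isotropic_near_zero(self):
        rng = np.random.default_rng(13)
        axes = rng.standard_normal((4000, 3))
        centers = np.zeros((4000, 3))
        centers[:, 0] = rng.uniform(0, 1, 4000)
        fs = rods_along(axes, centers=centers, length=0.05)
        edges = np.array([0.0, 1.0])
        _, prof, _ = axial_order_profile(fs, edges)
        assert abs(prof[0]) < 0.05

    def test_empty_window_is_missing_not_zero(self):
        fs = rods_along([[1, 0, 0]], centers=[[0.1, 0, 0]], length=0.2)
        edges = np.array([0.0, 0.4, 5.0, 6.0])
        _, prof, _ = axial_order_profile(fs, edges)
        assert np.isnan(prof[-1])

    def test_range_bounds(self):
        rng = np.random.default_rng(14)
        axes = rng.standard_normal((200, 3))
        centers = rng.random((200, 3))
        fs = rods_along(axes, centers=centers, length=0.3)
        edges = np.linspace(0, 1, 6)
        _, prof, _ = axial_order_profile(fs, edges)
        ok = ~np.isnan(prof)
        assert np.all(prof[ok] >= -0.5 - 1e-9) and np.all(prof[ok] <= 1.0 + 1e-9)


class TestRDF:
    def test_uniform_points_flat(self):
        rng = np.random.default_rng(15)
        b = PeriodicBox(np.array([4.0, 4.0, 4.0]))
        pts = rng.random((2000, 3)) * 4.0
        r, g = rdf_minus_ends(pts, b, 1.9, 0.1)
        assert np.allclose(g, 1.0, atol=0.15)

    def test_simple_cubic_lattice_peak(self):
        b = PeriodicBox(np.array([4.0, 4.0, 4.0]))
        ax = np.arange(0, 4.0, 1.0)
        pts = np.array([[x, y, z] for x in ax for y in ax for z in ax])
        r, g = rdf_minus_ends(pts, b, 1.9, 0.05)
        first = np.nonzero(g > 0)[0][0]
        assert abs(r[first] - 1.0) <= 0.05  # nearest-neighbor delta peak
        assert g[first] > 5
        assert np.all(g[: first] == 0)  # nothing below the lattice constant

    def test_matches_brute_force_pair_count(self):
        rng = np.random.default_rng(16)
        b = PeriodicBox(np.array([2.0, 2.0, 2.0]))
        pts = rng.random((300, 3)) * 2.0
        r, g = rdf_minus_ends(pts, b, 0.9, 0.05)
        # O(N²) reference histogram
        d = b.min_image(pts[:, None, :] - pts[None, :, :]).reshape(-1, 3)
        dist = np.linalg.norm(d, axis=1)
        iu = np.triu_indices(300, k=1)
        dist = np.linalg.norm(
            b.min_image(pts[iu[0]] - pts[iu[1]]), axis=1
        )
        counts, edges = np.histogram(dist, bins=np.arange(0, 0.9 + 0.05, 0.05))
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expect = len(iu[0]) * shell / 8.0
        g_ref = counts / expect
        assert np.allclose(g, g_ref, atol=1e-12)

    def test_normalization_conserves_pair_count(self):
        rng = np.random.default_rng(17)
        b = PeriodicBox(np.array([2.0, 2.0, 2.0]))
        pts = rng.random((200, 3)) * 2.0
        r, g = rdf_minus_ends(pts, b, 0.99, 0.03)
        edges = np.arange(0, 0.99 + 0.03, 0.03)
        edges = edges[edges <= 0.99 + 1e-12]
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        npairs = 200 * 199 / 2
        counted = np.sum(g * npairs * shell / 8.0)
        iu = np.triu_indices(200, k=1)
        dist = np.linalg.norm(b.min_image(pts[iu[0]] - pts[iu[1]]), axis=1)
        assert counted == pytest.approx(np.sum(dist < edges[-1]))

    def test_rmax_beyond_half_box_rejected(self):
        b = PeriodicBox(np.array([2.0, 2.0, 2.0]))
        with pytest.raises(ct.ConfigurationError):
            rdf_minus_ends(np.zeros((3, 3)), b, 1.5, 0.1)

    def test_peak_finder_orders_peaks_radially(self):
        r = np.arange(0.0, 1.0, 0.02)
        g = np.exp(-((r - 0.2) ** 2) / 1e-4) + 0.5 * np.exp(-((r - 0.6) ** 2) / 1e-4)
        peaks = rdf_peaks(r, g)
        assert abs(peaks[0] - 0.2) < 0.02 and abs(peaks[1] - 0.6) < 0.02


class TestVirialStress:
    def _qp(self, state, buffer=None):
        from cytorod.constraints import assemble_qp, collect_collisions, collect_tethers

        uni = collect_collisions(state, buffer)
        bil = collect_tethers(state)
        return assemble_qp(state, uni, bil, None, 1e-4)

    def test_no_constraints_zero_stress(self):
        st = SystemState(filaments=rods_along([[0, 0, 1]]), rng=np.random.default_rng(0))
        s = virial_stress(None, np.empty(0), 1.0)
        assert np.all(s.sigma_col == 0) and np.all(s.sigma_xl == 0)

    def test_stretched_spring_is_contractile(self):
        fs = rods_along([[1, 0, 0], [1, 0, 0]], centers=[[0, 0, 0], [0, 0.2, 0]])
        pop = MotorPopulation(MotorParams(kappa=100.0, ell0=0.053, vm=0.0), 1)
        pop.state[0] = STATE_D
        pop.fil[0] = (0, 1)
        pop.locked[:] = True
        st = SystemState(filaments=fs, motors=[pop], rng=np.random.default_rng(0))
        qp = self._qp(st)
        from cytorod.constraints import bbpgd_solve

        gamma, _ = bbpgd_solve(qp)
        s = virial_stress(qp, gamma, 1.0)
        assert s.pressure_xl < 0
        assert np.allclose(s.sigma_xl, s.sigma_xl.T, atol=1e-10)

    def test_overlapping_pair_is_extensile(self):
        fs = rods_along([[1, 0, 0], [1, 0, 0]], centers=[[0, 0, 0], [0, 0.02, 0]])
        st = SystemState(filaments=fs, rng=np.random.default_rng(0))
        qp = self._qp(st)
        from cytorod.constraints import bbpgd_solve

        gamma, _ = bbpgd_solve(qp)
        s = virial_stress(qp, gamma, 1.0)
        assert s.pressure_col > 0
        assert s.pressure == pytest.approx(s.pressure_col + s.pressure_xl)

    def test_translation_invariance(self):
        st = ct.gen_bulk_isotropic(30, 0, [2.0, 2.0, 2.0], seed=21, relax=False)
        pop = link(0, [(i, (i + 7) % 30) for i in range(30)])
        pop.arc[:, :] = 0.1
        st.motors = [pop]
        from cytorod.constraints import bbpgd_solve

        qp = self._qp(st, buffer=0.01)
        gamma, _ = bbpgd_solve(qp)
        s1 = virial_stress(qp, gamma, st.boundary.volume())
        st.filaments.centers[:] = st.boundary.wrap(st.filaments.centers + 0.77)
        qp2 = self._qp(st, buffer=0.01)
        gamma2, _ = bbpgd_solve(qp2)
        s2 = virial_stress(qp2, gamma2, st.boundary.volume())
        assert np.allclose(s1.sigma_xl, s2.sigma_xl, atol=1e-8)
        assert np.allclose(s1.sigma_col, s2.sigma_col, atol=1e-8)


def synthetic_trajectory(vx_by_group, n_per_group=40, T=10.0, frames=21, noise=0.0,
                         seed=0):
    """Constant-velocity ±x movers in a periodic tube (known drift oracle)."""
    rng = np.random.default_rng(seed)
    n = n_per_group * len(vx_by_group)
    b = ct.CylinderX(diameter=1.0, period=3.0)
    x0 = rng.random(n) * 3.0
    yz = rng.uniform(-0.05, 0.05, (n, 2))
    vx = np.repeat(vx_by_group, n_per_group)
    axes = np.where(np.repeat(vx_by_group, n_per_group)[:, None] >= 0,
                    [[1.0, 0, 0]], [[-1.0, 0, 0]])
    quats = np.array([quat_from_director(a) for a in axes])
    times = np.linspace(0, T, frames)
    centers = np.zeros((frames, n, 3))
    for k, t in enumerate(times):
        centers[k, :, 0] = x0 + vx * t + noise * rng.standard_normal(n)
        centers[k, :, 1:] = yz
    return Trajectory(
        times=times, centers=centers, quats=np.tile(quats, (frames, 1, 1)),
        lengths=np.full(n, 0.5), diameters=np.full(n, 0.025), boundary=b,
    )


class TestPlaneStrainingVelocity:
    def test_static_filaments_zero_velocity(self):
        traj = synthetic_trajectory([0.0, -0.0])
        df = plane_straining_velocity(traj, [1.0, 1.5], window=0.2, avg_time=10.0)
        if len(df):
            assert np.allclose(df["Vx"], 0.0)

    def test_two_group_drift_recovered(self):
        v = 0.013
        traj = synthetic_trajectory([v, -v])
        df = plane_straining_velocity(traj, np.linspace(0.2, 2.8, 10), window=0.2,
                                      avg_time=10.0)
        assert len(df) > 0
        assert df["Vx"].mean() == pytest.approx(2 * v, rel=1e-9)

    def test_noisy_drift_within_standard_error(self):
        v = 0.02
        traj = synthetic_trajectory([v, -v], noise=5e-4, seed=3)
        df = plane_straining_velocity(traj, np.linspace(0.2, 2.8, 12), window=0.2,
                                      avg_time=10.0)
        se = df["Vx"].std(ddof=1) / np.sqrt(len(df)) + 1e-6
        assert abs(df["Vx"].mean() - 2 * v) < 4 * se + 3e-4

    def test_single_polarity_windows_dropped(self):
        traj = synthetic_trajectory([0.01, 0.02])  # all +x movers
        df = plane_straining_velocity(traj, [1.0], window=0.2, avg_time=10.0)
        assert len(df) == 0


class TestPolarityDivergence:
    def test_uniform_field_zero_divergence(self):
        p = np.zeros((6, 6, 6, 3))
        p[..., 0] = 1.0
        div = polarity_divergence(p, 0.1, length_scale=0.5)
        assert np.allclose(div, 0.0)

    def test_radial_source_positive_divergence(self):
        # p = x̂ on a grid excluding the origin: ∇·(x/|x|) = 2/|x| > 0
        ax = np.linspace(0.5, 1.5, 11)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        R = np.sqrt(X**2 + Y**2 + Z**2)
        p = np.stack([X / R, Y / R, Z / R], axis=-1)
        div = polarity_divergence(p, ax[1] - ax[0], length_scale=1.0)
        interior = div[1:-1, 1:-1, 1:-1]
        expect = (2.0 / R)[1:-1, 1:-1, 1:-1]
        assert np.all(interior > 0)
        assert np.allclose(interior, expect, rtol=0.05)

    def test_opposing_polar_domains_positive_at_interface(self):
        """Minus-ends meeting minus-ends → ∇·p > 0 at the interface."""
        # left domain points −x (minus ends to the right), right domain +x
        edges = (np.linspace(0, 2, 11), np.linspace(0, 0.4, 3), np.linspace(0, 0.4, 3))
        axes = []
        centers = []
        rng = np.random.default_rng(30)
        for k in range(400):
            x = rng.uniform(0, 2)
            centers.append([x, rng.uniform(0, 0.4), rng.uniform(0, 0.4)])
            axes.append([-1.0, 0, 0] if x < 1.0 else [1.0, 0, 0])
        fs = rods_along(axes, centers=centers, length=0.1)
        grid = polarity_field(fs, edges)
        div = polarity_divergence(grid.values["polarity"], (0.2, 0.2, 0.2),
                                  length_scale=0.1)
        mid = div[4:6, :, :]
        assert np.nanmean(mid) > 0
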