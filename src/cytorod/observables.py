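"""Measurements: nematic order, RDF, virial stress, straining velocity.

All observables work on a SystemState (instantaneous) or on recorded
trajectory arrays (time-resolved).  Stress uses the constraint virial
σ = (1/V) Σ_k f_k ⊗ d_k with f_k the pair force on the first body and d_k
the minimum-image vector between the application points; collision
(excluded-volume) and crosslinker (tether) contributions are kept separate.
The sign convention makes pushed-apart overlapping pairs extensile
(Π_col > 0) and stretched tethers contractile (Π_xl < 0), with pressure
Π = ⅓ Tr σ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ConfigurationError, FilamentSet
from .state import SystemState


# ----------------------------------------------------------------------------
# Local nematic order (crosslink neighborhoods)
# ----------------------------------------------------------------------------

def local_nematic_order(state: SystemState):
    """Per-filament local nematic order S_local and neighborhood size Nd.

    The neighborhood of filament i is i itself plus every filament directly
    crosslinked to it by a doubly bound motor.  S_local = sqrt(3/2 Q:Q) with
    Q = ⟨p ⊗ p⟩ − δ/3 averaged over the neighborhood; an isolated filament
    has S_local = 1 (self average), an isotropic large neighborhood → 0.
    """
    from .kinetics import D as STATE_D

    filset = state.filaments
    n = filset.n
    partners = [set() for _ in range(n)]
    for pop in state.motors:
        idx = np.nonzero(pop.state == STATE_D)[0]
        for i, j in pop.fil[idx]:
            partners[i].add(int(j))
            partners[j].add(int(i))
    p = filset.directors()
    s_local = np.empty(n)
    nd = np.empty(n, dtype=int)
    eye3 = np.eye(3) / 3.0
    for i in range(n):
        members = sorted(partners[i] - {i})
        sel = np.array([i] + members, dtype=int)
        Q = np.einsum("ki,kj->ij", p[sel], p[sel]) / len(sel) - eye3
        s_local[i] = np.sqrt(1.5 * np.sum(Q * Q))
        nd[i] = len(sel)
    return s_local, nd


def nematic_order_of_directors(p: np.ndarray) -> float:
    """S_local of one director set (helper for isotropic-limit checks)."""
    p = np.atleast_2d(p)
    Q = np.einsum("ki,kj->ij", p, p) / len(p) - np.eye(3) / 3.0
    return float(np.sqrt(1.5 * np.sum(Q * Q)))


# ----------------------------------------------------------------------------
# Axial order profile
# ----------------------------------------------------------------------------

def axial_order_profile(filset: FilamentSet, x_edges: np.ndarray, boundary=None):
    """Windowed axial order S^x(x) = Σ_i W_i · ½(3cos²θ_i − 1) / Σ_i W_i.

    cosθ_i is the director x-component; the weight W_i is the centerline
    arclength of filament i inside the window.  Windows with no filament
    return NaN (missing, not zero).
    """
    x_edges = np.asarray(x_edges, dtype=float)
    p = filset.directors()
    px = p[:, 0]
    cx = filset.centers[:, 0]
    value = 0.5 * (3.0 * px**2 - 1.0)
    half_span = 0.5 * filset.lengths * np.abs(px)
    nbin = len(x_edges) - 1
    num = np.zeros(nbin)
    den = np.zeros(nbin)
    period = None
    if boundary is not None and 0 in getattr(boundary, "periodic_axes", ()):
        period = boundary.period_vector()[0]
    for k in range(nbin):
        e0, e1 = x_edges[k], x_edges[k + 1]
        mid = 0.5 * (e0 + e1)
        d = cx - mid
        if period is not None:
            d -= period * np.round(d / period)
        lo = d - half_span
        hi = d + half_span
        wid = 0.5 * (e1 - e0)
        overlap_x = np.minimum(hi, wid) - np.maximum(lo, -wid)
        w = np.zeros(len(cx))
        tilted = np.abs(px) > 1e-12
        w[tilted] = np.clip(overlap_x[tilted], 0.0, None) / np.abs(px[tilted])
        flat = ~tilted & (np.abs(d) <= wid)
        w[flat] = filset.lengths[flat]
        num[k] = np.sum(w * value)
        den[k] = np.sum(w)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    centers = 0.5 * (x_edges[:-1] + x_edges[1:])
    return centers, profile, den


# ----------------------------------------------------------------------------
# Radial distribution function of minus ends
# ----------------------------------------------------------------------------

def rdf_minus_ends(points, boundary, r_max: float, dr: float):
    """Pair-distance histogram g(r), ideal-gas normalized.

    `points` is one (N,3) array or a list of frames (averaged).  Distances
    use the minimum image; r_max must not exceed half the shortest periodic
    edge.
    """
    from scipy.spatial import cKDTree

    if boundary.kind != "periodic_box":
        raise ConfigurationError("rdf_minus_ends requires a fully periodic box")
    if r_max > 0.5 * np.min(boundary.lengths):
        raise ConfigurationError("r_max exceeds half the shortest box edge")
    frames = points if isinstance(points, (list, tuple)) else [points]
    edges = np.arange(0.0, r_max + dr, dr)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(len(edges) - 1)
    n_pairs_tot = 0.0
    vol = boundary.volume()
    for pts in frames:
        pts = boundary.wrap(np.asarray(pts, dtype=float))
        pts = np.minimum(pts, np.nextafter(boundary.lengths, 0.0))
        n = len(pts)
        tree = cKDTree(pts, boxsize=boundary.lengths)
        pairs = tree.query_pairs(edges[-1], output_type="ndarray")
        if len(pairs):
            d = boundary.min_image(pts[pairs[:, 0]] - pts[pairs[:, 1]])
            r = np.linalg.norm(d, axis=1)
            h, _ = np.histogram(r, bins=edges)
            counts += h
        n_pairs_tot += 0.5 * n * (n - 1)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = n_pairs_tot * shell / vol
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(expected > 0, counts / np.maximum(expected, 1e-300), 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, g


def rdf_peaks(r, g, min_separation: float = 0.0):
    """Radii of strict local maxima of g(r), largest-amplitude first kept in
    radial order; adjacent-bin plateaus count once."""
    peaks = []
    for k in range(1, len(g) - 1):
        if g[k] > 0 and g[k] >= g[k - 1] and g[k] > g[k + 1]:
            if peaks and r[k] - peaks[-1][0] < min_separation:
                if g[k] > peaks[-1][1]:
                    peaks[-1] = (r[k], g[k])
                continue
            peaks.append((r[k], g[k]))
    return [p[0] for p in peaks]


# ----------------------------------------------------------------------------
# Virial stress
# ----------------------------------------------------------------------------

@dataclass
class StressTensor:
    """Collision and crosslinker virial stress (pN·µm⁻²) over volume V."""

    sigma_col: np.ndarray
    sigma_xl: np.ndarray
    volume: float

    @property
    def pressure_col(self) -> float:
        return float(np.trace(self.sigma_col) / 3.0)

    @property
    def pressure_xl(self) -> float:
        return float(np.trace(self.sigma_xl) / 3.0)

    @property
    def pressure(self) -> float:
        return self.pressure_col + self.pressure_xl


def virial_stress(qp, gamma: np.ndarray, volume: float) -> StressTensor:
    """Constraint virial stress from a solved QP.

    σ = (1/V) Σ f ⊗ d with f = γ n̂ the force on the first body and d the
    minimum-image vector between application points.  Wall contacts
    contribute zero (their application points coincide).
    """
    sigma_col = np.zeros((3, 3))
    sigma_xl = np.zeros((3, 3))
    if qp is None or qp.n == 0:
        return StressTensor(sigma_col, sigma_xl, volume)
    gu = gamma[: qp.nu]
    gb = gamma[qp.nu :]
    if qp.nu:
        d = qp.uni.point_i - qp.uni.point_j
        f = gu[:, None] * qp.uni.normal
        sigma_col = np.einsum("ki,kj->ij", f, d) / volume
    if qp.nb:
        d = qp.bil.point_i - qp.bil.point_j
        f = gb[:, None] * qp.bil.normal
        sigma_xl = np.einsum("ki,kj->ij", f, d) / volume
    return StressTensor(sigma_col, sigma_xl, volume)


# ----------------------------------------------------------------------------
# Sampling-plane straining velocity
# ----------------------------------------------------------------------------

def plane_straining_velocity(
    traj,
    plane_xs,
    window: float = 0.2,
    avg_time: float = 10.0,
    sample_times=None,
    sample_offsets=None,
    center_yz=(0.0, 0.0),
) -> pd.DataFrame:
    """Joint (Px, Vx) samples from virtual sampling planes orthogonal to x.

    For each sampling time t0 and plane x0, square windows of edge `window`
    are drawn around sample points in the (y, z) plane.  For the filaments
    whose centerline crosses the plane inside a window at t0: Px is their
    mean director x-component, and V±x the mean x-velocity (unwrapped
    displacement over avg_time) of the +x and −x movers; Vx = V+x − V−x.
    Windows missing either mover group are dropped.
    """
    times = np.asarray(traj.times)
    if sample_times is None:
        sample_times = [times[0]]
    if sample_offsets is None:
        d = 0.5 * window
        sample_offsets = [(0.0, 0.0), (d, 0.0), (-d, 0.0), (0.0, d), (0.0, -d)]
    period = None
    if 0 in getattr(traj.boundary, "periodic_axes", ()):
        period = traj.boundary.period_vector()[0]
    from .geometry import quat_rotate

    rows = []
    for t0 in sample_times:
        k0 = int(np.argmin(np.abs(times - t0)))
        k1 = int(np.argmin(np.abs(times - (times[k0] + avg_time))))
        dt = times[k1] - times[k0]
        if dt <= 0:
            raise ConfigurationError("averaging interval extends past the trajectory")
        c0 = traj.centers[k0]
        p0 = quat_rotate(traj.quats[k0], np.array([0.0, 0.0, 1.0]))
        vx = (traj.centers[k1][:, 0] - c0[:, 0]) / dt
        half = 0.5 * traj.lengths
        cw = traj.boundary.wrap(c0)
        for x0 in np.atleast_1d(plane_xs):
            dx = cw[:, 0] - x0
            if period is not None:
                dx -= period * np.round(dx / period)
            px = p0[:, 0]
            with np.errstate(divide="ignore", invalid="ignore"):
                s_star = np.where(np.abs(px) > 1e-12, -dx / np.where(np.abs(px) > 1e-12, px, 1.0), np.inf)
            crosses = np.abs(s_star) <= half
            if not np.any(crosses):
                continue
            yz = cw[crosses, 1:] + s_star[crosses, None] * p0[crosses, 1:]
            for kp, (oy, oz) in enumerate(sample_offsets):
                y0, z0 = center_yz[0] + oy, center_yz[1] + oz
                inwin = (np.abs(yz[:, 0] - y0) <= 0.5 * window) & (
                    np.abs(yz[:, 1] - z0) <= 0.5 * window
                )
                if not np.any(inwin):
                    continue
                sel = np.nonzero(crosses)[0][inwin]
                vpos = vx[sel][vx[sel] > 0]
                vneg = vx[sel][vx[sel] < 0]
                if len(vpos) == 0 or len(vneg) == 0:
                    continue
                rows.append(
                    {
                        "time": times[k0],
                        "plane_x": float(x0),
                        "point": kp,
                        "Px": float(np.mean(p0[sel, 0])),
                        "Vx": float(np.mean(vpos) - np.mean(vneg)),
                        "n_plus": int(len(vpos)),
                        "n_minus": int(len(vneg)),
                    }
                )
    return pd.DataFrame(rows, columns=["time", "plane_x", "point", "Px", "Vx", "n_plus", "n_minus"])


# ----------------------------------------------------------------------------
# Polarity field and divergence
# ----------------------------------------------------------------------------

@dataclass
class FieldGrid:
    """Windowed fields on a regular Cartesian grid."""

    edges: tuple
    values: dict = field(default_factory=dict)

    @property
    def centers(self) -> tuple:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)


def polarity_field(filset: FilamentSet, edges) -> FieldGrid:
    """Mean director (polarity) per grid cell; NaN where a cell is empty."""
    p = filset.directors()
    c = filset.centers
    shape = tuple(len(e) - 1 for e in edges)
    counts = np.zeros(shape)
    psum = np.zeros(shape + (3,))
    ix = [np.clip(np.searchsorted(edges[a], c[:, a], side="right") - 1, 0, shape[a] - 1) for a in range(3)]
    np.add.at(counts, tuple(ix), 1.0)
    for comp in range(3):
        np.add.at(psum[..., comp], tuple(ix), p[:, comp])
    with np.errstate(invalid="ignore", divide="ignore"):
        pmean = np.where(counts[..., None] > 0, psum / np.maximum(counts[..., None], 1e-300), np.nan)
    grid = FieldGrid(edges=tuple(np.asarray(e) for e in edges))
    grid.values["polarity"] = pmean
    grid.values["count"] = counts
    return grid


def polarity_divergence(pfield: np.ndarray, spacing, length_scale: float = 1.0) -> np.ndarray:
    """Central-difference divergence of a polarity field, × filament length.

    NaN cells propagate NaN into their neighbors' derivatives."""
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    div = np.zeros(pfield.shape[:-1])
    for a in range(3):
        div += np.gradient(pfield[..., a], spacing[a], axis=a)
    return div * length_scale


def motor_density_field(state: SystemState, edges) -> np.ndarray:
    """Number of motors (any state, by current head/unbound position) per cell
    volume (µm⁻³)."""
    from .kinetics import D as STATE_D, SA, SB, U as STATE_U

    shape = tuple(len(e) - 1 for e in edges)
    counts = np.zeros(shape)
    p = state.filaments.directors()
    for pop in state.motors:
        pos = pop.x.copy()
        bound = pop.head_bound()
        anyb = bound.any(axis=1)
        if np.any(anyb):
            hd = np.where(bound[anyb, 0], 0, 1)
            f = pop.fil[anyb, hd]
            pos[anyb] = state.filaments.centers[f] + pop.arc[anyb, hd, None] * p[f]
        ix = [
            np.clip(np.searchsorted(edges[a], pos[:, a], side="right") - 1, 0, shape[a] - 1)
            for a in range(3)
        ]
        np.add.at(counts, tuple(ix), 1.0)
    cellvol = np.prod([np.diff(e)[0] for e in edges])
    return counts / cellvol
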