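"""Simulation domains: periodic boxes, spheres, spherical shells, cylinders.

A boundary provides (i) periodic wrapping / minimum-image displacement where
applicable, (ii) signed gaps between filament endcap spheres and impermeable
walls (fed to the collision constraint machinery as one-sided unilateral
constraints), and (iii) reflection of unbound motor positions at impermeable
walls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ConfigurationError, FilamentSet


class Boundary:
    """Base: free space (no walls, no periodicity)."""

    kind = "free"
    periodic_axes: tuple[int, ...] = ()

    def min_image(self, dx: np.ndarray) -> np.ndarray:
        return np.asarray(dx, dtype=float)

    def wrap(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)

    def wrap_filaments(self, filset: FilamentSet) -> None:
        return None

    def wall_gaps(self, filset: FilamentSet):
        """Signed endcap-to-wall separations below are returned by subclasses
        as (fil_idx, sep, contact_point, inward_normal) arrays; free space has
        no walls."""
        return (
            np.empty(0, dtype=int),
            np.empty(0),
            np.empty((0, 3)),
            np.empty((0, 3)),
        )

    def reflect(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)

    def volume(self) -> float:
        raise ConfigurationError(f"boundary kind '{self.kind}' has no finite volume")


def _endcap_centers(filset: FilamentSet):
    p = filset.directors()
    half = 0.5 * filset.lengths[:, None]
    ends = np.concatenate([filset.centers - half * p, filset.centers + half * p], axis=0)
    idx = np.concatenate([np.arange(filset.n), np.arange(filset.n)])
    radii = np.concatenate([filset.diameters, filset.diameters]) * 0.5
    return idx, ends, radii


@dataclass
class PeriodicBox(Boundary):
    """Fully periodic orthorhombic box with edge lengths (Lx, Ly, Lz)."""

    lengths: np.ndarray

    kind = "periodic_box"
    periodic_axes = (0, 1, 2)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.shape != (3,) or np.any(self.lengths <= 0):
            raise ConfigurationError("periodic_box requires 3 positive edge lengths")

    def period_vector(self) -> np.ndarray:
        return self.lengths

    def min_image(self, dx: np.ndarray) -> np.ndarray:
        dx = np.asarray(dx, dtype=float)
        return dx - self.lengths * np.round(dx / self.lengths)

    def wrap(self, x: np.ndarray) -> np.ndarray:
        return np.mod(np.asarray(x, dtype=float), self.lengths)

    def wrap_filaments(self, filset: FilamentSet) -> None:
        shift = np.floor(filset.centers / self.lengths).astype(np.int64)
        filset.images += shift
        filset.centers -= shift * self.lengths

    def reflect(self, x: np.ndarray) -> np.ndarray:
        return self.wrap(x)

    def volume(self) -> float:
        return float(np.prod(self.lengths))


@dataclass
class Sphere(Boundary):
    """Impermeable sphere of radius R centered at the origin (interior domain)."""

    radius: float

    kind = "sphere"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError("sphere radius must be positive")

    def wall_gaps(self, filset: FilamentSet):
        idx, ends, radii = _endcap_centers(filset)
        rho = np.linalg.norm(ends, axis=1)
        sep = self.radius - rho - radii
        with np.errstate(invalid="ignore", divide="ignore"):
            rhat = np.where(rho[:, None] > 1e-12, ends / np.maximum(rho, 1e-12)[:, None], 0.0)
        contact = ends + radii[:, None] * rhat
        normal = -rhat  # inward
        return idx, sep, contact, normal

    def reflect(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float)).copy()
        rho = np.linalg.norm(x, axis=1)
        out = rho > self.radius
        if np.any(out):
            new_rho = 2 * self.radius - rho[out]
            new_rho = np.clip(new_rho, 0.0, self.radius)
            x[out] *= (new_rho / rho[out])[:, None]
        return x

    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3


@dataclass
class SphericalShell(Boundary):
    """Gap between two concentric impermeable spheres, r_in < |x| < r_out."""

    r_in: float
    r_out: float

    kind = "spherical_shell"

    def __post_init__(self) -> None:
        if not (0 < self.r_in < self.r_out):
            raise ConfigurationError("spherical_shell requires 0 < r_in < r_out")

    def wall_gaps(self, filset: FilamentSet):
        idx, ends, radii = _endcap_centers(filset)
        rho = np.linalg.norm(ends, axis=1)
        rhat = ends / np.maximum(rho, 1e-12)[:, None]
        # outer wall (inward normal) and inner wall (outward normal)
        sep = np.concatenate([self.r_out - rho - radii, rho - self.r_in - radii])
        contact = np.concatenate([ends + radii[:, None] * rhat, ends - radii[:, None] * rhat])
        normal = np.concatenate([-rhat, rhat])
        return np.concatenate([idx, idx]), sep, contact, normal

    def reflect(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float)).copy()
        rho = np.linalg.norm(x, axis=1)
        new_rho = rho.copy()
        out = rho > self.r_out
        new_rho[out] = 2 * self.r_out - rho[out]
        inn = rho < self.r_in
        new_rho[inn] = 2 * self.r_in - rho[inn]
        new_rho = np.clip(new_rho, self.r_in, self.r_out)
        x *= (new_rho / np.maximum(rho, 1e-12))[:, None]
        return x

    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * (self.r_out**3 - self.r_in**3)


@dataclass
class CylinderX(Boundary):
    """Cylinder along x with impermeable lateral wall; periodic along x."""

    diameter: float
    period: float

    kind = "cylinder_periodic_x"
    periodic_axes = (0,)

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.period <= 0:
            raise ConfigurationError("cylinder diameter and period must be positive")

    def period_vector(self) -> np.ndarray:
        return np.array([self.period, 0.0, 0.0])

    def min_image(self, dx: np.ndarray) -> np.ndarray:
        dx = np.array(dx, dtype=float, copy=True)
        dx[..., 0] -= self.period * np.round(dx[..., 0] / self.period)
        return dx

    def wrap(self, x: np.ndarray) -> np.ndarray:
        x = np.array(x, dtype=float, copy=True)
        x[..., 0] = np.mod(x[..., 0], self.period)
        return x

    def wrap_filaments(self, filset: FilamentSet) -> None:
        shift = np.floor(filset.centers[:, 0] / self.period).astype(np.int64)
        filset.images[:, 0] += shift
        filset.centers[:, 0] -= shift * self.period

    def wall_gaps(self, filset: FilamentSet):
        idx, ends, radii = _endcap_centers(filset)
        rho = np.linalg.norm(ends[:, 1:], axis=1)
        sep = 0.5 * self.diameter - rho - radii
        rhat = np.zeros_like(ends)
        ok = rho > 1e-12
        rhat[ok, 1:] = ends[ok, 1:] / rho[ok, None]
        contact = ends + radii[:, None] * rhat
        normal = -rhat
        # endcaps on the axis have no defined normal; they are far from the
        # wall whenever diameter > filament diameter, so drop them
        return idx[ok], sep[ok], contact[ok], normal[ok]

    def reflect(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float)).copy()
        x[:, 0] = np.mod(x[:, 0], self.period)
        rho = np.linalg.norm(x[:, 1:], axis=1)
        R = 0.5 * self.diameter
        out = rho > R
        if np.any(out):
            new_rho = np.clip(2 * R - rho[out], 0.0, R)
            x[out, 1:] *= (new_rho / rho[out])[:, None]
        return x

    def volume(self) -> float:
        return 0.25 * np.pi * self.diameter**2 * self.period


def make_boundary(spec) -> Boundary:
    """Build a boundary from a config mapping, e.g.
    {"kind": "periodic_box", "lengths": [10, 10, 10]}."""
    if spec is None:
        return Boundary()
    if isinstance(spec, Boundary):
        return spec
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ConfigurationError("boundary spec must be a mapping with a 'kind' key")
    kind = spec["kind"]
    extra = {k: v for k, v in spec.items() if k != "kind"}
    try:
        if kind == "free":
            if extra:
                raise ConfigurationError(f"unexpected keys for free boundary: {sorted(extra)}")
            return Boundary()
        if kind == "periodic_box":
            return PeriodicBox(lengths=np.asarray(extra.pop("lengths")))
        if kind == "sphere":
            return Sphere(radius=float(extra.pop("radius")))
        if kind == "spherical_shell":
            return SphericalShell(r_in=float(extra.pop("r_in")), r_out=float(extra.pop("r_out")))
        if kind == "cylinder_periodic_x":
            return CylinderX(diameter=float(extra.pop("diameter")), period=float(extra.pop("period")))
    except KeyError as exc:
        raise ConfigurationError(f"boundary kind '{kind}' is missing required key {exc}") from exc
    finally:
        pass
    raise ConfigurationError(
        f"unsupported boundary kind '{kind}' "
        "(expected one of free, periodic_box, sphere, spherical_shell, cylinder_periodic_x)"
    )


def wall_gap(f, b: Boundary):
    """Per-filament wall gaps of a single spherocylinder (spec-level API).

    Returns a list of (sep, contact_point, inward_normal) for both endcap
    spheres against every wall of the domain."""
    filset = FilamentSet(
        centers=f.center[None, :],
        quats=f.quat[None, :],
        lengths=[f.length],
        diameters=[f.diameter],
        mobile=[f.mobile],
        bindable=[f.bindable],
    )
    _, sep, contact, normal = b.wall_gaps(filset)
    return [(float(s), c.copy(), n.copy()) for s, c, n in zip(sep, contact, normal)]


def wrap_and_image(x: np.ndarray, b: Boundary) -> np.ndarray:
    """Canonical coordinates of x in the primary cell of b."""
    return b.wrap(x)


# ----------------------------------------------------------------------------
# Neighbor search helpers (cell-list equivalent via kd-trees)
# ----------------------------------------------------------------------------

def filament_pair_candidates(filset: FilamentSet, cutoff: float, boundary: Boundary) -> np.ndarray:
    """Candidate filament pairs with center distance < cutoff (K, 2) int array.

    Uses a periodic kd-tree where the box is fully periodic, ghost images for
    the x-periodic cylinder, and brute force for small systems or when the
    cutoff exceeds half the periodic cell.
    """
    from scipy.spatial import cKDTree

    n = filset.n
    if n < 2:
        return np.empty((0, 2), dtype=int)
    if n <= 24:
        ii, jj = np.triu_indices(n, k=1)
        dx = filset.centers[ii] - filset.centers[jj]
        dx = boundary.min_image(dx)
        keep = np.einsum("ij,ij->i", dx, dx) < cutoff * cutoff
        return np.stack([ii[keep], jj[keep]], axis=1)
    if boundary.kind == "periodic_box" and cutoff < 0.5 * np.min(boundary.lengths):
        pos = boundary.wrap(filset.centers)
        pos = np.minimum(pos, np.nextafter(boundary.lengths, 0.0))
        tree = cKDTree(pos, boxsize=boundary.lengths)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        return pairs
    if boundary.kind == "cylinder_periodic_x" and cutoff < 0.5 * boundary.period:
        pos = boundary.wrap(filset.centers)
        ghosts = []
        src = []
        near_lo = pos[:, 0] < cutoff
        near_hi = pos[:, 0] > boundary.period - cutoff
        for mask, shift in ((near_lo, +boundary.period), (near_hi, -boundary.period)):
            g = pos[mask].copy()
            g[:, 0] += shift
            ghosts.append(g)
            src.append(np.nonzero(mask)[0])
        allpos = np.concatenate([pos] + ghosts, axis=0)
        srcidx = np.concatenate([np.arange(n)] + src)
        tree = cKDTree(allpos)
        raw = tree.query_pairs(cutoff, output_type="ndarray")
        a = srcidx[raw[:, 0]]
        b = srcidx[raw[:, 1]]
        keep = a != b
        a, b = a[keep], b[keep]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        codes = np.unique(lo.astype(np.int64) * n + hi)
        return np.stack([codes // n, codes % n], axis=1)
    # free space / sphere / shell, or oversized cutoff: plain tree or all pairs
    if boundary.kind in ("free", "sphere", "spherical_shell"):
        tree = cKDTree(filset.centers)
        return tree.query_pairs(cutoff, output_type="ndarray")
    ii, jj = np.triu_indices(n, k=1)
    dx = boundary.min_image(filset.centers[ii] - filset.centers[jj])
    keep = np.einsum("ij,ij->i", dx, dx) < cutoff * cutoff
    return np.stack([ii[keep], jj[keep]], axis=1)


def point_filament_candidates(
    points: np.ndarray, filset: FilamentSet, radius: float, boundary: Boundary
):
    """For each query point, indices of filaments whose center lies within
    radius.  Returns (flat_point_idx, flat_fil_idx) arrays."""
    from scipy.spatial import cKDTree

    points = np.atleast_2d(points)
    m, n = points.shape[0], filset.n
    if m == 0 or n == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    if m * n <= 4096:
        dx = points[:, None, :] - filset.centers[None, :, :]
        dx = boundary.min_image(dx.reshape(-1, 3)).reshape(m, n, 3)
        mask = np.einsum("ijk,ijk->ij", dx, dx) < radius * radius
        pi, fi = np.nonzero(mask)
        return pi, fi
    if boundary.kind == "periodic_box" and radius < 0.5 * np.min(boundary.lengths):
        pos = boundary.wrap(filset.centers)
        pos = np.minimum(pos, np.nextafter(boundary.lengths, 0.0))
        qry = boundary.wrap(points)
        qry = np.minimum(qry, np.nextafter(boundary.lengths, 0.0))
        tree = cKDTree(pos, boxsize=boundary.lengths)
        lists = tree.query_ball_point(qry, radius)
        pi = np.repeat(np.arange(m), [len(l) for l in lists])
        fi = np.concatenate([np.asarray(l, dtype=int) for l in lists]) if len(pi) else np.empty(0, dtype=int)
        return pi, fi
    # generic fallback in blocks
    out_p, out_f = [], []
    block = max(1, 20000 // max(n, 1))
    for start in range(0, m, block):
        sub = points[start : start + block]
        dx = sub[:, None, :] - filset.centers[None, :, :]
        dx = boundary.min_image(dx.reshape(-1, 3)).reshape(len(sub), n, 3)
        mask = np.einsum("ijk,ijk->ij", dx, dx) < radius * radius
        pi, fi = np.nonzero(mask)
        out_p.append(pi + start)
        out_f.append(fi)
    return np.concatenate(out_p), np.concatenate(out_f)
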