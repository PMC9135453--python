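"""Rigid spherocylinder geometry, quaternion kinematics, and mobility.

Filaments are rigid spherocylinders (cylinders with hemispherical caps) described
by a center position ``x`` (µm), a unit quaternion ``q = [s, p]`` (scalar-first),
a length ``L`` (end-sphere-center to end-sphere-center plus the caps, i.e. the
centerline segment has length ``L``) and a diameter ``D``.  The director
``p_hat`` is obtained by rotating the reference axis (0, 0, 1) by the
quaternion; the minus end sits at ``x - (L/2) p_hat`` and the plus end at
``x + (L/2) p_hat``.

Units used throughout the package: length µm, force pN, time s, energy pN·µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Boltzmann constant times 300 K, in pN·µm.
KBT_ROOM = 4.141e-3

_QUAT_NORM_TOL = 1e-9
_REF_AXIS = np.array([0.0, 0.0, 1.0])


class ConfigurationError(ValueError):
    """Raised for invalid filament or parameter configurations."""


# ----------------------------------------------------------------------------
# Quaternion helpers (scalar-first convention, q = [s, px, py, pz])
# ----------------------------------------------------------------------------

def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-14):
        raise ConfigurationError("zero quaternion cannot be normalized")
    return q / n


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b, broadcasting over leading axes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    s1, v1 = a[..., 0], a[..., 1:]
    s2, v2 = b[..., 0], b[..., 1:]
    s = s1 * s2 - np.sum(v1 * v2, axis=-1)
    v = (
        s1[..., None] * v2
        + s2[..., None] * v1
        + np.cross(v1, v2)
    )
    return np.concatenate([s[..., None], v], axis=-1)


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by quaternion(s) q."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    s, p = q[..., 0:1], q[..., 1:]
    t = 2.0 * np.cross(p, v)
    return v + s * t + np.cross(p, t)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """3×3 rotation matrix of a single quaternion."""
    s, x, y, z = np.asarray(q, dtype=float)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - s * z), 2 * (x * z + s * y)],
            [2 * (x * y + s * z), 1 - 2 * (x * x + z * z), 2 * (y * z - s * x)],
            [2 * (x * z - s * y), 2 * (y * z + s * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_from_rotvec(w: np.ndarray) -> np.ndarray:
    """Exponential map: rotation vector(s) w (axis * angle) → quaternion(s)."""
    w = np.asarray(w, dtype=float)
    angle = np.linalg.norm(w, axis=-1, keepdims=True)
    half = 0.5 * angle
    small = angle[..., 0] < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(angle > 1e-12, w / angle, 0.0)
    q = np.concatenate([np.cos(half), np.sin(half) * axis], axis=-1)
    if np.any(small):
        ident = np.zeros_like(q)
        ident[..., 0] = 1.0
        q = np.where(small[..., None], ident, q)
    return q


# ----------------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------------

@dataclass
class Spherocylinder:
    """A single rigid filament (view object; bulk data lives in FilamentSet)."""

    id: int
    center: np.ndarray
    quat: np.ndarray
    length: float
    diameter: float
    mobile: bool = True
    bindable: bool = True

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        if self.length <= 0 or self.diameter <= 0:
            raise ConfigurationError("filament length and diameter must be > 0")
        n = np.linalg.norm(self.quat)
        if abs(n - 1.0) > 1e-6:
            raise ConfigurationError(f"quaternion norm {n} too far from 1")
        self.quat = self.quat / n

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    def director(self) -> np.ndarray:
        return director(self)

    def minus_end(self) -> np.ndarray:
        return self.center - 0.5 * self.length * self.director()

    def plus_end(self) -> np.ndarray:
        return self.center + 0.5 * self.length * self.director()

    def point_at(self, s: float) -> np.ndarray:
        """Centerline point at arc coordinate s ∈ [−L/2, L/2]."""
        return self.center + s * self.director()


def director(f: Spherocylinder | np.ndarray) -> np.ndarray:
    """Unit orientation vector from minus to plus end.

    Accepts a Spherocylinder or a raw quaternion.  The reference axis (0,0,1)
    is rotated by the (normalized) quaternion.
    """
    q = f.quat if isinstance(f, Spherocylinder) else np.asarray(f, dtype=float)
    n = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(n - 1.0) > _QUAT_NORM_TOL):
        raise ConfigurationError("quaternion not normalized")
    return quat_rotate(q, _REF_AXIS)


@dataclass
class MobilityCoefficients:
    """Slender-body drag coefficients for one filament.

    zeta_par/zeta_perp are translational drags along/perpendicular to the
    axis (pN·s·µm⁻¹); zeta_rot is the rotational drag about a transverse axis
    through the center (pN·s·µm).
    """

    eta: float
    zeta_par: float
    zeta_perp: float
    zeta_rot: float

    def __post_init__(self) -> None:
        if min(self.zeta_par, self.zeta_perp, self.zeta_rot) <= 0:
            raise ConfigurationError("drag coefficients must be positive")
        if self.zeta_perp < self.zeta_par:
            raise ConfigurationError("slender rods require zeta_perp >= zeta_par")


def slender_body_drag(eta: float, length: float, diameter: float) -> MobilityCoefficients:
    """Standard slender-body drags: ζ∥ = 2πηL/ln(2L/D), ζ⊥ = 2ζ∥,
    ζrot = πηL³/(3 ln(2L/D))."""
    if length <= 0 or diameter <= 0:
        raise ConfigurationError("length and diameter must be positive")
    g = np.log(2.0 * length / diameter)
    if g <= 0:
        raise ConfigurationError("aspect ratio 2L/D must exceed 1")
    zpar = 2.0 * np.pi * eta * length / g
    return MobilityCoefficients(eta, zpar, 2.0 * zpar, np.pi * eta * length**3 / (3.0 * g))


# ----------------------------------------------------------------------------
# Filament container (struct-of-arrays)
# ----------------------------------------------------------------------------

@dataclass
class FilamentSet:
    """All filaments of a system, stored columnar for vectorized kernels."""

    centers: np.ndarray        # (N, 3)
    quats: np.ndarray          # (N, 4)
    lengths: np.ndarray        # (N,)
    diameters: np.ndarray      # (N,)
    mobile: np.ndarray         # (N,) bool
    bindable: np.ndarray       # (N,) bool
    eta: float = 0.01          # solvent viscosity, pN·s·µm⁻²
    images: np.ndarray = field(default=None)  # (N, 3) int, periodic wrap count

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.quats = np.atleast_2d(np.asarray(self.quats, dtype=float))
        self.lengths = np.atleast_1d(np.asarray(self.lengths, dtype=float))
        self.diameters = np.atleast_1d(np.asarray(self.diameters, dtype=float))
        self.mobile = np.atleast_1d(np.asarray(self.mobile, dtype=bool))
        self.bindable = np.atleast_1d(np.asarray(self.bindable, dtype=bool))
        if np.any(self.lengths <= 0) or np.any(self.diameters <= 0):
            raise ConfigurationError("filament length and diameter must be > 0")
        if self.images is None:
            self.images = np.zeros((self.n, 3), dtype=np.int64)
        self._refresh_drags()

    def _refresh_drags(self) -> None:
        g = np.log(2.0 * self.lengths / self.diameters)
        zpar = 2.0 * np.pi * self.eta * self.lengths / g
        self.zeta_par = zpar
        self.zeta_perp = 2.0 * zpar
        self.zeta_rot = np.pi * self.eta * self.lengths**3 / (3.0 * g)

    @property
    def n(self) -> int:
        return self.centers.shape[0]

    @classmethod
    def from_list(cls, filaments: list[Spherocylinder], eta: float = 0.01) -> "FilamentSet":
        return cls(
            centers=np.array([f.center for f in filaments], dtype=float),
            quats=np.array([f.quat for f in filaments], dtype=float),
            lengths=np.array([f.length for f in filaments], dtype=float),
            diameters=np.array([f.diameter for f in filaments], dtype=float),
            mobile=np.array([f.mobile for f in filaments], dtype=bool),
            bindable=np.array([f.bindable for f in filaments], dtype=bool),
            eta=eta,
        )

    def view(self, i: int) -> Spherocylinder:
        return Spherocylinder(
            id=i,
            center=self.centers[i].copy(),
            quat=self.quats[i].copy(),
            length=float(self.lengths[i]),
            diameter=float(self.diameters[i]),
            mobile=bool(self.mobile[i]),
            bindable=bool(self.bindable[i]),
        )

    def directors(self) -> np.ndarray:
        # closed form for rotating the reference axis (0,0,1): avoids the
        # general quaternion product in the hot paths
        q = self.quats
        s, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
        out = np.empty((self.n, 3))
        out[:, 0] = 2.0 * (x * z + s * y)
        out[:, 1] = 2.0 * (y * z - s * x)
        out[:, 2] = 1.0 - 2.0 * (x * x + y * y)
        return out

    def minus_ends(self) -> np.ndarray:
        return self.centers - 0.5 * self.lengths[:, None] * self.directors()

    def plus_ends(self) -> np.ndarray:
        return self.centers + 0.5 * self.lengths[:, None] * self.directors()

    def points_at(self, idx: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Centerline points at arc coordinates s on filaments idx."""
        idx = np.asarray(idx, dtype=int)
        s = np.asarray(s, dtype=float)
        return self.centers[idx] + s[..., None] * self.directors()[idx]

    def unwrapped_centers(self, boundary=None) -> np.ndarray:
        if boundary is None or not hasattr(boundary, "period_vector"):
            return self.centers.copy()
        return self.centers + self.images * boundary.period_vector()

    def copy(self) -> "FilamentSet":
        return FilamentSet(
            centers=self.centers.copy(),
            quats=self.quats.copy(),
            lengths=self.lengths.copy(),
            diameters=self.diameters.copy(),
            mobile=self.mobile.copy(),
            bindable=self.bindable.copy(),
            eta=self.eta,
            images=self.images.copy(),
        )


# ----------------------------------------------------------------------------
# Mobility map U = M F
# ----------------------------------------------------------------------------

def mobility_apply(filset: FilamentSet, F: np.ndarray) -> np.ndarray:
    """Apply the block-diagonal mobility matrix: U = M F.

    F is a 6N vector ordered [force_1, torque_1, ..., force_N, torque_N].
    Translational mobility is anisotropic (1/ζ∥ along the director, 1/ζ⊥
    transverse); rotation uses 1/ζrot with the axial spin component projected
    out (a spherocylinder's spin about its own axis is a null mode).
    Immobile filaments get zero velocity.
    """
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ConfigurationError("non-finite force vector")
    n = filset.n
    FT = F.reshape(n, 6)
    f, tau = FT[:, :3], FT[:, 3:]
    p = filset.directors()
    fpar = np.sum(f * p, axis=1, keepdims=True) * p
    fperp = f - fpar
    v = fpar / filset.zeta_par[:, None] + fperp / filset.zeta_perp[:, None]
    tau_perp = tau - np.sum(tau * p, axis=1, keepdims=True) * p
    w = tau_perp / filset.zeta_rot[:, None]
    U = np.empty_like(FT)
    U[:, :3] = v
    U[:, 3:] = w
    U[~filset.mobile] = 0.0
    return U.reshape(-1)


def mobility_apply_multi(filset: FilamentSet, F: np.ndarray) -> np.ndarray:
    """U = M F for a (6N, m) matrix of force/torque columns."""
    F = np.asarray(F, dtype=float)
    n, m = filset.n, F.shape[1]
    FT = F.reshape(n, 6, m)
    f, tau = FT[:, :3, :], FT[:, 3:, :]
    p = filset.directors()[:, :, None]
    fpar = np.sum(f * p, axis=1, keepdims=True) * p
    fperp = f - fpar
    v = fpar / filset.zeta_par[:, None, None] + fperp / filset.zeta_perp[:, None, None]
    tau_perp = tau - np.sum(tau * p, axis=1, keepdims=True) * p
    w = tau_perp / filset.zeta_rot[:, None, None]
    out = np.concatenate([v, w], axis=1)
    out[~filset.mobile] = 0.0
    return out.reshape(6 * n, m)


def advance_configuration(filset: FilamentSet, U: np.ndarray, h: float, boundary=None) -> None:
    """Advance centers and quaternions by velocities U over a step h (in place).

    Rotation uses the quaternion exponential map of h·ω followed by
    renormalization; centers are wrapped back into the primary periodic cell.
    """
    if h <= 0:
        raise ConfigurationError("timestep must be positive")
    U = np.asarray(U, dtype=float)
    if not np.all(np.isfinite(U)):
        raise ConfigurationError("non-finite velocity in advance_configuration")
    n = filset.n
    UT = U.reshape(n, 6)
    filset.centers += h * UT[:, :3]
    w = UT[:, 3:]
    moving = np.einsum("ij,ij->i", w, w) > 0
    if np.any(moving):
        dq = quat_from_rotvec(h * w[moving])
        filset.quats[moving] = quat_multiply(dq, filset.quats[moving])
        filset.quats[moving] /= np.linalg.norm(filset.quats[moving], axis=1, keepdims=True)
    if boundary is not None:
        boundary.wrap_filaments(filset)


# ----------------------------------------------------------------------------
# Pairwise minimal distance between spherocylinders
# ----------------------------------------------------------------------------

def segment_pair_geometry(
    r: np.ndarray,
    p1: np.ndarray,
    h1: np.ndarray,
    p2: np.ndarray,
    h2: np.ndarray,
):
    """Closest points between centerline segments, vectorized over pairs.

    Parameters: r = c1 − c2 (minimum image already applied), unit directors
    p1/p2, half-lengths h1/h2.  Returns (dist, s1, s2, nhat) with arc
    coordinates in [−h, h] and nhat the unit vector from segment 2's closest
    point toward segment 1's.  The degenerate parallel-overlap case uses the
    midpoint of the overlap interval (deterministic, symmetric tie-break).
    """
    r = np.atleast_2d(np.asarray(r, dtype=float))
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    p2 = np.atleast_2d(np.asarray(p2, dtype=float))
    h1 = np.atleast_1d(np.asarray(h1, dtype=float))
    h2 = np.atleast_1d(np.asarray(h2, dtype=float))

    b = np.einsum("ij,ij->i", p1, p2)
    f = np.einsum("ij,ij->i", p1, r)
    e = np.einsum("ij,ij->i", p2, r)
    denom = 1.0 - b * b

    parallel = denom < 1e-12

    # --- generic (skew) branch: clamped alternating projection (exact for
    # segment-segment: the constrained minimum lies on a boundary or interior
    # stationary point, both covered by the two-pass clamp).
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(parallel, 0.0, np.clip((b * e - f) / np.where(parallel, 1.0, denom), -h1, h1))
    t = np.clip(s * b + e, -h2, h2)
    s = np.clip(t * b - f, -h1, h1)
    # after clamping s, t may need one more projection
    t = np.clip(s * b + e, -h2, h2)

    if np.any(parallel):
        sgn = np.where(b[parallel] >= 0, 1.0, -1.0)
        fp = f[parallel]
        h1p, h2p = h1[parallel], h2[parallel]
        # projections of segment-2 endpoints onto segment-1's axis coordinate
        sa = -h2p * sgn - fp
        sb = h2p * sgn - fp
        lo = np.minimum(sa, sb)
        hi = np.maximum(sa, sb)
        olo = np.maximum(-h1p, lo)
        ohi = np.minimum(h1p, hi)
        has_overlap = olo <= ohi
        sp = np.where(has_overlap, 0.5 * (olo + ohi), np.where(lo > h1p, h1p, -h1p))
        tp = np.clip((sp + fp) * sgn, -h2p, h2p)
        sp = np.clip(np.where(has_overlap, sp, tp * sgn - fp), -h1p, h1p)
        s[parallel] = sp
        t[parallel] = tp

    diff = r + s[:, None] * p1 - t[:, None] * p2
    dist = np.linalg.norm(diff, axis=1)
    nhat = np.empty_like(diff)
    ok = dist > 1e-12
    nhat[ok] = diff[ok] / dist[ok, None]
    if np.any(~ok):
        # coincident closest points: deterministic perpendicular to p1
        for k in np.nonzero(~ok)[0]:
            a = np.argmin(np.abs(p1[k]))
            ref = np.zeros(3)
            ref[a] = 1.0
            v = np.cross(p1[k], ref)
            nhat[k] = v / np.linalg.norm(v)
    return dist, s, t, nhat


def min_distance(f1: Spherocylinder, f2: Spherocylinder, boundary=None):
    """Signed surface separation and contact geometry of two spherocylinders.

    Returns (sep, s1, s2, nhat): sep = centerline distance − (D1+D2)/2
    (negative iff the surfaces overlap), arc coordinates of the closest
    centerline points, and the unit normal pointing from f2's closest point
    toward f1's.  Periodic images are resolved by the minimum-image
    convention on the center-center displacement.
    """
    r = f1.center - f2.center
    if boundary is not None:
        r = boundary.min_image(r)
    d1 = director(f1)
    d2 = director(f2)
    dist, s, t, nhat = segment_pair_geometry(
        r[None, :], d1[None, :], [0.5 * f1.length], d2[None, :], [0.5 * f2.length]
    )
    sep = dist[0] - 0.5 * (f1.diameter + f2.diameter)
    return float(sep), float(s[0]), float(t[0]), nhat[0]
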