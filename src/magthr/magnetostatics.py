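"""Analytic magnetic flux density of small permanent magnets.

Forward model for a magnet-plus-magnetometer sensing system: uniformly
magnetised cylinders and cuboids evaluated at points outside the magnet
body, expressed in an arbitrary laboratory frame through a rigid-body
:class:`Pose`.

Units are fixed package-wide and conversions are centralised here:

* geometry in **mm** (the field of a uniformly magnetised body depends only
  on shape ratios, so any consistent length unit works),
* remanence ``Br`` in **mT** (N42 NdFeB is about 1300 mT),
* returned flux density in **µT**.

Three routes to the field coexist deliberately:

1. exact closed forms — elliptic integrals for the axially magnetised
   cylinder (Derby–Olbert form, via Carlson symmetric integrals) and
   log/arctan charged-plate sums for the cuboid;
2. a surface-charge Gauss–Legendre quadrature engine, spectrally accurate
   in the periodic angle, which is the production path for transversely
   (diametrally) magnetised cylinders and an independent cross-check for
   the closed forms;
3. the point dipole, used as the far-field oracle for everything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import elliprf, elliprj

__all__ = [
    "MagnetSpec",
    "Pose",
    "FieldVector",
    "field",
    "field_cylinder_axial",
    "field_cylinder_diametral",
    "field_cuboid",
    "field_dipole",
    "field_poses",
    "field_quadrature",
    "magnet_moment",
    "MT_TO_UT",
    "MU0",
]

MT_TO_UT = 1.0e3  # millitesla -> microtesla
MU0 = 4.0e-7 * np.pi  # vacuum permeability, T·m/A

# relative perturbation applied to evaluation points that land exactly on a
# formula singularity (cylinder rim circle, cuboid faces/edges)
_SINGULAR_EPS = 1.0e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MagnetSpec:
    """A uniformly magnetised permanent magnet.

    Parameters
    ----------
    shape:
        ``"cylinder"`` (dimensions = diameter, length, mm) or ``"cuboid"``
        (dimensions = a, b, c edge lengths, mm).
    dimensions:
        Outer dimensions in mm, all positive.
    br_mT:
        Remanence vector in the magnet body frame, mT.  An axially
        magnetised cylinder has ``(0, 0, Br)``; a diametral one
        ``(Br, 0, 0)``.
    grade:
        Material grade label, e.g. ``"N42"`` (informational).
    name:
        Free-text identifier used in ranking tables.
    """

    shape: str
    dimensions: tuple[float, ...]
    br_mT: tuple[float, float, float]
    grade: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "cuboid"):
            raise ValueError(f"unknown magnet shape {self.shape!r}")
        ndim = 2 if self.shape == "cylinder" else 3
        dims = tuple(float(d) for d in self.dimensions)
        if len(dims) != ndim:
            raise ValueError(
                f"{self.shape} magnet needs {ndim} dimensions, got {len(dims)}"
            )
        if any(d <= 0 for d in dims):
            raise ValueError("magnet dimensions must be positive")
        object.__setattr__(self, "dimensions", dims)
        object.__setattr__(
            self, "br_mT", tuple(float(b) for b in self.br_mT)
        )

    @property
    def volume_mm3(self) -> float:
        if self.shape == "cylinder":
            d, length = self.dimensions
            return np.pi * (d / 2.0) ** 2 * length
        a, b, c = self.dimensions
        return a * b * c

    @property
    def characteristic_length_mm(self) -> float:
        """Largest outer dimension, used for far-field distance scaling."""
        return max(self.dimensions)

    def scaled_br(self, k: float) -> "MagnetSpec":
        return MagnetSpec(
            self.shape,
            self.dimensions,
            tuple(k * b for b in self.br_mT),
            self.grade,
            self.name,
        )


@dataclass(frozen=True)
class Pose:
    """Rigid placement of a magnet: body frame -> laboratory frame.

    ``position`` is the magnet centre in mm; ``rotation`` the proper
    orthonormal matrix mapping body-frame vectors into the lab frame.
    """

    position: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1.0e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(rot) < 0.0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "rotation", rot)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.zeros(3), np.eye(3))

    def transform(self, rotation: np.ndarray, translation: np.ndarray = None) -> "Pose":
        """Apply a further lab-frame rigid motion ``x -> R x + t``."""
        rotation = np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return Pose(rotation @ self.position + t, rotation @ self.rotation)


class FieldVector(np.ndarray):
    """A three-axis flux density reading in µT.

    Thin ndarray subclass: behaves as a ``(..., 3)`` array in all numerics
    while exposing ``bx/by/bz`` and ``magnitude`` accessors.
    """

    def __new__(cls, data) -> "FieldVector":
        arr = np.asarray(data, dtype=float)
        if arr.shape[-1] != 3:
            raise ValueError("FieldVector needs 3 components on the last axis")
        return arr.view(cls)

    @property
    def bx(self):
        return np.asarray(self[..., 0])

    @property
    def by(self):
        return np.asarray(self[..., 1])

    @property
    def bz(self):
        return np.asarray(self[..., 2])

    @property
    def magnitude(self):
        return np.linalg.norm(np.asarray(self), axis=-1)


# ---------------------------------------------------------------------------
# generalised complete elliptic integral (Bulirsch cel) via Carlson forms
# ---------------------------------------------------------------------------


def _cel(kc, p, a, b):
    """Bulirsch ``cel(kc, p, a, b)`` for p > 0, vectorised.

    Expressed through Carlson symmetric integrals:
    ``cel = a·RF(0, kc², 1) + (b − a·p)/3 · RJ(0, kc², 1, p)``.
    """
    kc = np.asarray(kc, dtype=float)
    p = np.asarray(p, dtype=float)
    a_ = np.asarray(a, dtype=float)
    b_ = np.asarray(b, dtype=float)
    kc2 = kc * kc
    rf = elliprf(0.0, kc2, 1.0)
    coef = b_ - a_ * p
    # RJ(…, p) diverges as p -> 0 but always appears here multiplied by a
    # coefficient that vanishes at least as fast; mask to avoid warnings.
    small = np.abs(p) < 1.0e-14
    p_safe = np.where(small, 1.0, p)
    rj = elliprj(0.0, kc2, 1.0, p_safe)
    out = a_ * rf + coef * rj / 3.0
    return np.where(small, a_ * rf, out)


def _cylinder_axial_body(points: np.ndarray, radius: float, half_len: float,
                         br_uT: float) -> np.ndarray:
    """Field of an axially magnetised cylinder in its body frame, µT.

    Exact elliptic-integral solution for a uniform axial magnetisation;
    valid outside the magnet body.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    rho = np.hypot(x, y)
    a = radius

    # rim-plane ring (z = ±half_len, rho = a) is a true singularity of the
    # formula; nudge radially by a documented epsilon
    on_ring = np.abs(rho - a) < _SINGULAR_EPS * a
    rho = np.where(on_ring, a * (1.0 + _SINGULAR_EPS), rho)

    zp = z + half_len
    zm = z - half_len
    sum_ra = rho + a
    dif_ra = a - rho
    denp = np.sqrt(zp * zp + sum_ra * sum_ra)
    denm = np.sqrt(zm * zm + sum_ra * sum_ra)
    alphap = a / denp
    alpham = a / denm
    betap = zp / denp
    betam = zm / denm
    gamma = dif_ra / sum_ra
    kp = np.sqrt((zp * zp + dif_ra * dif_ra) / (zp * zp + sum_ra * sum_ra))
    km = np.sqrt((zm * zm + dif_ra * dif_ra) / (zm * zm + sum_ra * sum_ra))

    b0 = br_uT / np.pi
    b_rho = b0 * (alphap * _cel(kp, 1.0, 1.0, -1.0)
                  - alpham * _cel(km, 1.0, 1.0, -1.0))
    g2 = gamma * gamma
    b_z = (b0 * a / sum_ra) * (betap * _cel(kp, g2, 1.0, gamma)
                               - betam * _cel(km, g2, 1.0, gamma))

    # resolve radial direction; on the axis b_rho -> 0 and the direction is
    # irrelevant
    safe = np.where(rho > 0.0, rho, 1.0)
    out = np.empty_like(pts)
    out[:, 0] = b_rho * x / safe
    out[:, 1] = b_rho * y / safe
    out[:, 2] = b_z
    out[rho == 0.0, 0:2] = 0.0
    return out


# ---------------------------------------------------------------------------
# cuboid: superposition of uniformly charged rectangular plates
# ---------------------------------------------------------------------------


def _charged_plate(points: np.ndarray, hx: float, hy: float,
                   sigma_uT: float) -> np.ndarray:
    """Field of a uniformly magnetically charged rectangle at z = 0.

    Plate spans [-hx, hx] × [-hy, hy]; ``sigma_uT`` is the magnetic surface
    charge expressed directly in output field units (Br·(M̂·n̂)).
    Closed form: arctan solid-angle term for Bz, log terms in-plane.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    # points exactly in the plate plane hit log/atan branch points
    z = np.where(np.abs(z) < _SINGULAR_EPS * max(hx, hy),
                 _SINGULAR_EPS * max(hx, hy), z)

    u = (x[:, None] - np.array([-hx, hx]))  # (n, 2)
    v = (y[:, None] - np.array([-hy, hy]))
    bx = np.zeros_like(x)
    by = np.zeros_like(x)
    bz = np.zeros_like(x)
    for i, su in ((0, -1.0), (1, 1.0)):
        for j, sv in ((0, -1.0), (1, 1.0)):
            sgn = su * sv
            uu, vv = u[:, i], v[:, j]
            r = np.sqrt(uu * uu + vv * vv + z * z)
            bz += sgn * np.arctan2(uu * vv, z * r)
            bx -= sgn * np.log(vv + r)
            by -= sgn * np.log(uu + r)
    c = sigma_uT / (4.0 * np.pi)
    return np.stack([c * bx, c * by, c * bz], axis=1)


_AXIS_PERMS = {
    # magnetisation axis -> (permutation into plate frame, inverse)
    2: ((0, 1, 2), (0, 1, 2)),
    0: ((1, 2, 0), (2, 0, 1)),
    1: ((2, 0, 1), (1, 2, 0)),
}


def _cuboid_body(points: np.ndarray, half_dims: np.ndarray,
                 br_uT: np.ndarray) -> np.ndarray:
    """Exact field of a uniform cuboid magnet in its body frame, µT.

    The field for each magnetisation component is the superposition of two
    oppositely charged rectangular pole plates; an arbitrary Br vector is
    the sum over its three components (axis permutation).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    total = np.zeros_like(pts)
    for axis in range(3):
        sigma = br_uT[axis]
        if sigma == 0.0:
            continue
        perm, inv = _AXIS_PERMS[axis]
        p = pts[:, perm]
        hx, hy, hz = half_dims[list(perm)]
        plus = p - np.array([0.0, 0.0, hz])
        minus = p + np.array([0.0, 0.0, hz])
        f = _charged_plate(plus, hx, hy, sigma) - _charged_plate(minus, hx, hy, sigma)
        total += f[:, inv]
    return total


# ---------------------------------------------------------------------------
# surface-charge quadrature engine
# ---------------------------------------------------------------------------


def _quadrature_nodes(magnet: MagnetSpec, n_phi: int, n_ax: int):
    """Surface-charge nodes (positions mm, charge·area weights µT·mm²)."""
    br = np.asarray(magnet.br_mT, dtype=float) * MT_TO_UT
    nodes = []
    weights = []
    if magnet.shape == "cylinder":
        d, length = magnet.dimensions
        a, b = d / 2.0, length / 2.0
        phi = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
        gz, gw = leggauss(n_ax)
        zz = b * gz
        # curved side: sigma = Brx cos(phi) + Bry sin(phi)
        if br[0] != 0.0 or br[1] != 0.0:
            P, Z = np.meshgrid(phi, zz, indexing="ij")
            xyz = np.stack([a * np.cos(P), a * np.sin(P), Z], axis=-1).reshape(-1, 3)
            sigma = (br[0] * np.cos(P) + br[1] * np.sin(P)).reshape(-1)
            # area element a dphi dz
            darea = (2.0 * np.pi * a / n_phi) * np.repeat(b * gw[None, :], n_phi, axis=0).reshape(-1)
            nodes.append(xyz)
            weights.append(sigma * darea)
        # end caps: sigma = ±Brz, polar Gauss grid
        if br[2] != 0.0:
            gr, gwr = leggauss(n_ax)
            rr = a * 0.5 * (gr + 1.0)  # map [-1,1] -> [0,a]
            wr = a * 0.5 * gwr
            P, R = np.meshgrid(phi, rr, indexing="ij")
            WR = np.meshgrid(phi, wr, indexing="ij")[1]
            darea = (2.0 * np.pi / n_phi) * R * WR  # r dr dphi
            for sz, sgn in ((b, 1.0), (-b, -1.0)):
                xyz = np.stack(
                    [R * np.cos(P), R * np.sin(P), np.full_like(R, sz)], axis=-1
                ).reshape(-1, 3)
                nodes.append(xyz)
                weights.append(sgn * br[2] * darea.reshape(-1))
    else:
        dims = np.asarray(magnet.dimensions, dtype=float)
        half = dims / 2.0
        g, gw = leggauss(n_ax)
        for axis in range(3):
            if br[axis] == 0.0:
                continue
            t_axes = [i for i in range(3) if i != axis]
            u = half[t_axes[0]] * g
            wu = half[t_axes[0]] * gw
            v = half[t_axes[1]] * g
            wv = half[t_axes[1]] * gw
            U, V = np.meshgrid(u, v, indexing="ij")
            W = np.outer(wu, wv)
            for s, sgn in ((half[axis], 1.0), (-half[axis], -1.0)):
                xyz = np.zeros(U.shape + (3,))
                xyz[..., t_axes[0]] = U
                xyz[..., t_axes[1]] = V
                xyz[..., axis] = s
                nodes.append(xyz.reshape(-1, 3))
                weights.append(sgn * br[axis] * W.reshape(-1))
    return np.concatenate(nodes, axis=0), np.concatenate(weights, axis=0)


def field_quadrature(magnet: MagnetSpec, pose: Pose, points,
                     n_phi: int = 64, n_ax: int = 24,
                     chunk: int = 4096) -> FieldVector:
    """Surface-charge (magnetic pole) quadrature of the magnet field, µT.

    Converges spectrally in the periodic angle for cylinders; serves as the
    production evaluator for transversely magnetised cylinders and as an
    independent numerical cross-check for the closed-form paths.
    """
    pts_body = _to_body(pose, points)
    src, w = _quadrature_nodes(magnet, n_phi, n_ax)
    out = np.empty_like(pts_body)
    for lo in range(0, len(pts_body), chunk):
        p = pts_body[lo:lo + chunk]
        d = p[:, None, :] - src[None, :, :]  # (m, k, 3)
        r2 = np.einsum("mkc,mkc->mk", d, d)
        inv_r3 = r2 ** -1.5
        out[lo:lo + chunk] = np.einsum("mk,mkc->mc", w * inv_r3 / (4.0 * np.pi), d)
    return _from_body(pose, points, out)


# ---------------------------------------------------------------------------
# frame plumbing and public dispatch
# ---------------------------------------------------------------------------


def _to_body(pose: Pose, points) -> np.ndarray:
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    return (pts - pose.position) @ pose.rotation


def _from_body(pose: Pose, points, field_body: np.ndarray) -> FieldVector:
    lab = field_body @ pose.rotation.T
    shape = np.asarray(points, dtype=float).shape
    return FieldVector(lab.reshape(shape))


def _inside_cylinder(pts_body, radius, half_len) -> np.ndarray:
    rho = np.hypot(pts_body[:, 0], pts_body[:, 1])
    return (rho < radius) & (np.abs(pts_body[:, 2]) < half_len)


def _inside_cuboid(pts_body, half_dims) -> np.ndarray:
    return np.all(np.abs(pts_body) < half_dims, axis=1)


def _reject_inside(magnet: MagnetSpec, pts_body: np.ndarray) -> None:
    if magnet.shape == "cylinder":
        d, length = magnet.dimensions
        bad = _inside_cylinder(pts_body, d / 2.0, length / 2.0)
    else:
        bad = _inside_cuboid(pts_body, np.asarray(magnet.dimensions) / 2.0)
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} evaluation point(s) inside the magnet body; "
            "the exterior field formulas do not apply there"
        )


def _field_body(magnet: MagnetSpec, pts_body: np.ndarray,
                chunk: int = 4096) -> np.ndarray:
    """Body-frame field dispatch shared by all public entry points."""
    _reject_inside(magnet, pts_body)
    br = np.asarray(magnet.br_mT, dtype=float) * MT_TO_UT
    if magnet.shape == "cuboid":
        return _cuboid_body(pts_body, np.asarray(magnet.dimensions) / 2.0, br)
    d, length = magnet.dimensions
    body = np.zeros_like(pts_body)
    if br[2] != 0.0:
        body += _cylinder_axial_body(pts_body, d / 2.0, length / 2.0, br[2])
    if br[0] != 0.0 or br[1] != 0.0:
        transverse = MagnetSpec(
            "cylinder", magnet.dimensions,
            (magnet.br_mT[0], magnet.br_mT[1], 0.0),
        )
        src, w = _quadrature_nodes(transverse, 64, 24)
        cw = w / (4.0 * np.pi)
        for lo in range(0, len(pts_body), chunk):
            dvec = pts_body[lo:lo + chunk, None, :] - src[None, :, :]
            r2 = np.einsum("mkc,mkc->mk", dvec, dvec)
            body[lo:lo + chunk] += np.einsum("mk,mkc->mc", cw * r2 ** -1.5, dvec)
    return body


def field(magnet: MagnetSpec, pose: Pose, points) -> FieldVector:
    """Flux density of ``magnet`` at ``points`` (mm, lab frame) in µT.

    Dispatches to the exact closed form where one exists (axial cylinder,
    cuboid) and to the converged surface-charge quadrature for transverse
    cylinder magnetisation; the two are superposed for an oblique Br.
    """
    pts_body = _to_body(pose, points)
    body = _field_body(magnet, pts_body)
    return _from_body(pose, points, body)


def field_poses(magnet: MagnetSpec, rotations: np.ndarray,
                positions: np.ndarray, point) -> np.ndarray:
    """Field of one magnet under many poses at a single fixed lab point.

    ``rotations``: (n, 3, 3) body->lab matrices; ``positions``: (n, 3) mm.
    Returns an (n, 3) array in µT (lab frame).  This is the batched inner
    loop of state-grid dataset construction.
    """
    rotations = np.asarray(rotations, dtype=float)
    positions = np.asarray(positions, dtype=float)
    rel = np.asarray(point, dtype=float).reshape(3) - positions
    pts_body = np.einsum("nji,nj->ni", rotations, rel)
    body = _field_body(magnet, pts_body)
    return np.einsum("nij,nj->ni", rotations, body)


def field_cylinder_axial(magnet: MagnetSpec, pose: Pose, points) -> FieldVector:
    """Exact elliptic-integral field of an axially magnetised cylinder."""
    if magnet.shape != "cylinder":
        raise ValueError("magnet is not a cylinder")
    if magnet.br_mT[0] != 0.0 or magnet.br_mT[1] != 0.0:
        raise ValueError("magnetisation is not purely axial")
    return field(magnet, pose, points)


def field_cylinder_diametral(magnet: MagnetSpec, pose: Pose, points) -> FieldVector:
    """Field of a diametrally (transversely) magnetised cylinder."""
    if magnet.shape != "cylinder":
        raise ValueError("magnet is not a cylinder")
    if magnet.br_mT[2] != 0.0:
        raise ValueError("magnetisation is not purely diametral")
    return field(magnet, pose, points)


def field_cuboid(magnet: MagnetSpec, pose: Pose, points) -> FieldVector:
    """Exact charged-plate field of a cuboid (bar) magnet."""
    if magnet.shape != "cuboid":
        raise ValueError("magnet is not a cuboid")
    return field(magnet, pose, points)


def magnet_moment(magnet: MagnetSpec) -> np.ndarray:
    """Equivalent point-dipole moment ``Br·V/µ0`` in A·m² (body frame)."""
    br_T = np.asarray(magnet.br_mT, dtype=float) * 1.0e-3
    vol_m3 = magnet.volume_mm3 * 1.0e-9
    return br_T * vol_m3 / MU0


def field_dipole(moment, pose: Pose, points) -> FieldVector:
    """Point-dipole field, µT; ``moment`` in A·m² in the body frame."""
    m_lab = pose.rotation @ np.asarray(moment, dtype=float).reshape(3)
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    r_mm = pts - pose.position
    r = np.linalg.norm(r_mm, axis=1)
    if np.any(r == 0.0):
        raise ValueError("dipole field undefined at the source point")
    r_m = r * 1.0e-3
    rhat = r_mm / r[:, None]
    mdotr = rhat @ m_lab
    b_T = 1.0e-7 * (3.0 * mdotr[:, None] * rhat - m_lab) / (r_m ** 3)[:, None]
    shape = np.asarray(points, dtype=float).shape
    return FieldVector((b_T * 1.0e6).reshape(shape))
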