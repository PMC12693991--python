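"""Ball-and-socket kinematics of the instrumented hip replacement.

The prosthesis is modelled as an ideal ball-and-socket joint.  The
laboratory (acetabular) frame has its origin at the joint centre of
rotation (the seated femoral head centre) with +Z pointing from the origin
toward the magnetometer potted at the shell pole.  Stem-neck orientation is
described by two degrees of freedom:

* tilt ``θ`` — angle between the stem-neck axis and the acetabular central
  axis (+Z), degrees;
* azimuth ``ψ`` — rotation of the neck axis about the central axis,
  degrees, with ψ = 0 toward +X.

The magnet sits on the neck axis a small distance ``a`` (mm) from the joint
centre toward the sensor, magnetised along the neck axis.  At tilt 0 every
azimuth yields the identical magnet pose — a genuine degeneracy of the
parameterisation that downstream inversion must tie-break.

Beyond the impingement onset tilt the neck contacts the liner rim and
further commanded rotation levers the head out of the liner about that
contact point (impingement-driven subluxation); :func:`subluxation_pose`
models this as a single rigid rotation about the rim fulcrum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .magnetostatics import MagnetSpec, Pose, field_poses

__all__ = [
    "GeometryConfig",
    "OrientationState",
    "SubluxationState",
    "rotation_y",
    "rotation_z",
    "pose_from_state",
    "poses_from_states",
    "state_grid",
    "sensor_field",
    "calibrate_geometry",
    "subluxation_pose",
]


def rotation_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass(frozen=True)
class GeometryConfig:
    """Build geometry of the instrumented implant.

    Parameters
    ----------
    d_s:
        Joint centre -> sensor distance along +Z, mm.  The sensor is potted
        in the shell introducer hole at the pole.
    a:
        Joint centre -> magnet centre offset along the neck axis toward the
        sensor, mm.  Not directly measurable on the build; solved by
        :func:`calibrate_geometry` against the neutral-state field.
    liner_radius:
        Liner bearing radius, mm (half the femoral head diameter).
    shell_outer_diameter:
        Acetabular shell outer diameter, mm (informational).
    impingement_onset:
        Tilt at which neck-liner impingement begins, degrees.
    max_tilt:
        Largest stem tilt the components allow, degrees.
    sensor_yaw_deg:
        Mounting rotation of the magnetometer about +Z relative to the
        acetabular frame.  The default 180° makes the sensed in-plane field
        at ψ = 0 point along the sensor +X axis, so the azimuth arctangent
        convention holds as stated for the physical build.
    """

    d_s: float = 24.0
    a: float = 2.3
    liner_radius: float = 18.0
    shell_outer_diameter: float = 56.0
    impingement_onset: float = 64.0
    max_tilt: float = 66.0
    sensor_yaw_deg: float = 180.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a < self.d_s:
            raise ValueError("need 0 <= a < d_s")
        if self.liner_radius <= 0.0:
            raise ValueError("liner_radius must be positive")
        if not self.impingement_onset < self.max_tilt <= 90.0:
            raise ValueError("need impingement_onset < max_tilt <= 90")

    @property
    def sensor_position(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.d_s])

    @property
    def sensor_rotation(self) -> np.ndarray:
        """Sensor frame -> acetabular frame rotation."""
        return rotation_z(self.sensor_yaw_deg)


@dataclass(frozen=True)
class OrientationState:
    """Two-DoF stem-neck orientation (tilt θ, azimuth ψ), degrees."""

    tilt_deg: float
    azimuth_deg: float

    def __post_init__(self) -> None:
        if self.tilt_deg < 0.0:
            raise ValueError("tilt must be non-negative")
        object.__setattr__(self, "azimuth_deg", float(self.azimuth_deg) % 360.0)

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.tilt_deg, self.azimuth_deg])


@dataclass(frozen=True)
class SubluxationState:
    """Lever-out state during impingement-driven subluxation.

    ``separation_mm`` is the head-centre chord displacement
    ``2·r_l·sin(δ/2)`` for over-rotation δ past the impingement onset.
    """

    commanded_tilt_deg: float
    over_rotation_deg: float
    displacement_mm: np.ndarray
    separation_mm: float


def _states_array(states) -> np.ndarray:
    if isinstance(states, OrientationState):
        return states.as_array.reshape(1, 2)
    arr = np.asarray(
        [s.as_array if isinstance(s, OrientationState) else s for s in np.atleast_2d(states)],
        dtype=float,
    )
    return arr.reshape(-1, 2)


def pose_from_state(state, geom: GeometryConfig) -> Pose:
    """Magnet pose for one orientation state.

    The state (θ, ψ) tilts the neck by θ about the in-plane axis
    ``(−sin ψ, cos ψ, 0)``: ``R = Rz(ψ)·Ry(θ)·Rz(−ψ)``, i.e. the stem does
    not spin about its own axis during an azimuth sweep, so tilt 0 gives
    the identity pose for every ψ.  The magnet centre is ``R·(0,0,a)`` and
    the body +Z (magnetisation axis of the build disc) maps to the neck
    axis ``R·(0,0,1) = (sin θ cos ψ, sin θ sin ψ, cos θ)``.
    """
    tilt, azim = _states_array(state)[0]
    if not 0.0 <= tilt <= geom.max_tilt:
        raise ValueError(f"tilt {tilt} outside [0, {geom.max_tilt}]")
    rot = rotation_z(azim) @ rotation_y(tilt) @ rotation_z(-azim)
    return Pose(rot @ np.array([0.0, 0.0, geom.a]), rot)


def poses_from_states(states, geom: GeometryConfig):
    """Vectorised :func:`pose_from_state`: (n,3,3) rotations, (n,3) centres."""
    arr = _states_array(states)
    if np.any(arr[:, 0] < 0.0) or np.any(arr[:, 0] > geom.max_tilt):
        raise ValueError("tilt outside allowed range")
    th = np.deg2rad(arr[:, 0])
    ps = np.deg2rad(arr[:, 1])
    ct, st = np.cos(th), np.sin(th)
    cp, sp = np.cos(ps), np.sin(ps)
    n = len(arr)
    rot = np.empty((n, 3, 3))
    # Rz(psi) @ Ry(theta) @ Rz(-psi): tilt about the in-plane axis
    # (-sin psi, cos psi, 0), no spin about the neck axis
    rot[:, 0, 0] = ct + (1.0 - ct) * sp * sp
    rot[:, 0, 1] = -(1.0 - ct) * sp * cp
    rot[:, 0, 2] = st * cp
    rot[:, 1, 0] = -(1.0 - ct) * sp * cp
    rot[:, 1, 1] = ct + (1.0 - ct) * cp * cp
    rot[:, 1, 2] = st * sp
    rot[:, 2, 0] = -st * cp
    rot[:, 2, 1] = -st * sp
    rot[:, 2, 2] = ct
    centres = rot[:, :, 2] * geom.a
    return rot, centres


def state_grid(tilt_range: tuple[float, float] = (0.0, 65.0),
               azimuth_range: tuple[float, float] = (0.0, 359.0),
               step: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Regular (tilt, azimuth) grid as an (n, 2) array, tilt-major order.

    The default grid covers tilt 0–65° and azimuth 0–359° in 1° steps:
    66 × 360 = 23,760 states.  Rows are ordered tilt-major (all azimuths of
    tilt 0 first), deterministically.
    """
    t0, t1 = tilt_range
    a0, a1 = azimuth_range
    dt, da = step
    if t1 < t0 or a1 < a0 or dt <= 0 or da <= 0:
        raise ValueError("empty or invalid grid range")
    nt = int(round((t1 - t0) / dt)) + 1
    na = int(round((a1 - a0) / da)) + 1
    if not (np.isclose(t0 + (nt - 1) * dt, t1) and np.isclose(a0 + (na - 1) * da, a1)):
        raise ValueError("step must divide the range")
    tilts = t0 + dt * np.arange(nt)
    azims = a0 + da * np.arange(na)
    tt, aa = np.meshgrid(tilts, azims, indexing="ij")
    return np.column_stack([tt.ravel(), aa.ravel()])


def sensor_field(geom: GeometryConfig, magnet: MagnetSpec, states) -> np.ndarray:
    """Noiseless field at the sensor for each state, sensor frame, µT."""
    rot, centres = poses_from_states(states, geom)
    b_lab = field_poses(magnet, rot, centres, geom.sensor_position)
    return b_lab @ geom.sensor_rotation


def calibrate_geometry(geom: GeometryConfig, magnet: MagnetSpec,
                       target_neutral_uT: float,
                       tol_uT: float = 0.1) -> GeometryConfig:
    """Solve the magnet offset ``a`` so the neutral-state |B| hits a target.

    One-dimensional root find over ``a`` in [0, d_s − magnet half-length −
    1 mm]; |B| at the neutral state (tilt 0) increases monotonically with
    ``a`` as the magnet approaches the sensor.  Raises with the achievable
    range if the target lies outside the bracket.
    """
    if magnet.shape == "cylinder":
        half_len = magnet.dimensions[1] / 2.0
    else:
        half_len = magnet.dimensions[2] / 2.0
    a_hi = geom.d_s - half_len - 1.0

    def neutral_mag(a: float) -> float:
        g = replace(geom, a=a)
        return float(np.linalg.norm(sensor_field(g, magnet, [(0.0, 0.0)])[0]))

    lo, hi = neutral_mag(0.0), neutral_mag(a_hi)
    if not lo <= target_neutral_uT <= hi:
        raise ValueError(
            f"target {target_neutral_uT} µT outside achievable range "
            f"[{lo:.1f}, {hi:.1f}] µT for a in [0, {a_hi}] mm"
        )
    if target_neutral_uT == lo:
        return replace(geom, a=0.0)
    a_star = brentq(lambda a: neutral_mag(a) - target_neutral_uT, 0.0, a_hi,
                    xtol=1.0e-10)
    out = replace(geom, a=float(a_star))
    if abs(neutral_mag(a_star) - target_neutral_uT) > tol_uT:
        raise RuntimeError("calibration failed to reach target within tolerance")
    return out


def subluxation_pose(commanded_tilt_deg: float, azimuth_deg: float,
                     geom: GeometryConfig) -> tuple[Pose, SubluxationState]:
    """Magnet pose and head displacement for a commanded over-tilt.

    Up to the impingement onset this is plain ball-and-socket motion.
    Beyond it, the neck bears on the liner rim at the point it contacts
    (radius ``liner_radius`` in the tilt plane, on the side opposite the
    tilt direction) and the head-stem body rotates rigidly by the
    over-rotation δ about the axis through that fulcrum perpendicular to
    the tilt plane.  The head centre then displaces out of the liner by the
    chord ``2·r_l·sin(δ/2)``, away from the sensor.
    """
    if commanded_tilt_deg < 0.0:
        raise ValueError("commanded tilt must be non-negative")
    if commanded_tilt_deg > 90.0:
        raise ValueError("commanded tilt beyond 90° not modelled")
    theta_imp = geom.impingement_onset
    if commanded_tilt_deg <= theta_imp:
        pose = pose_from_state((commanded_tilt_deg, azimuth_deg), geom)
        return pose, SubluxationState(commanded_tilt_deg, 0.0, np.zeros(3), 0.0)

    delta = commanded_tilt_deg - theta_imp
    base = pose_from_state((theta_imp, azimuth_deg), geom)
    rz = rotation_z(azimuth_deg)
    fulcrum = rz @ np.array([-geom.liner_radius, 0.0, 0.0])
    lever = rz @ rotation_y(delta) @ rz.T
    pose = Pose(
        fulcrum + lever @ (base.position - fulcrum),
        lever @ base.rotation,
    )
    head_disp = fulcrum + lever @ (-fulcrum)  # head centre starts at origin
    separation = 2.0 * geom.liner_radius * np.sin(np.deg2rad(delta) / 2.0)
    return pose, SubluxationState(commanded_tilt_deg, delta, head_disp, separation)
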