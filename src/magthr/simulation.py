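"""Synthetic stand-ins for the bench hardware: sensor, robot and camera.

The physical validation rig — a robot arm articulating the implant
components, a three-axis magnetometer streaming over I2C, and a camera
tracking system (CTS) for the subluxation ground truth — is replaced by:

* piecewise-linear commanded motion :class:`Trajectory` objects replicating
  the bench protocols (azimuth sweeps over a ladder of tilt angles; the
  three-event impingement-driven subluxation routine);
* a sensor model applying Gaussian noise then per-axis quantisation to the
  analytic field at the configured sample rate;
* ground-truth streams at the robot (125 Hz) or camera (25 Hz) rates, and
  closest-timestamp alignment between streams of different rates.

All randomness is seeded; identical seeds give identical streams.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field as _dc_field, replace

import numpy as np
import pandas as pd

from .kinematics import (
    GeometryConfig,
    poses_from_states,
    subluxation_pose,
)
from .magnetostatics import MagnetSpec, field as _field, field_poses

__all__ = [
    "SensorSpec",
    "SensorStream",
    "GroundTruthStream",
    "Trajectory",
    "generate_protocol_2dof",
    "generate_protocol_subluxation",
    "magnet_poses",
    "simulate_sensor",
    "ground_truth",
    "align_streams",
]

ROBOT_RATE_HZ = 125.0
CTS_RATE_HZ = 25.0


@dataclass(frozen=True)
class SensorSpec:
    """Magnetometer model: per-axis quantisation, rate, noise, seed.

    The defaults mirror the bench magnetometer configuration: sensitivity
    (one least-significant bit) of 6.01 µT on X and Y and 9.68 µT on Z at
    a measured 49 Hz output rate.  ``noise_sigma_uT = None`` applies
    zero-mean Gaussian noise of one LSB per axis before quantisation.
    """

    step_uT: tuple[float, float, float] = (6.01, 6.01, 9.68)
    rate_hz: float = 49.0
    noise_sigma_uT: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0.0 for s in self.step_uT) or self.rate_hz <= 0.0:
            raise ValueError("quantisation steps and rate must be positive")

    @property
    def sigma(self) -> np.ndarray:
        if self.noise_sigma_uT is None:
            return np.asarray(self.step_uT, dtype=float)
        return np.asarray(self.noise_sigma_uT, dtype=float)


@dataclass(frozen=True)
class SensorStream:
    """Timestamped quantised field readings (sensor frame, µT)."""

    t_s: np.ndarray
    b_uT: np.ndarray
    spec: SensorSpec
    provenance: dict = _dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        if np.any(np.diff(t) <= 0.0):
            raise ValueError("timestamps must be strictly increasing")
        if len(t) != len(self.b_uT):
            raise ValueError("timestamp/reading length mismatch")

    def __len__(self) -> int:
        return len(self.t_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t_s,
            "Bx_uT": self.b_uT[:, 0],
            "By_uT": self.b_uT[:, 1],
            "Bz_uT": self.b_uT[:, 2],
        })

    def to_csv(self, path) -> None:
        header = "".join(f"# {k}: {v}\n" for k, v in self.provenance.items())
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, spec: SensorSpec | None = None) -> "SensorStream":
        """Ingest a sensor CSV stream (`t_s, Bx_uT, By_uT, Bz_uT`).

        Accepts real magnetometer logs through the same format used for
        simulated streams; `#`-prefixed provenance lines are skipped.
        """
        df = pd.read_csv(path, comment="#")
        b = df[["Bx_uT", "By_uT", "Bz_uT"]].to_numpy()
        return cls(df["t_s"].to_numpy(), b, spec or SensorSpec())


@dataclass(frozen=True)
class GroundTruthStream:
    """Reference orientation (and optional displacement) samples."""

    t_s: np.ndarray
    states: np.ndarray  # (n, 2) commanded tilt/azimuth, degrees
    z_mm: np.ndarray | None = None
    imp_flag: np.ndarray | None = None
    rate_hz: float = ROBOT_RATE_HZ
    trigger_t_s: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.diff(np.asarray(self.t_s, float)) <= 0.0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)

    def to_frame(self) -> pd.DataFrame:
        d = {"t_s": self.t_s,
             "tilt_deg": self.states[:, 0],
             "azimuth_deg": self.states[:, 1]}
        if self.z_mm is not None:
            d["z_mm"] = self.z_mm
        if self.imp_flag is not None:
            d["imp_flag"] = self.imp_flag.astype(int)
        return pd.DataFrame(d)


@dataclass(frozen=True)
class Trajectory:
    """Piecewise-linear commanded motion of the stem.

    Keyframes are interpolated linearly in time; ``sample`` returns the
    commanded (tilt, azimuth) and ``channels`` the derived subluxation
    ground truth (head separation and the continuity-switch flag).
    """

    key_t: np.ndarray
    key_tilt: np.ndarray
    key_azimuth: np.ndarray
    geom: GeometryConfig
    kind: str = "2dof"
    repeat_index: int = 0

    @property
    def duration_s(self) -> float:
        return float(self.key_t[-1])

    def sample(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tilt = np.interp(t, self.key_t, self.key_tilt)
        azim = np.interp(t, self.key_t, self.key_azimuth)
        return np.column_stack([tilt, azim])

    def channels(self, t) -> tuple[np.ndarray, np.ndarray]:
        """(head separation mm, impingement flag) at times ``t``."""
        states = self.sample(t)
        over = np.maximum(0.0, states[:, 0] - self.geom.impingement_onset)
        z = 2.0 * self.geom.liner_radius * np.sin(np.deg2rad(over) / 2.0)
        flag = states[:, 0] >= self.geom.impingement_onset - 1.0e-9
        return z, flag


def _build_keyframes(segments, rate_deg_s: float):
    """Turn a list of (tilt, azimuth) waypoints into timed keyframes."""
    t = [0.0]
    tilts = [segments[0][0]]
    azims = [segments[0][1]]
    for tilt, azim in segments[1:]:
        travel = max(abs(tilt - tilts[-1]), abs(azim - azims[-1]))
        t.append(t[-1] + travel / rate_deg_s)
        tilts.append(tilt)
        azims.append(azim)
    return np.asarray(t), np.asarray(tilts), np.asarray(azims)


def generate_protocol_2dof(geom: GeometryConfig,
                           tilts=None,
                           azimuth_end_deg: float = 355.0,
                           repeats: int = 3,
                           rate_deg_s: float = 30.0) -> list[Trajectory]:
    """Commanded motion of the orientation-accuracy bench protocol.

    From neutral, the stem moves to each tilt of the ladder (default 5° to
    60° in 5° steps — 12 levels) and sweeps the azimuth across the full
    0–355° range at each level, alternating sweep direction so the motion
    is continuous.  The same deterministic trajectory is returned once per
    repeat (repeat-to-repeat variation enters through the sensor noise
    seed, offset by the repeat index).
    """
    if tilts is None:
        tilts = np.arange(5.0, 60.0 + 1.0e-9, 5.0)
    tilts = np.asarray(tilts, dtype=float)
    if np.any(tilts <= 0.0) or np.any(tilts > geom.max_tilt):
        raise ValueError(f"tilt levels must lie in (0, {geom.max_tilt}]")
    segments = [(0.0, 0.0)]
    psi = 0.0
    for tilt in tilts:
        segments.append((tilt, psi))
        psi = azimuth_end_deg if psi == 0.0 else 0.0
        segments.append((tilt, psi))
    key_t, kt, ka = _build_keyframes(segments, rate_deg_s)
    return [
        Trajectory(key_t, kt, ka, geom, kind="2dof", repeat_index=i)
        for i in range(repeats)
    ]


def generate_protocol_subluxation(geom: GeometryConfig,
                                  angles=(70.0, 72.0, 74.0),
                                  azimuth_deg: float = 0.0,
                                  rest_tilt_deg: float = 40.0,
                                  rate_deg_s: float = 30.0) -> Trajectory:
    """Commanded motion of the impingement/subluxation bench protocol.

    An initial excursion to the impingement onset and back (contact but no
    bearing-surface separation), then one lever-out excursion to each of
    the listed angles beyond the onset.  The continuity-switch flag channel
    is true whenever the commanded tilt reaches the onset.
    """
    onset = geom.impingement_onset
    if any(a <= onset for a in angles):
        raise ValueError("subluxation angles must exceed the impingement onset")
    segments = [(0.0, azimuth_deg), (onset, azimuth_deg), (rest_tilt_deg, azimuth_deg)]
    for a in angles:
        segments.append((float(a), azimuth_deg))
        segments.append((rest_tilt_deg, azimuth_deg))
    key_t, kt, ka = _build_keyframes(segments, rate_deg_s)
    return Trajectory(key_t, kt, ka, geom, kind="subluxation")


def magnet_poses(states: np.ndarray, geom: GeometryConfig):
    """(rotations, positions) for commanded states, lever model included.

    States at or below the impingement onset follow plain ball-and-socket
    motion; beyond it the subluxation lever-out applies.
    """
    states = np.asarray(states, dtype=float)
    rot = np.empty((len(states), 3, 3))
    pos = np.empty((len(states), 3))
    normal = states[:, 0] <= geom.impingement_onset
    if np.any(normal):
        r, c = poses_from_states(states[normal], geom)
        rot[normal], pos[normal] = r, c
    for i in np.nonzero(~normal)[0]:
        pose, _ = subluxation_pose(states[i, 0], states[i, 1], geom)
        rot[i], pos[i] = pose.rotation, pose.position
    return rot, pos


def simulate_sensor(traj: Trajectory, geom: GeometryConfig, magnet: MagnetSpec,
                    spec: SensorSpec) -> SensorStream:
    """Sample the magnetometer along a trajectory: noise, then quantise.

    The analytic field at the sensor (sensor frame) is sampled at
    ``spec.rate_hz``; zero-mean Gaussian noise per axis is added and the
    result rounded to the per-axis quantisation step.  Fully reproducible
    from ``spec.seed``.
    """
    t = np.arange(0.0, traj.duration_s + 0.5 / spec.rate_hz, 1.0 / spec.rate_hz)
    states = traj.sample(t)
    rot, pos = magnet_poses(states, geom)
    b_lab = field_poses(magnet, rot, pos, geom.sensor_position)
    b = b_lab @ geom.sensor_rotation
    rng = np.random.default_rng(spec.seed)
    b = b + rng.normal(0.0, 1.0, size=b.shape) * spec.sigma
    step = np.asarray(spec.step_uT)
    b = step * np.round(b / step)
    prov = {
        "kind": traj.kind,
        "repeat": traj.repeat_index,
        "seed": spec.seed,
        "rate_hz": spec.rate_hz,
        "step_uT": spec.step_uT,
    }
    return SensorStream(t, b, spec, prov)


def ground_truth(traj: Trajectory, rate_hz: float = ROBOT_RATE_HZ) -> GroundTruthStream:
    """Reference stream at the robot (125 Hz) or camera (25 Hz) rate."""
    t = np.arange(0.0, traj.duration_s + 0.5 / rate_hz, 1.0 / rate_hz)
    states = traj.sample(t)
    if traj.kind == "subluxation":
        z, flag = traj.channels(t)
        return GroundTruthStream(t, states, z, flag, rate_hz=rate_hz)
    return GroundTruthStream(t, states, rate_hz=rate_hz)


def _nearest_indices(query_t: np.ndarray, ref_t: np.ndarray) -> np.ndarray:
    pos = np.searchsorted(ref_t, query_t)
    pos = np.clip(pos, 1, len(ref_t) - 1)
    left = ref_t[pos - 1]
    right = ref_t[pos]
    return np.where(query_t - left <= right - query_t, pos - 1, pos)


def align_streams(sensor: SensorStream, truth: GroundTruthStream,
                  key: str = "sensor") -> pd.DataFrame:
    """Pair two streams by closest timestamp.

    ``key="sensor"`` keeps one row per sensor sample (the robot-rate truth
    stream is decimated to the sensor timestamps, surplus truth samples
    dropped); ``key="truth"`` keys the pairing to the truth stream instead
    (used with the camera-rate subluxation reference).  Pairing error never
    exceeds half the sampling interval of the denser stream.
    """
    ts, tt = np.asarray(sensor.t_s), np.asarray(truth.t_s)
    if ts[-1] < tt[0] or tt[-1] < ts[0]:
        raise ValueError("streams do not overlap in time")
    sf = sensor.to_frame()
    tf = truth.to_frame()
    if key == "sensor":
        idx = _nearest_indices(ts, tt)
        out = pd.concat(
            [sf.reset_index(drop=True),
             tf.iloc[idx].drop(columns="t_s").reset_index(drop=True)],
            axis=1,
        )
    elif key == "truth":
        idx = _nearest_indices(tt, ts)
        out = pd.concat(
            [tf.reset_index(drop=True),
             sf.iloc[idx].drop(columns="t_s").reset_index(drop=True)],
            axis=1,
        )
    else:
        raise ValueError("key must be 'sensor' or 'truth'")
    return out
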