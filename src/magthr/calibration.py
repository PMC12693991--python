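"""Hard-iron / soft-iron magnetometer calibration by ellipsoid fitting.

A magnetometer rotated through diverse orientations in a constant field
should trace a sphere of readings.  Nearby ferromagnetic material distorts
this: a fixed additive offset (hard iron) translates the sphere and a
linear distortion (soft iron) maps it to an ellipsoid.  Fitting the
general quadric to raw readings and mapping the ellipsoid back to a sphere
recovers the correction

    corrected = W · (raw − b)

with ``b`` the hard-iron offset (µT) and ``W`` symmetric positive-definite
undoing the soft-iron distortion, scaled so the corrected radius equals
the expected field magnitude β.  A seeded synthetic distortion generator
is included for end-to-end testing of the recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CalibrationModel",
    "fit_calibration",
    "apply_calibration",
    "distort",
    "fibonacci_sphere",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Hard-iron offset, soft-iron correction and expected magnitude."""

    offset_uT: np.ndarray  # (3,) hard-iron b
    correction: np.ndarray  # (3, 3) symmetric positive-definite W
    beta_uT: float  # expected corrected field magnitude
    residual_rms_uT: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.correction, dtype=float)
        if not np.allclose(w, w.T, atol=1.0e-9):
            raise ValueError("correction matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(w) <= 0.0):
            raise ValueError("correction matrix must be positive-definite")
        object.__setattr__(self, "offset_uT",
                           np.asarray(self.offset_uT, dtype=float).reshape(3))
        object.__setattr__(self, "correction", w)

    @classmethod
    def identity(cls, beta_uT: float = 1.0) -> "CalibrationModel":
        return cls(np.zeros(3), np.eye(3), beta_uT)

    def to_dict(self) -> dict:
        return {
            "offset_uT": self.offset_uT.tolist(),
            "correction": self.correction.tolist(),
            "beta_uT": float(self.beta_uT),
            "residual_rms_uT": float(self.residual_rms_uT),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(np.asarray(d["offset_uT"]), np.asarray(d["correction"]),
                   float(d["beta_uT"]), float(d.get("residual_rms_uT", 0.0)))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def fit_calibration(raw_uT: np.ndarray) -> CalibrationModel:
    """Least-squares ellipsoid fit of raw readings (10-parameter quadric).

    Solves ``xᵀAx + 2bᵀx = 1`` for the symmetric A and centre, symmetrises
    the correction to SPD through its eigendecomposition, and fixes β to
    the ellipsoid's geometric-mean radius so an undistorted spherical
    cloud maps to itself.  Raises if the readings do not determine an
    ellipsoid (too few, coplanar, or not enclosing all axes).
    """
    x = np.asarray(raw_uT, dtype=float).reshape(-1, 3)
    if len(x) < 9:
        raise ValueError("need at least 9 readings for an ellipsoid fit")
    d = np.column_stack([
        x[:, 0] ** 2, x[:, 1] ** 2, x[:, 2] ** 2,
        2.0 * x[:, 0] * x[:, 1], 2.0 * x[:, 0] * x[:, 2],
        2.0 * x[:, 1] * x[:, 2],
        2.0 * x[:, 0], 2.0 * x[:, 1], 2.0 * x[:, 2],
    ])
    sol, _, rank, _ = np.linalg.lstsq(d, np.ones(len(x)), rcond=None)
    if rank < 9:
        raise ValueError("readings are degenerate; ellipsoid not identifiable")
    amat = np.array([
        [sol[0], sol[3], sol[4]],
        [sol[3], sol[1], sol[5]],
        [sol[4], sol[5], sol[2]],
    ])
    bvec = sol[6:9]
    if abs(np.linalg.det(amat)) < 1.0e-30:
        raise ValueError("fitted quadric is degenerate")
    centre = -np.linalg.solve(amat, bvec)
    # recentre: (x-c)ᵀ A (x-c) = 1 + cᵀAc; A itself may carry either sign
    # when the origin lies outside the ellipsoid
    k = 1.0 + centre @ amat @ centre
    m = amat / k  # (x-c)ᵀ M (x-c) = 1
    if np.any(np.linalg.eigvalsh(m) <= 0.0):
        raise ValueError("fitted quadric is not an ellipsoid; "
                         "readings must sample diverse orientations")
    lam, vec = np.linalg.eigh(m)
    w_unit = vec @ np.diag(np.sqrt(lam)) @ vec.T  # SPD sqrt: |W₀(x-c)| = 1
    beta = float(np.prod(lam) ** (-1.0 / 6.0))  # geometric-mean semi-axis
    w = beta * w_unit
    corrected = (x - centre) @ w.T
    radii = np.linalg.norm(corrected, axis=1)
    return CalibrationModel(centre, w, beta,
                            residual_rms_uT=float(np.sqrt(np.mean((radii - beta) ** 2))))


def apply_calibration(model: CalibrationModel, raw_uT) -> np.ndarray:
    """``W · (raw − b)`` applied row-wise."""
    raw = np.asarray(raw_uT, dtype=float)
    single = raw.ndim == 1
    out = (np.atleast_2d(raw) - model.offset_uT) @ model.correction.T
    return out[0] if single else out


def distort(readings_uT, offset_uT=(0.0, 0.0, 0.0), matrix=None,
            noise_sigma_uT: float = 0.0, seed: int = 0) -> np.ndarray:
    """Synthetic hard/soft-iron distortion: ``M·x + b`` plus Gaussian noise."""
    x = np.asarray(readings_uT, dtype=float).reshape(-1, 3)
    m = np.eye(3) if matrix is None else np.asarray(matrix, dtype=float)
    rng = np.random.default_rng(seed)
    out = x @ m.T + np.asarray(offset_uT, dtype=float)
    if noise_sigma_uT > 0.0:
        out = out + rng.normal(0.0, noise_sigma_uT, size=out.shape)
    return out


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Near-uniform directions on a sphere (calibration-fixture sampling)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return radius * np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])
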