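"""Inversion methods: from a sensed field vector to an orientation state.

Three complementary trackers map a three-axis reading ``B = (Bx, By, Bz)``
(sensor frame, µT) to the stem orientation (tilt θ, azimuth ψ):

* **look-up table** — nearest neighbour of ``B`` among the pre-simulated
  reference dataset ``(Statesₙ, Bₙ)`` in Euclidean field space;
* **responsivity ratio** — the in-plane field fraction
  ``R = √((Bx/|B|)² + (By/|B|)²)`` rises monotonically with tilt and is
  inverted through a 1°-spaced table, while azimuth comes from
  ``atan2(By, Bx)``;
* **neural network** — a 12/12/12 tanh net regressing (θ, ψ) from the raw
  field components, trained by Levenberg–Marquardt with a 70/15/15
  train/validation/test split.

A fourth, one-dimensional look-up maps fields to the femoral-head
displacement during an impingement-driven subluxation lever-out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy.spatial import cKDTree

from .kinematics import GeometryConfig, sensor_field, subluxation_pose
from .magnetostatics import MagnetSpec, field as _field
from .statespace import StateDataset

__all__ = [
    "LookupModel",
    "ResponsivityModel",
    "NeuralModel",
    "ZLookupModel",
    "build_lookup_model",
    "lookup_invert",
    "r_ratio_lutz",
    "r_ratio_bmag",
    "azimuth_atan2",
    "build_responsivity_model",
    "responsivity_track",
    "nn_train",
    "nn_predict",
    "build_z_lookup",
    "z_invert",
]


# ---------------------------------------------------------------------------
# look-up table
# ---------------------------------------------------------------------------


@dataclass
class LookupModel:
    """Reference (states, fields) pairs with a k-d tree search index."""

    dataset: StateDataset
    _tree: cKDTree = _dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._tree = cKDTree(self.dataset.fields)


def build_lookup_model(ds: StateDataset) -> LookupModel:
    return LookupModel(ds)


def lookup_invert(b, model: LookupModel) -> np.ndarray:
    """States of the nearest reference fields; ties -> lowest index.

    ``b`` may be a single 3-vector or an (n, 3) array; returns the matching
    (tilt, azimuth) rows.  Exact ties (the degenerate tilt-0 duplicates)
    resolve to the lowest dataset index, i.e. grid order.
    """
    b = np.asarray(b, dtype=float)
    single = b.ndim == 1
    q = np.atleast_2d(b)
    dist, idx = model._tree.query(q, k=1)
    # refine exact/near ties to the lowest index for determinism
    ties = model._tree.query_ball_point(q, dist * (1.0 + 1.0e-12) + 1.0e-300)
    idx = np.array([min(t) if t else i for t, i in zip(ties, idx)])
    out = model.dataset.states[idx]
    return out[0] if single else out


# ---------------------------------------------------------------------------
# responsivity ratios and azimuth arctangent
# ---------------------------------------------------------------------------


def r_ratio_lutz(b) -> np.ndarray:
    """Ratio ``√((Bx/Bz)² + (By/Bz)²)``; infinite where Bz = 0 (flagged)."""
    b = np.asarray(b, dtype=float)
    bz = b[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.hypot(b[..., 0], b[..., 1]) / np.abs(bz)
    if np.any(bz == 0.0):
        warnings.warn("Bz = 0: responsivity ratio is infinite there")
        r = np.where(bz == 0.0, np.inf, r)
    return r


def r_ratio_bmag(b) -> np.ndarray:
    """In-plane field fraction ``√((Bx/|B|)² + (By/|B|)²)`` ∈ [0, 1].

    Undefined (NaN, flagged) for a zero field.
    """
    b = np.asarray(b, dtype=float)
    mag = np.linalg.norm(b, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.hypot(b[..., 0], b[..., 1]) / mag
    if np.any(mag == 0.0):
        warnings.warn("|B| = 0: responsivity ratio undefined there")
        r = np.where(mag == 0.0, np.nan, r)
    return r


def azimuth_atan2(b) -> np.ndarray:
    """Azimuth ``atan2(By, Bx)`` in degrees wrapped to [0, 360).

    ψ = 0 corresponds to the in-plane field along sensor +X.  At the
    neutral singularity Bx = By = 0 the azimuth is undefined; the reading
    is flagged with a warning and the arctangent-convention value 0 is
    returned so that streaming inversion stays total (a quantised reading
    can land exactly on zero in-plane field near the neutral state).
    """
    b = np.asarray(b, dtype=float)
    bx, by = b[..., 0], b[..., 1]
    psi = np.degrees(np.arctan2(by, bx)) % 360.0
    if np.any((bx == 0.0) & (by == 0.0)):
        warnings.warn("Bx = By = 0: azimuth undefined at the neutral state; "
                      "reporting the atan2 convention value 0")
    return psi


@dataclass(frozen=True)
class ResponsivityModel:
    """(tilt, R) table over the full tilt range with linear interpolation.

    ``r_table`` must be strictly increasing in tilt — checked at build —
    which is what makes the scalar ratio invertible.
    """

    tilt_table: np.ndarray
    r_table: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r_table, dtype=float)
        if np.any(np.diff(r) <= 0.0):
            raise ValueError("responsivity table is not strictly increasing")
        if np.any((r < 0.0) | (r > 1.0)):
            raise ValueError("R ratio must lie in [0, 1]")


def build_responsivity_model(geom: GeometryConfig, magnet: MagnetSpec,
                             step_deg: float = 1.0) -> ResponsivityModel:
    """Tabulate the noiseless R ratio over tilt 0 .. max_tilt at ψ = 0."""
    tilts = np.arange(0.0, geom.max_tilt + 0.5 * step_deg, step_deg)
    states = np.column_stack([tilts, np.zeros_like(tilts)])
    b = sensor_field(geom, magnet, states)
    return ResponsivityModel(tilts, r_ratio_bmag(b))


def responsivity_track(b, model: ResponsivityModel) -> np.ndarray:
    """(tilt, azimuth) via table interpolation and the arctangent.

    The ratio is clamped to the table ends (R below the minimum reads as
    tilt 0, above the maximum as the maximum tilt).  The azimuth NaN flag
    at the neutral singularity propagates.
    """
    b = np.asarray(b, dtype=float)
    single = b.ndim == 1
    q = np.atleast_2d(b)
    r = r_ratio_bmag(q)
    tilt = np.interp(r, model.r_table, model.tilt_table)
    psi = azimuth_atan2(q)
    out = np.column_stack([tilt, psi])
    return out[0] if single else out


# ---------------------------------------------------------------------------
# neural network
# ---------------------------------------------------------------------------


@dataclass
class NeuralModel:
    """Trained 12/12/12 feed-forward tracker with its normalisers."""

    net: "LMNet"
    x_scaler: "MinMaxScaler"
    y_scaler: "MinMaxScaler"
    metadata: dict

    def predict(self, b) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        single = b.ndim == 1
        q = np.atleast_2d(b)
        yn = self.net.predict_norm(self.x_scaler.transform(q))
        y = self.y_scaler.inverse(yn)
        y[:, 1] %= 360.0
        return y[0] if single else y


def nn_train(fields: np.ndarray, states: np.ndarray,
             split: tuple[float, float, float] = (0.70, 0.15, 0.15),
             seed: int = 0, hidden=(12, 12, 12), max_iter: int = 150,
             patience: int = 6, min_samples: int = 60) -> NeuralModel:
    """Train the orientation net on (field, state) pairs.

    The pairs are shuffled once with ``seed`` and split 70/15/15 into
    training, validation and test sets; the network trains full-batch by
    damped least squares with early stopping on the validation error
    (patience 6) and reports per-split RMSEs in the model metadata.
    Azimuth is regressed in raw degrees, so predictions near the 0°/360°
    wrap are intrinsically hard for this tracker.
    """
    from .nnet import LMNet, MinMaxScaler

    fields = np.asarray(fields, dtype=float)
    states = np.asarray(states, dtype=float)
    n = len(fields)
    if n < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {n}")
    if abs(sum(split) - 1.0) > 1.0e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    i_tr = order[:n_train]
    i_va = order[n_train:n_train + n_val]
    i_te = order[n_train + n_val:]

    xs = MinMaxScaler.fit(fields[i_tr])
    ys = MinMaxScaler.fit(states[i_tr])
    xn = xs.transform(fields)
    yn = ys.transform(states)

    net = LMNet((fields.shape[1], *hidden, states.shape[1]), seed=seed)
    net.fit(xn[i_tr], yn[i_tr], xn[i_va], yn[i_va],
            max_iter=max_iter, patience=patience)
    if net.history.get("stop_reason") == "max_iter":
        warnings.warn("LM training hit the iteration cap; "
                      "returning the best validation checkpoint")

    def _rmse(ii) -> list[float]:
        pred = ys.inverse(net.predict_norm(xn[ii]))
        err = pred - states[ii]
        return [float(np.sqrt(np.mean(err[:, k] ** 2))) for k in range(err.shape[1])]

    meta = {
        "seed": int(seed),
        "split": tuple(split),
        "n_train": len(i_tr),
        "n_val": len(i_va),
        "n_test": len(i_te),
        "stop_reason": net.history.get("stop_reason"),
        "n_iterations": len(net.history.get("train_mse", [])),
        "rmse_train": _rmse(i_tr),
        "rmse_val": _rmse(i_va),
        "rmse_test": _rmse(i_te),
        "hidden": tuple(hidden),
    }
    return NeuralModel(net, xs, ys, meta)


def nn_predict(model: NeuralModel, b) -> np.ndarray:
    """Forward pass of the trained net; azimuth wrapped to [0, 360)."""
    return model.predict(b)


# ---------------------------------------------------------------------------
# subluxation Z look-up
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZLookupModel:
    """25-entry field -> head-displacement table for lever-out tracking."""

    fields: np.ndarray  # (n, 3) µT, sensor frame
    z_mm: np.ndarray  # (n,) head-centre separation

    def __post_init__(self) -> None:
        if len(self.fields) != len(self.z_mm):
            raise ValueError("fields and z values must have equal length")


def build_z_lookup(geom: GeometryConfig, magnet: MagnetSpec,
                   theta_max_deg: float = 74.0, azimuth_deg: float = 0.0,
                   n: int = 25) -> ZLookupModel:
    """Populate the displacement table from a simulated lever-out sweep.

    ``n`` entries are sampled uniformly in over-rotation δ from 0 (onset,
    zero displacement) to ``theta_max_deg − impingement_onset``; each holds
    the noiseless sensor-frame field and the head-centre separation.
    """
    if n < 2:
        raise ValueError("need at least two table entries")
    if theta_max_deg <= geom.impingement_onset:
        raise ValueError("theta_max must exceed the impingement onset")
    deltas = np.linspace(0.0, theta_max_deg - geom.impingement_onset, n)
    fields = np.empty((n, 3))
    z = np.empty(n)
    sensor = geom.sensor_position
    for i, d in enumerate(deltas):
        pose, sub = subluxation_pose(geom.impingement_onset + d, azimuth_deg, geom)
        b_lab = _field(magnet, pose, sensor)
        fields[i] = np.asarray(b_lab).reshape(3) @ geom.sensor_rotation
        z[i] = sub.separation_mm
    return ZLookupModel(fields, z)


def z_invert(b, model: ZLookupModel) -> np.ndarray:
    """Head displacement of the nearest table field; ties -> lowest index."""
    b = np.asarray(b, dtype=float)
    single = b.ndim == 1
    q = np.atleast_2d(b)
    d2 = ((q[:, None, :] - model.fields[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)  # argmin takes the first (lowest) index
    out = model.z_mm[idx]
    return float(out[0]) if single else out
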