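"""State-space construction and magnet selection by state separation.

A sensing configuration is judged by how far apart, in three-axis field
space, the sensor readings of neighbouring orientation states lie: the
larger the separation, the easier it is to distinguish states through
sensor quantisation and noise.  For every state on the two-DoF grid the
Euclidean distance to its nearest *distinct* neighbour in (Bx, By, Bz)
space is computed with a k-d tree; the grid-wide mean (meanSS) and minimum
(minSS) summarise the configuration, and ranking nine candidate magnets by
these metrics reproduces the magnet-selection study for the implant build.

The tilt-0 states are mutually degenerate for any magnet whose on-axis
field is axisymmetric (identical pose ⇒ identical field), so the raw
minimum separation is exactly zero there.  The headline minSS therefore
excludes exact duplicates; the raw value is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .kinematics import GeometryConfig, sensor_field, state_grid
from .magnetostatics import MagnetSpec

__all__ = [
    "StateDataset",
    "SeparationReport",
    "build_dataset",
    "state_separation",
    "directional_separation",
    "rank_magnets",
]


@dataclass(frozen=True)
class StateDataset:
    """Paired (states, fields) arrays over an orientation grid.

    ``states``: (n, 2) tilt/azimuth degrees, tilt-major grid order;
    ``fields``: (n, 3) noiseless sensor-frame readings, µT.  Geometry and
    magnet are retained so the dataset can be regenerated bit-identically.
    """

    states: np.ndarray
    fields: np.ndarray
    geometry: GeometryConfig
    magnet: MagnetSpec

    def __post_init__(self) -> None:
        if len(self.states) != len(self.fields):
            raise ValueError("states and fields must have equal length")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class SeparationReport:
    """Nearest-neighbour separation statistics of a state dataset, µT."""

    mean_uT: float
    min_uT: float
    min_with_duplicates_uT: float
    nn_distance_uT: np.ndarray
    n_duplicates: int

    @property
    def has_duplicates(self) -> bool:
        return self.n_duplicates > 0


def build_dataset(geom: GeometryConfig, magnet: MagnetSpec,
                  grid: np.ndarray | None = None) -> StateDataset:
    """Simulate the sensor field at every grid state (deterministic)."""
    if grid is None:
        grid = state_grid()
    fields = sensor_field(geom, magnet, grid)
    return StateDataset(np.asarray(grid, float), fields, geom, magnet)


def state_separation(ds: StateDataset) -> SeparationReport:
    """Per-state nearest-distinct-neighbour distances in field space.

    Uses a k-d tree (k = 2 query; the first neighbour of each point is
    itself).  Exact duplicates (distance 0, the degenerate tilt-0 states)
    count toward the mean and the raw minimum but are excluded from the
    headline ``min_uT`` so the metric stays informative.
    """
    if len(ds) < 2:
        raise ValueError("need at least two states")
    tree = cKDTree(ds.fields)
    dist, _ = tree.query(ds.fields, k=2)
    nn = dist[:, 1]
    nonzero = nn[nn > 0.0]
    return SeparationReport(
        mean_uT=float(nn.mean()),
        min_uT=float(nonzero.min()) if len(nonzero) else 0.0,
        min_with_duplicates_uT=float(nn.min()),
        nn_distance_uT=nn,
        n_duplicates=int((nn == 0.0).sum()),
    )


def _grid_shape(ds: StateDataset) -> tuple[np.ndarray, np.ndarray]:
    tilts = np.unique(ds.states[:, 0])
    azims = np.unique(ds.states[:, 1])
    if len(tilts) * len(azims) != len(ds):
        raise ValueError("dataset is not a full regular grid")
    return tilts, azims


def directional_separation(ds: StateDataset, direction: str) -> pd.DataFrame:
    """Field-space distance across one grid step, reported per tilt state.

    ``direction="tilt_step"``: distance between states (θ, ψ) and
    (θ+Δθ, ψ); ``direction="azimuth_step"``: between (θ, ψ) and (θ, ψ+Δψ)
    (cyclically).  Each row gives the mean over azimuth and the spread
    (max − min) across azimuth, which is zero for an axisymmetric build.
    """
    tilts, azims = _grid_shape(ds)
    f = ds.fields.reshape(len(tilts), len(azims), 3)
    if direction == "tilt_step":
        d = np.linalg.norm(np.diff(f, axis=0), axis=2)  # (nt-1, na)
        t = tilts[:-1]
    elif direction == "azimuth_step":
        d = np.linalg.norm(np.roll(f, -1, axis=1) - f, axis=2)  # (nt, na)
        t = tilts
    else:
        raise ValueError("direction must be 'tilt_step' or 'azimuth_step'")
    return pd.DataFrame({
        "tilt_deg": t,
        "separation_uT": d.mean(axis=1),
        "spread_uT": d.max(axis=1) - d.min(axis=1),
    })


def rank_magnets(candidates: list[MagnetSpec], geom: GeometryConfig,
                 grid: np.ndarray | None = None) -> pd.DataFrame:
    """Separation metrics for each candidate magnet, best first.

    All candidates are posed identically (body +Z along the neck axis) in
    the one calibrated build geometry; ordering is by meanSS, ties by
    headline minSS.
    """
    if grid is None:
        grid = state_grid()
    rows = []
    for magnet in candidates:
        ds = build_dataset(geom, magnet, grid)
        rep = state_separation(ds)
        rows.append({
            "magnet": magnet.name or f"{magnet.shape} {magnet.dimensions}",
            "shape": magnet.shape,
            "dimensions_mm": "x".join(f"{d:g}" for d in magnet.dimensions),
            "br_mT": tuple(magnet.br_mT),
            "mean_ss_uT": rep.mean_uT,
            "min_ss_uT": rep.min_uT,
            "min_ss_with_duplicates_uT": rep.min_with_duplicates_uT,
            "max_field_uT": float(np.linalg.norm(ds.fields, axis=1).max()),
        })
    table = pd.DataFrame(rows).sort_values(
        ["mean_ss_uT", "min_ss_uT"], ascending=False, ignore_index=True
    )
    table.index = table.index + 1
    table.index.name = "rank"
    return table
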