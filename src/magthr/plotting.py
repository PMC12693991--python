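"""Diagnostic plots (optional; requires matplotlib).

Imported lazily so the core library has no hard plotting dependency.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_directional_separation(ds, path=None):
    """Tilt-step vs azimuth-step state separation across tilt angle.

    The horizontal line marks the coarsest sensor quantisation step; where
    the azimuth-step curve runs below it, neighbouring azimuth states are
    indistinguishable to the sensor.
    """
    from .statespace import directional_separation

    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 4))
    ts = directional_separation(ds, "tilt_step")
    az = directional_separation(ds, "azimuth_step")
    ax.plot(ts.tilt_deg, ts.separation_uT, "r-", label="tilt step (+1°)")
    ax.plot(az.tilt_deg, az.separation_uT, "g-", label="azimuth step (+1°)")
    ax.axhline(9.68, color="k", ls=":", lw=1, label="sensor Z sensitivity (9.68 µT)")
    ax.set_xlabel("tilt angle (°)")
    ax.set_ylabel("state separation (µT)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_subluxation_track(pairs, path=None):
    """Predicted vs reference head displacement over the lever-out protocol."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(pairs["t_s"], pairs["z_mm"], "k-", lw=1, label="ground truth")
    ax.plot(pairs["t_s"], pairs["z_pred_mm"], "r.", ms=3, label="sensing system")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("head-centre displacement (mm)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
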