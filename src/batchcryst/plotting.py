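"""Optional matplotlib views of trajectories and size distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .batch import BatchTrajectory
from .csd import VolumeCSD

__all__ = ["plot_trajectory", "plot_csd"]


def plot_trajectory(traj: BatchTrajectory, ax=None):
    """Concentration, solubility, and supersaturation against time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    t_min = traj.time / 60.0
    ax.plot(t_min, traj.C, label="C (mole fraction)", color="tab:blue")
    ax.plot(t_min, traj.Cstar, label="C* (solubility)", color="tab:green", ls="--")
    ax.set_xlabel("time [min]")
    ax.set_ylabel("mole fraction")
    ax2 = ax.twinx()
    ax2.plot(t_min, traj.S, label="S = C/C*", color="tab:red")
    ax2.set_ylabel("supersaturation ratio S")
    lines, labels = ax.get_legend_handles_labels()
    l2, lab2 = ax2.get_legend_handles_labels()
    ax.legend(lines + l2, labels + lab2, loc="upper left")
    return ax.figure


def plot_csd(csd: VolumeCSD, ax=None, **kwargs):
    """Volume-percent CSD on a logarithmic diameter axis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(csd.d_um, csd.volume_percent, marker="o", ms=3, **kwargs)
    ax.set_xscale("log")
    ax.set_xlabel("diameter [μm]")
    ax.set_ylabel("volume percent per bin")
    return ax.figure
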