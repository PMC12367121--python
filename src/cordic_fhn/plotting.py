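"""Optional matplotlib views: traces, phase planes, bifurcation, rasters.

Matplotlib is imported lazily; nothing in the library or test suite
requires these helpers.
"""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_trajectory(traj, ax=None, **kwargs):
    """Membrane potential against time."""
    ax = _axes(ax)
    ax.plot(traj.t, traj.V, **kwargs)
    ax.set_xlabel("t (ms)")
    ax.set_ylabel("V")
    return ax


def plot_phase_plane(traj, transient: float = 0.0, ax=None, **kwargs):
    mask = traj.t >= transient
    ax = _axes(ax)
    ax.plot(traj.V[mask], traj.W[mask], lw=0.5, **kwargs)
    ax.set_xlabel("V")
    ax.set_ylabel("W")
    return ax


def plot_bifurcation(result, ax=None, **kwargs):
    """Scatter of post-transient V peaks against the swept parameter."""
    ax = _axes(ax)
    df = result.to_frame()
    ax.plot(df["param"], df["peak"], ".", ms=1, **kwargs)
    ax.set_xlabel(result.param_name)
    ax.set_ylabel("V peaks")
    return ax


def plot_raster(raster, ax=None, **kwargs):
    """Spike times of every neuron in the population."""
    ax = _axes(ax)
    for i, times in enumerate(raster.spike_times):
        if len(times):
            ax.plot(times, np.full(len(times), i), "|", ms=2, **kwargs)
    ax.set_xlabel("t (ms)")
    ax.set_ylabel("neuron")
    return ax
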