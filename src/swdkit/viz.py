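"""Plotting helpers: rate/LFP traces and 2D region maps.

Figures are plain matplotlib; every function accepts an existing Axes
and returns it, so the helpers compose with user layouts.
"""

from __future__ import annotations

import numpy as np

from .network import RegionStats, SimulationResult, grid_layout

__all__ = ["plot_node_timeseries", "plot_region_map"]


def plot_node_timeseries(sim: dict, ax=None, lfp=None):
    """Excitatory/inhibitory rates (and optionally the LFP) of one node.

    ``sim`` is the dict returned by
    :func:`swdkit.meanfield.simulate_node`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(sim["t"], sim["nu_e"], label="nu_e", lw=0.8)
    ax.plot(sim["t"], sim["nu_i"], label="nu_i", lw=0.8, alpha=0.7)
    if lfp is not None:
        scale = np.ptp(sim["nu_e"]) / max(np.ptp(lfp), 1e-12)
        ax.plot(sim["t"], lfp * scale, label="LFP (scaled)", lw=0.8, alpha=0.7)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("rate (Hz)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_region_map(stats_or_result, value: str = "t", ax=None, cmap="coolwarm"):
    """Per-region statistic on the near-square 2D grid layout.

    Accepts a :class:`~swdkit.network.RegionStats` (plots the ``value``
    column, hatching non-significant regions as NaN-free zeros) or a
    :class:`~swdkit.network.SimulationResult` (plots time-averaged
    nu_e).
    """
    import matplotlib.pyplot as plt

    if isinstance(stats_or_result, RegionStats):
        labels = list(stats_or_result.table["region"])
        values = stats_or_result.table[value].to_numpy(dtype=float)
    elif isinstance(stats_or_result, SimulationResult):
        labels = list(stats_or_result.labels)
        values = stats_or_result.nu_e.mean(axis=1)
    else:
        raise TypeError("expected RegionStats or SimulationResult")
    layout = grid_layout(labels)
    rows = max(r for r, _ in layout.values()) + 1
    cols = max(c for _, c in layout.values()) + 1
    img = np.full((rows, cols), np.nan)
    for name, val in zip(labels, values):
        r, c = layout[name]
        img[r, c] = val
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    vmax = np.nanmax(np.abs(img)) or 1.0
    im = ax.imshow(img, cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.figure.colorbar(im, ax=ax, shrink=0.8, label=value)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
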