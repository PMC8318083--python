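"""Minimal plotting: statistic / accuracy heat maps and flow-grid matrices."""

from __future__ import annotations

import numpy as np

from .connectivity import FlowGrid
from .stats import StatResult


def plot_stat_map(result: StatResult, what: str = "stat", ax=None, **imshow_kw):
    """Heat map of a StatResult map on its (space x time) or (t x dt) grid."""
    import matplotlib.pyplot as plt

    values = {"stat": result.stat, "tfce": result.tfce, "p": result.p}[what]
    grid = result.to_grid(values) if result.grid_shape else values[None, :]
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(grid, aspect="auto", origin="lower", **imshow_kw)
    ax.set_xlabel("time sample")
    ax.set_ylabel("grid row")
    ax.figure.colorbar(im, ax=ax, label=what)
    return ax


def plot_flow_grid(grid: FlowGrid | np.ndarray, t_axis_ms=None, dt_axis_ms=None, ax=None, **imshow_kw):
    """Heat map of a t x dt partial-correlation matrix (dt on the y axis)."""
    import matplotlib.pyplot as plt

    if isinstance(grid, FlowGrid):
        pc, t_axis_ms, dt_axis_ms = grid.pc, grid.t_axis_ms, grid.dt_axis_ms
        title = f"{grid.source} → {grid.target}"
    else:
        pc, title = np.asarray(grid), ""
    if ax is None:
        _, ax = plt.subplots()
    extent = None
    if t_axis_ms is not None and dt_axis_ms is not None:
        extent = [t_axis_ms[0], t_axis_ms[-1], dt_axis_ms[0], dt_axis_ms[-1]]
    im = ax.imshow(pc.T, aspect="auto", origin="lower", extent=extent, **imshow_kw)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("dt (ms)")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, label="partial r")
    return ax
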