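"""Small matplotlib helpers for cross-sections and sampling schedules."""

from __future__ import annotations

import numpy as np


def plot_plane(plane, ax=None, n_levels: int = 8, **kwargs):
    """Signed contour plot of a 2D cross-section (positive solid, negative
    dashed), axes in ppm with the conventional reversed direction."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    top = np.max(np.abs(plane.data))
    if top == 0:
        return ax
    levels = top * np.geomspace(0.05, 1.0, n_levels)
    x, y = plane.axes[1].ppm, plane.axes[0].ppm
    ax.contour(x, y, plane.data, levels=levels, colors="C0", linewidths=0.7, **kwargs)
    ax.contour(x, y, -plane.data, levels=levels, colors="C3",
               linestyles="dashed", linewidths=0.7, **kwargs)
    ax.set_xlabel(f"{plane.axes[1].label} (ppm)")
    ax.set_ylabel(f"{plane.axes[0].label} (ppm)")
    ax.invert_xaxis()
    ax.invert_yaxis()
    ax.set_title(f"{plane.experiment} ({plane.variant}) @ {plane.basis_peak_id}")
    return ax


def plot_schedule(schedule, dims=(0, 1), ax=None):
    """Scatter of a schedule's grid indices in two chosen dimensions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    idx = schedule.indices
    if idx.shape[1] == 1:
        ax.hist(idx[:, 0], bins=40)
        ax.set_xlabel("grid index")
        ax.set_ylabel("count")
    else:
        d0, d1 = dims
        ax.plot(idx[:, d0], idx[:, d1], ".", ms=3)
        ax.set_xlabel(f"dimension {d0 + 1} index")
        ax.set_ylabel(f"dimension {d1 + 1} index")
    return ax
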