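"""Minimal plotting helpers (circular vector plot, virtual path).

Display-only: the "three angles per dot" binning in the circular
histogram is purely cosmetic and never feeds back into any statistic.
"""

from __future__ import annotations

import numpy as np

from .circstats import mean_vector


def _polar_axes(ax):
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)  # compass: clockwise
    return ax


def circular_histogram(angles_deg, ax=None, angles_per_dot: int = 3):
    """Dot histogram of an angle series on a compass-oriented polar axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    _polar_axes(ax)
    binned = np.sort(np.round(np.asarray(angles_deg) / 5.0) * 5.0 % 360.0)
    radii, seen = [], {}
    for a in binned:
        seen[a] = seen.get(a, 0) + 1
    for a, count in seen.items():
        for level in range(int(np.ceil(count / angles_per_dot))):
            radii.append((a, 0.95 - 0.05 * level))
    if radii:
        th = np.deg2rad([a for a, _ in radii])
        rr = [r for _, r in radii]
        ax.plot(th, rr, "o", ms=3, color="tab:blue")
    mv = mean_vector(angles_deg)
    if not mv.undefined:
        ax.annotate(
            "",
            xy=(np.deg2rad(mv.theta), mv.r),
            xytext=(0, 0),
            arrowprops={"color": "tab:red", "width": 1.5},
        )
    ax.set_rlim(0, 1)
    ax.set_yticklabels([])
    return ax


def group_vector_plot(vectors, ax=None, r_star: float | None = None, theta_w: float | None = None):
    """Per-fly mean vectors plus the group weighted mean arrow."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    _polar_axes(ax)
    for v in vectors:
        theta, r = (v.theta, v.r) if hasattr(v, "theta") else (v[0], v[1])
        ax.plot([np.deg2rad(theta)] * 2, [0, r], color="tab:blue", lw=1)
    if theta_w is not None and r_star is not None:
        ax.annotate(
            "",
            xy=(np.deg2rad(theta_w), min(r_star / 2.5, 1.0)),
            xytext=(0, 0),
            arrowprops={"color": "tab:red", "width": 2.0},
        )
    ax.set_rlim(0, 1)
    ax.set_yticklabels([])
    return ax


def path_plot(trace, ax=None):
    """Plot a virtual flight path in kilometres (x east, y north)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    km = trace.positions / 1000.0
    ax.plot(km[:, 0], km[:, 1], color="tab:blue", lw=1)
    ax.plot(0, 0, "k^", ms=6)
    ax.set_xlabel("east (km)")
    ax.set_ylabel("north (km)")
    ax.set_aspect("equal")
    return ax
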