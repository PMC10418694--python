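"""Figures: MSD curves, displacement distributions, density/difference maps.

Axes follow the field's conventions: MSD in mrad² against lag in ms with
the fitted line overlaid; displacement distributions and 2-D maps on
log-spaced |displacement| axes.  Plots are diagnostics, not analysis
surfaces.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_msd",
    "plot_displacement_distribution",
    "plot_density_map",
]


def plot_msd(results, ax=None):
    """MSD curves and fitted lines for both axes of one fitted condition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = {"theta": "tab:green", "chi": "tab:purple"}
    for axis, curve in results.curves.items():
        fit = results.fits[axis]
        ax.plot(curve.lags, curve.msd, "o", color=colors[axis],
                label=f"{axis}: {fit.slope:.2f} mrad$^2$/ms")
        xs = np.linspace(0, curve.lags[-1], 50)
        ax.plot(xs, fit.intercept + fit.slope * xs, "-", color=colors[axis], alpha=0.6)
    ax.set_xlabel(r"$\Delta t$ (ms)")
    ax.set_ylabel(r"MSD (mrad$^2$)")
    ax.set_title(f"MSD, {results.condition_label}")
    ax.legend(frameon=False)
    return ax


def plot_displacement_distribution(dists: Sequence, ax=None):
    """Overlay |displacement| distributions (log-log)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for dist in dists:
        centers = np.sqrt(dist.bin_edges[:-1] * dist.bin_edges[1:])
        label = f"{dist.condition_label} {dist.axis}".strip()
        ax.plot(centers, dist.mass, drawstyle="steps-mid", label=label)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("|displacement| (mrad)")
    ax.set_ylabel("probability mass")
    ax.legend(frameon=False)
    return ax


def plot_density_map(dmap, ax=None):
    """2-D (|Δθ|, |Δχ|) probability-mass map; diverging scale for
    difference maps."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    if dmap.is_difference:
        vmax = float(np.abs(dmap.mass).max()) or 1.0
        kw = dict(cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    else:
        kw = dict(cmap="viridis", vmin=0)
    mesh = ax.pcolormesh(dmap.chi_edges, dmap.theta_edges, dmap.mass, **kw)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$|\Delta\chi|$ (mrad)")
    ax.set_ylabel(r"$|\Delta\theta|$ (mrad)")
    ax.set_title(dmap.condition_label)
    plt.colorbar(mesh, ax=ax)
    return ax
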