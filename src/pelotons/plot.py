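"""Basic kymograph and profile figures (matplotlib helpers)."""

from __future__ import annotations

import numpy as np

from .observables import ProfileEstimate
from .simulate import Kymograph

__all__ = ["plot_kymograph", "plot_profiles"]


def plot_kymograph(kymo: Kymograph, ax=None, path=None):
    """Render occupancy as position (x) vs time (y): motors black,
    roadblocks pink, empty track white."""
    import matplotlib
    from matplotlib.colors import ListedColormap
    if ax is None:
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(8, 5))
    cmap = ListedColormap(["white", "black", "#f4a6b8"])
    extent = (0, kymo.matrix.shape[1],
              kymo.t0 + kymo.n_bins * kymo.dt_bin, kymo.t0)
    ax.imshow(kymo.matrix, aspect="auto", cmap=cmap, vmin=0, vmax=2,
              interpolation="nearest", extent=extent)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("time (s)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_profiles(profile: ProfileEstimate, axes=None, path=None):
    """Motor density, motor velocity, and roadblock density vs position."""
    if axes is None:
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(3, 1, sharex=True, figsize=(7, 7))
    labels = ("motor density (occupancy)", "motor velocity (bp/s)",
              "roadblock density (occupancy)")
    for ax, y, lab in zip(axes, (profile.rho_m, profile.v_m,
                                 profile.rho_rb), labels):
        ax.plot(profile.x, y, lw=1)
        ax.set_ylabel(lab)
    axes[-1].set_xlabel("position (bp)")
    if path is not None:
        axes[0].figure.savefig(path, dpi=150, bbox_inches="tight")
    return axes
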