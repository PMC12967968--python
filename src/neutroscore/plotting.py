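"""Optional thin plotting layer over the numeric landscape artifacts.

Requires matplotlib (the ``plot`` extra). Nothing in the core pipeline or
the tests depends on this module.
"""

from __future__ import annotations

import pandas as pd


def plot_membership_profiles(profiles: pd.DataFrame, ax=None):
    """Line plot of T/I/F vs d, one panel row per instability level."""
    import matplotlib.pyplot as plt

    levels = sorted(profiles["s_level"].unique())
    fig, axes = plt.subplots(1, len(levels), figsize=(4 * len(levels), 3),
                             sharey=True, squeeze=False)
    for ax_, level in zip(axes[0], levels):
        sub = profiles[profiles["s_level"] == level]
        for name, style in (("T", "-"), ("I", "--"), ("F", ":")):
            ax_.plot(sub["d"], sub[name], style, label=name)
        ax_.set_title(f"s = {level:g}")
        ax_.set_xlabel("deviation d (mm)")
        ax_.set_ylim(-0.02, 1.02)
    axes[0][0].set_ylabel("membership")
    axes[0][0].legend()
    fig.tight_layout()
    return fig


def plot_competence_surface(grid, contour_levels=(0.3, 0.5, 0.7), ax=None):
    """Heatmap of S(d, s) with contour lines at the band cut points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(grid.d_axis, grid.s_axis, grid.S, shading="auto",
                         vmin=0, vmax=1, cmap="viridis")
    cs = ax.contour(grid.d_axis, grid.s_axis, grid.S, levels=contour_levels,
                    colors="white", linewidths=1)
    ax.clabel(cs, fmt="S=%.1f")
    ax.set_xlabel("deviation d (mm)")
    ax.set_ylabel("instability s")
    ax.figure.colorbar(mesh, ax=ax, label="competence score S")
    return ax
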