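"""Plot helpers: IL-2 field heatmaps and activation dose-response curves."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_field", "plot_activation_curves"]


def plot_field(result, tissue, ax=None, cmap="magma"):
    """Heatmap of the final IL-2 concentration with cell positions overlaid.

    Producers are drawn as open red circles, Th consumers blue, Treg green.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    grid = result.grid
    img = np.full(grid.inside.shape, np.nan)
    img[grid.inside] = result.final_field
    half = (grid.inside.shape[0] - 1) / 2 * grid.dx
    im = ax.imshow(img.T, origin="lower", extent=[-half, half, -half, half],
                   cmap=cmap)
    colors = {"Th": "tab:blue", "Treg": "tab:green"}
    for (x, y), pop, prod in zip(tissue.centers, tissue.population, tissue.producer):
        ec = "red" if prod else colors[pop]
        ax.add_patch(__import__("matplotlib.patches", fromlist=["Circle"]).Circle(
            (x, y), tissue.radius, fill=False, ec=ec, lw=0.8))
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.figure.colorbar(im, ax=ax, label="IL-2 (pM)")
    return ax


def plot_activation_curves(binary_sweep, graded_sweep, threshold, ax=None):
    """Activated fraction vs stimulus for both scenarios and populations."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    styles = {"binary": "-", "graded": "--"}
    colors = {"Th": "tab:blue", "Treg": "tab:green"}
    for sweep in (binary_sweep, graded_sweep):
        fr = sweep.fractions(threshold)
        for pop in ("Th", "Treg"):
            ax.plot(sweep.a_grid, fr[pop], styles[sweep.mode], color=colors[pop],
                    marker="o", ms=3, label=f"{pop} ({sweep.mode})")
    ax.set_xlabel("antigen stimulus A")
    ax.set_ylabel("fraction activated")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return ax
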