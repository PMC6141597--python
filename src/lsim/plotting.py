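"""Plotting helpers for sweep heatmaps and depth-resolved metric curves."""

from __future__ import annotations

import pandas as pd

__all__ = ["na_sweep_heatmap", "depth_curves"]


def na_sweep_heatmap(table: pd.DataFrame, ax=None, cmap: str = "viridis"):
    """Heatmap of a sweep metric over the (NA_y, NA_x) grid.

    ``table`` is the output of :func:`lsim.acquisition.run_na_sweep`
    (columns ``na_x``, ``na_y``, ``value``).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pivot = table.pivot_table(index="na_x", columns="na_y", values="value")
    im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto", cmap=cmap,
                   extent=(pivot.columns.min(), pivot.columns.max(),
                           pivot.index.min(), pivot.index.max()))
    ax.set_xlabel("NA$_y$")
    ax.set_ylabel("NA$_x$")
    metric = table["metric"].iloc[0] if "metric" in table else "value"
    ax.figure.colorbar(im, ax=ax, label=metric)
    return ax


def depth_curves(profiles: dict[str, pd.DataFrame], column: str = "sigma_I_y",
                 ax=None):
    """Overlay per-mode depth profiles (e.g. sigma_I_y(z) or contrast(z))."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, frame in profiles.items():
        ax.plot(frame["z"], frame[column], label=label)
    ax.set_xlabel("z (um)")
    ax.set_ylabel(column)
    ax.legend()
    return ax
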