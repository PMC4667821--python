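"""Plot helpers for cell index tables (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np

from .mapping import LatitudeProfile

__all__ = ["plot_latitude_profile", "plot_index_map"]


def plot_latitude_profile(profile: LatitudeProfile, ax=None):
    """Binned means with the signed-latitude LOWESS curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(
        profile.binned["bin_center"],
        profile.binned["mean"],
        s=10 + 2 * profile.binned["count"],
        alpha=0.6,
        label="band mean",
    )
    ax.plot(
        profile.lowess_signed[:, 0],
        profile.lowess_signed[:, 1],
        color="C1",
        label="LOWESS",
    )
    ax.set_xlabel("latitude (deg)")
    ax.set_ylabel(profile.column)
    ax.legend(frameon=False)
    return ax


def plot_index_map(table, column: str, ax=None, cmap: str = "RdYlBu_r"):
    """Crude cell map: one colored marker per 1x1-degree cell, percentile scale."""
    import matplotlib.pyplot as plt

    from .mapping import percentile_rank

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    sub = table.dropna(subset=[column])
    pct = percentile_rank(sub[column].to_numpy())
    sc = ax.scatter(
        sub["cell_lon"] + 0.5,
        sub["cell_lat"] + 0.5,
        c=pct,
        cmap=cmap,
        marker="s",
        vmin=0,
        vmax=100,
    )
    plt.colorbar(sc, ax=ax, label=f"{column} percentile")
    ax.set_xlabel("longitude (deg)")
    ax.set_ylabel("latitude (deg)")
    ax.set_xlim(-180, 180)
    ax.set_ylim(-90, 90)
    return ax
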