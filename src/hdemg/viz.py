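"""Activation-map heat-map rendering.

A small convenience layer over matplotlib: draws the 8x4 grid as an image,
masked electrode greyed out, low-to-high activation running dark blue to
dark red. When the map is MVC-normalized, pass ``vmax=1.0`` (or the
individual's peak) so maps from the same participant share a scale.
"""

from __future__ import annotations

import numpy as np

from .maps import ActivationMap

__all__ = ["plot_map"]


def plot_map(
    map: ActivationMap,
    ax=None,
    *,
    vmin: float = 0.0,
    vmax: float | None = None,
    cmap: str = "jet",
    colorbar: bool = True,
):
    """Render an activation map as a heat image; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 5))
    data = np.ma.masked_invalid(map.values)
    im = ax.imshow(
        data,
        cmap=cmap,
        vmin=vmin,
        vmax=vmax if vmax is not None else float(data.max()),
        origin="upper",
        interpolation="nearest",
    )
    ax.set_xlabel("column")
    ax.set_ylabel("row (fiber direction)")
    ax.set_xticks(range(map.layout.n_cols))
    ax.set_yticks(range(map.layout.n_rows))
    label = "%MVC" if map.normalized else "RMS (a.u.)"
    if colorbar:
        ax.figure.colorbar(im, ax=ax, label=label)
    return ax
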