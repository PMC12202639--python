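"""Minimal plotting helpers (matplotlib imported lazily)."""

from __future__ import annotations

from .types import PressureMap


def plot_pressure_map(pmap: PressureMap, ax=None, **imshow_kw):
    """Heatmap of one pressure map with physically scaled axes (mm)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rows, cols = pmap.shape
    extent = (0, cols * pmap.cell_pitch[1], rows * pmap.cell_pitch[0], 0)
    im = ax.imshow(pmap.grid, extent=extent, **imshow_kw)
    ax.set_xlabel("mm")
    ax.set_ylabel("mm")
    ax.set_title(f"{pmap.interface.value} pressure (kPa)")
    ax.figure.colorbar(im, ax=ax, label="kPa")
    return ax
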