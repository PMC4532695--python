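"""Chaos-map visualization over the thalamic-input plane.

Scatter of swept (p_ee, p_ei) points colored by the largest Lyapunov
exponent on a diverging blue-green-red scale, hard-clipped to [-20, 20]
s^-1: blue = strongly attracting fixed points, green = LLE near zero
(limit cycles), red = strong chaos.  Four-dimensional chaotic points can be
overlaid in black.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from matplotlib.figure import Figure

from . import __version__
from .sweep import SweepResult

__all__ = ["plot_lle_map", "LLE_CLIP"]

#: Hard clipping bound for the LLE color scale (s^-1).
LLE_CLIP = 20.0

_CMAP = LinearSegmentedColormap.from_list(
    "lle_bgr", [(0.0, "#1f3bd1"), (0.5, "#1fa833"), (1.0, "#d12a1f")]
)


def plot_lle_map(
    result: SweepResult,
    fdc_overlay: bool = True,
    path: str | Path | None = None,
    dpi: int = 150,
) -> Figure:
    """Render the LLE map of a sweep; optionally save to ``path`` (PNG/SVG).

    Marker size scales inversely with point density so both sparse test
    sweeps and dense production maps stay readable.  The config hash and
    package version are embedded in the figure (and in PNG metadata).
    """
    pts = [pt for pt in result.points if not pt.diverged]
    if not pts:
        raise ValueError("no valid points to plot")
    p_ee = np.array([pt.p_ee for pt in pts])
    p_ei = np.array([pt.p_ei for pt in pts])
    lle = np.clip(np.array([pt.exponents[0] for pt in pts]), -LLE_CLIP, LLE_CLIP)

    fig = Figure(figsize=(7.2, 4.8))
    ax = fig.add_subplot(111)
    size = max(2.0, min(40.0, 4000.0 / max(len(pts), 1)))
    sc = ax.scatter(p_ee, p_ei, c=lle, cmap=_CMAP, vmin=-LLE_CLIP, vmax=LLE_CLIP,
                    s=size, linewidths=0)
    fdc = [pt for pt in pts if pt.classification.label == "chaotic_4d"]
    if fdc_overlay and fdc:
        ax.scatter([pt.p_ee for pt in fdc], [pt.p_ei for pt in fdc],
                   c="black", s=size, linewidths=0, label="four-dimensional chaos")
        ax.legend(loc="upper right", frameon=False, fontsize=8)
    cbar = fig.colorbar(sc, ax=ax)
    cbar.set_label(r"largest Lyapunov exponent (s$^{-1}$, base e, clipped)")
    ax.set_xlabel(r"$p_{ee}$ (ms$^{-1}$)")
    ax.set_ylabel(r"$p_{ei}$ (ms$^{-1}$)")
    stamp = f"lileychaos {__version__}  config={result.spec.config_hash()}"
    ax.set_title(stamp, fontsize=7, loc="right", color="0.4")
    fig.tight_layout()
    if path is not None:
        path = Path(path)
        meta = None
        if path.suffix.lower() == ".png":
            meta = {"Software": stamp}
        fig.savefig(path, dpi=dpi, metadata=meta)
    return fig
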