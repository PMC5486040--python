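"""Topographic-map rendering of height matrices.

The landscape is drawn as a top view with hypsometric colors — blue/green
valleys (lakes) up to brown/white heights — with optional best-matching-unit
dots, either neutral or colored by class.  Rendering uses a matplotlib Agg
canvas directly so it works headless.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .heights import HeightMatrix

_CLASS_COLORS = {"patient": "#2ca02c", "control": "#1f77b4"}


@dataclasses.dataclass(frozen=True)
class TopographicRender:
    """Rendering style: colormap and BMU overlay mode."""

    cmap: str = "terrain"       # hypsometric ramp: blue -> green -> brown -> white
    overlay: str = "none"       # none | neutral | by-class
    scale: int = 16             # pixels per grid unit


def render_map(
    heights: HeightMatrix,
    path: str | Path,
    *,
    bmus: np.ndarray | None = None,
    truth=None,
    style: TopographicRender = TopographicRender(),
) -> Path:
    """Write a PNG of the height landscape; returns the written path.

    Image pixel dimensions are ``scale * (cols, rows)``.  With
    ``overlay='by-class'`` exactly one dot is drawn per occupied BMU unit
    and class (patients green, controls blue, as in the cohort figures).
    """
    h = heights.heights
    if h.size == 0:
        raise ValueError("empty height matrix")
    rows, cols = h.shape
    dpi = 100
    fig = Figure(figsize=(cols * style.scale / dpi, rows * style.scale / dpi), dpi=dpi)
    FigureCanvasAgg(fig)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_axis_off()
    ax.imshow(h, cmap=style.cmap, interpolation="nearest",
              extent=(-0.5, cols - 0.5, rows - 0.5, -0.5))

    if style.overlay != "none" and bmus is not None:
        bmus = np.asarray(bmus, dtype=int)
        if style.overlay == "neutral" or truth is None:
            units = np.unique(bmus, axis=0)
            ax.scatter(units[:, 1], units[:, 0], s=12, c="0.35", edgecolors="none")
        elif style.overlay == "by-class":
            truth = np.asarray(truth)
            for cls, color in _CLASS_COLORS.items():
                sel = bmus[truth == cls]
                if len(sel):
                    units = np.unique(sel, axis=0)
                    ax.scatter(units[:, 1], units[:, 0], s=12, c=color, edgecolors="none")
        else:
            raise ValueError(f"unknown overlay mode {style.overlay!r}")

    path = Path(path)
    fig.savefig(path, dpi=dpi)
    return path
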