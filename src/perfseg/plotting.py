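"""Polar (bullseye) maps of per-segment values."""

from __future__ import annotations

import numpy as np

from .geometry import AHA_BIN_IDS, APICAL_OFFSET_DEG


def polar_map(segment_values: dict[int, float], ax=None, cmap="RdYlBu",
              vmin=None, vmax=None, title: str | None = None):
    """16-segment bullseye plot of per-segment values.

    ``segment_values`` maps AHA segment ids (1-16) to values; basal
    segments form the outer ring, apical the inner.  Returns the axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    vals = [v for v in segment_values.values() if np.isfinite(v)]
    vmin = min(vals) if vmin is None else vmin
    vmax = max(vals) if vmax is None else vmax
    norm = colors.Normalize(vmin=vmin, vmax=vmax)
    mapper = cm.ScalarMappable(norm=norm, cmap=cmap)
    rings = {"basal": (2.0, 3.0), "mid": (1.0, 2.0), "apical": (0.0, 1.0)}
    for level, (r0, r1) in rings.items():
        ids = AHA_BIN_IDS[level]
        n = len(ids)
        width = 2 * np.pi / n
        offset = np.deg2rad(APICAL_OFFSET_DEG) if level == "apical" else 0.0
        for j, sid in enumerate(ids):
            v = segment_values.get(sid, np.nan)
            color = mapper.to_rgba(v) if np.isfinite(v) else (0.8, 0.8, 0.8)
            ax.bar(offset + j * width + width / 2, r1 - r0, width=width,
                   bottom=r0, color=color, edgecolor="k", linewidth=0.5)
            if np.isfinite(v):
                ax.text(offset + j * width + width / 2, (r0 + r1) / 2, f"{v:.2f}",
                        ha="center", va="center", fontsize=7)
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    plt.colorbar(mapper, ax=ax, shrink=0.7)
    return ax
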