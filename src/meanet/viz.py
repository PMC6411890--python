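"""MEA grid plot: the 8x8-minus-corners electrode layout, communities colored."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from meanet.containers import Partition

# standard 60-electrode layout: an 8x8 grid without the four corners,
# electrodes numbered 1-60 column-major
_GRID = [(r, c) for c in range(8) for r in range(8)
         if (r, c) not in ((0, 0), (7, 0), (0, 7), (7, 7))]


def plot_mea_grid(partition: Partition | None, active: set[int],
                  ax: "plt.Axes | None" = None) -> "plt.Axes":
    """Plot electrodes 1-60 on the array grid.

    Inactive electrodes are grey; active electrodes are colored by
    their community (singletons white with a colored rim).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    cmap = plt.get_cmap("tab10")
    labels = partition.labels if partition else {}
    multi = {c for c in set(labels.values())
             if sum(1 for v in labels.values() if v == c) >= 2}
    for eid, (r, c) in enumerate(_GRID, start=1):
        if eid in active and eid in labels and labels[eid] in multi:
            color = cmap(labels[eid] % 10)
        elif eid in active:
            color = "white"
        else:
            color = "lightgrey"
        ax.add_patch(plt.Circle((c, 7 - r), 0.38, facecolor=color,
                                edgecolor="black", linewidth=0.5))
        ax.text(c, 7 - r, str(eid), ha="center", va="center", fontsize=6)
    ax.set_xlim(-0.6, 7.6)
    ax.set_ylim(-0.6, 7.6)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
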