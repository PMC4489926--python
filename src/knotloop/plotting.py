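"""Optional heat-map rendering of campaign tables (requires matplotlib)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def heatmap(
    table: pd.DataFrame,
    metric: str = "rkp",
    ax=None,
):
    """Render a placement-grid heat map from a tidy campaign table.

    ``table`` is the output of :meth:`CampaignResult.table` (one row per
    placement with ``l_x``, ``l_y`` and metric columns).  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    rows = table.dropna(subset=["l_x", "l_y"])
    xs = sorted(rows["l_x"].unique())
    ys = sorted(rows["l_y"].unique())
    grid = np.full((len(ys), len(xs)), np.nan)
    for _, r in rows.iterrows():
        grid[ys.index(r["l_y"]), xs.index(r["l_x"])] = r[metric]
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(grid, origin="lower", aspect="equal")
    ax.set_xticks(range(len(xs)), [int(x) for x in xs])
    ax.set_yticks(range(len(ys)), [int(y) for y in ys])
    ax.set_xlabel("l_x (beads)")
    ax.set_ylabel("l_y (beads)")
    ax.set_title(metric.upper())
    ax.figure.colorbar(im, ax=ax)
    return ax
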