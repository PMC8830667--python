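"""Minimal plotting: the top-k ranking bar chart."""

from __future__ import annotations

import pandas as pd


def plot_ranking(ranking: pd.DataFrame, ax=None, title: str | None = None):
    """Horizontal bar chart of regions with the greatest coverage gain.

    ``ranking`` is the frame returned by
    :meth:`VaccineCoverageResults.ranking` (columns region_id, delta_pp).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * max(len(ranking), 4) + 1))
    ordered = ranking.iloc[::-1]
    ax.barh(ordered["region_id"], ordered["delta_pp"], color="#2c7fb8")
    ax.set_xlabel("Coverage change vs calibration vaccine (percentage points)")
    ax.set_title(title or "Regions with the greatest estimated coverage gain")
    for y, v in enumerate(ordered["delta_pp"]):
        ax.annotate(f"{v:+.1f}", (v, y), va="center", ha="left", fontsize=8)
    return ax
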