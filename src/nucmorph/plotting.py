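"""Minimal plotting helper: per-class boxplots of a score column."""

from __future__ import annotations

import pandas as pd

__all__ = ["boxplot_by_class"]


def boxplot_by_class(scores: pd.DataFrame, metric: str, ax=None,
                     classes=("NILM", "LSIL", "HSIL")):
    """Boxplot of one metric column grouped by diagnostic class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    data = [scores.loc[scores["label"] == c, metric].to_numpy() for c in classes]
    ax.boxplot(data, tick_labels=list(classes))
    ax.set_ylabel(metric)
    ax.set_title("%s by diagnostic class" % metric)
    return ax
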