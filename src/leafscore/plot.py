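"""Basic plotting helpers (Manhattan plot for clumped GWAS summaries)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["manhattan"]


def manhattan(snps: pd.DataFrame, thresholds=None, ax=None):
    """Scatter -log10(p) against cumulative genome position.

    ``snps`` needs ``chrom``, ``pos`` and ``pvalue`` columns; chromosomes
    are laid out in sorted order with alternating shades.  ``thresholds``
    may be a :class:`leafscore.gwas.Thresholds` (drawn as horizontal
    lines).  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, tick_labels = [], []
    for i, (chrom, group) in enumerate(
        snps.sort_values(["chrom", "pos"]).groupby("chrom", sort=True)
    ):
        x = group["pos"].to_numpy() + offset
        ax.scatter(
            x,
            -np.log10(group["pvalue"].to_numpy()),
            s=6,
            color="tab:green" if i % 2 else "tab:olive",
            linewidths=0,
        )
        ticks.append(offset + group["pos"].max() / 2)
        tick_labels.append(str(chrom))
        offset += int(group["pos"].max()) + 1
    if thresholds is not None:
        ax.axhline(-np.log10(thresholds.suggestive), ls="--", c="grey", lw=1)
        ax.axhline(-np.log10(thresholds.significant), ls="--", c="red", lw=1)
    ax.set_xticks(ticks, tick_labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}\,P$")
    return ax
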