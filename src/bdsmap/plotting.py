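"""Manhattan-style plots of per-SNP scan values across chromosome panels."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["manhattan", "write_manhattan_data"]


def _chrom_sort_key(label: str):
    try:
        return (0, int(label))
    except ValueError:
        return (1, label)


def write_manhattan_data(table: pd.DataFrame, value_col: str, path):
    """Write the (chrom, pos, value) TSV consumed by external plotters."""
    table[["chrom", "pos", value_col]].rename(
        columns={value_col: "value"}).to_csv(path, sep="\t", index=False)


def manhattan(table: pd.DataFrame, value_col: str = "var_2pqa2",
              log10: bool = False, ax=None, highlight_top: int | None = None):
    """Plot a scan value per SNP with chromosomes laid side by side.

    ``table`` needs columns ``chrom, pos`` and ``value_col`` (for q-value
    scans pass ``value_col='q'`` with ``log10=True``).  Up to 30 chromosome
    panels are alternately shaded; ``highlight_top`` draws a horizontal line
    at the k-th largest value, marking the selected tail.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 4))
    vals = table[value_col].to_numpy(dtype=float)
    if log10:
        vals = -np.log10(np.clip(vals, 1e-300, None))
    chroms = sorted(table["chrom"].astype(str).unique(), key=_chrom_sort_key)
    offset = 0.0
    ticks, labels = [], []
    for ci, chrom in enumerate(chroms):
        sub = table["chrom"].astype(str) == chrom
        pos = table.loc[sub, "pos"].to_numpy(dtype=float)
        span = pos.max() - pos.min() + 1
        x = offset + pos - pos.min()
        ax.scatter(x, vals[sub.to_numpy()], s=4,
                   color="C0" if ci % 2 == 0 else "C1", rasterized=True)
        ticks.append(offset + span / 2)
        labels.append(chrom)
        offset += span * 1.02
    if highlight_top is not None and 0 < highlight_top <= vals.size:
        cut = np.sort(vals)[-highlight_top]
        ax.axhline(cut, color="red", lw=1)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 " + value_col if log10 else value_col)
    return ax
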