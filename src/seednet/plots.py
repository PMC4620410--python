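"""Minimal diagnostic figures: degree CCDF and metric-correlation heat map."""

from __future__ import annotations

from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def degree_ccdf_plot(degrees: Sequence[int], path) -> None:
    deg = np.asarray(degrees, dtype=float)
    deg = deg[deg >= 1]
    uniq = np.unique(deg)
    ccdf = np.array([(deg >= k).mean() for k in uniq])
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.loglog(uniq, ccdf, "o", ms=4)
    ax.set_xlabel("degree k")
    ax.set_ylabel("P(K >= k)")
    ax.set_title("degree CCDF")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def correlation_heatmap(corr: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=45,
                  ha="right", fontsize=8)
    ax.set_yticks(range(len(corr.index)), corr.index, fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
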