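"""Heatmap rendering of the pair matrix.

A pure view over the TSV twin written by the pipeline: the lower
triangle shows mosaic density (mosaics per 10 kb), the upper triangle
the mean number of HR traces per mosaic, and pairs removed by the
relatedness screen render as black cells.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def render_matrix(matrix: pd.DataFrame | str | Path, out_path: str | Path) -> None:
    """Render a pair matrix (as produced by the pipeline) to an image.

    Accepts the DataFrame or the path of its TSV twin; non-square input
    is an error.  Excluded pairs are drawn black, empty cells white.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.read_csv(matrix, sep="\t", index_col=0)
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"pair matrix must be square, got {matrix.shape}")
    n = matrix.shape[0]
    lower = np.full((n, n), np.nan)
    upper = np.full((n, n), np.nan)
    excluded = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            cell = matrix.iloc[i, j]
            if isinstance(cell, str) and cell.strip() == "excluded":
                excluded[i, j] = True
            else:
                try:
                    val = float(cell)
                except (TypeError, ValueError):
                    continue
                (lower if i > j else upper)[i, j] = val

    fig, ax = plt.subplots(figsize=(max(4, n * 0.35), max(4, n * 0.35)))
    im1 = ax.imshow(lower, cmap="viridis")
    im2 = ax.imshow(upper, cmap="YlOrRd")
    black = np.zeros((n, n, 4))
    black[..., 3] = np.where(excluded, 1.0, 0.0)
    ax.imshow(black)
    ax.set_xticks(range(n), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(n), matrix.index, fontsize=6)
    fig.colorbar(im1, ax=ax, shrink=0.6, label="mosaics / 10 kb (lower)")
    fig.colorbar(im2, ax=ax, shrink=0.6, label="mean HR traces (upper)")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
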