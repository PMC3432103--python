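"""Small plotting helpers: metric maps and estimate-vs-observed scatters."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_metric_map(grid: np.ndarray, title: str = "", path=None):
    """Render one per-cell metric grid as an image."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid, origin="upper", cmap="viridis")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    ax.set_xlabel("col")
    ax.set_ylabel("row")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_estimate_vs_observed(observed, estimated, label: str = "", path=None):
    """Scatter of map-based estimates against observed site values with the
    y = x reference line along which an unbiased estimator falls."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(estimated, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=18, alpha=0.8)
    lo = np.nanmin([x.min(), y.min()])
    hi = np.nanmax([x.max(), y.max()])
    ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="y = x")
    ax.set_xlabel("observed")
    ax.set_ylabel("estimated")
    ax.set_title(label)
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
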