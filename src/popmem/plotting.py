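"""Error-histogram plots with overlaid model predictions."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .fitting import ErrorDistribution
from .spaces import CircularSpace, FeatureSpace, fitting_bin_edges, bin_index

__all__ = ["plot_error_distribution"]


def plot_error_distribution(
    trials: pd.DataFrame,
    space: FeatureSpace,
    predicted: Optional[ErrorDistribution] = None,
    n_bins: int = 40,
    ax=None,
):
    """Histogram of observed reproduction errors, with the model overlaid.

    Circular spaces plot signed errors; bounded spaces plot responses (so
    the predicted per-target distribution lines up).  Returns the axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    if predicted is not None:
        edges = predicted.bin_edges
        n_bins = predicted.n_bins
    else:
        edges = fitting_bin_edges(space, n_bins)
    if isinstance(space, CircularSpace):
        x = space.signed_error(
            trials["target"].to_numpy(dtype=float), trials["response"].to_numpy(dtype=float)
        )
        closed = "left"
        xlabel = "signed error (deg)"
    else:
        x = trials["response"].to_numpy(dtype=float)
        closed = "right"
        xlabel = "response (% intensity)"
    counts = np.bincount(bin_index(edges, x, closed=closed), minlength=n_bins)
    probs = counts / counts.sum()
    centers_ = 0.5 * (edges[:-1] + edges[1:])
    ax.bar(centers_, probs, width=np.diff(edges), color="0.8", edgecolor="0.5", label="data")
    if predicted is not None:
        ax.plot(centers_, predicted.probabilities, "-o", ms=3, color="crimson", label="model")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("probability")
    ax.legend(frameon=False)
    return ax
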