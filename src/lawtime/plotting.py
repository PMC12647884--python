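"""Optional matplotlib views of sweep results and feature scatters."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_noise_sweep", "plot_feature_scatter"]


def plot_noise_sweep(result, ax=None):
    """Mean-accuracy curves vs noise multiplier with 95% CI ribbons."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    summ = result.summary()
    for rep_name, grp in summ.groupby("representation"):
        grp = grp.sort_values("noise")
        ax.plot(grp["noise"], grp["mean"], marker="o", label=rep_name)
        ax.fill_between(grp["noise"], grp["mean"] - grp["ci95_half"],
                        grp["mean"] + grp["ci95_half"], alpha=0.2)
    ax.set_xlabel("noise multiplier")
    ax.set_ylabel("test accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_feature_scatter(features, x: str, y: str, ax=None, log: bool = True):
    """Scatter of two named feature columns, colored by class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xi, yi = features.names.index(x), features.names.index(y)
    X = features.values
    labels = features.labels if features.labels is not None else \
        np.zeros(X.shape[0], dtype=int)
    for cls in np.unique(labels):
        sel = labels == cls
        ax.scatter(X[sel, xi], X[sel, yi], label=f"class {cls}", s=18)
    if log:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend()
    return ax
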