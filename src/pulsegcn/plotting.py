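"""Small diagnostic figures (matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_local_rates", "plot_cv_summary"]


def plot_local_rates(rates: dict[str, float], threshold: float | None = None, ax=None):
    """Histogram of per-clade local evolution rates on a log10 scale (a small
    offset of 0.1 keeps zero rates plottable); optional split threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    vals = np.log10(np.array(list(rates.values())) + 0.1)
    ax.hist(vals, bins=30, color="steelblue", edgecolor="white")
    if threshold is not None:
        ax.axvline(threshold, color="red", linestyle="--")
    ax.set_xlabel("log10(local rate + 0.1)")
    ax.set_ylabel("clades")
    return ax


def plot_cv_summary(summary, ax=None):
    """Precision/recall/R^2 against mean NSTD from a cross-validation run."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    x = summary["mean_nstd"]
    for col, style in (("r2", "o-"), ("precision", "s-"), ("recall", "^-")):
        if col in summary:
            ax.errorbar(x, summary[col], yerr=summary.get(f"ci_{col}"),
                        fmt=style, label=col, capsize=2)
    ax.set_xscale("log")
    ax.set_xlabel("mean NSTD (substitutions/site)")
    ax.set_ylabel("score")
    ax.legend(frameon=False)
    return ax
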