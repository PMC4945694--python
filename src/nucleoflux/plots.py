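"""Optional matplotlib conveniences for run outputs.

Figures are derived from the CSV/summary artifacts the pipeline writes;
they are never inputs to any computation or test.
"""

from __future__ import annotations

import numpy as np


def plot_flux_trace(trace, ax=None, label=None):
    """Normalized interface-flux trace vs time (masked samples dropped)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ok = np.isfinite(trace.normalized)
    ax.plot(trace.times[ok], trace.normalized[ok], marker=".", lw=1.2,
            label=label)
    ax.axhline(1.0, color="0.6", lw=0.8, ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(r"$\|\phi\| / \|\phi_0\|$")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_group_feature(summaries, feature: str, ax=None):
    """Bar chart of group means with 99 % interval bars for one feature."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.2))
    labels = list(summaries)
    means = [summaries[g].mean[feature] for g in labels]
    hw = [summaries[g].halfwidth99[feature] for g in labels]
    ax.bar(labels, means, yerr=hw, capsize=4, color="0.75", edgecolor="k")
    ax.set_ylabel(feature)
    return ax
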