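"""Basic agreement plots (requires the optional matplotlib dependency)."""

from __future__ import annotations

import numpy as np

from .metrics import bland_altman


def bland_altman_plot(estimates, references, ax=None):
    """Scatter of difference vs mean with bias and 1.96-SD limits of agreement."""
    import matplotlib.pyplot as plt

    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    ba = bland_altman(est, ref)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((est + ref) / 2, est - ref, s=18, alpha=0.8)
    ax.axhline(ba.bias, color="k", label=f"bias = {ba.bias:+.4f}")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel("mean of vFFR and reference FFR")
    ax.set_ylabel("vFFR - reference FFR")
    ax.legend(loc="best")
    return ax


def sobol_heatmap(result, ax=None):
    """Heatmap-style table of main/total/interaction sensitivity indices."""
    import matplotlib.pyplot as plt

    frame = result.to_frame()[["s_main", "s_total", "s_interaction"]]
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(frame.to_numpy(), cmap="viridis", aspect="auto")
    ax.set_xticks(range(3), frame.columns)
    ax.set_yticks(range(len(frame)), frame.index)
    plt.colorbar(im, ax=ax, label="sensitivity index")
    return ax
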