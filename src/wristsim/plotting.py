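"""Motion-path plots in the conventional RUD-vs-FE plane.

Radioulnar deviation (radial negative, ulnar positive) on the x-axis,
flexion-extension (extension negative, flexion positive) on the y-axis --
one curve per specimen, as motion envelopes are usually displayed.
"""

from __future__ import annotations

import numpy as np


def plot_motion_paths(profiles, labels=None, ax=None, title=None):
    """Plot (rud, fe) mean motion paths.

    ``profiles`` is a list of (n, 2) arrays of (rud_deg, fe_deg).  Returns
    the matplotlib axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    labels = labels or [None] * len(profiles)
    for path, label in zip(profiles, labels):
        path = np.asarray(path)
        ax.plot(path[:, 0], path[:, 1], lw=1.2, label=label)
    ax.axhline(0.0, color="0.8", lw=0.8, zorder=0)
    ax.axvline(0.0, color="0.8", lw=0.8, zorder=0)
    ax.set_xlabel("radial(-) / ulnar(+) deviation (deg)")
    ax.set_ylabel("extension(-) / flexion(+) (deg)")
    if title:
        ax.set_title(title)
    if any(lbl is not None for lbl in labels):
        ax.legend(fontsize=8)
    ax.set_aspect("equal", adjustable="datalim")
    return ax
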