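"""Small diagnostic plots (matplotlib required only here)."""

from __future__ import annotations

import numpy as np

from .match import MatchCurve


def plot_match_curve(curve: MatchCurve, ax=None, label: str | None = None):
    """Gaussian match vs delay, with the optimal delay marked.

    Returns the matplotlib axes; save with ``ax.figure.savefig(...)``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(curve.delays_s * 1000, curve.values, label=label)
    ax.plot([curve.optimal_delay_s * 1000], [curve.max_match], "o")
    ax.set_xlabel("delay (ms)")
    ax.set_ylabel("Gaussian match")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_tdistance_curves(curves, k_star: int | None = None, ax=None):
    """Per-block t-distance curves and their across-block mean."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ks = sorted({k for c in curves for k in c})
    for c in curves:
        kk = sorted(c)
        ax.plot(kk, [c[k] for k in kk], color="0.7", lw=0.8)
    mean = [np.mean([c[k] for c in curves if k in c and np.isfinite(c[k])])
            for k in ks]
    ax.plot(ks, mean, color="C0", lw=2, label="mean")
    if k_star is not None:
        ax.axvline(k_star, color="C1", ls="--", label=f"k* = {k_star}")
    ax.set_xlabel("number of states k")
    ax.set_ylabel("t-distance")
    ax.legend(frameon=False)
    return ax
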