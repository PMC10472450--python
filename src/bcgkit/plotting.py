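"""Minimal plotting helpers (Bland-Altman and beat overlays)."""

from __future__ import annotations

import numpy as np

__all__ = ["bland_altman_plot", "plot_beats"]


def bland_altman_plot(seq_ref, seq_test, ax=None, label: str = ""):
    """Difference-vs-mean scatter with bias and 1.96-SD limits of agreement."""
    import matplotlib.pyplot as plt

    ref = np.asarray(seq_ref, dtype=float)
    test = np.asarray(seq_test, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    mean = (ref + test) / 2.0
    diff = test - ref
    bias = diff.mean()
    sd = diff.std(ddof=1)
    ax.scatter(mean, diff, s=8, alpha=0.6)
    ax.axhline(bias, color="k", lw=1)
    for lim in (bias - 1.96 * sd, bias + 1.96 * sd):
        ax.axhline(lim, color="r", lw=1, ls="--")
    ax.set_xlabel(f"mean of methods {label}")
    ax.set_ylabel(f"difference (test - ref) {label}")
    return ax


def plot_beats(record, ann, channel: str = "bcg", ax=None):
    """Overlay detected I/J/K markers on a signal channel."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    x = record.channel(channel)
    t = np.arange(x.size) / record.fs
    ax.plot(t, x, lw=0.6, color="C0")
    for marker, idx, color in (
        ("v", ann.i_indices, "C2"),
        ("^", ann.j_indices, "C3"),
        ("v", ann.k_indices, "C4"),
    ):
        sel = idx[idx >= 0]
        ax.plot(sel / record.fs, x[sel], marker, color=color, ms=4, ls="none")
    ax.set_xlabel("time (s)")
    return ax
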