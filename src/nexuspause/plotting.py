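"""Matplotlib renderings of profiles and sequence composition.

Profiles are drawn in the strand-separated convention: plus-strand stop
bases above the axis, minus-strand below.
"""

from __future__ import annotations

import numpy as np

from .cohort_stats import BASES, PositionFrequencyMatrix
from .profiles import StopBaseProfile

_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def plot_profile(profile: StopBaseProfile, ax=None, window: tuple[int, int] | None = None):
    """Plot a stop-base profile, plus strand up (red), minus strand down (blue)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    start, end = (0, profile.length) if window is None else window
    x = np.arange(start, end)
    ax.fill_between(x, profile.plus_counts[start:end], step="mid",
                    color="#D62839", label="+ strand")
    ax.fill_between(x, -profile.minus_counts[start:end], step="mid",
                    color="#255C99", label="- strand")
    ax.axhline(0, lw=0.8, color="black")
    ax.set_xlabel("position (0-based)")
    ax.set_ylabel("stop-base count" + (" (RPM)" if profile.normalized else ""))
    ax.legend(frameon=False)
    return ax


def plot_information_logo(pfm: PositionFrequencyMatrix, ax=None):
    """Stacked letter-height bars: per-base information content in bits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.25 * pfm.counts.shape[1] + 1, 2.5))
    freqs = pfm.frequencies
    ic = pfm.info_content
    lo, hi = pfm.window_bio
    positions = [p for p in range(lo, hi + 1) if p != 0]
    for j, pos in enumerate(positions):
        bottom = 0.0
        order = np.argsort(freqs[:, j])
        for b in order:
            height = freqs[b, j] * ic[j]
            if height > 0:
                ax.bar(pos, height, bottom=bottom, width=0.9,
                       color=_COLORS[BASES[b]])
                bottom += height
    ax.set_ylim(0, 2)
    ax.set_xlabel("position relative to TSS")
    ax.set_ylabel("bits")
    return ax
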