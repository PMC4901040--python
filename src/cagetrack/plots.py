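"""Matplotlib figures: double-plotted actograms and proximity traces."""

from __future__ import annotations

import numpy as np

from .schedule import LightSchedule

__all__ = ["plot_actogram", "plot_proximity"]


def plot_actogram(matrix: np.ndarray, schedule: LightSchedule | None = None,
                  title: str = "", ax=None):
    """Raster a double-plotted actogram matrix (days x 2*bins_per_day).

    Darker cells mean more distance traveled; the dark phase is shaded
    when a schedule is given.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.5 * len(matrix) + 1))
    n_days, width = matrix.shape
    bpd = width // 2
    for d in range(n_days):
        row = matrix[d]
        x = (np.arange(width) + 0.5) * (48.0 / width)
        heights = row / np.nanmax(matrix) if np.nanmax(matrix) > 0 else row
        ax.bar(x, np.nan_to_num(heights) * 0.9, bottom=n_days - d - 1,
               width=48.0 / width, color="black")
    if schedule is not None:
        # shade the dark phase on both halves of the double plot
        t = np.arange(0, 48 * 60) * 60.0  # minute grid over 48 h of clock time
        dark = schedule.is_dark(t - schedule.start_s % 86400)
        edges = np.flatnonzero(np.diff(dark.astype(int)))
        spans = np.split(np.flatnonzero(dark), np.flatnonzero(np.diff(np.flatnonzero(dark)) > 1) + 1)
        for span in spans:
            if span.size:
                ax.axvspan(span[0] / 60.0, (span[-1] + 1) / 60.0, color="0.85", zorder=0)
    ax.set_xlim(0, 48)
    ax.set_ylim(0, n_days)
    ax.set_xlabel("time (h, double-plotted)")
    ax.set_ylabel("day")
    ax.set_yticks(np.arange(n_days) + 0.5, [str(n_days - d) for d in range(n_days)])
    if title:
        ax.set_title(title)
    return ax


def plot_proximity(proximity, ax=None):
    """Plot mean inter-animal distance over time with the huddle band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(proximity.t / 3600.0, proximity.mean_distance, lw=0.5, color="tab:blue")
    ax.axhline(proximity.huddle_radius_mm, color="tab:red", ls="--",
               label=f"huddle radius {proximity.huddle_radius_mm:g} mm")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("mean pairwise distance (mm)")
    ax.legend(loc="upper right")
    return ax
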