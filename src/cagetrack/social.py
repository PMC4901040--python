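"""Group structure over time: inter-animal distances and occupancy maps.

Group-housed mice huddle in a quietly active cluster during the light
phase and disperse around the activity onset that anticipates the dark
phase.  This module quantifies that narrative: pairwise inter-animal
distances on the shared tracking grid (with a huddle indicator), and
per-animal occupancy heatmaps in 6-min bins around a detected onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .geometry import BaseplateGeometry

__all__ = [
    "ProximitySeries",
    "pairwise_distances",
    "OccupancyGrid",
    "onset_heatmaps",
    "occupancy_entropy",
]

DEFAULT_HUDDLE_RADIUS_MM = 50.0  # one antenna tile


@dataclass(frozen=True)
class ProximitySeries:
    """Pairwise inter-animal distances on a shared time grid."""

    t: np.ndarray
    pairs: list[tuple[str, str]]
    distances: np.ndarray  # (n_pairs, n_times), mm
    huddle_radius_mm: float

    @property
    def mean_distance(self) -> np.ndarray:
        """Mean over pairs at each time point."""
        return self.distances.mean(axis=0)

    @property
    def huddled(self) -> np.ndarray:
        """True where every pair is within the huddle radius."""
        return (self.distances <= self.huddle_radius_mm).all(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = {"t_s": self.t}
        for (a, b), d in zip(self.pairs, self.distances):
            rows[f"{a}-{b}"] = d
        rows["mean_distance_mm"] = self.mean_distance
        rows["huddled"] = self.huddled
        return pd.DataFrame(rows)


def pairwise_distances(
    tracks, huddle_radius_mm: float = DEFAULT_HUDDLE_RADIUS_MM
) -> ProximitySeries:
    """Euclidean distance between every animal pair at every grid point.

    All tracks must share an identical time grid (interpolate them with
    the same step and span first).
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    t0 = tracks[0].t
    for tr in tracks[1:]:
        if len(tr.t) != len(t0) or not np.allclose(tr.t, t0):
            raise ValueError("tracks must share one time grid")
    pairs = list(combinations(range(len(tracks)), 2))
    d = np.empty((len(pairs), len(t0)))
    for k, (i, j) in enumerate(pairs):
        diff = tracks[i].xy - tracks[j].xy
        d[k] = np.hypot(diff[:, 0], diff[:, 1])
    return ProximitySeries(
        t=t0,
        pairs=[(tracks[i].tag_id, tracks[j].tag_id) for i, j in pairs],
        distances=d,
        huddle_radius_mm=huddle_radius_mm,
    )


@dataclass(frozen=True)
class OccupancyGrid:
    """Per-animal occupancy fractions around an onset.

    ``fractions`` has shape ``(n_bins, n_rows, n_cols)``; each bin's
    cell values sum to 1 whenever the bin contains any data.  The
    midpoint of the central bin coincides with the onset time.
    ``mean_xy`` summarizes each bin by the mean position.
    """

    tag_id: str
    bin_starts_s: np.ndarray
    fractions: np.ndarray
    mean_xy: np.ndarray  # (n_bins, 2)

    @property
    def n_bins(self) -> int:
        return len(self.bin_starts_s)

    def to_frame(self) -> pd.DataFrame:
        n_bins, n_rows, n_cols = self.fractions.shape
        bins, rows, cols = np.meshgrid(
            np.arange(n_bins), np.arange(n_rows), np.arange(n_cols), indexing="ij"
        )
        return pd.DataFrame(
            {
                "tag_id": self.tag_id,
                "bin": bins.ravel(),
                "bin_start_s": self.bin_starts_s[bins.ravel()],
                "cell_row": rows.ravel(),
                "cell_col": cols.ravel(),
                "fraction": self.fractions.ravel(),
            }
        )


def onset_heatmaps(
    tracks,
    geometry: BaseplateGeometry,
    onset_time_s: float,
    n_bins_before: int = 5,
    n_bins_after: int = 5,
    bin_width_s: float = 360.0,
) -> list[OccupancyGrid]:
    """Occupancy heatmaps in time bins centered on an activity onset.

    For each animal, positions on the tracking grid are histogrammed
    over antenna tiles within each of ``n_bins_before + 1 +
    n_bins_after`` bins; the central bin's midpoint is the onset time
    (from the circadian detector).  Cells are the antenna tiles — the
    honest resolution of the hardware — and fractions are normalized per
    bin.
    """
    n_bins = n_bins_before + 1 + n_bins_after
    t_first = onset_time_s - (n_bins_before + 0.5) * bin_width_s
    bin_starts = t_first + np.arange(n_bins) * bin_width_s

    out = []
    for tr in tracks:
        fractions = np.zeros((n_bins, geometry.n_rows, geometry.n_cols))
        mean_xy = np.full((n_bins, 2), np.nan)
        for b, b0 in enumerate(bin_starts):
            m = (tr.t >= b0) & (tr.t < b0 + bin_width_s)
            if not m.any():
                continue
            xy = tr.xy[m]
            col, row = geometry.cell_of(xy[:, 0], xy[:, 1])
            counts = np.zeros((geometry.n_rows, geometry.n_cols))
            np.add.at(counts, (row, col), 1.0)
            fractions[b] = counts / counts.sum()
            mean_xy[b] = xy.mean(axis=0)
        out.append(
            OccupancyGrid(
                tag_id=tr.tag_id,
                bin_starts_s=bin_starts,
                fractions=fractions,
                mean_xy=mean_xy,
            )
        )
    return out


def occupancy_entropy(grid: OccupancyGrid) -> np.ndarray:
    """Shannon entropy (nats) of each bin's occupancy distribution.

    Low when the animal sits in one tile (huddled at the nest), rising
    as it ranges over the cage — a compact summary of the
    clustering-then-dispersal pattern around the activity onset.
    """
    ent = np.zeros(grid.n_bins)
    for b in range(grid.n_bins):
        p = grid.fractions[b].ravel()
        p = p[p > 0]
        ent[b] = float(-(p * np.log(p)).sum()) if p.size else np.nan
    return ent
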