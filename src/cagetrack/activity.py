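"""Binned activity series and the headline activity statistics.

Distance traveled is summed into fixed-width time bins (6 min by
default) aligned to the recording start, then analysed relative to the
light schedule: double-plotted actograms, light/dark phase totals with
the standard acclimation exclusions, the duration of the post-transfer
settling bout, the anticipatory-activity index for the hour before
lights-off, and group comparisons (one-way ANOVA / ANCOVA with Tukey's
post-hoc test, implemented from first principles so the sums of squares
can be audited against independent references).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import DAY_S, LightSchedule

__all__ = [
    "ActivitySeries",
    "bin_activity",
    "double_plot_actogram",
    "PhaseTotals",
    "phase_totals",
    "SettlingBout",
    "detect_settling_bout",
    "anticipatory_index",
    "GroupComparison",
    "compare_groups",
]


@dataclass(frozen=True)
class ActivitySeries:
    """Per-animal distance traveled per time bin.

    Bin ``i`` covers recording time ``[i * bin_width_s, (i+1) * bin_width_s)``;
    the bin width must divide 24 h so that bins align identically across
    days.  ``partial_first`` / ``partial_last`` flag bins not fully
    covered by data.
    """

    tag_id: str
    bin_width_s: float
    values: np.ndarray
    partial_first: bool = False
    partial_last: bool = False

    def __post_init__(self) -> None:
        if DAY_S % self.bin_width_s != 0:
            raise ValueError(
                f"bin width {self.bin_width_s} s must divide 24 h"
            )
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("activity values must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def bins_per_day(self) -> int:
        return int(DAY_S // self.bin_width_s)

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width_s

    def bin_mids(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_s

    def zt_hours(self, schedule: LightSchedule) -> np.ndarray:
        return schedule.zt_hours(self.bin_mids())


def bin_activity(
    track, bin_width_s: float = 360.0
) -> ActivitySeries:
    """Bin a location track's distance traveled into an activity series.

    Each grid step's distance is attributed to the bin containing the
    step's start time, so the bin totals sum exactly to the track's
    total distance (conservation).
    """
    if DAY_S % bin_width_s != 0:
        raise ValueError(f"bin width {bin_width_s} s must divide 24 h")
    steps = np.diff(track.xy, axis=0)
    d = np.hypot(steps[:, 0], steps[:, 1])
    t = np.asarray(track.t, dtype=float)
    bins = (t[:-1] // bin_width_s).astype(int)
    n_bins = int(t[-1] // bin_width_s) + 1
    values = np.bincount(bins, weights=d, minlength=n_bins)
    return ActivitySeries(
        tag_id=track.tag_id,
        bin_width_s=bin_width_s,
        values=values,
        partial_first=t[0] > 0.0,
        partial_last=(t[-1] % bin_width_s) != 0.0 or t[-1] < n_bins * bin_width_s,
    )


def double_plot_actogram(series: ActivitySeries) -> np.ndarray:
    """Double-plotted actogram matrix, shape ``(days, 2 * bins_per_day)``.

    Row ``d`` shows day ``d`` followed by day ``d + 1``; the right half
    of the last row is padded with NaN.  By construction the right half
    of each row equals the left half of the next, which makes phase
    drift across days visible when rastered.
    """
    bpd = series.bins_per_day
    if series.n_bins < bpd:
        raise ValueError("need at least one full day of data for an actogram")
    n_days = int(np.ceil(series.n_bins / bpd))
    padded = np.full(n_days * bpd, np.nan)
    padded[: series.n_bins] = series.values
    days = padded.reshape(n_days, bpd)
    out = np.full((n_days, 2 * bpd), np.nan)
    out[:, :bpd] = days
    out[:-1, bpd:] = days[1:]
    return out


@dataclass(frozen=True)
class PhaseTotals:
    """Light/dark activity totals over the retained analysis window."""

    tag_id: str
    light_total_mm: float
    dark_total_mm: float
    light_hours: float
    dark_hours: float

    @property
    def light_mean_daily_mm(self) -> float:
        """Mean distance per 12 h light phase."""
        return self.light_total_mm / self.light_hours * 12.0 if self.light_hours else 0.0

    @property
    def dark_mean_daily_mm(self) -> float:
        return self.dark_total_mm / self.dark_hours * 12.0 if self.dark_hours else 0.0


def phase_totals(
    series: ActivitySeries,
    schedule: LightSchedule,
    window: tuple[float, float] | None = None,
) -> PhaseTotals:
    """Light- and dark-phase activity totals on the retained window.

    ``window`` is a ``(t0, t1)`` pair in recording seconds (for the
    standard acclimation exclusions use
    :meth:`LightSchedule.retained_window`); only bins fully inside the
    window are counted, and each bin is classified by its midpoint.
    """
    starts = series.bin_starts()
    mids = series.bin_mids()
    keep = np.ones(series.n_bins, dtype=bool)
    if window is not None:
        t0, t1 = window
        keep = (starts >= t0) & (starts + series.bin_width_s <= t1)
    dark = schedule.is_dark(mids)
    vals = np.asarray(series.values)
    light_mask = keep & ~dark
    dark_mask = keep & dark
    h = series.bin_width_s / 3600.0
    return PhaseTotals(
        tag_id=series.tag_id,
        light_total_mm=float(vals[light_mask].sum()),
        dark_total_mm=float(vals[dark_mask].sum()),
        light_hours=float(light_mask.sum() * h),
        dark_hours=float(dark_mask.sum() * h),
    )


@dataclass(frozen=True)
class SettlingBout:
    """Duration of the transient activity bout after cage transfer."""

    tag_id: str
    duration_min: float
    detected: bool


def detect_settling_bout(
    series: ActivitySeries, schedule: LightSchedule, k: int = 2
) -> SettlingBout:
    """Duration of the post-transfer settling bout.

    The cage transfer at t = 0 triggers a bout of elevated activity that
    typically lasts up to ~60 min.  Its end is taken as the first moment
    activity stays at or below the animal's light-phase median for ``k``
    consecutive bins; the bout duration is the time from t = 0 to that
    moment.  If activity never settles the full span is returned with a
    warning and ``detected=False``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mids = series.bin_mids()
    vals = np.asarray(series.values, dtype=float)
    light = ~schedule.is_dark(mids)
    if not light.any():
        raise ValueError("series contains no light-phase bins")
    threshold = float(np.median(vals[light]))
    below = vals <= threshold
    # first run of k consecutive settled bins
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run == k:
            start = i - k + 1
            return SettlingBout(
                tag_id=series.tag_id,
                duration_min=start * series.bin_width_s / 60.0,
                detected=True,
            )
    warnings.warn(
        f"tag {series.tag_id}: activity never settled below the light-phase "
        "median; returning the full span"
    )
    return SettlingBout(
        tag_id=series.tag_id,
        duration_min=series.n_bins * series.bin_width_s / 60.0,
        detected=False,
    )


def anticipatory_index(
    series: ActivitySeries,
    schedule: LightSchedule,
    window: tuple[str, str] = ("18:00", "19:00"),
) -> tuple[float, float]:
    """Anticipatory activity and its covariate.

    Returns ``(anticip_sum, daytime_sum)``: the total distance in the
    clock window before lights-off (18:00–19:00 by default) summed over
    the whole recording, and the total light-phase (daytime) distance
    over the same span.  The daytime total is the covariate used to
    adjust for overall activity differences when comparing groups
    (ANCOVA), since a more active animal accumulates more pre-dark
    activity regardless of anticipation.
    """
    mids = series.bin_mids()
    vals = np.asarray(series.values, dtype=float)
    in_window = schedule.clock_window_mask(mids, *window)
    daytime = ~schedule.is_dark(mids)
    return float(vals[in_window].sum()), float(vals[daytime].sum())


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA / ANCOVA with Tukey's post-hoc test."""

    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]  # covariate-adjusted when a covariate is used
    tukey: pd.DataFrame = field(repr=False)  # group1, group2, diff, q, p_adj

    def summary(self) -> str:
        lines = [
            f"F({self.df_between}, {self.df_within}) = {self.F:.3f}, p = {self.p:.3g}"
        ]
        for _, r in self.tukey.iterrows():
            lines.append(
                f"  {r['group1']} vs {r['group2']}: diff = {r['diff']:.3g}, "
                f"p_adj = {r['p_adj']:.3g}"
            )
        return "\n".join(lines)


def compare_groups(values, groups, covariate=None) -> GroupComparison:
    """Compare per-animal statistics across groups.

    Without a covariate this is a one-way ANOVA computed directly from
    between- and within-group sums of squares.  With a covariate (e.g.
    the daytime activity total for the anticipatory index) it is an
    ANCOVA: the group effect is tested by comparing the residual sum of
    squares of ``value ~ group + covariate`` against ``value ~
    covariate``, and group means are adjusted to the grand covariate
    mean.  Pairwise comparisons use Tukey's studentized-range test
    (Tukey–Kramer for unequal group sizes).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise ValueError("values and groups must have the same length")
    labels = sorted(set(g.tolist()))
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    idx = {lab: np.nonzero(g == lab)[0] for lab in labels}
    n_g = {lab: len(idx[lab]) for lab in labels}
    if min(n_g.values()) < 2:
        raise ValueError("every group needs at least 2 observations")
    n = y.size

    if covariate is None:
        grand = y.mean()
        means = {lab: float(y[idx[lab]].mean()) for lab in labels}
        ss_between = sum(n_g[lab] * (means[lab] - grand) ** 2 for lab in labels)
        ss_within = sum(((y[idx[lab]] - means[lab]) ** 2).sum() for lab in labels)
        df_b, df_w = k - 1, n - k
        if ss_within <= 0:
            raise ValueError("zero within-group variance: F is undefined")
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
        mse = ss_within / df_w

        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                a, b = labels[i], labels[j]
                diff = means[a] - means[b]
                se = np.sqrt(mse / 2.0 * (1.0 / n_g[a] + 1.0 / n_g[b]))
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_w))
                rows.append((a, b, diff, q, p_adj))
    else:
        x = np.asarray(covariate, dtype=float)
        if x.shape != y.shape:
            raise ValueError("covariate must have the same length as values")
        dummies = np.column_stack([(g == lab).astype(float) for lab in labels[1:]])
        X_full = np.column_stack([np.ones(n), dummies, x])
        X_red = np.column_stack([np.ones(n), x])
        beta_f, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        beta_r, *_ = np.linalg.lstsq(X_red, y, rcond=None)
        sse_f = float(((y - X_full @ beta_f) ** 2).sum())
        sse_r = float(((y - X_red @ beta_r) ** 2).sum())
        df_b, df_w = k - 1, n - k - 1
        if sse_f <= 0:
            raise ValueError("zero residual variance: F is undefined")
        F = ((sse_r - sse_f) / df_b) / (sse_f / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
        mse = sse_f / df_w
        slope = float(beta_f[-1])

        x_grand = x.mean()
        xbar = {lab: float(x[idx[lab]].mean()) for lab in labels}
        means = {
            lab: float(y[idx[lab]].mean() - slope * (xbar[lab] - x_grand))
            for lab in labels
        }
        e_xx = sum(((x[idx[lab]] - xbar[lab]) ** 2).sum() for lab in labels)

        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                a, b = labels[i], labels[j]
                diff = means[a] - means[b]
                se_diff = np.sqrt(
                    mse
                    * (
                        1.0 / n_g[a]
                        + 1.0 / n_g[b]
                        + (xbar[a] - xbar[b]) ** 2 / e_xx
                    )
                )
                q = np.sqrt(2.0) * abs(diff) / se_diff
                p_adj = float(stats.studentized_range.sf(q, k, df_w))
                rows.append((a, b, diff, q, p_adj))

    tukey = pd.DataFrame(rows, columns=["group1", "group2", "diff", "q", "p_adj"])
    tukey["reject_05"] = tukey["p_adj"] < 0.05
    return GroupComparison(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means=means,
        tukey=tukey,
    )
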