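"""CSV file formats for read streams, tracks, activity and ground truth.

All files are plain CSV with a ``#``-prefixed header block that carries
the baseplate geometry, the light schedule and the recording's clock
anchor, so every downstream file is self-describing and clock-window
statistics (e.g. the 18:00–19:00 anticipation window) stay unambiguous:

    # cagetrack reads v1
    # geometry: n_cols=3 n_rows=6 pitch_mm=50.0
    # schedule: lights_on=07:00 lights_off=19:00 start_clock=12:00
    t_s,antenna_col,antenna_row,tag_id
    ...

Timestamps are seconds since recording start.  Readers are fail-fast:
missing columns and malformed rows raise with the offending column or
line number.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import BaseplateGeometry
from .schedule import LightSchedule, format_clock
from .tracking import LocationTrack

__all__ = [
    "write_reads",
    "read_reads",
    "write_tracks",
    "read_tracks",
    "write_ground_truth",
    "read_ground_truth",
    "write_activity",
    "read_activity",
]

_READ_COLUMNS = {"t_s": float, "antenna_col": int, "antenna_row": int, "tag_id": str}
_TRACK_COLUMNS = {"t_s": float, "tag_id": str, "x_mm": float, "y_mm": float,
                  "provenance": str}
_TRUTH_COLUMNS = {"t_s": float, "tag_id": str, "x_mm": float, "y_mm": float}


def _header(kind: str, geometry: BaseplateGeometry, schedule: LightSchedule) -> str:
    return "\n".join(
        [
            f"# cagetrack {kind} v1",
            f"# geometry: n_cols={geometry.n_cols} n_rows={geometry.n_rows} "
            f"pitch_mm={geometry.pitch_mm:g}",
            f"# schedule: lights_on={format_clock(schedule.lights_on_s)} "
            f"lights_off={format_clock(schedule.lights_off_s)} "
            f"start_clock={format_clock(schedule.start_s)}",
            "",
        ]
    )


def _parse_header(lines: list[str]) -> tuple[BaseplateGeometry, LightSchedule]:
    meta: dict[str, dict[str, str]] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" not in body:
            continue
        section, _, rest = body.partition(":")
        fields = dict(
            item.split("=", 1) for item in rest.split() if "=" in item
        )
        if fields:
            meta[section.strip()] = fields
    g = meta.get("geometry", {})
    s = meta.get("schedule", {})
    geometry = BaseplateGeometry(
        n_cols=int(g.get("n_cols", 3)),
        n_rows=int(g.get("n_rows", 6)),
        pitch_mm=float(g.get("pitch_mm", 50.0)),
    )
    schedule = LightSchedule(
        lights_on=s.get("lights_on", "07:00"),
        lights_off=s.get("lights_off", "19:00"),
        start_clock=s.get("start_clock", "12:00"),
    )
    return geometry, schedule


def _read_csv_with_header(path, required: dict[str, type]):
    path = Path(path)
    header_lines: list[str] = []
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        header_lines.append(lines[i])
        i += 1
    geometry, schedule = _parse_header(header_lines)
    body = "\n".join(lines[i:])
    if not body.strip():
        warnings.warn(f"{path}: no data rows")
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in required.items()})
        return df, geometry, schedule
    df = pd.read_csv(_io.StringIO(body), dtype=str, skipinitialspace=True)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    # fail-fast conversion with line numbers (1-based, counting header lines)
    offset = len(header_lines) + 2  # + column header + 1-based
    for col, typ in required.items():
        if typ is str:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line_no = int(np.nonzero(bad.to_numpy())[0][0]) + offset
            raise ValueError(
                f"{path}: malformed value {df[col][bad].iloc[0]!r} in column "
                f"'{col}' at line {line_no}"
            )
        if converted.isna().any():
            line_no = int(np.nonzero(converted.isna().to_numpy())[0][0]) + offset
            raise ValueError(f"{path}: empty value in column '{col}' at line {line_no}")
        df[col] = converted.astype(typ)
    return df, geometry, schedule


def _write_csv_with_header(df, path, kind, geometry, schedule, float_format="%.6g"):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(kind, geometry, schedule))
        df.to_csv(fh, index=False, float_format=float_format)


# -- read events -------------------------------------------------------------


def write_reads(reads: pd.DataFrame, path, geometry: BaseplateGeometry,
                schedule: LightSchedule) -> None:
    """Write a read-event stream (``t_s, antenna_col, antenna_row, tag_id``)."""
    _write_csv_with_header(
        reads[list(_READ_COLUMNS)], path, "reads", geometry, schedule
    )


def read_reads(path):
    """Read a read-event stream; returns ``(df, geometry, schedule)``."""
    return _read_csv_with_header(path, _READ_COLUMNS)


# -- location tracks ---------------------------------------------------------


def write_tracks(tracks, path, geometry, schedule) -> None:
    """Write interpolated tracks in long format with provenance flags."""
    frames = [
        pd.DataFrame(
            {
                "t_s": tr.t,
                "tag_id": tr.tag_id,
                "x_mm": tr.xy[:, 0],
                "y_mm": tr.xy[:, 1],
                "provenance": np.where(tr.observed, "observed", "interpolated"),
            }
        )
        for tr in tracks
    ]
    _write_csv_with_header(
        pd.concat(frames, ignore_index=True), path, "tracks", geometry, schedule,
        float_format="%.10g",
    )


def read_tracks(path):
    """Read tracks back into :class:`LocationTrack` objects.

    Returns ``(tracks, geometry, schedule)``.
    """
    df, geometry, schedule = _read_csv_with_header(path, _TRACK_COLUMNS)
    tracks = []
    for tag, sub in df.groupby("tag_id", sort=True):
        sub = sub.sort_values("t_s")
        tracks.append(
            LocationTrack(
                tag_id=str(tag),
                t=sub["t_s"].to_numpy(),
                xy=sub[["x_mm", "y_mm"]].to_numpy(),
                observed=(sub["provenance"] == "observed").to_numpy(),
            )
        )
    return tracks, geometry, schedule


# -- ground truth ------------------------------------------------------------


def write_ground_truth(trajectories, path, geometry, schedule) -> None:
    """Write simulator ground-truth positions (``t_s, tag_id, x_mm, y_mm``)."""
    frames = [
        pd.DataFrame(
            {"t_s": tr.t, "tag_id": tr.tag_id, "x_mm": tr.xy[:, 0], "y_mm": tr.xy[:, 1]}
        )
        for tr in trajectories
    ]
    _write_csv_with_header(
        pd.concat(frames, ignore_index=True), path, "ground-truth", geometry, schedule,
        float_format="%.10g",
    )


def read_ground_truth(path):
    """Read ground-truth trajectories; returns ``(trajectories, geometry, schedule)``."""
    from .simulate import Trajectory

    df, geometry, schedule = _read_csv_with_header(path, _TRUTH_COLUMNS)
    trajs = []
    for tag, sub in df.groupby("tag_id", sort=True):
        sub = sub.sort_values("t_s")
        trajs.append(
            Trajectory(
                tag_id=str(tag),
                t=sub["t_s"].to_numpy(),
                xy=sub[["x_mm", "y_mm"]].to_numpy(),
            )
        )
    return trajs, geometry, schedule


# -- binned activity ---------------------------------------------------------


def write_activity(series_list, path, geometry, schedule) -> None:
    """Write binned activity in long format (one row per animal and bin)."""
    frames = []
    for s in series_list:
        bins = np.arange(s.n_bins)
        frames.append(
            pd.DataFrame(
                {
                    "tag_id": s.tag_id,
                    "bin": bins,
                    "t_start_s": s.bin_starts(),
                    "day": (s.bin_starts() // 86400).astype(int),
                    "zt_h": s.zt_hours(schedule),
                    "distance_mm": s.values,
                }
            )
        )
    _write_csv_with_header(
        pd.concat(frames, ignore_index=True), path, "activity", geometry, schedule
    )


def read_activity(path):
    """Read binned activity back into :class:`ActivitySeries` objects.

    Returns ``(series_list, geometry, schedule)``.
    """
    from .activity import ActivitySeries

    required = {"tag_id": str, "bin": int, "t_start_s": float, "distance_mm": float}
    df, geometry, schedule = _read_csv_with_header(path, required)
    out = []
    for tag, sub in df.groupby("tag_id", sort=True):
        sub = sub.sort_values("bin")
        starts = sub["t_start_s"].to_numpy()
        width = float(starts[1] - starts[0]) if len(starts) > 1 else 360.0
        out.append(
            ActivitySeries(
                tag_id=str(tag),
                bin_width_s=width,
                values=sub["distance_mm"].to_numpy(),
            )
        )
    return out, geometry, schedule
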