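"""Light/dark schedule and clock arithmetic.

Recordings are indexed by seconds since recording start.  The schedule
anchors that axis to wall-clock time (``start_clock``) and to the light
cycle: lights on at 07:00 and off at 19:00 by default (a 12:12 LD
cycle).  Zeitgeber time (ZT) is hours since lights-on, so ZT0 is the
light onset and ZT12 the dark onset under the default cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LightSchedule", "parse_clock", "format_clock"]

DAY_S = 86_400.0


def parse_clock(value) -> float:
    """Parse ``"HH:MM"`` / ``"HH:MM:SS"`` (or a number of seconds) to
    seconds since midnight."""
    if isinstance(value, (int, float)):
        s = float(value)
    else:
        parts = str(value).strip().split(":")
        if len(parts) not in (2, 3) or not all(p.strip().isdigit() for p in parts):
            raise ValueError(f"cannot parse clock time {value!r} (expected HH:MM[:SS])")
        nums = [int(p) for p in parts] + [0] * (3 - len(parts))
        s = nums[0] * 3600.0 + nums[1] * 60.0 + nums[2]
    if not 0 <= s < DAY_S:
        raise ValueError(f"clock time {value!r} outside [00:00, 24:00)")
    return s


def format_clock(seconds: float) -> str:
    """Format seconds-since-midnight as ``HH:MM:SS`` (or ``HH:MM`` when whole)."""
    s = int(round(seconds)) % int(DAY_S)
    h, rem = divmod(s, 3600)
    m, sec = divmod(rem, 60)
    return f"{h:02d}:{m:02d}" if sec == 0 else f"{h:02d}:{m:02d}:{sec:02d}"


@dataclass(frozen=True)
class LightSchedule:
    """Light cycle and the clock anchor of the recording.

    Parameters
    ----------
    lights_on, lights_off
        Clock times of the abrupt light transitions ("HH:MM").
    start_clock
        Wall-clock time at recording start (t = 0), i.e. the moment the
        cage is transferred onto the recording rack.
    """

    lights_on: str | float = "07:00"
    lights_off: str | float = "19:00"
    start_clock: str | float = "12:00"

    def __post_init__(self) -> None:
        if self.lights_on_s == self.lights_off_s:
            raise ValueError("lights_on and lights_off must differ")

    @property
    def lights_on_s(self) -> float:
        return parse_clock(self.lights_on)

    @property
    def lights_off_s(self) -> float:
        return parse_clock(self.lights_off)

    @property
    def start_s(self) -> float:
        return parse_clock(self.start_clock)

    # -- clock mapping ---------------------------------------------------

    def clock_at(self, t_s):
        """Wall-clock seconds-since-midnight at recording time ``t_s``."""
        return (self.start_s + np.asarray(t_s, dtype=float)) % DAY_S

    def zt_hours(self, t_s):
        """Zeitgeber time (hours since lights-on, in [0, 24)) at ``t_s``."""
        return ((self.clock_at(t_s) - self.lights_on_s) % DAY_S) / 3600.0

    def is_dark(self, t_s):
        """Boolean (array): is the cage in the dark phase at ``t_s``?"""
        c = self.clock_at(t_s)
        on, off = self.lights_on_s, self.lights_off_s
        if on < off:
            return (c >= off) | (c < on)
        return (c >= off) & (c < on)

    # -- transition events ----------------------------------------------

    def _events(self, clock_s: float, t0: float, t1: float) -> np.ndarray:
        first = (clock_s - self.start_s) % DAY_S
        if first < t0:
            first += DAY_S * np.ceil((t0 - first) / DAY_S)
        return np.arange(first, t1, DAY_S)

    def lights_off_times(self, t0: float, t1: float) -> np.ndarray:
        """Recording times of lights-off events within ``[t0, t1)``."""
        return self._events(self.lights_off_s, t0, t1)

    def lights_on_times(self, t0: float, t1: float) -> np.ndarray:
        """Recording times of lights-on events within ``[t0, t1)``."""
        return self._events(self.lights_on_s, t0, t1)

    def clock_window_mask(self, t_s, win_start, win_end):
        """Mask of times whose wall clock falls in ``[win_start, win_end)``.

        The window is given in clock time (e.g. ``"18:00"``–``"19:00"``
        for the hour before the default lights-off) and may wrap past
        midnight.
        """
        ws, we = parse_clock(win_start), parse_clock(win_end)
        c = self.clock_at(t_s)
        if ws < we:
            return (c >= ws) & (c < we)
        return (c >= ws) | (c < we)

    def retained_window(
        self, span_s: float, n_lights_on: int | None = None
    ) -> tuple[float, float]:
        """Standard acclimation/disturbance exclusion window.

        Data before the first dark onset are treated as acclimation to
        the recording rack and discarded; optionally the analysis also
        stops at the ``n_lights_on``-th lights-on event (the morning the
        experiment is dismantled).  Returns the retained ``(t0, t1)`` in
        recording seconds.  For a 72 h recording started at 12:00 under
        the default cycle this retains exactly 60 h.
        """
        offs = self.lights_off_times(0.0, span_s)
        if offs.size == 0:
            raise ValueError("no dark onset within the recording span")
        t0 = float(offs[0])
        t1 = span_s
        if n_lights_on is not None:
            ons = self.lights_on_times(0.0, span_s)
            if ons.size < n_lights_on:
                raise ValueError(
                    f"recording contains only {ons.size} lights-on events, "
                    f"cannot stop at number {n_lights_on}"
                )
            t1 = float(ons[n_lights_on - 1])
        if t1 <= t0:
            raise ValueError("retained window is empty")
        return t0, t1
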