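"""Seconds-denominated key-frame timeline and segment frame counts.

The timeline is calibrated at a fixed 30 frames per second: a one-second
gap between two key frames expands into 30 interpolated frames.  The
export frame rate chosen later (25/29.97/30/60) only affects playback
timing of the written movie, never these counts.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

from .errors import NotFoundError, RangeError
from .frame_model import KeyFrame, retime
from .interpolation import round_half_up

#: Fixed timeline calibration: interpolated frames per second of timeline.
FPS_BASE = 30


@dataclass(frozen=True)
class Timeline:
    """Ordered key frames; entries sorted non-decreasing by time."""

    entries: tuple[KeyFrame, ...] = ()
    fps_base: int = FPS_BASE

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def times(self) -> list[float]:
        return [f.time_s for f in self.entries]

    def frame(self, frame_id: str) -> KeyFrame:
        for f in self.entries:
            if f.frame_id == frame_id:
                return f
        raise NotFoundError(f"no key frame with id {frame_id!r}")


def _sorted_insert(entries: Sequence[KeyFrame], frame: KeyFrame) -> tuple:
    times = [f.time_s for f in entries]
    i = bisect.bisect_right(times, frame.time_s)
    return tuple(entries[:i]) + (frame,) + tuple(entries[i:])


def add_keyframe(tl: Timeline, frame: KeyFrame) -> Timeline:
    """Insert a key frame, keeping the sort order.

    A frame captured without a time lands one second after the current last
    frame (at t=0 on an empty timeline).
    """
    if frame.time_s is None:
        t = tl.entries[-1].time_s + 1.0 if tl.entries else 0.0
        frame = retime(frame, t)
    elif frame.time_s < 0:
        raise RangeError(f"timeline positions must be >= 0, got {frame.time_s}")
    return Timeline(_sorted_insert(tl.entries, frame), tl.fps_base)


def remove_keyframes(tl: Timeline, ids: Sequence[str]) -> Timeline:
    """Drop the identified frames; unknown ids raise NotFoundError."""
    known = {f.frame_id for f in tl.entries}
    missing = [i for i in ids if i not in known]
    if missing:
        raise NotFoundError(f"no key frame(s) with id(s) {missing}")
    drop = set(ids)
    return Timeline(tuple(f for f in tl.entries if f.frame_id not in drop),
                    tl.fps_base)


def clear_all(tl: Timeline) -> Timeline:
    """Remove every frame from the timeline."""
    return Timeline((), tl.fps_base)


def move_keyframe(tl: Timeline, frame_id: str, new_time_s: float) -> Timeline:
    """Retime one frame and re-sort (the drag gesture)."""
    if new_time_s < 0:
        raise RangeError(f"timeline positions must be >= 0, got {new_time_s}")
    frame = tl.frame(frame_id)
    rest = tuple(f for f in tl.entries if f.frame_id != frame_id)
    return Timeline(_sorted_insert(rest, retime(frame, new_time_s)), tl.fps_base)


def shift_following(tl: Timeline, frame_id: str, dt_s: float) -> Timeline:
    """Shift the identified frame and every later frame by ``dt_s``.

    Pairwise gaps among the shifted frames are preserved exactly (the
    shift-drag gesture that moves all following frames the same amount).
    """
    pivot = tl.frame(frame_id).time_s
    new_times = [f.time_s + dt_s if f.time_s >= pivot else f.time_s
                 for f in tl.entries]
    if any(t < 0 for t in new_times):
        raise RangeError(
            f"shifting by {dt_s} s would move a frame before t=0")
    return Timeline(tuple(retime(f, t) for f, t in zip(tl.entries, new_times)),
                    tl.fps_base)


def segment_counts(tl: Timeline) -> list[int]:
    """Interpolation counts per segment at the 30 fps calibration.

    ``n_j = max(1, round(gap_j * 30))`` with round-half-up; coincident
    frames clamp to a single interpolation (an instantaneous cut).  Fewer
    than two entries mean no segments.
    """
    ts = tl.times()
    return [max(1, round_half_up((t1 - t0) * tl.fps_base))
            for t0, t1 in zip(ts, ts[1:])]
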