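"""End-to-end convenience: storyboard -> reconciled frames -> sequence."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

from .errors import ConsistencyError
from .interpolation import (BezierControl, DEFAULT_EASING, FrameSequence,
                            make_frames)
from .reconciliation import ObjectUniverse, reconcile_timeline
from .scene_io import load_storyboard, storyboard_timeline
from .timeline import Timeline, segment_counts


@dataclass
class CompiledAnimation:
    """A timeline compiled into its fully interpolated frame sequence."""

    timeline: Timeline
    universe: ObjectUniverse
    counts: list[int]
    sequence: FrameSequence


def compile_timeline(tl: Timeline,
                     ctrl: BezierControl = DEFAULT_EASING) -> CompiledAnimation:
    """Reconcile, derive segment counts at 30 fps, and expand the frames."""
    if len(tl) == 0:
        raise ConsistencyError("cannot compile an empty timeline")
    universe, frames = reconcile_timeline(tl.entries)
    counts = segment_counts(tl)
    seq = make_frames(frames, counts, ctrl)
    return CompiledAnimation(tl, universe, counts, seq)


def compile_storyboard(path: Union[str, Path],
                       ctrl: BezierControl = DEFAULT_EASING
                       ) -> CompiledAnimation:
    """Load a storyboard file and compile it."""
    sb = load_storyboard(path)
    return compile_timeline(storyboard_timeline(sb), ctrl)
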