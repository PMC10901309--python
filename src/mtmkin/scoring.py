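"""Occurrence metrics from MTM event annotations.

An annotated contact interval only counts in whole seconds: a run of 30
consecutive frames at 30 fps is one second, and an event shorter than one
second's worth of frames contributes nothing. Per-item seconds are summed
into a total, an occurrence percentage (total seconds over video duration,
times 100) and per-minute occurrence rates for three groupings:

* lower-limb items: FF, FL, PEDIPULATION
* upper-limb items: HH, HF, HM, HT, HL, MANIPULATION, FIDDLING
* total: all ten.

The per-minute rate is group seconds divided by video duration in seconds,
times 60 — a time fraction expressed per minute.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

from .errors import IntervalError
from .landmark_io import MTM_ITEMS, MtmEvent

LOWER_ITEMS = frozenset({"FF", "FL", "PEDIPULATION"})
UPPER_ITEMS = frozenset(MTM_ITEMS) - LOWER_ITEMS

_FLOAT_GUARD = 1e-9  # absorbs float fuzz in frames/fps before flooring


@dataclasses.dataclass(frozen=True)
class MtmScore:
    """Per-video MTM occurrence summary."""

    video_id: str
    per_item_seconds: Mapping[str, float]
    total_seconds: float
    occurrence_percentage: float
    rate_total: float
    rate_lower: float
    rate_upper: float

    @property
    def shows_total(self) -> bool:
        return self.rate_total > 0

    @property
    def shows_lower(self) -> bool:
        return self.rate_lower > 0

    @property
    def shows_upper(self) -> bool:
        return self.rate_upper > 0


def event_seconds(event: MtmEvent, fps: float = 30.0, fractional: bool = False) -> float:
    """Seconds contributed by one event under the whole-second rule.

    floor(frames / fps): a 29-frame event at 30 fps contributes 0 s, 45
    frames contribute 1 s, 60 frames 2 s. ``fractional=True`` switches to
    plain frames/fps for sensitivity analyses.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    raw = event.n_frames / fps
    if fractional:
        return raw
    return float(math.floor(raw + _FLOAT_GUARD))


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals (merges same-item overlaps/abutments)."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def score_video(
    events: Sequence[MtmEvent],
    duration_s: float = 120.0,
    fps: float = 30.0,
    video_id: str | None = None,
    fractional: bool = False,
) -> MtmScore:
    """Score one video's events into seconds, percentage and per-minute rates.

    Same-item overlapping or abutting events are merged before counting so a
    behaviour annotated twice is not double-counted; different items that
    overlap in time each count in full. Events must lie within the video.
    """
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration_s and fps must be positive")
    n_frames = int(round(duration_s * fps))
    vid = video_id
    by_item: dict[str, list[tuple[int, int]]] = {item: [] for item in MTM_ITEMS}
    for ev in events:
        if vid is None:
            vid = ev.video_id
        elif ev.video_id != vid:
            raise IntervalError(
                f"events from multiple videos ({vid!r} and {ev.video_id!r})"
            )
        if ev.end_frame > n_frames:
            raise IntervalError(
                f"{ev.video_id}/{ev.item}: event ends at frame {ev.end_frame}, "
                f"video has {n_frames}"
            )
        by_item[ev.item].append((ev.start_frame, ev.end_frame))

    per_item: dict[str, float] = {}
    for item, intervals in by_item.items():
        secs = 0.0
        for start, end in _merge_intervals(intervals):
            run = MtmEvent(vid or "", item, start, end)
            secs += event_seconds(run, fps=fps, fractional=fractional)
        per_item[item] = secs

    total = sum(per_item.values())
    lower = sum(per_item[i] for i in LOWER_ITEMS)
    upper = sum(per_item[i] for i in UPPER_ITEMS)
    return MtmScore(
        video_id=vid or "",
        per_item_seconds=per_item,
        total_seconds=total,
        occurrence_percentage=total / duration_s * 100.0,
        rate_total=total / duration_s * 60.0,
        rate_lower=lower / duration_s * 60.0,
        rate_upper=upper / duration_s * 60.0,
    )


def classify_videos(
    scores: Sequence[MtmScore],
) -> dict[str, dict[str, list[MtmScore]]]:
    """Partition videos into shows / no-shows for each MTM category.

    Returns {"Total": {"shows": [...], "noshow": [...]}, "Lower": ...,
    "Upper": ...}.
    """
    if not scores:
        raise ValueError("classify_videos requires at least one score")
    out: dict[str, dict[str, list[MtmScore]]] = {}
    for category, flag in (
        ("Total", lambda s: s.shows_total),
        ("Lower", lambda s: s.shows_lower),
        ("Upper", lambda s: s.shows_upper),
    ):
        out[category] = {
            "shows": [s for s in scores if flag(s)],
            "noshow": [s for s in scores if not flag(s)],
        }
    return out
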