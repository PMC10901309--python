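"""Reading, validating and writing 33-landmark pose series and MTM annotations.

The on-disk landmark format is a long CSV with header
``frame,landmark,x,y,visibility`` (visibility optional): one row per landmark
per frame, frames 0-based and contiguous, landmarks indexed 0-32 following the
standard 33-landmark full-body pose schema (11/12 shoulders, 23/24 hips, 15/16
wrists, 27/28 ankles). Coordinates are normalized image coordinates — origin
top-left, x rightward, y downward, nominally in [0, 1] but values slightly
outside are accepted, as 2D pose models emit them for limbs near the frame
edge.

Annotation files are CSVs with header ``video_id,item,start_frame,end_frame``;
intervals are half-open ``[start_frame, end_frame)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CatalogueError,
    FrameGapError,
    IntervalError,
    MalformedFrameError,
    NoDataError,
    SchemaError,
)

N_LANDMARKS = 33

#: The 10-item movement-toward-midline catalogue: foot-foot, foot-leg,
#: hand-hand, hand-face, hand-mouth, hand-trunk, hand-leg, plus the three
#: manipulative variants.
MTM_ITEMS = (
    "FF",
    "FL",
    "HH",
    "HF",
    "HM",
    "HT",
    "HL",
    "PEDIPULATION",
    "MANIPULATION",
    "FIDDLING",
)

DEFAULT_FPS = 30.0
DEFAULT_VISIBILITY_THRESHOLD = 0.5

#: Landmarks needed for midline/distance features (shoulders, hips, wrists,
#: ankles).
DISTANCE_LANDMARKS = (11, 12, 15, 16, 23, 24, 27, 28)


@dataclasses.dataclass(frozen=True)
class LandmarkFrame:
    """One video frame: 33 (x, y) points plus optional per-landmark visibility.

    ``valid`` is True when every landmark is finite and (when visibility is
    present) at or above the threshold used at read time.
    """

    frame_index: int
    points: np.ndarray  # (33, 2) float
    visibility: Optional[np.ndarray] = None  # (33,) float in [0, 1]
    valid: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise MalformedFrameError(
                f"frame {self.frame_index}: expected {N_LANDMARKS} (x, y) points, "
                f"got array of shape {pts.shape}"
            )
        object.__setattr__(self, "points", pts)
        if self.visibility is not None:
            vis = np.asarray(self.visibility, dtype=float)
            if vis.shape != (N_LANDMARKS,):
                raise MalformedFrameError(
                    f"frame {self.frame_index}: visibility must have "
                    f"{N_LANDMARKS} entries"
                )
            object.__setattr__(self, "visibility", vis)


@dataclasses.dataclass
class LandmarkSeries:
    """A per-video landmark trajectory backed by dense arrays.

    ``coords`` has shape (n_frames, 33, 2); ``visibility`` (n_frames, 33) or
    None; ``landmark_ok`` (n_frames, 33) marks landmarks that are finite and
    above the visibility threshold.
    """

    video_id: str
    fps: float
    coords: np.ndarray
    visibility: Optional[np.ndarray] = None
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_LANDMARKS, 2):
            raise MalformedFrameError(
                f"coords must have shape (n, {N_LANDMARKS}, 2), "
                f"got {self.coords.shape}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.visibility is not None:
            self.visibility = np.asarray(self.visibility, dtype=float)
            if self.visibility.shape != self.coords.shape[:2]:
                raise MalformedFrameError("visibility shape mismatch with coords")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def landmark_ok(self) -> np.ndarray:
        """(n_frames, 33) bool: finite coordinates and acceptable visibility."""
        ok = np.isfinite(self.coords).all(axis=2)
        if self.visibility is not None:
            ok &= self.visibility >= self.visibility_threshold
        return ok

    @property
    def frame_valid(self) -> np.ndarray:
        """(n_frames,) bool: every landmark usable."""
        return self.landmark_ok.all(axis=1)

    def frame(self, i: int) -> LandmarkFrame:
        vis = None if self.visibility is None else self.visibility[i]
        return LandmarkFrame(
            frame_index=i,
            points=self.coords[i],
            visibility=vis,
            valid=bool(self.frame_valid[i]),
        )

    def frames(self) -> list[LandmarkFrame]:
        return [self.frame(i) for i in range(self.n_frames)]


@dataclasses.dataclass(frozen=True)
class MtmEvent:
    """One annotated midline-contact interval, frames half-open [start, end)."""

    video_id: str
    item: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.item not in MTM_ITEMS:
            raise CatalogueError(
                f"unknown MTM item {self.item!r}; expected one of {MTM_ITEMS}"
            )
        if self.start_frame < 0 or self.end_frame <= self.start_frame:
            raise IntervalError(
                f"bad interval [{self.start_frame}, {self.end_frame}) "
                f"for {self.video_id}/{self.item}"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def read_landmark_csv(
    path: str | Path,
    fps: float = DEFAULT_FPS,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
    video_id: Optional[str] = None,
) -> LandmarkSeries:
    """Read a long-format landmark CSV into a :class:`LandmarkSeries`.

    Required columns: ``frame, landmark, x, y``; ``visibility`` is optional.
    Every frame must carry exactly 33 landmark rows and frame indices must be
    contiguous from 0.
    """
    path = Path(path)
    # round_trip parsing keeps read(write(s)) exact to the last bit
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "landmark", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise NoDataError(f"{path}: no landmark rows")

    df = df.sort_values(["frame", "landmark"], kind="mergesort").reset_index(drop=True)
    frames = df["frame"].to_numpy()
    unique_frames, counts = np.unique(frames, return_counts=True)
    bad = unique_frames[counts != N_LANDMARKS]
    if bad.size:
        raise MalformedFrameError(
            f"{path}: frame {int(bad[0])} has {int(counts[counts != N_LANDMARKS][0])} "
            f"landmark rows, expected {N_LANDMARKS}"
        )
    n = unique_frames.size
    if unique_frames[0] != 0 or unique_frames[-1] != n - 1:
        raise FrameGapError(
            f"{path}: frame indices must be contiguous from 0 "
            f"(found range {int(unique_frames[0])}..{int(unique_frames[-1])} "
            f"over {n} frames)"
        )
    lms = df["landmark"].to_numpy().reshape(n, N_LANDMARKS)
    if not (lms == np.arange(N_LANDMARKS)).all():
        raise MalformedFrameError(f"{path}: landmark indices must cover 0..32 per frame")

    coords = np.column_stack([df["x"].to_numpy(), df["y"].to_numpy()])
    coords = coords.reshape(n, N_LANDMARKS, 2)
    visibility = None
    if "visibility" in df.columns:
        visibility = df["visibility"].to_numpy().reshape(n, N_LANDMARKS)
    return LandmarkSeries(
        video_id=video_id if video_id is not None else path.stem,
        fps=fps,
        coords=coords,
        visibility=visibility,
        visibility_threshold=visibility_threshold,
    )


def write_landmark_csv(series: LandmarkSeries, path: str | Path) -> Path:
    """Write a series as a long CSV; exact round-trip with read_landmark_csv.

    Floats are written at full shortest round-trip precision, so
    ``read_landmark_csv(write_landmark_csv(s))`` reproduces the coordinate
    arrays bit for bit.
    """
    if series.n_frames == 0:
        raise NoDataError("cannot write a series with no frames")
    path = Path(path)
    n = series.n_frames
    frame_col = np.repeat(np.arange(n), N_LANDMARKS)
    lm_col = np.tile(np.arange(N_LANDMARKS), n)
    data = {
        "frame": frame_col,
        "landmark": lm_col,
        "x": series.coords[:, :, 0].ravel(),
        "y": series.coords[:, :, 1].ravel(),
    }
    if series.visibility is not None:
        data["visibility"] = series.visibility.ravel()
    # %.17g preserves every float64 exactly across the round trip
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return path


def read_annotations(path: str | Path, n_frames: Optional[int] = None) -> list[MtmEvent]:
    """Read an MTM annotation CSV and validate every event.

    Columns: ``video_id,item,start_frame,end_frame``. If ``n_frames`` is
    given, events must lie within ``[0, n_frames]``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"video_id", "item", "start_frame", "end_frame"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        item = str(row.item).strip().upper()
        ev = MtmEvent(
            video_id=str(row.video_id),
            item=item,
            start_frame=int(row.start_frame),
            end_frame=int(row.end_frame),
        )
        if n_frames is not None and ev.end_frame > n_frames:
            raise IntervalError(
                f"{path}: event {ev.video_id}/{ev.item} ends at frame "
                f"{ev.end_frame} beyond the video ({n_frames} frames)"
            )
        events.append(ev)
    return events


def write_annotations(events: Sequence[MtmEvent], path: str | Path) -> Path:
    """Write MTM events to the annotation CSV format."""
    path = Path(path)
    pd.DataFrame(
        {
            "video_id": [e.video_id for e in events],
            "item": [e.item for e in events],
            "start_frame": [e.start_frame for e in events],
            "end_frame": [e.end_frame for e in events],
        }
    ).to_csv(path, index=False)
    return path
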