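"""Midline and area features from supine-infant pose landmarks.

The midbody imaginary line runs through the midpoint of the shoulders
(landmarks 11, 12) and the midpoint of the hips (landmarks 23, 24). Because a
top-down supine recording puts the body axis close to vertical in the image,
the line is parameterized as ``x = a*y + b`` — the slope/intercept roles are
swapped relative to the textbook ``y = m*x + c`` form (a = 1/m, b = -c/m for
m != 0), which keeps near-vertical midlines numerically benign and makes an
exactly vertical midline an ordinary case rather than an infinity. A
horizontal body axis (shoulder and hip midpoints at equal image y) is the
degenerate case and raises.

The limb-to-midline distance is the *horizontal offset*: evaluate the line at
the landmark's own y and subtract the landmark's x. It is signed — positive
when the landmark sits left (smaller x) of the midline — because left and
right limbs sit on opposite sides and averaging must not fold them together.
A perpendicular-distance variant (the x-offset divided by sqrt(1 + a^2)) is
available via config; it is the rotation-invariant cousin used by the
invariance test-suite.

Area features: the shoelace area of the wrist-wrist-ankle-ankle quadrilateral
(vertex order 15 -> 16 -> 28 -> 27), and the two triangles joining the wrist
pair / ankle pair to the body centre (mean of all 33 landmarks).

Every distance is divided by the frame's body length — the mean of the two
shoulder-to-hip Euclidean distances (11-23 and 12-24) — and areas by body
length to a configurable power (1 by default, 2 for a fully dimensionless
area).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InvalidCoordinateError,
    InvalidFrameError,
    NoDataError,
)
from .landmark_io import (
    DEFAULT_VISIBILITY_THRESHOLD,
    DISTANCE_LANDMARKS,
    N_LANDMARKS,
    LandmarkFrame,
    LandmarkSeries,
)

# Left/right homologous landmark pairs of the 33-landmark schema (nose, index
# 0, is unpaired). Used when mirroring a pose about the midline.
LEFT_RIGHT_PAIRS = (
    (1, 4), (2, 5), (3, 6), (7, 8), (9, 10), (11, 12), (13, 14), (15, 16),
    (17, 18), (19, 20), (21, 22), (23, 24), (25, 26), (27, 28), (29, 30),
    (31, 32),
)

_LIMB_LANDMARKS = (15, 16, 27, 28)
_DEGENERACY_EPS_FACTOR = 1e-6  # |dy| threshold as a fraction of body length


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    """Tunable choices for feature extraction.

    area_norm_exponent: power of body length dividing areas (1 = literal
        length normalization, 2 = dimensionless).
    distance_mode: "x_offset" (horizontal offset at the landmark's y, the
        reference measure) or "perpendicular".
    max_invalid_fraction: a video whose invalid-frame fraction exceeds this
        is flagged unusable and excluded from cohort statistics.
    """

    area_norm_exponent: int = 1
    distance_mode: str = "x_offset"
    max_invalid_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.distance_mode not in ("x_offset", "perpendicular"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")
        if self.area_norm_exponent not in (1, 2):
            raise ValueError("area_norm_exponent must be 1 or 2")


@dataclasses.dataclass(frozen=True)
class Midpoints:
    shoulder_mid: tuple[float, float]
    hip_mid: tuple[float, float]


@dataclasses.dataclass(frozen=True)
class MidbodyLine:
    """The midbody line in x = a*y + b form."""

    a: float
    b: float

    def x_at(self, y: float) -> float:
        return self.a * y + self.b

    def slope_intercept(self) -> tuple[float, float]:
        """Return (m, c) of the y = m*x + c form; raises for vertical lines."""
        if self.a == 0.0:
            raise DegenerateGeometryError(
                "vertical midline has no finite y = m*x + c form"
            )
        return 1.0 / self.a, -self.b / self.a


@dataclasses.dataclass(frozen=True)
class FrameFeatures:
    """Per-frame normalized features; NaN where not computable."""

    dlm15: float
    dlm16: float
    dlm27: float
    dlm28: float
    body_length: float
    center: tuple[float, float]
    area_whole: float
    area_upper: float
    area_lower: float
    valid: bool


@dataclasses.dataclass(frozen=True)
class VideoFeatureSummary:
    """Per-video means of the frame features, over valid frames only."""

    video_id: str
    mean_dlm15: float
    mean_dlm16: float
    mean_dlm27: float
    mean_dlm28: float
    mean_area_whole: float
    mean_area_upper: float
    mean_area_lower: float
    n_valid_frames: int
    n_frames: int
    usable: bool = True


def midpoint(p: Sequence[float], q: Sequence[float]) -> tuple[float, float]:
    """Componentwise mean of two points."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise InvalidCoordinateError("midpoint requires finite coordinates")
    m = (p + q) / 2.0
    return float(m[0]), float(m[1])


def body_midpoints(frame: LandmarkFrame) -> Midpoints:
    pts = frame.points
    return Midpoints(
        shoulder_mid=midpoint(pts[11], pts[12]),
        hip_mid=midpoint(pts[23], pts[24]),
    )


def body_length(frame: LandmarkFrame) -> float:
    """Mean of the left (11-23) and right (12-24) shoulder-to-hip distances."""
    pts = frame.points
    needed = pts[[11, 12, 23, 24]]
    if not np.isfinite(needed).all():
        raise InvalidFrameError("body_length requires landmarks 11, 12, 23, 24")
    left = float(np.hypot(*(pts[11] - pts[23])))
    right = float(np.hypot(*(pts[12] - pts[24])))
    length = (left + right) / 2.0
    if length <= 0.0:
        raise DegenerateGeometryError("zero body length (coincident trunk landmarks)")
    return length


def midbody_line(frame: LandmarkFrame) -> MidbodyLine:
    """Line through the shoulder and hip midpoints, as x = a*y + b."""
    mids = body_midpoints(frame)
    (xs, ys), (xh, yh) = mids.shoulder_mid, mids.hip_mid
    L = body_length(frame)
    dy = ys - yh
    dx = xs - xh
    if math.hypot(dx, dy) == 0.0:
        raise DegenerateGeometryError("shoulder and hip midpoints coincide")
    if abs(dy) <= _DEGENERACY_EPS_FACTOR * L:
        raise DegenerateGeometryError(
            "body axis is horizontal in the image; midline undefined in x = a*y + b form"
        )
    a = dx / dy
    b = xs - a * ys
    return MidbodyLine(a=a, b=b)


def signed_distance(
    landmark: Sequence[float], line: MidbodyLine, mode: str = "x_offset"
) -> float:
    """Signed distance from a landmark to the midline.

    ``x_offset``: x_line(y_lm) - x_lm, the horizontal offset at the
    landmark's own image row. ``perpendicular``: the same offset scaled by
    1/sqrt(1 + a^2), i.e. the signed Euclidean point-line distance.
    """
    x, y = float(landmark[0]), float(landmark[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise InvalidCoordinateError("signed_distance requires finite coordinates")
    d = line.x_at(y) - x
    if mode == "perpendicular":
        d /= math.sqrt(1.0 + line.a * line.a)
    elif mode != "x_offset":
        raise ValueError(f"unknown distance mode {mode!r}")
    return d


def body_center(frame: LandmarkFrame) -> tuple[float, float]:
    """Arithmetic mean of all 33 landmark coordinates."""
    pts = frame.points
    if not np.isfinite(pts).all():
        raise InvalidFrameError("body_center requires all 33 landmarks")
    c = pts.mean(axis=0)
    return float(c[0]), float(c[1])


def tri_area(p: Sequence[float], q: Sequence[float], r: Sequence[float]) -> float:
    """Unsigned triangle area: |cross(q - p, r - p)| / 2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    u, v = q - p, r - p
    return abs(float(u[0] * v[1] - u[1] * v[0])) / 2.0


def quad_area(
    p15: Sequence[float],
    p16: Sequence[float],
    p28: Sequence[float],
    p27: Sequence[float],
) -> float:
    """Absolute shoelace area of the quadrilateral 15 -> 16 -> 28 -> 27.

    The traversal order left wrist, right wrist, right ankle, left ankle
    walks around the body and cannot self-intersect for an anatomically
    ordered pose; degenerate (collinear) configurations return 0.
    """
    pts = np.asarray([p15, p16, p28, p27], dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    s = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    return abs(float(s)) / 2.0


def reflect_frame_across_midline(frame: LandmarkFrame) -> LandmarkFrame:
    """Mirror the pose about its own midbody line, swapping left/right labels.

    Each point is reflected Euclidean-wise across the midline (an isometry,
    so body length and areas are preserved) and the homologous left/right
    landmark indices are exchanged, giving the anatomical mirror image of
    the input pose.
    """
    line = midbody_line(frame)
    pts = frame.points.copy()
    direction = np.array([line.a, 1.0]) / math.sqrt(1.0 + line.a * line.a)
    anchor = np.array([line.b, 0.0])  # the y = 0 point of x = a*y + b
    rel = pts - anchor
    proj = np.outer(rel @ direction, direction)
    pts = anchor + 2.0 * proj - rel
    order = np.arange(N_LANDMARKS)
    for left, right in LEFT_RIGHT_PAIRS:
        order[left], order[right] = right, left
    vis = None if frame.visibility is None else frame.visibility[order]
    return LandmarkFrame(
        frame_index=frame.frame_index,
        points=pts[order],
        visibility=vis,
        valid=frame.valid,
    )


def _series_features(
    coords: np.ndarray,
    landmark_ok: np.ndarray,
    config: FeatureConfig,
) -> dict[str, np.ndarray]:
    """Vectorized per-frame features over a whole (n, 33, 2) array.

    Returns arrays keyed dlm15/16/27/28, body_length, center, area_whole,
    area_upper, area_lower, dist_ok, area_ok (boolean validity per feature
    group). NaN marks frames where a feature is unavailable.
    """
    sh_mid = (coords[:, 11] + coords[:, 12]) / 2.0
    hip_mid = (coords[:, 23] + coords[:, 24]) / 2.0
    left_len = np.hypot(*(coords[:, 11] - coords[:, 23]).T)
    right_len = np.hypot(*(coords[:, 12] - coords[:, 24]).T)
    L = (left_len + right_len) / 2.0

    dy = sh_mid[:, 1] - hip_mid[:, 1]
    dx = sh_mid[:, 0] - hip_mid[:, 0]
    nondegenerate = (L > 0) & (np.abs(dy) > _DEGENERACY_EPS_FACTOR * L)
    safe_dy = np.where(nondegenerate, dy, 1.0)
    a = np.where(nondegenerate, dx / safe_dy, np.nan)
    b = sh_mid[:, 0] - a * sh_mid[:, 1]

    dist_ok = landmark_ok[:, list(DISTANCE_LANDMARKS)].all(axis=1) & nondegenerate
    area_ok = landmark_ok.all(axis=1) & (L > 0)

    out: dict[str, np.ndarray] = {}
    scale = np.sqrt(1.0 + a * a) if config.distance_mode == "perpendicular" else 1.0
    safe_L = np.where(L > 0, L, np.nan)
    for lm in _LIMB_LANDMARKS:
        d = (a * coords[:, lm, 1] + b) - coords[:, lm, 0]
        if config.distance_mode == "perpendicular":
            d = d / scale
        d = d / safe_L
        out[f"dlm{lm}"] = np.where(dist_ok, d, np.nan)

    center = coords.mean(axis=1)
    p15, p16 = coords[:, 15], coords[:, 16]
    p27, p28 = coords[:, 27], coords[:, 28]
    # shoelace over the fixed cycle 15 -> 16 -> 28 -> 27
    xs = np.stack([p15[:, 0], p16[:, 0], p28[:, 0], p27[:, 0]], axis=1)
    ys = np.stack([p15[:, 1], p16[:, 1], p28[:, 1], p27[:, 1]], axis=1)
    whole = np.abs(
        (xs * np.roll(ys, -1, axis=1)).sum(axis=1)
        - (ys * np.roll(xs, -1, axis=1)).sum(axis=1)
    ) / 2.0

    def tri(p, q):
        u = q - p
        v = center - p
        return np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]) / 2.0

    upper = tri(p15, p16)
    lower = tri(p27, p28)
    norm = safe_L ** config.area_norm_exponent
    out["area_whole"] = np.where(area_ok, whole / norm, np.nan)
    out["area_upper"] = np.where(area_ok, upper / norm, np.nan)
    out["area_lower"] = np.where(area_ok, lower / norm, np.nan)
    out["body_length"] = np.where(L > 0, L, np.nan)
    out["center"] = center
    out["dist_ok"] = dist_ok
    out["area_ok"] = area_ok
    return out


def frame_features(
    frame: LandmarkFrame,
    config: Optional[FeatureConfig] = None,
    landmark_ok: Optional[np.ndarray] = None,
) -> FrameFeatures:
    """Normalized features for a single frame.

    Degenerate or incomplete frames yield valid=False with NaN features
    rather than raising, so that per-video aggregation can simply skip them.
    ``landmark_ok`` optionally masks landmarks deemed unusable (low
    visibility); defaults to finiteness of the coordinates.
    """
    config = config or FeatureConfig()
    coords = frame.points[np.newaxis]
    if landmark_ok is None:
        ok = np.isfinite(frame.points).all(axis=1)
        if frame.visibility is not None:
            ok = ok & (frame.visibility >= DEFAULT_VISIBILITY_THRESHOLD)
    else:
        ok = np.asarray(landmark_ok, dtype=bool)
    feats = _series_features(coords, ok[np.newaxis], config)
    valid = bool(feats["dist_ok"][0] and feats["area_ok"][0])
    return FrameFeatures(
        dlm15=float(feats["dlm15"][0]),
        dlm16=float(feats["dlm16"][0]),
        dlm27=float(feats["dlm27"][0]),
        dlm28=float(feats["dlm28"][0]),
        body_length=float(feats["body_length"][0]),
        center=(float(feats["center"][0, 0]), float(feats["center"][0, 1])),
        area_whole=float(feats["area_whole"][0]),
        area_upper=float(feats["area_upper"][0]),
        area_lower=float(feats["area_lower"][0]),
        valid=valid,
    )


def summarize_video(
    series: LandmarkSeries, config: Optional[FeatureConfig] = None
) -> VideoFeatureSummary:
    """Average per-frame features over the video's valid frames.

    Distance features are averaged over frames valid for the midline
    computation; area features over frames with all 33 landmarks. A video is
    flagged unusable when the fraction of frames invalid for *any* feature
    exceeds ``config.max_invalid_fraction``.
    """
    config = config or FeatureConfig()
    if series.n_frames == 0:
        raise NoDataError(f"{series.video_id}: empty series")
    feats = _series_features(series.coords, series.landmark_ok, config)
    fully_valid = feats["dist_ok"] & feats["area_ok"]
    n_valid = int(fully_valid.sum())
    if n_valid == 0:
        raise NoDataError(f"{series.video_id}: no valid frames")
    invalid_fraction = 1.0 - n_valid / series.n_frames
    with np.errstate(invalid="ignore"):
        means = {k: float(np.nanmean(feats[k])) for k in
                 ("dlm15", "dlm16", "dlm27", "dlm28",
                  "area_whole", "area_upper", "area_lower")}
    return VideoFeatureSummary(
        video_id=series.video_id,
        mean_dlm15=means["dlm15"],
        mean_dlm16=means["dlm16"],
        mean_dlm27=means["dlm27"],
        mean_dlm28=means["dlm28"],
        mean_area_whole=means["area_whole"],
        mean_area_upper=means["area_upper"],
        mean_area_lower=means["area_lower"],
        n_valid_frames=n_valid,
        n_frames=series.n_frames,
        usable=invalid_fraction <= config.max_invalid_fraction,
    )
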