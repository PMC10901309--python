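"""Seeded synthetic supine-infant landmark trajectories with known MTM events.

The generator emulates what a top-down 2D pose estimate of a supine infant
looks like: a bilaterally symmetric 33-landmark rest pose with the body axis
near-vertical in the image, smooth baseline limb wander (a mean-reverting
AR(1) process per moving landmark), hand-held-camera jitter applied as a
per-frame rigid rotation/translation of the whole pose, and i.i.d. Gaussian
measurement noise added last. Midline-contact events are injected with known
timing: during an event the item's contact landmarks ease toward a target
point (on the body midline, the face, the trunk, or the opposite leg,
depending on the item), hold within a contact radius, and ease back.

Everything is deterministic given the config seed. The event truth labels
are emitted alongside the series so scoring and statistics can be validated
against a known ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .errors import ScheduleError
from .landmark_io import MTM_ITEMS, N_LANDMARKS, LandmarkSeries, MtmEvent

# Rest pose in body coordinates: x lateral (left limbs at negative x),
# y running head -> feet, one unit = the shoulder-to-hip span.
_TEMPLATE = np.array(
    [
        (0.00, -0.45),   # 0 nose
        (-0.04, -0.52), (-0.07, -0.53), (-0.10, -0.52),   # 1-3 left eye
        (0.04, -0.52), (0.07, -0.53), (0.10, -0.52),      # 4-6 right eye
        (-0.14, -0.48), (0.14, -0.48),                    # 7-8 ears
        (-0.05, -0.38), (0.05, -0.38),                    # 9-10 mouth
        (-0.28, 0.00), (0.28, 0.00),                      # 11-12 shoulders
        (-0.44, 0.26), (0.44, 0.26),                      # 13-14 elbows
        (-0.52, 0.62), (0.52, 0.62),                      # 15-16 wrists
        (-0.56, 0.68), (0.56, 0.68),                      # 17-18 pinkies
        (-0.58, 0.66), (0.58, 0.66),                      # 19-20 index fingers
        (-0.53, 0.65), (0.53, 0.65),                      # 21-22 thumbs
        (-0.14, 1.00), (0.14, 1.00),                      # 23-24 hips
        (-0.26, 1.34), (0.26, 1.34),                      # 25-26 knees
        (-0.32, 1.68), (0.32, 1.68),                      # 27-28 ankles
        (-0.34, 1.75), (0.34, 1.75),                      # 29-30 heels
        (-0.30, 1.83), (0.30, 1.83),                      # 31-32 foot tips
    ],
    dtype=float,
)

# Landmarks that wander independently; hands and feet ride on their wrist /
# ankle with a little extra wander of their own.
_MOVERS = (13, 14, 15, 16, 25, 26, 27, 28)
_CHILDREN = {17: 15, 19: 15, 21: 15, 18: 16, 20: 16, 22: 16,
             29: 27, 31: 27, 30: 28, 32: 28}

# Per-item contact kinematics: which landmarks move and where they go
# (body coordinates). One-sided items pick a side at random per event.
_SIDED = {"FL", "HF", "HM", "HT", "HL", "FIDDLING"}


def _item_targets(item: str, side_left: bool) -> list[tuple[int, tuple[float, float]]]:
    wrist = 15 if side_left else 16
    ankle = 27 if side_left else 28
    sgn = -1.0 if side_left else 1.0
    if item == "FF":
        return [(27, (-0.05, 1.45)), (28, (0.05, 1.45))]
    if item == "PEDIPULATION":
        return [(27, (-0.05, 1.40)), (28, (0.05, 1.40))]
    if item == "FL":  # one foot to the opposite lower leg
        return [(ankle, (-sgn * 0.22, 1.40))]
    if item == "HH":
        return [(15, (-0.05, 0.30)), (16, (0.05, 0.30))]
    if item == "MANIPULATION":
        return [(15, (-0.06, 0.35)), (16, (0.06, 0.35))]
    if item == "HF":
        return [(wrist, (0.0, -0.40))]
    if item == "HM":
        return [(wrist, (0.0, -0.38))]
    if item == "HT":
        return [(wrist, (0.0, 0.45))]
    if item == "HL":  # hand to same-side knee
        return [(wrist, (sgn * 0.24, 1.30))]
    if item == "FIDDLING":
        return [(wrist, (0.0, 0.60))]
    raise ScheduleError(f"no kinematics for item {item!r}")


@dataclasses.dataclass
class SyntheticConfig:
    """Generator settings; the defaults mirror the target recording protocol
    (120 s supine videos at 30 fps, hand-held phone about 1 m overhead)."""

    duration_s: float = 120.0
    fps: float = 30.0
    seed: int = 0
    video_id: str = "synthetic"
    # pose placement
    scale: float = 0.25  # shoulder-hip span in normalized image units
    orientation: float = 0.0  # body-axis angle from image vertical, radians
    center: tuple[float, float] = (0.5, 0.5)
    # baseline limb motility: stationary SD and correlation time of the
    # mean-reverting wander, in normalized image units / seconds
    baseline_amplitude: float = 0.03
    baseline_timescale_s: float = 1.5
    # measurement noise per landmark per frame (normalized units)
    noise_sigma: float = 0.003
    # hand-held camera jitter: smooth rigid rotation/translation
    camera_rot_sd: float = 0.02  # radians
    camera_trans_sd: float = 0.005
    camera_timescale_s: float = 2.0
    # events: explicit schedule [(item, start_s, duration_s)] wins over rates
    event_schedule: Optional[Sequence[tuple[str, float, float]]] = None
    event_rates: Optional[dict[str, float]] = None  # events per minute
    event_duration_mean_s: float = 2.0
    min_event_s: float = 1.0
    easing_s: float = 0.3
    contact_radius_factor: float = 0.25  # of body length
    contact_noise: float = 0.004
    # when False, events are annotated but the limbs do not react (the
    # decoupled null for calibration studies)
    couple_events: bool = True
    # probability a landmark drops out (visibility 0) per frame
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        for name in ("baseline_amplitude", "noise_sigma", "camera_rot_sd",
                     "camera_trans_sd", "dropout_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclasses.dataclass
class SyntheticBundle:
    series: LandmarkSeries
    truth_events: list[MtmEvent]
    config: SyntheticConfig


def template_pose(
    scale: float = 0.25,
    orientation: float = 0.0,
    center: tuple[float, float] = (0.5, 0.5),
) -> np.ndarray:
    """The rest pose mapped into image coordinates; shape (33, 2).

    The pose centroid lands on ``center``; ``orientation`` rotates the body
    axis away from image-vertical.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    body = _TEMPLATE - _TEMPLATE.mean(axis=0)
    c, s = math.cos(orientation), math.sin(orientation)
    rot = np.array([[c, -s], [s, c]])
    return np.asarray(center, dtype=float) + scale * body @ rot.T


def _body_to_image(points: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Map body-coordinate points through the same placement as the template."""
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - _TEMPLATE.mean(axis=0)
    c, s = math.cos(config.orientation), math.sin(config.orientation)
    rot = np.array([[c, -s], [s, c]])
    return np.asarray(config.center) + config.scale * pts @ rot.T


def _ar1(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, ...],
    sd: float,
    timescale_s: float,
    fps: float,
) -> np.ndarray:
    """Stationary mean-reverting Gaussian noise, smooth over ~timescale_s."""
    if sd == 0.0:
        return np.zeros((n, *shape))
    rho = math.exp(-1.0 / (timescale_s * fps))
    w = rng.standard_normal((n, *shape)) * (sd * math.sqrt(1.0 - rho * rho))
    x0 = rng.standard_normal(shape) * sd
    zi = (rho * x0)[np.newaxis]
    out, _ = lfilter([1.0], [1.0, -rho], w, axis=0, zi=zi)
    return out


def _envelope(n_event: int, ease_frames: int) -> np.ndarray:
    """Cosine ease-in / hold / ease-out profile over an event's frames."""
    ease = min(ease_frames, n_event // 2)
    s = np.ones(n_event)
    if ease > 0:
        ramp = 0.5 - 0.5 * np.cos(np.pi * (np.arange(1, ease + 1) / ease))
        s[:ease] = ramp
        s[n_event - ease:] = ramp[::-1]
    return s


def _draw_schedule(
    rng: np.random.Generator, config: SyntheticConfig
) -> list[tuple[str, int, int]]:
    """Event schedule in frames, same-item overlaps resolved by dropping."""
    n = config.n_frames
    fps = config.fps
    out: list[tuple[str, int, int]] = []
    if config.event_schedule is not None:
        by_item: dict[str, list[tuple[int, int]]] = {}
        for item, start_s, dur_s in config.event_schedule:
            if item not in MTM_ITEMS:
                raise ScheduleError(f"unknown item {item!r}")
            start = int(round(start_s * fps))
            end = start + int(round(dur_s * fps))
            if start < 0 or end > n:
                raise ScheduleError(
                    f"{item} at {start_s}s+{dur_s}s lies outside the video"
                )
            for s0, e0 in by_item.get(item, []):
                if start < e0 and s0 < end:
                    raise ScheduleError(f"overlapping {item} events")
            by_item.setdefault(item, []).append((start, end))
            out.append((item, start, end))
        return sorted(out, key=lambda e: (e[1], e[0]))

    min_frames = int(round(config.min_event_s * fps))
    for item in MTM_ITEMS:
        rate = (config.event_rates or {}).get(item, 0.0)
        if rate <= 0:
            continue
        k = rng.poisson(rate * config.duration_s / 60.0)
        intervals: list[tuple[int, int]] = []
        for _ in range(k):
            dur_s = config.min_event_s + rng.exponential(
                max(config.event_duration_mean_s - config.min_event_s, 1e-6)
            )
            dur = max(int(round(dur_s * fps)), min_frames)
            if dur >= n:
                continue
            start = int(rng.integers(0, n - dur + 1))
            end = start + dur
            if any(start < e0 and s0 < end for s0, e0 in intervals):
                continue  # same-item overlap: drop the later draw
            intervals.append((start, end))
            out.append((item, start, end))
    return sorted(out, key=lambda e: (e[1], e[0]))


def simulate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate one video's landmark series plus its ground-truth events."""
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    base = template_pose(config.scale, config.orientation, config.center)
    pos = np.broadcast_to(base, (n, N_LANDMARKS, 2)).copy()

    # baseline motility for limbs; hands/feet follow their wrist/ankle
    wander = _ar1(
        rng, n, (len(_MOVERS), 2),
        config.baseline_amplitude, config.baseline_timescale_s, config.fps,
    )
    mover_index = {lm: i for i, lm in enumerate(_MOVERS)}
    for lm, i in mover_index.items():
        pos[:, lm] += wander[:, i]
    child_wander = _ar1(
        rng, n, (len(_CHILDREN), 2),
        0.5 * config.baseline_amplitude, config.baseline_timescale_s, config.fps,
    )
    for j, (child, parent) in enumerate(_CHILDREN.items()):
        pos[:, child] += wander[:, mover_index[parent]] + child_wander[:, j]

    schedule = _draw_schedule(rng, config)
    events = [
        MtmEvent(config.video_id, item, start, end) for item, start, end in schedule
    ]

    if config.couple_events:
        ease_frames = int(round(config.easing_s * config.fps))
        for item, start, end in schedule:
            side_left = bool(rng.integers(0, 2)) if item in _SIDED else True
            env = _envelope(end - start, ease_frames)[:, np.newaxis]
            for lm, target_body in _item_targets(item, side_left):
                target = _body_to_image(target_body, config)[0]
                cnoise = _ar1(
                    rng, end - start, (2,), config.contact_noise, 0.4, config.fps
                )
                old = pos[start:end, lm].copy()
                new = old + env * (target + cnoise - old)
                delta = new - old
                pos[start:end, lm] = new
                for child, parent in _CHILDREN.items():
                    if parent == lm:
                        pos[start:end, child] += delta

    # hand-held camera: smooth rigid rotation about the image centre + shift
    if config.camera_rot_sd > 0 or config.camera_trans_sd > 0:
        theta = _ar1(rng, n, (), config.camera_rot_sd,
                     config.camera_timescale_s, config.fps)
        trans = _ar1(rng, n, (2,), config.camera_trans_sd,
                     config.camera_timescale_s, config.fps)
        c, s = np.cos(theta), np.sin(theta)
        pivot = np.array([0.5, 0.5])
        rel = pos - pivot
        x, y = rel[..., 0], rel[..., 1]
        pos = np.stack(
            [c[:, None] * x - s[:, None] * y, s[:, None] * x + c[:, None] * y],
            axis=-1,
        ) + pivot + trans[:, np.newaxis, :]

    if config.noise_sigma > 0:
        pos = pos + rng.standard_normal(pos.shape) * config.noise_sigma

    visibility = np.ones((n, N_LANDMARKS))
    if config.dropout_prob > 0:
        visibility[rng.random((n, N_LANDMARKS)) < config.dropout_prob] = 0.0

    series = LandmarkSeries(
        video_id=config.video_id,
        fps=config.fps,
        coords=pos,
        visibility=visibility,
    )
    return SyntheticBundle(series=series, truth_events=events, config=config)


def _default_rates(
    rng: np.random.Generator, lower_show_prob: float
) -> dict[str, float]:
    """Per-video event rates (events/min): roughly half the cohort shows
    lower-limb MTM; upper-limb items (HT most often, as in young infants)
    appear in most videos."""
    rates: dict[str, float] = {}
    if rng.random() < lower_show_prob:
        rates["FF"] = float(rng.uniform(1.5, 3.5))
        if rng.random() < 0.4:
            rates["FL"] = float(rng.uniform(0.3, 0.8))
        if rng.random() < 0.3:
            rates["PEDIPULATION"] = float(rng.uniform(0.2, 0.6))
    if rng.random() < 0.85:
        rates["HT"] = float(rng.uniform(0.5, 2.5))
    if rng.random() < 0.4:
        rates["HH"] = float(rng.uniform(0.3, 1.2))
    if rng.random() < 0.3:
        rates["HM"] = float(rng.uniform(0.2, 0.8))
    if rng.random() < 0.2:
        rates["FIDDLING"] = float(rng.uniform(0.2, 0.6))
    return rates


def make_cohort(
    n_videos: int,
    seed: int = 0,
    coupling: str = "strong",
    duration_s: float = 120.0,
    fps: float = 30.0,
    lower_show_prob: float = 0.5,
    rate_sampler: Optional[Callable[[np.random.Generator], dict[str, float]]] = None,
    **config_overrides,
) -> list[SyntheticBundle]:
    """Generate a cohort of videos with per-video random event burdens.

    ``coupling="strong"`` lets events drive the limbs, so a higher lower-limb
    event burden mechanically yields more time with the ankles at the midline
    and hence smaller mean lower areas — the association emerges from the
    kinematics. ``coupling="none"`` annotates the same event schedules but
    leaves the limbs unaffected: features and labels are then independent,
    the null configuration for calibration.
    """
    if n_videos < 2:
        raise ValueError("a cohort needs at least 2 videos")
    if coupling not in ("strong", "none"):
        raise ValueError(f"unknown coupling {coupling!r}")
    master = np.random.SeedSequence(seed)
    bundles: list[SyntheticBundle] = []
    for i, child_ss in enumerate(master.spawn(n_videos)):
        child_seed = int(child_ss.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child_seed)
        rates = (
            rate_sampler(rng) if rate_sampler is not None
            else _default_rates(rng, lower_show_prob)
        )
        cfg = SyntheticConfig(
            duration_s=duration_s,
            fps=fps,
            seed=child_seed + 1,
            video_id=f"video{i:03d}",
            event_rates=rates,
            couple_events=(coupling == "strong"),
            **config_overrides,
        )
        bundles.append(simulate(cfg))
    return bundles
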