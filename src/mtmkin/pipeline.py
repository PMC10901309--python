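"""End-to-end analysis: landmark CSVs + annotations -> feature, score,
correlation and comparison tables plus a machine-readable run manifest.

Every video found in the landmark directory appears in the manifest exactly
once with a terminal status: ``included``, or ``excluded`` with a categorized
reason (unreadable file, too many invalid frames, no valid frames). The
exclusion rules run before any statistics, so the n in every correlation is
the number of included videos. All outputs are plain CSV / JSON, written
atomically, and byte-identical across reruns on identical inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .errors import (
    FrameGapError,
    InsufficientDataError,
    MalformedFrameError,
    NoDataError,
    PipelineError,
    SchemaError,
)
from .geometry import FeatureConfig, VideoFeatureSummary, summarize_video
from .landmark_io import (
    DEFAULT_VISIBILITY_THRESHOLD,
    MTM_ITEMS,
    read_annotations,
    read_landmark_csv,
)
from .scoring import MtmScore, score_video
from .stats import run_group_comparisons, run_table2

log = logging.getLogger("mtmkin")


@dataclasses.dataclass
class PipelineConfig:
    fps: float = 30.0
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD
    features: FeatureConfig = dataclasses.field(default_factory=FeatureConfig)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _atomic_write_text(text: str, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_to_csv(df: pd.DataFrame, path: Path) -> None:
    _atomic_write_text(df.to_csv(index=False), path)


def features_to_frame(features: Sequence[VideoFeatureSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "video_id": f.video_id,
                "mean_dlm15": f.mean_dlm15,
                "mean_dlm16": f.mean_dlm16,
                "mean_dlm27": f.mean_dlm27,
                "mean_dlm28": f.mean_dlm28,
                "mean_area_whole": f.mean_area_whole,
                "mean_area_upper": f.mean_area_upper,
                "mean_area_lower": f.mean_area_lower,
                "n_valid_frames": f.n_valid_frames,
                "n_frames": f.n_frames,
            }
            for f in features
        ]
    )


def scores_to_frame(scores: Sequence[MtmScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {"video_id": s.video_id}
        row.update({item: s.per_item_seconds.get(item, 0.0) for item in MTM_ITEMS})
        row.update(
            {
                "total_seconds": s.total_seconds,
                "occurrence_percentage": s.occurrence_percentage,
                "rate_total": s.rate_total,
                "rate_lower": s.rate_lower,
                "rate_upper": s.rate_upper,
                "shows_total": s.shows_total,
                "shows_lower": s.shows_lower,
                "shows_upper": s.shows_upper,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def correlations_to_frame(table) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": feat,
                "metric": metric,
                "r": res.r,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "n": res.n,
                "significant": res.significant,
            }
            for (feat, metric), res in table.items()
        ]
    )


def comparisons_to_frame(comps) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in comps])


def run_analysis(
    landmark_dir: str | Path,
    annotation_file: str | Path,
    out_dir: str | Path,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Run the full analysis and write the four tables plus the manifest.

    Returns the manifest as a dict. Raises :class:`PipelineError` when no
    video survives exclusion.
    """
    config = config or PipelineConfig()
    landmark_dir = Path(landmark_dir)
    annotation_file = Path(annotation_file)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    landmark_files = sorted(landmark_dir.glob("*.csv"))
    if not landmark_files:
        raise PipelineError(f"no landmark CSVs found in {landmark_dir}")
    all_events = read_annotations(annotation_file)
    events_by_video: dict[str, list] = {}
    for ev in all_events:
        events_by_video.setdefault(ev.video_id, []).append(ev)

    statuses: list[dict] = []
    features: list[VideoFeatureSummary] = []
    scores: list[MtmScore] = []
    for path in landmark_files:
        video_id = path.stem
        entry = {"video_id": video_id, "file": path.name, "sha256": _sha256(path)}
        try:
            series = read_landmark_csv(
                path,
                fps=config.fps,
                visibility_threshold=config.visibility_threshold,
                video_id=video_id,
            )
            summary = summarize_video(series, config.features)
        except (SchemaError, MalformedFrameError, FrameGapError) as exc:
            entry.update(status="excluded", reason="incomplete-coordinates",
                         detail=str(exc))
            statuses.append(entry)
            log.warning("%s excluded: %s", video_id, exc)
            continue
        except NoDataError as exc:
            entry.update(status="excluded", reason="no-valid-frames", detail=str(exc))
            statuses.append(entry)
            log.warning("%s excluded: %s", video_id, exc)
            continue
        if not summary.usable:
            frac = 1.0 - summary.n_valid_frames / summary.n_frames
            entry.update(
                status="excluded",
                reason="invalid-fraction-exceeded",
                detail=f"{frac:.3f} of frames invalid "
                f"(limit {config.features.max_invalid_fraction})",
            )
            statuses.append(entry)
            log.warning("%s excluded: invalid fraction %.3f", video_id, frac)
            continue
        entry.update(status="included")
        statuses.append(entry)
        features.append(summary)
        scores.append(
            score_video(
                events_by_video.get(video_id, []),
                duration_s=series.duration_s,
                fps=series.fps,
                video_id=video_id,
            )
        )
        log.info("%s: features and score computed", video_id)

    manifest = {
        "software": {"name": "mtmkin", "version": __version__},
        "config": {
            "fps": config.fps,
            "visibility_threshold": config.visibility_threshold,
            "area_norm_exponent": config.features.area_norm_exponent,
            "distance_mode": config.features.distance_mode,
            "max_invalid_fraction": config.features.max_invalid_fraction,
        },
        "annotation_file": {
            "file": annotation_file.name,
            "sha256": _sha256(annotation_file),
        },
        "videos": statuses,
        "n_included": len(features),
        "n_excluded": len(statuses) - len(features),
    }

    if not features:
        _atomic_write_text(
            json.dumps(manifest, indent=2, sort_keys=True), out_dir / "manifest.json"
        )
        raise PipelineError(
            "every video was excluded; see manifest.json for per-video reasons"
        )

    _atomic_to_csv(features_to_frame(features), out_dir / "features.csv")
    _atomic_to_csv(scores_to_frame(scores), out_dir / "scores.csv")

    try:
        table = run_table2(features, scores)
        _atomic_to_csv(correlations_to_frame(table), out_dir / "correlations.csv")
    except InsufficientDataError as exc:
        manifest["correlations"] = f"skipped: {exc}"
        log.warning("correlations skipped: %s", exc)
    comps = run_group_comparisons(features, scores)
    _atomic_to_csv(comparisons_to_frame(comps), out_dir / "comparisons.csv")

    _atomic_write_text(
        json.dumps(manifest, indent=2, sort_keys=True), out_dir / "manifest.json"
    )
    return manifest
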