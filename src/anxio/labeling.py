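"""Anxiety-label assignment and window segmentation.

Five labeling approaches assign low/medium/high anxiety classes to session
time windows:

* ``HR1`` / ``EDA1`` — *clip-based*: the 16 exposure clips are ranked by the
  cohort-mean baseline-normalized signal; the top three clips are 'high',
  the middle three (ranks 7–9) are 'medium', and the last 3 minutes of the
  training-session rest are 'low'.  The clip→label map is identical for
  every subject.
* ``HR2`` / ``EDA2`` — *subject-based*: each subject's own clip ranking
  splits the 16 clips 8/8 into 'high'/'medium'; the entire 5-minute
  training rest is 'low'.
* ``SB`` — *subjective*: only the clip immediately preceding each of the
  four arousal ratings is labeled — ratings 3–4 map to 'high', 1–2 to
  'medium' — and the last 3 minutes of the training rest are 'low'.

Each labeled segment is tiled into non-overlapping windows of 10 or 60
seconds from the segment start; a trailing remainder shorter than the
window is discarded.  Two-level variants simply drop the 'medium' windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import ecg as _ecg
from . import eda as _eda
from .session import Baseline, SessionValidationError, SubjectDataset, compute_baseline

logger = logging.getLogger(__name__)

APPROACHES = ("SB", "HR1", "HR2", "EDA1", "EDA2")
LEVELS_3 = ("low", "medium", "high")

__all__ = [
    "APPROACHES",
    "LabelingConfig",
    "LabeledWindow",
    "segment_windows",
    "clip_signal_means",
    "clip_based_labels",
    "subject_based_labels",
    "subjective_labels",
    "label_windows",
    "rest_span_for",
]


@dataclass(frozen=True)
class LabelingConfig:
    approach: str
    levels: int = 3
    window_s: float = 10.0

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}")
        if self.levels not in (2, 3):
            raise ValueError("levels must be 2 or 3")
        if self.window_s not in (10, 10.0, 60, 60.0):
            raise ValueError("window_s must be 10 or 60 seconds")

    @property
    def signal(self) -> Optional[str]:
        if self.approach in ("HR1", "HR2"):
            return "hr"
        if self.approach in ("EDA1", "EDA2"):
            return "eda"
        return None


@dataclass(frozen=True)
class LabeledWindow:
    subject_id: str
    session_kind: str  # which session the window indexes into
    start: float
    end: float
    label: str
    config: LabelingConfig

    def __post_init__(self) -> None:
        if self.label not in LEVELS_3:
            raise ValueError(f"unknown label {self.label!r}")
        if self.config.levels == 2 and self.label == "medium":
            raise ValueError("two-level window sets contain no 'medium'")

    @property
    def window(self) -> tuple[float, float]:
        return (self.start, self.end)


def rest_span_for(approach: str) -> str:
    """Resting span referenced by an approach: last 3 minutes for the
    clip-based and subjective approaches, the full 5 minutes for the
    subject-based ones."""
    return "full_5min" if approach in ("HR2", "EDA2") else "last_3min"


def segment_windows(
    segments: Iterable[tuple[float, float, str, str]],
    window_s: float,
) -> list[tuple[float, float, str, str]]:
    """Tile labeled segments ``(start, end, label, session_kind)`` into
    non-overlapping windows from each segment's start; remainders shorter
    than ``window_s`` are discarded."""
    out = []
    for start, end, label, kind in segments:
        n = int(np.floor((end - start) / window_s + 1e-9))
        for k in range(n):
            out.append((start + k * window_s, start + (k + 1) * window_s, label, kind))
    return out


def _windows_from_segments(subject_id, segments, config) -> list[LabeledWindow]:
    tiles = segment_windows(segments, config.window_s)
    wins = [
        LabeledWindow(subject_id=subject_id, session_kind=kind, start=s, end=e,
                      label=label, config=config)
        for s, e, label, kind in tiles
        if not (config.levels == 2 and label == "medium")
    ]
    wins.sort(key=lambda w: (w.session_kind, w.start))
    return wins


# ---------------------------------------------------------------------------
# Normalized clip means


def _normalized_clip_means(
    subject: SubjectDataset, signal: str, baseline: Baseline
) -> dict[int, float]:
    """Per-clip mean of the baseline-normalized signal for one subject.

    HR clips use the mean deviation of beat-wise HR from the resting mean;
    EDA clips use the mean range-corrected (Lykken) tonic level.
    """
    layout = subject.exposure.layout
    means: dict[int, float] = {}
    if signal == "hr":
        nni = _ecg.detect_r_peaks(subject.exposure.record("ecg"))
        hr = _ecg.instantaneous_hr(nni)
        for seg in layout.clip_segments():
            vals = hr.in_window((seg.start, seg.end))
            if len(vals):
                means[seg.clip_index] = float(np.mean(vals - baseline.hr_rest_mean))
    elif signal == "eda":
        rec = subject.exposure.record("eda")
        tonic = _eda.tonic_filter(rec)
        rng = baseline.eda_rest_max - baseline.eda_rest_min
        if rng <= 0:
            raise _eda.DegenerateBaselineError(
                f"subject {subject.subject_id}: resting EDA range is zero"
            )
        for seg in layout.clip_segments():
            i0, i1 = rec.index_range(seg.start, seg.end)
            if i1 > i0:
                means[seg.clip_index] = float(
                    np.mean((tonic[i0:i1] - baseline.eda_rest_min) / rng)
                )
    else:
        raise ValueError("signal must be 'hr' or 'eda'")
    return means


def clip_signal_means(
    cohort: Sequence[SubjectDataset],
    signal: str,
    baselines: Optional[dict[str, Baseline]] = None,
    *,
    rest_span: str = "last_3min",
) -> np.ndarray:
    """Cohort-mean baseline-normalized signal per clip (16-vector).

    Subjects missing a clip are excluded from that clip's average (logged).
    """
    if not cohort:
        raise ValueError("clip_signal_means needs at least one subject")
    sums = np.zeros(16)
    counts = np.zeros(16, dtype=int)
    for subject in cohort:
        base = (baselines or {}).get(subject.subject_id) or compute_baseline(subject, rest_span)
        means = _normalized_clip_means(subject, signal, base)
        for clip in range(1, 17):
            if clip in means:
                sums[clip - 1] += means[clip]
                counts[clip - 1] += 1
            else:
                logger.warning("subject %s missing clip %d; averaged over the rest",
                               subject.subject_id, clip)
    if np.any(counts == 0):
        raise SessionValidationError("some clips are missing from every subject")
    return sums / counts


def _rank_clips(values: dict[int, float]) -> list[int]:
    """Clip indices sorted by descending value; ties broken by ascending clip index."""
    items = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    vals = [v for _, v in items]
    if len(set(vals)) != len(vals):
        logger.info("clip ranking ties broken by ascending clip index")
    return [c for c, _ in items]


def _rest_window(subject: SubjectDataset, approach: str) -> tuple[float, float]:
    span = 300.0 if rest_span_for(approach) == "full_5min" else 180.0
    rest = subject.training.layout.rest_segment()
    if rest.duration + 1e-9 < span:
        raise SessionValidationError(
            f"training rest of {rest.duration:.0f} s shorter than the {span:.0f} s the "
            f"{approach} approach requires"
        )
    return (rest.end - span, rest.end)


# ---------------------------------------------------------------------------
# The labeling approaches


def clip_based_labels(
    cohort: Sequence[SubjectDataset],
    config: LabelingConfig,
    baselines: Optional[dict[str, Baseline]] = None,
) -> list[LabeledWindow]:
    """Clip-based (HR1/EDA1) labels: one cohort-level clip→label map applied
    to every subject.  Top-3 ranked clips are 'high', ranks 7–9 'medium',
    last 3 rest minutes 'low'."""
    if config.approach not in ("HR1", "EDA1"):
        raise ValueError("clip_based_labels requires approach HR1 or EDA1")
    means = clip_signal_means(cohort, config.signal, baselines,
                              rest_span=rest_span_for(config.approach))
    ranking = _rank_clips({c + 1: means[c] for c in range(16)})
    high = set(ranking[:3])
    medium = set(ranking[6:9])

    windows: list[LabeledWindow] = []
    for subject in cohort:
        segments = []
        for seg in subject.exposure.layout.clip_segments():
            if seg.clip_index in high:
                segments.append((seg.start, seg.end, "high", "exposure"))
            elif seg.clip_index in medium:
                segments.append((seg.start, seg.end, "medium", "exposure"))
        lo = _rest_window(subject, config.approach)
        segments.append((lo[0], lo[1], "low", "training"))
        windows.extend(_windows_from_segments(subject.subject_id, segments, config))
    return windows


def subject_based_labels(
    subject: SubjectDataset,
    config: LabelingConfig,
    baseline: Optional[Baseline] = None,
) -> list[LabeledWindow]:
    """Subject-based (HR2/EDA2) labels: the subject's own 8/8 clip split plus
    the full 5-minute rest as 'low'."""
    if config.approach not in ("HR2", "EDA2"):
        raise ValueError("subject_based_labels requires approach HR2 or EDA2")
    clips = subject.exposure.layout.clip_segments()
    if len(clips) < 16:
        raise SessionValidationError(
            f"subject {subject.subject_id}: 8/8 split undefined with "
            f"{len(clips)} of 16 clips"
        )
    base = baseline or compute_baseline(subject, rest_span_for(config.approach))
    means = _normalized_clip_means(subject, config.signal, base)
    if len(means) < 16:
        raise SessionValidationError(
            f"subject {subject.subject_id}: no signal in some clips; 8/8 split undefined"
        )
    ranking = _rank_clips(means)
    high = set(ranking[:8])

    segments = []
    for seg in clips:
        label = "high" if seg.clip_index in high else "medium"
        segments.append((seg.start, seg.end, label, "exposure"))
    lo = _rest_window(subject, config.approach)
    segments.append((lo[0], lo[1], "low", "training"))
    return _windows_from_segments(subject.subject_id, segments, config)


RATING_LABELS = {1: "medium", 2: "medium", 3: "high", 4: "high"}


def subjective_labels(subject: SubjectDataset, config: LabelingConfig) -> list[LabeledWindow]:
    """Subjective (SB) labels from the four arousal ratings.

    Only the clip right before each rating is labeled; missing ratings leave
    that clip unlabeled (logged), so counts may be unbalanced."""
    if config.approach != "SB":
        raise ValueError("subjective_labels requires approach SB")
    layout = subject.exposure.layout
    segments = []
    rated = {r.after_clip_index: r for r in layout.ratings}
    for clip_index in (4, 8, 12, 16):
        rating = rated.get(clip_index)
        seg = layout.clip_segment(clip_index)
        if rating is None or seg is None:
            logger.warning("subject %s: no rating after clip %d; clip unlabeled",
                           subject.subject_id, clip_index)
            continue
        segments.append((seg.start, seg.end, RATING_LABELS[rating.value], "exposure"))
    lo = _rest_window(subject, "SB")
    segments.append((lo[0], lo[1], "low", "training"))
    windows = _windows_from_segments(subject.subject_id, segments, config)
    if config.levels == 2 and not any(w.label == "high" for w in windows):
        logger.warning("subject %s: SB two-level set degenerate (no 'high' windows)",
                       subject.subject_id)
    return windows


def label_windows(
    cohort: Sequence[SubjectDataset],
    config: LabelingConfig,
    baselines: Optional[dict[str, Baseline]] = None,
) -> list[LabeledWindow]:
    """Dispatch to the approach-specific labeler for a whole cohort."""
    if config.approach in ("HR1", "EDA1"):
        return clip_based_labels(cohort, config, baselines)
    out: list[LabeledWindow] = []
    for subject in cohort:
        if config.approach in ("HR2", "EDA2"):
            base = (baselines or {}).get(subject.subject_id)
            out.extend(subject_based_labels(subject, config, base))
        else:
            out.extend(subjective_labels(subject, config))
    return out
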